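"""Seeded synthetic genotype/phenotype/covariate datasets with known truth.

Emulates a quantitative-trait association study at desk scale: additive
dosages drawn in Hardy-Weinberg proportions (Binomial(2, f) per variant,
allele frequency uniform over a MAF range), a small covariate block, and
phenotypes built as a sparse linear genetic signal plus covariate effects
plus Gaussian noise.  No linkage disequilibrium or population structure is
simulated — the regression algebra under test is insensitive to both.

Datasets can be partitioned into virtual sites to exercise the multi-cohort
exchange protocol without any real multi-center data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import CovariateMatrix, with_intercept
from .store import (SampleIndex, VariantIndex, write_covariate_store,
                    write_genotype_store, write_phenotype_store)


class SimulationError(Exception):
    pass


#: default covariate block beyond the intercept: one uniform (age-like,
#: standardized to [0,1]) and one binary (sex-like) covariate, for a total
#: design of n_c = 4 columns once the tested variant is appended.
DEFAULT_COVARIATES = (("age", "uniform"), ("sex", "binary"))


@dataclass
class SimulationConfig:
    """Study-design parameters of one synthetic dataset."""

    n_i: int = 200
    n_t: int = 100
    n_p: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    effects: tuple[tuple[int, int, float], ...] = ()  # (variant, phenotype, beta)
    noise_sd: float = 1.0
    covariate_spec: tuple[tuple[str, str], ...] = DEFAULT_COVARIATES
    seed: int = 0
    n_sites: int = 1
    site_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if min(self.n_i, self.n_t, self.n_p) < 1:
            raise SimulationError("n_i, n_t, n_p must all be >= 1")
        for v, p, b in self.effects:
            if not (0 <= v < self.n_t and 0 <= p < self.n_p):
                raise SimulationError(f"effect index ({v}, {p}) out of range")
        if self.n_sites < 1:
            raise SimulationError("n_sites must be >= 1")
        if self.site_fractions is not None:
            if len(self.site_fractions) != self.n_sites:
                raise SimulationError("site_fractions length != n_sites")
            if abs(sum(self.site_fractions) - 1.0) > 1e-9:
                raise SimulationError("site_fractions must sum to 1")

    @property
    def n_c(self) -> int:
        """Design width per test: intercept + covariates + tested variant."""
        return 1 + len(self.covariate_spec) + 1


@dataclass
class SimulatedData:
    """In-memory dataset plus ground truth."""

    G: np.ndarray               # n_i x n_t dosages
    Y: np.ndarray               # n_i x n_p phenotypes
    Z: CovariateMatrix          # n_i x (n_c - 1), intercept first
    samples: SampleIndex
    variants: VariantIndex
    phenotype_ids: tuple[str, ...]
    truth: pd.DataFrame         # variant_id, phenotype_id, beta
    gamma: np.ndarray           # covariate effects, (n_c - 1) x n_p
    allele_freq: np.ndarray     # simulated f per variant


def _draw_covariate(rng: np.random.Generator, kind: str, n: int) -> np.ndarray:
    if kind == "constant":
        return np.ones(n)
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if kind == "binary":
        return rng.binomial(1, 0.5, n).astype(np.float64)
    raise SimulationError(f"unknown covariate kind {kind!r}")


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Generate one dataset, fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_t)
    G = rng.binomial(2, freq[None, :], (cfg.n_i, cfg.n_t)).astype(np.float64)

    cov_cols = [_draw_covariate(rng, kind, cfg.n_i)
                for _, kind in cfg.covariate_spec]
    names = [name for name, _ in cfg.covariate_spec]
    Z = with_intercept(np.column_stack(cov_cols) if cov_cols
                       else np.empty((cfg.n_i, 0)), names)

    gamma = rng.standard_normal((Z.Z.shape[1], cfg.n_p))
    B = np.zeros((cfg.n_t, cfg.n_p))
    for v, p, b in cfg.effects:
        B[v, p] += b
    Y = G @ B + Z.Z @ gamma + rng.normal(0.0, cfg.noise_sd, (cfg.n_i, cfg.n_p))

    samples = SampleIndex(tuple(f"S{i:06d}" for i in range(cfg.n_i)))
    variants = VariantIndex(
        ids=tuple(f"rs{j + 1}" for j in range(cfg.n_t)),
        chrom=("1",) * cfg.n_t,
        pos=np.arange(1, cfg.n_t + 1, dtype=np.int64) * 1000,
        ref=("A",) * cfg.n_t, alt=("G",) * cfg.n_t)
    phenotype_ids = tuple(f"pheno{p + 1}" for p in range(cfg.n_p))

    truth = pd.DataFrame(
        [(variants.ids[v], phenotype_ids[p], b) for v, p, b in cfg.effects],
        columns=["variant_id", "phenotype_id", "beta"])
    return SimulatedData(G=G, Y=Y, Z=Z, samples=samples, variants=variants,
                         phenotype_ids=phenotype_ids, truth=truth,
                         gamma=gamma, allele_freq=freq)


def site_sizes(n: int, fractions: Sequence[float]) -> tuple[int, ...]:
    """Largest-remainder apportionment of n rows to len(fractions) sites."""
    exact = np.asarray(fractions, dtype=np.float64) * n
    base = np.floor(exact).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    return tuple(int(x) for x in base)


def split_sites(data: SimulatedData, cfg: SimulationConfig
                ) -> list[tuple[np.ndarray, np.ndarray, CovariateMatrix, SampleIndex]]:
    """Partition rows into contiguous disjoint blocks, one per site.

    Returns per-site (G, Y, Z, samples).  Sites smaller than the design
    width n_c cannot fit the model and raise an error.
    """
    fractions = cfg.site_fractions or (1.0 / cfg.n_sites,) * cfg.n_sites
    sizes = site_sizes(cfg.n_i, fractions)
    if min(sizes) < cfg.n_c:
        raise SimulationError(
            f"site of {min(sizes)} rows cannot fit {cfg.n_c} design columns")
    out = []
    start = 0
    for size in sizes:
        rows = slice(start, start + size)
        out.append((data.G[rows], data.Y[rows],
                    CovariateMatrix(data.Z.Z[rows], data.Z.names),
                    SampleIndex(data.samples.ids[rows])))
        start += size
    return out


def save_dataset(data: SimulatedData, out_dir: str | os.PathLike,
                 chunk_shape: tuple[int, int] = (1000, 1000),
                 provenance: dict | None = None,
                 provenance_line: str | None = None) -> dict[str, str]:
    """Write genotype/phenotype/covariate stores and truth.tsv to a directory."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotype": os.path.join(out_dir, "genotype.h5"),
        "phenotype": os.path.join(out_dir, "phenotype.h5"),
        "covariates": os.path.join(out_dir, "covariates.h5"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_genotype_store(paths["genotype"], data.G, data.samples,
                         data.variants, chunk_shape, provenance)
    write_phenotype_store(paths["phenotype"], data.Y, data.samples,
                          data.phenotype_ids, chunk_shape, provenance)
    write_covariate_store(paths["covariates"], data.Z.Z, data.samples,
                          data.Z.names, provenance)
    with open(paths["truth"], "w") as fh:
        if provenance_line:
            fh.write(f"# {provenance_line}\n")
        data.truth.to_csv(fh, sep="\t", index=False)
    return paths
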