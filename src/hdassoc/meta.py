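"""Pooled-equivalent meta-analysis via partial derivatives and matrix encoding.

A consortium of K cohorts can reproduce the exact association statistics of
an analysis of the pooled individual-level data by exchanging only the OLS
sufficient statistics: each block of (a1, a2, a3, b_cov, C) is additive over
row-partitions of the sample, so the central site simply sums them.

The remaining block, b4 = Y'G, has n_p x n_t entries and dominates transfer
size in high-dimensional studies (10^6 phenotypes x 10^7 variants is 10^13
values).  Instead of shipping it, each site draws a random nonsingular
n_i x n_i matrix F and transfers the encoded pair

    Y_F = F' Y        (n_i x n_p)
    G_F = F^-1 G      (n_i x n_t)

whose product Y_F' G_F = Y' F F^-1 G = Y'G recovers b4 exactly, while the
payload grows additively, O(n_i (n_p + n_t)).  F never leaves the site:
without it neither Y nor G can be reconstructed from the encoded pair, so
no individual-level rows are exchanged.

The central site sums derivatives, decodes b4 per site, and runs the same
block solver as a single-site analysis with df = (sum_k n_k) - n_c.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import h5py
import numpy as np

from .regression import (AnalysisConfig, CovariateMatrix, PartialDerivatives,
                         RegressionError, build_partial_derivatives, maf_mask,
                         solve_block)
from .store import ResultRecord, VariantIndex, ids_digest

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
#: encodings with a 2-norm condition number above this are redrawn
CONDITION_LIMIT = 1e6
_STR = h5py.string_dtype(encoding="utf-8")


class MetaError(Exception):
    pass


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodingMatrix:
    """Site-private random nonsingular encoding F and its inverse."""

    F: np.ndarray
    F_inv: np.ndarray
    seed: int
    condition_estimate: float


@dataclass
class EncodedData:
    """Phenotype/determinant information in encoded form; Y_F'G_F = Y'G."""

    Y_F: np.ndarray
    G_F: np.ndarray


def generate_encoding(n_i: int, seed: int) -> EncodingMatrix:
    """Draw F with i.i.d. standard-normal entries, seeded and reproducible.

    Gaussian square matrices are almost surely nonsingular; a condition
    guard (redraw from the next substream while cond(F) > 1e6) bounds the
    round-off in the decoded product.  An orthogonal F would condition
    perfectly but leak the Gram matrices Y'Y and G'G, so it is not used.
    """
    if n_i < 1:
        raise MetaError("need at least one sample to build an encoding")
    ss = np.random.SeedSequence(seed)
    for attempt in range(64):
        rng = np.random.default_rng(ss.spawn(1)[0] if attempt else ss)
        F = rng.standard_normal((n_i, n_i))
        cond = float(np.linalg.cond(F))
        if cond < CONDITION_LIMIT:
            return EncodingMatrix(F=F, F_inv=np.linalg.inv(F), seed=seed,
                                  condition_estimate=cond)
        ss = ss.spawn(1)[0]
    raise MetaError("could not draw a well-conditioned encoding matrix")


def encode(Y: np.ndarray, G: np.ndarray, enc: EncodingMatrix) -> EncodedData:
    """Encode phenotypes and determinants: Y_F = F'Y, G_F = F^-1 G."""
    Y = np.asarray(Y, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    n_i = enc.F.shape[0]
    if Y.shape[0] != n_i or G.shape[0] != n_i:
        raise MetaError(f"row counts ({Y.shape[0]}, {G.shape[0]}) != encoding "
                        f"size {n_i}")
    return EncodedData(Y_F=enc.F.T @ Y, G_F=enc.F_inv @ G)


def decode_b4(encoded: EncodedData, chunk_variants: int = 1000) -> np.ndarray:
    """Central-site reconstruction b4 = Y_F'G_F, in variant chunks."""
    n_t = encoded.G_F.shape[1]
    n_p = encoded.Y_F.shape[1]
    out = np.empty((n_p, n_t))
    for start in range(0, n_t, max(1, chunk_variants)):
        sl = slice(start, min(start + max(1, chunk_variants), n_t))
        out[:, sl] = encoded.Y_F.T @ encoded.G_F[:, sl]
    return out


# ---------------------------------------------------------------------------
# site packages
# ---------------------------------------------------------------------------

#: datasets a serialized package may contain — and nothing else
PACKAGE_DATASETS = ("a1", "a2", "a3", "b_cov", "C", "Y_F", "G_F")


@dataclass
class SitePackage:
    """Everything a cohort transfers: aggregate derivatives + encoded pair.

    Contains no raw Y, G or Z rows and never the encoding matrix F.
    """

    derivatives: PartialDerivatives
    encoded: EncodedData
    site_id: str
    covariate_names: tuple[str, ...]
    n_c: int
    variant_index: VariantIndex
    phenotype_ids: tuple[str, ...]

    @property
    def variant_digest(self) -> str:
        return self.variant_index.digest()

    @property
    def phenotype_digest(self) -> str:
        return ids_digest(self.phenotype_ids)


def build_site_package(Z: CovariateMatrix, Y: np.ndarray, G: np.ndarray,
                       seed: int, site_id: str,
                       variant_index: VariantIndex,
                       phenotype_ids: Sequence[str]) -> SitePackage:
    """Compute a cohort's transfer package from aligned, imputed matrices.

    The encoding matrix exists only inside this call; it is discarded as
    soon as the encoded pair is formed.
    """
    Y = np.asarray(Y, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    deriv = build_partial_derivatives(Z, Y, G)
    enc = generate_encoding(Z.n_samples, seed)
    encoded = encode(Y, G, enc)
    del enc  # F and F_inv never persist beyond this frame
    return SitePackage(derivatives=deriv, encoded=encoded, site_id=str(site_id),
                       covariate_names=Z.names, n_c=Z.n_c,
                       variant_index=variant_index,
                       phenotype_ids=tuple(phenotype_ids))


def save_site_package(pkg: SitePackage, path: str | os.PathLike,
                      provenance: dict | None = None) -> None:
    from . import __version__

    d, e = pkg.derivatives, pkg.encoded
    with h5py.File(path, "w") as f:
        for name, arr in zip(PACKAGE_DATASETS,
                             (d.a1, d.a2, d.a3, d.b_cov, d.C, e.Y_F, e.G_F)):
            f.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
        m = f.create_group("metadata")
        v = pkg.variant_index
        m.create_dataset("variant_id", data=np.array(v.ids, dtype=_STR))
        m.create_dataset("variant_chrom", data=np.array(v.chrom, dtype=_STR))
        m.create_dataset("variant_pos", data=np.asarray(v.pos, dtype=np.int64))
        m.create_dataset("variant_ref", data=np.array(v.ref, dtype=_STR))
        m.create_dataset("variant_alt", data=np.array(v.alt, dtype=_STR))
        m.create_dataset("phenotype_ids", data=np.array(pkg.phenotype_ids, dtype=_STR))
        f.attrs["site_id"] = pkg.site_id
        f.attrs["n_samples"] = d.n_samples
        f.attrs["n_c"] = pkg.n_c
        f.attrs["covariate_names"] = json.dumps(list(pkg.covariate_names))
        f.attrs["variant_digest"] = pkg.variant_digest
        f.attrs["phenotype_digest"] = pkg.phenotype_digest
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["hdassoc_version"] = __version__
        for k, val in (provenance or {}).items():
            f.attrs[str(k)] = val


def load_site_package(path: str | os.PathLike) -> SitePackage:
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("format_version", -1)) != FORMAT_VERSION:
            raise MetaError(f"{path}: unsupported package format version")
        arrs = {name: np.asarray(f[name][()], dtype=np.float64)
                for name in PACKAGE_DATASETS}
        m = f["metadata"]
        dec = lambda xs: tuple(x.decode() if isinstance(x, bytes) else x for x in xs)
        vix = VariantIndex(ids=dec(m["variant_id"][:]),
                           chrom=dec(m["variant_chrom"][:]),
                           pos=np.asarray(m["variant_pos"][:], dtype=np.int64),
                           ref=dec(m["variant_ref"][:]),
                           alt=dec(m["variant_alt"][:]))
        pids = dec(m["phenotype_ids"][:])
        deriv = PartialDerivatives(a1=arrs["a1"], a2=arrs["a2"], a3=arrs["a3"],
                                   b_cov=arrs["b_cov"], C=arrs["C"],
                                   n_samples=int(f.attrs["n_samples"]))
        return SitePackage(
            derivatives=deriv,
            encoded=EncodedData(Y_F=arrs["Y_F"], G_F=arrs["G_F"]),
            site_id=str(f.attrs["site_id"]), n_c=int(f.attrs["n_c"]),
            covariate_names=tuple(json.loads(f.attrs["covariate_names"])),
            variant_index=vix, phenotype_ids=pids)


def package_manifest(path: str | os.PathLike) -> tuple[str, ...]:
    """Names of every dataset in a serialized package (privacy audit surface)."""
    names: list[str] = []
    with h5py.File(path, "r") as f:
        f.visititems(lambda name, obj: names.append(name)
                     if isinstance(obj, h5py.Dataset) else None)
    return tuple(sorted(names))


# ---------------------------------------------------------------------------
# central site
# ---------------------------------------------------------------------------

@dataclass
class MergedDerivatives:
    """Componentwise sums over sites, with b4 decoded and summed."""

    derivatives: PartialDerivatives  # summed a1..C, n_samples = total n
    b4: np.ndarray
    total_n: int
    n_sites: int
    n_c: int
    covariate_names: tuple[str, ...]
    variant_index: VariantIndex
    phenotype_ids: tuple[str, ...]


def merge_sites(packages: Sequence[SitePackage],
                chunk_variants: int = 1000) -> MergedDerivatives:
    """Sum per-site derivatives; decode and sum b4 = sum_k Y_F,k' G_F,k.

    All packages must agree on covariate names and on the variant and
    phenotype manifests (compared by digest).
    """
    if not packages:
        raise MetaError("no site packages to merge")
    ref = packages[0]
    seen: set[str] = set()
    for pkg in packages:
        if pkg.site_id in seen:
            raise MetaError(f"duplicate site id {pkg.site_id!r}")
        seen.add(pkg.site_id)
        if pkg.covariate_names != ref.covariate_names:
            raise MetaError(f"site {pkg.site_id!r}: covariate names "
                            f"{pkg.covariate_names} != {ref.covariate_names}")
        if pkg.variant_digest != ref.variant_digest:
            raise MetaError(f"site {pkg.site_id!r}: variant manifest differs")
        if pkg.phenotype_digest != ref.phenotype_digest:
            raise MetaError(f"site {pkg.site_id!r}: phenotype manifest differs")

    a1 = sum(p.derivatives.a1 for p in packages)
    a2 = sum(p.derivatives.a2 for p in packages)
    a3 = sum(p.derivatives.a3 for p in packages)
    b_cov = sum(p.derivatives.b_cov for p in packages)
    C = sum(p.derivatives.C for p in packages)
    b4 = sum(decode_b4(p.encoded, chunk_variants) for p in packages)
    total_n = sum(p.derivatives.n_samples for p in packages)

    merged = PartialDerivatives(a1=a1, a2=a2, a3=a3, b_cov=b_cov, C=C,
                                n_samples=total_n)
    return MergedDerivatives(derivatives=merged, b4=b4, total_n=total_n,
                             n_sites=len(packages), n_c=ref.n_c,
                             covariate_names=ref.covariate_names,
                             variant_index=ref.variant_index,
                             phenotype_ids=ref.phenotype_ids)


def run_meta(merged: MergedDerivatives,
             config: AnalysisConfig | None = None) -> Iterator[ResultRecord]:
    """Solve the pooled-equivalent regressions from merged derivatives.

    Identical algebra to the single-site block solver, with
    df = total_n - n_c: the virtual pooled sample fits one model.
    """
    config = config or AnalysisConfig()
    df = merged.total_n - merged.n_c
    if df <= 0:
        raise RegressionError(f"meta df = {merged.total_n} - {merged.n_c} <= 0")

    d = merged.derivatives
    keep = np.ones(d.n_variants, dtype=bool)
    if config.maf_min > 0:
        # first covariate is the intercept, so a2[:, 0] = sum of dosages
        freq = d.a2[:, 0] / (2.0 * merged.total_n)
        keep = maf_mask(freq, config.maf_min)

    vix = merged.variant_index
    pids = merged.phenotype_ids
    n_filtered = int(np.sum(~keep))
    n_singular = n_perfect = 0
    for vsl in _chunk_slices(d.n_variants, config.chunk_variants):
        cols = np.flatnonzero(keep[vsl]) + vsl.start
        if cols.size == 0:
            continue
        sub = PartialDerivatives(a1=d.a1, a2=d.a2[cols], a3=d.a3[cols],
                                 b_cov=d.b_cov, C=d.C, n_samples=merged.total_n)
        stats = solve_block(sub, merged.b4[:, cols], df)
        n_singular += stats.n_singular
        n_perfect += stats.n_perfect
        for j, v in enumerate(cols):
            for i, pid in enumerate(pids):
                p = stats.p[i, j]
                if not np.isnan(p) and p > config.p_threshold:
                    continue
                yield ResultRecord(
                    phenotype_id=pid, variant_id=vix.ids[v],
                    chrom=vix.chrom[v], pos=int(vix.pos[v]), ref=vix.ref[v],
                    alt=vix.alt[v], n=merged.total_n,
                    beta=float(stats.beta[i, j]), se=float(stats.se[i, j]),
                    t=float(stats.t[i, j]), p=float(p), df=df)
    logger.info("meta run complete: %d site(s), %d variant(s) MAF-filtered, "
                "%d singular, %d perfect-fit",
                merged.n_sites, n_filtered, n_singular, n_perfect)


def _chunk_slices(n: int, size: int) -> Iterator[slice]:
    for start in range(0, n, max(1, size)):
        yield slice(start, min(start + max(1, size), n))
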