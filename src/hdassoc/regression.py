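"""Exact mass-univariate OLS with the redundancy-eliminating block decomposition.

Every association fits the same model

    y_p = Z gamma + g_t beta + eps,        eps ~ N(0, sigma^2 I)

for each of n_p phenotypes crossed with n_t tested determinants (variant
dosages), sharing the covariate block Z (intercept first).  Writing
X_t = [Z | g_t], the normal-equations matrix

    A_t = X_t' X_t = [[ Z'Z    Z'g_t ],
                      [ g_t'Z  g_t'g_t ]]

has a covariate-only block a1 = Z'Z that is identical across all n_t
variants and is computed once; only the border (a2_t = Z'g_t, a3_t =
g_t'g_t) varies.  Likewise the right-hand side splits into b_cov = Z'Y
(computed once) and b4 = Y'G (one dot product per phenotype x variant
pair).  With C_p = y_p'y_p, every beta, standard error, t and p follows
from (a1, a2, a3, b_cov, b4, C) by small-matrix algebra, removing the
per-pair regression loop entirely: the per-pair cost collapses from a full
n_i-row least-squares solve to O(1) arithmetic on precomputed products.

These six quantities are also exactly the sufficient statistics a cohort
must share for a pooled-equivalent meta-analysis (see ``hdassoc.meta``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sstats

from .store import (CovariateStore, GenotypeStore, PhenotypeStore,
                    ResultRecord, SampleIndex, align_samples)

logger = logging.getLogger(__name__)

#: relative eigenvalue ratio below which A_t is declared numerically singular
SINGULAR_RTOL = 1e-10


class RegressionError(Exception):
    pass


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateMatrix:
    """Covariate design block Z (n_i x (n_c - 1)); first column all ones.

    n_c counts the intercept, the measured covariates, and the tested
    determinant, so Z holds n_c - 1 columns.
    """

    Z: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2 or self.Z.shape[1] != len(self.names):
            raise RegressionError("covariate matrix / name length mismatch")
        if not np.all(np.isfinite(self.Z)):
            raise RegressionError("covariate matrix contains non-finite values")
        if not np.allclose(self.Z[:, 0], 1.0):
            raise RegressionError("first covariate column must be the intercept (all ones)")
        _check_full_rank(self.Z, self.names)

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_c(self) -> int:
        """Total covariate count of the per-variant design, incl. determinant."""
        return self.Z.shape[1] + 1


def with_intercept(values: np.ndarray, names: Sequence[str]) -> CovariateMatrix:
    """Prepend an intercept column unless one is already present."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if values.shape[1] and np.allclose(values[:, 0], 1.0):
        return CovariateMatrix(values, tuple(names))
    ones = np.ones((values.shape[0], 1))
    return CovariateMatrix(np.hstack([ones, values]),
                           ("intercept", *names))


def _check_full_rank(Z: np.ndarray, names: Sequence[str]) -> None:
    # QR with column pivoting localises the collinear columns for the error
    r_diag = np.abs(np.diag(np.linalg.qr(Z, mode="r")))
    if r_diag.size == 0:
        raise RegressionError("empty covariate matrix")
    bad = r_diag < r_diag.max() * 1e-10
    if np.any(bad):
        culprits = [names[j] for j in np.flatnonzero(bad)]
        raise RegressionError(
            f"covariate matrix is rank deficient; collinear column(s): {culprits}")


# ---------------------------------------------------------------------------
# partial derivatives (sufficient statistics)
# ---------------------------------------------------------------------------

@dataclass
class PartialDerivatives:
    """Sufficient statistics of the block decomposition.

    a1     : (n_c-1, n_c-1)  = Z'Z
    a2     : (n_t, n_c-1)    row t = Z'g_t
    a3     : (n_t,)          entry t = g_t'g_t
    b_cov  : (n_c-1, n_p)    = Z'Y
    C      : (n_p,)          diag of Y'Y
    """

    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    b_cov: np.ndarray
    C: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        nz = self.a1.shape[0]
        if self.a1.shape != (nz, nz) or not np.allclose(self.a1, self.a1.T):
            raise RegressionError("a1 must be square symmetric (Z'Z)")
        if self.a2.shape[1] != nz or self.b_cov.shape[0] != nz:
            raise RegressionError("a2/b_cov width inconsistent with a1")
        if self.a3.shape != (self.a2.shape[0],):
            raise RegressionError("a3 length inconsistent with a2")
        if np.any(self.a3 < -1e-9) or np.any(self.C < -1e-9):
            raise RegressionError("sum-of-squares terms must be nonnegative")

    @property
    def n_variants(self) -> int:
        return self.a2.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.b_cov.shape[1]


def compute_a1(Z: CovariateMatrix) -> np.ndarray:
    """Z'Z — depends only on covariates, so computed once per study."""
    return Z.Z.T @ Z.Z


def compute_a2_a3(Z: CovariateMatrix, G_chunk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant border of A_t: a2[t] = Z'g_t, a3[t] = g_t'g_t."""
    G_chunk = np.asarray(G_chunk, dtype=np.float64)
    if G_chunk.shape[0] != Z.n_samples:
        raise RegressionError(
            f"genotype rows {G_chunk.shape[0]} != covariate rows {Z.n_samples}")
    a2 = G_chunk.T @ Z.Z
    a3 = np.einsum("ij,ij->j", G_chunk, G_chunk)
    return a2, a3


def compute_b_cov(Z: CovariateMatrix, Y: np.ndarray) -> np.ndarray:
    """Covariate-phenotype products Z'Y ((n_c-1) x n_p)."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != Z.n_samples:
        raise RegressionError("phenotype rows do not match covariate rows")
    return Z.Z.T @ Y


def compute_c(Y: np.ndarray) -> np.ndarray:
    """Per-phenotype total sum of squares y_p'y_p."""
    Y = np.asarray(Y, dtype=np.float64)
    return np.einsum("ij,ij->j", Y, Y)


def compute_b4(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Determinant-phenotype products Y'G (n_p x n_t) — the single-site path.

    In a multi-site study this is the block reconstructed centrally from the
    encoded matrices instead of being computed from raw data.
    """
    return np.asarray(Y, dtype=np.float64).T @ np.asarray(G, dtype=np.float64)


def build_partial_derivatives(Z: CovariateMatrix, Y: np.ndarray,
                              G: np.ndarray) -> PartialDerivatives:
    """All site-side sufficient statistics except b4 in one call."""
    a2, a3 = compute_a2_a3(Z, G)
    return PartialDerivatives(a1=compute_a1(Z), a2=a2, a3=a3,
                              b_cov=compute_b_cov(Z, Y), C=compute_c(Y),
                              n_samples=Z.n_samples)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class AssociationStats:
    """Statistics of the tested determinant for a phenotype x variant block.

    All arrays are n_p x n_t.  ``na_mask`` marks degenerate fits (singular
    design or perfect fit); their beta/se/t/p are NaN.  When requested,
    ``beta_all``/``se_all``/``t_all`` additionally carry the statistics of
    every covariate, shaped n_c x n_p x n_t.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    na_mask: np.ndarray
    n_singular: int = 0
    n_perfect: int = 0
    beta_all: np.ndarray | None = None
    se_all: np.ndarray | None = None
    t_all: np.ndarray | None = None


def t_to_p(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Two-sided p-value of a t-statistic: p = 2 S(|t|; df)."""
    if df < 1:
        raise RegressionError(f"df must be >= 1, got {df}")
    return 2.0 * sstats.t.sf(np.abs(t), df)


def solve_block(pd_: PartialDerivatives, b4_block: np.ndarray, df: int,
                all_covariates: bool = False) -> AssociationStats:
    """Assemble and solve the per-variant normal equations for a block.

    For variant t and phenotype p:

        A_t  = [[a1, a2_t'], [a2_t, a3_t]]
        B_pt = [b_cov[:, p]; b4[p, t]]
        beta_hat = A_t^-1 B_pt
        RSS      = C_p - B_pt' A_t^-1 B_pt      (clamped at 0)
        se_j     = sqrt(RSS/df * [A_t^-1]_jj)

    Vectorized over phenotypes and variants; no per-combination loop.
    A_t whose eigenvalue ratio falls below ``SINGULAR_RTOL`` (monomorphic or
    covariate-collinear variant) yields NA.  Perfect fits (se = 0) yield NA
    with a separate flag rather than an infinite t.
    """
    if df <= 0:
        raise RegressionError(f"nonpositive degrees of freedom: {df}")
    b4_block = np.asarray(b4_block, dtype=np.float64)
    n_p, n_t = pd_.n_phenotypes, pd_.n_variants
    if b4_block.shape != (n_p, n_t):
        raise RegressionError(f"b4 block shape {b4_block.shape} != ({n_p}, {n_t})")
    nz = pd_.a1.shape[0]
    n_c = nz + 1

    A = np.empty((n_t, n_c, n_c))
    A[:, :nz, :nz] = pd_.a1
    A[:, nz, :nz] = pd_.a2
    A[:, :nz, nz] = pd_.a2
    A[:, nz, nz] = pd_.a3

    eig = np.linalg.eigvalsh(A)
    emax = np.abs(eig).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(eig).min(axis=1) / emax
    ok = (emax > 0) & (ratio >= SINGULAR_RTOL)
    n_singular = int(n_t - ok.sum())

    beta = np.full((n_p, n_t), np.nan)
    se = np.full((n_p, n_t), np.nan)
    tt = np.full((n_p, n_t), np.nan)
    pp = np.full((n_p, n_t), np.nan)
    na = np.ones((n_p, n_t), dtype=bool)
    full = None

    n_perfect = 0
    if np.any(ok):
        Ainv = np.linalg.inv(A[ok])                      # (k, n_c, n_c)
        B = np.empty((int(ok.sum()), n_c, n_p))
        B[:, :nz, :] = pd_.b_cov[None, :, :]
        B[:, nz, :] = b4_block[:, ok].T
        beta_full = Ainv @ B                             # (k, n_c, n_p)
        rss = pd_.C[None, :] - np.einsum("kcp,kcp->kp", B, beta_full)
        # RSS within round-off of zero (relative to the total SS) is a
        # perfect fit: clamp it to exactly zero before dividing
        rss_tol = np.maximum(pd_.C, 0.0) * 1e-12
        perfect = rss <= rss_tol[None, :]
        rss = np.where(perfect, 0.0, np.maximum(rss, 0.0))
        sigma2 = rss / df                                # (k, n_p)
        diag = np.einsum("kcc->kc", Ainv)                # (k, n_c)

        se_k = np.sqrt(sigma2 * diag[:, nz, None])       # (k, n_p)
        beta_k = beta_full[:, nz, :]                     # (k, n_p)
        # a perfect fit that owes nothing to the determinant (its explained
        # SS is itself round-off, e.g. a constant phenotype absorbed by the
        # intercept) is a clean null: t = 0.  A perfect fit driven by the
        # determinant has no finite t and is flagged NA instead.
        zero_signal = perfect & (beta_k ** 2 * pd_.a3[ok, None]
                                 <= rss_tol[None, :])
        good = (se_k > 0) | zero_signal
        n_perfect = int((~good).sum())
        t_k = np.full_like(beta_k, np.nan)
        t_k[zero_signal] = 0.0
        beta_k = np.where(zero_signal, 0.0, beta_k)
        nz_se = se_k > 0
        t_k[nz_se] = beta_k[nz_se] / se_k[nz_se]

        idx = np.flatnonzero(ok)
        beta[:, idx] = beta_k.T
        se_out = np.where(good, se_k, np.nan)
        se[:, idx] = se_out.T
        tt[:, idx] = t_k.T
        pp[:, idx] = t_to_p(t_k, df).T
        na[:, idx] = ~good.T

        if all_covariates:
            se_all = np.sqrt(sigma2[:, None, :] * diag[:, :, None])  # (k,n_c,n_p)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_all = np.where(se_all > 0, beta_full / se_all, np.nan)
            full = (np.transpose(beta_full, (1, 2, 0)),
                    np.transpose(se_all, (1, 2, 0)),
                    np.transpose(t_all, (1, 2, 0)), idx)

    stats = AssociationStats(beta=beta, se=se, t=tt, p=pp, df=df, na_mask=na,
                             n_singular=n_singular, n_perfect=n_perfect)
    if full is not None:
        ball = np.full((n_c, n_p, n_t), np.nan)
        sall = np.full((n_c, n_p, n_t), np.nan)
        tall = np.full((n_c, n_p, n_t), np.nan)
        ball[:, :, full[3]], sall[:, :, full[3]], tall[:, :, full[3]] = full[:3]
        stats.beta_all, stats.se_all, stats.t_all = ball, sall, tall
    return stats


# ---------------------------------------------------------------------------
# missing-data / MAF policies
# ---------------------------------------------------------------------------

def impute_missing(G: np.ndarray, policy: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Apply the missing-dosage policy to a genotype chunk.

    ``mean``       per-variant mean imputation (keeps n constant per variant)
    ``drop-stat``  variants with any missing dosage are flagged; their
                   statistics become NA downstream

    Returns the (possibly modified) chunk and a boolean mask of variants to
    force-NA.
    """
    G = np.array(G, dtype=np.float64, copy=True)
    missing = np.isnan(G)
    drop = np.zeros(G.shape[1], dtype=bool)
    if not missing.any():
        return G, drop
    if policy == "mean":
        counts = (~missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0,
                             np.nansum(G, axis=0) / np.maximum(counts, 1), 0.0)
        G[missing] = np.broadcast_to(means, G.shape)[missing]
    elif policy == "drop-stat":
        drop = missing.any(axis=0)
        G[:, drop] = 0.0  # placeholder; masked out of the output
    else:
        raise RegressionError(f"unknown missing policy {policy!r}")
    return G, drop


def allele_freq(G: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency of each column of an imputed dosage chunk."""
    return np.nanmean(G, axis=0) / 2.0


def maf_mask(freq: np.ndarray, maf_min: float) -> np.ndarray:
    """True for variants whose minor allele frequency is >= maf_min."""
    maf = np.minimum(freq, 1.0 - freq)
    return maf >= maf_min


# ---------------------------------------------------------------------------
# single-site driver
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    chunk_variants: int = 1000
    chunk_phenotypes: int = 1000
    p_threshold: float = 1.0
    maf_min: float = 0.0
    missing: str = "mean"


def _iter_chunks(n: int, size: int) -> Iterator[slice]:
    for start in range(0, n, max(1, size)):
        yield slice(start, min(start + max(1, size), n))


def run_single_site(genotype: GenotypeStore, phenotype: PhenotypeStore,
                    covariates: CovariateStore | CovariateMatrix,
                    config: AnalysisConfig | None = None) -> Iterator[ResultRecord]:
    """Stream association records for every phenotype x variant pair.

    Iterates variant chunks x phenotype chunks so peak memory is bounded by
    the chunk sizes, independent of n_t * n_p.  Output order is variant-major
    within a chunk grid, deterministic for a given input and config.
    """
    config = config or AnalysisConfig()
    if isinstance(covariates, CovariateStore):
        cov_samples = covariates.samples
        cov_values = covariates.read()
        cov_names = covariates.names
    else:
        cov_samples = None
        cov_values = covariates.Z
        cov_names = covariates.names

    if cov_samples is not None:
        common, (g_rows, p_rows, c_rows) = align_samples(
            genotype.samples, phenotype.samples, cov_samples)
        cov_values = cov_values[c_rows]
    else:
        if cov_values.shape[0] != len(genotype.samples):
            raise RegressionError("in-memory covariates must already be aligned "
                                  "to the genotype store")
        common, (g_rows, p_rows) = align_samples(genotype.samples,
                                                 phenotype.samples)
        cov_values = cov_values[g_rows]

    Z = with_intercept(cov_values[:, 1:], cov_names[1:]) \
        if np.allclose(cov_values[:, 0], 1.0) else with_intercept(cov_values, cov_names)
    n = len(common)
    df = n - Z.n_c
    if df <= 0:
        raise RegressionError(f"df = {n} - {Z.n_c} <= 0")
    a1 = compute_a1(Z)

    vix = genotype.variants
    n_filtered = n_singular = n_perfect = 0
    for vsl in _iter_chunks(genotype.n_variants, config.chunk_variants):
        G = genotype.read(vsl, rows=g_rows)
        G, force_na = impute_missing(G, config.missing)
        keep = ~force_na
        if config.maf_min > 0:
            keep &= maf_mask(allele_freq(G), config.maf_min)
        n_filtered += int(np.sum(~keep & ~force_na))
        if not np.any(keep):
            continue
        cols = np.flatnonzero(keep)
        Gk = G[:, cols]
        a2, a3 = compute_a2_a3(Z, Gk)

        for psl in _iter_chunks(phenotype.n_phenotypes, config.chunk_phenotypes):
            Y = phenotype.read(psl, rows=p_rows)
            if not np.all(np.isfinite(Y)):
                raise RegressionError("phenotype matrix contains non-finite "
                                      "values after alignment")
            pd_ = PartialDerivatives(a1=a1, a2=a2, a3=a3,
                                     b_cov=compute_b_cov(Z, Y),
                                     C=compute_c(Y), n_samples=n)
            stats = solve_block(pd_, compute_b4(Y, Gk), df)
            n_singular += stats.n_singular
            n_perfect += stats.n_perfect
            yield from _emit(stats, vix, vsl.start + cols,
                             phenotype.phenotype_ids, psl, n, config.p_threshold)
    logger.info("run complete: %d variant(s) MAF-filtered, %d singular, "
                "%d perfect-fit", n_filtered, n_singular, n_perfect)


def _emit(stats: AssociationStats, vix, vcols: np.ndarray,
          phenotype_ids: Sequence[str], psl: slice, n: int,
          p_threshold: float) -> Iterator[ResultRecord]:
    pids = phenotype_ids[psl]
    for j, v in enumerate(vcols):
        for i, pid in enumerate(pids):
            p = stats.p[i, j]
            if not np.isnan(p) and p > p_threshold:
                continue
            yield ResultRecord(
                phenotype_id=pid, variant_id=vix.ids[v], chrom=vix.chrom[v],
                pos=int(vix.pos[v]), ref=vix.ref[v], alt=vix.alt[v], n=n,
                beta=float(stats.beta[i, j]), se=float(stats.se[i, j]),
                t=float(stats.t[i, j]), p=float(p), df=stats.df)
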