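"""Chunked HDF5 storage for genotype dosages, phenotypes and covariates.

Mass-univariate association studies read tall-and-wide matrices column-slice
by column-slice; plain text formats force a full parse for every slice.  All
inputs are therefore converted once to an HDF5 store whose chunked layout
permits reading any column block directly from disk.

Layout of a store file (one group per matrix kind, all values float64):

    /genotype/dosage            n_samples x n_variants, chunked
    /genotype/samples           sample ids (utf-8 strings)
    /genotype/variants/{id,chrom,pos,ref,alt}
    /phenotype/values           n_samples x n_phenotypes, chunked
    /phenotype/samples, /phenotype/ids
    /covariates/values          n_samples x n_covariate_columns
    /covariates/samples, /covariates/names

Missing dosages are stored as NaN; how they are handled (per-variant mean
imputation or NA propagation) is an analysis-time policy, not a storage one.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CHUNK = (1000, 1000)
_STR = h5py.string_dtype(encoding="utf-8")

RESULT_COLUMNS = (
    "phenotype_id", "variant_id", "chrom", "pos", "ref", "alt",
    "n", "beta", "se", "t", "p", "df",
)


class StoreError(Exception):
    """Raised for malformed inputs or inconsistent store contents."""


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleIndex:
    """Ordered, duplicate-free sample identifiers; order fixes matrix rows."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Index(self.ids)[pd.Index(self.ids).duplicated()]
            raise StoreError(f"duplicate sample ids: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class VariantIndex:
    """Variant annotations aligned with dosage columns."""

    ids: tuple[str, ...]
    chrom: tuple[str, ...]
    pos: np.ndarray  # int64, 1-based
    ref: tuple[str, ...]
    alt: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise StoreError("variant index field lengths differ")
        if len(set(self.ids)) != n:
            raise StoreError("duplicate variant ids")
        if n and int(np.min(self.pos)) < 1:
            raise StoreError("variant positions must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "chrom": self.chrom, "pos": self.pos,
             "ref": self.ref, "alt": self.alt}
        )

    def digest(self) -> str:
        h = hashlib.sha1()
        for row in zip(self.ids, self.chrom, self.pos, self.ref, self.alt):
            h.update(("\t".join(str(x) for x in row) + "\n").encode())
        return h.hexdigest()


def ids_digest(ids: Sequence[str]) -> str:
    h = hashlib.sha1()
    for s in ids:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# store wrappers
# ---------------------------------------------------------------------------

class _MatrixStore:
    """Common machinery for an HDF5-backed samples x columns matrix."""

    group: str
    values_name: str

    def __init__(self, path: str | os.PathLike):
        self.path = str(path)
        with h5py.File(self.path, "r") as f:
            if self.group not in f:
                raise StoreError(f"{self.path}: no /{self.group} group")
            g = f[self.group]
            self.samples = SampleIndex(tuple(s.decode() if isinstance(s, bytes) else s
                                             for s in g["samples"][:]))
            self.shape = g[self.values_name].shape

    @property
    def n_samples(self) -> int:
        return self.shape[0]

    def read(self, cols: slice | np.ndarray | None = None,
             rows: np.ndarray | None = None) -> np.ndarray:
        """Read a column block, optionally gathering a row subset."""
        with h5py.File(self.path, "r") as f:
            ds = f[self.group][self.values_name]
            block = ds[:, cols] if cols is not None else ds[:]
        if rows is not None:
            block = block[rows]
        return np.asarray(block, dtype=np.float64)


class GenotypeStore(_MatrixStore):
    group = "genotype"
    values_name = "dosage"

    def __init__(self, path: str | os.PathLike):
        super().__init__(path)
        with h5py.File(self.path, "r") as f:
            v = f["genotype/variants"]
            self.variants = VariantIndex(
                ids=tuple(x.decode() if isinstance(x, bytes) else x for x in v["id"][:]),
                chrom=tuple(x.decode() if isinstance(x, bytes) else x for x in v["chrom"][:]),
                pos=np.asarray(v["pos"][:], dtype=np.int64),
                ref=tuple(x.decode() if isinstance(x, bytes) else x for x in v["ref"][:]),
                alt=tuple(x.decode() if isinstance(x, bytes) else x for x in v["alt"][:]),
            )

    @property
    def n_variants(self) -> int:
        return self.shape[1]


class PhenotypeStore(_MatrixStore):
    group = "phenotype"
    values_name = "values"

    def __init__(self, path: str | os.PathLike):
        super().__init__(path)
        with h5py.File(self.path, "r") as f:
            self.phenotype_ids = tuple(
                x.decode() if isinstance(x, bytes) else x
                for x in f["phenotype/ids"][:])

    @property
    def n_phenotypes(self) -> int:
        return self.shape[1]


class CovariateStore(_MatrixStore):
    group = "covariates"
    values_name = "values"

    def __init__(self, path: str | os.PathLike):
        super().__init__(path)
        with h5py.File(self.path, "r") as f:
            self.names = tuple(
                x.decode() if isinstance(x, bytes) else x
                for x in f["covariates/names"][:])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _chunks_for(shape: tuple[int, int], chunk_shape: tuple[int, int]) -> tuple[int, int]:
    return (min(shape[0], max(1, chunk_shape[0])),
            min(shape[1], max(1, chunk_shape[1])))


def _write_provenance(f: h5py.File, provenance: dict | None) -> None:
    from . import __version__
    f.attrs["hdassoc_version"] = __version__
    for k, v in (provenance or {}).items():
        f.attrs[str(k)] = v


def write_genotype_store(out_path: str | os.PathLike, dosages: np.ndarray,
                         samples: SampleIndex, variants: VariantIndex,
                         chunk_shape: tuple[int, int] = DEFAULT_CHUNK,
                         provenance: dict | None = None) -> GenotypeStore:
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.shape != (len(samples), len(variants)):
        raise StoreError(f"dosage shape {dosages.shape} does not match indices "
                         f"({len(samples)}, {len(variants)})")
    with h5py.File(out_path, "w") as f:
        g = f.create_group("genotype")
        g.create_dataset("dosage", data=dosages,
                         chunks=_chunks_for(dosages.shape, chunk_shape))
        g.create_dataset("samples", data=np.array(samples.ids, dtype=_STR))
        v = g.create_group("variants")
        v.create_dataset("id", data=np.array(variants.ids, dtype=_STR))
        v.create_dataset("chrom", data=np.array(variants.chrom, dtype=_STR))
        v.create_dataset("pos", data=np.asarray(variants.pos, dtype=np.int64))
        v.create_dataset("ref", data=np.array(variants.ref, dtype=_STR))
        v.create_dataset("alt", data=np.array(variants.alt, dtype=_STR))
        _write_provenance(f, provenance)
    return GenotypeStore(out_path)


def write_phenotype_store(out_path: str | os.PathLike, values: np.ndarray,
                          samples: SampleIndex, phenotype_ids: Sequence[str],
                          chunk_shape: tuple[int, int] = DEFAULT_CHUNK,
                          provenance: dict | None = None) -> PhenotypeStore:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (len(samples), len(phenotype_ids)):
        raise StoreError("phenotype shape does not match indices")
    if len(set(phenotype_ids)) != len(phenotype_ids):
        raise StoreError("duplicate phenotype ids")
    with h5py.File(out_path, "w") as f:
        g = f.create_group("phenotype")
        g.create_dataset("values", data=values,
                         chunks=_chunks_for(values.shape, chunk_shape))
        g.create_dataset("samples", data=np.array(samples.ids, dtype=_STR))
        g.create_dataset("ids", data=np.array(list(phenotype_ids), dtype=_STR))
        _write_provenance(f, provenance)
    return PhenotypeStore(out_path)


def write_covariate_store(out_path: str | os.PathLike, values: np.ndarray,
                          samples: SampleIndex, names: Sequence[str],
                          provenance: dict | None = None) -> CovariateStore:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (len(samples), len(names)):
        raise StoreError("covariate shape does not match indices")
    with h5py.File(out_path, "w") as f:
        g = f.create_group("covariates")
        g.create_dataset("values", data=values,
                         chunks=_chunks_for(values.shape, DEFAULT_CHUNK))
        g.create_dataset("samples", data=np.array(samples.ids, dtype=_STR))
        g.create_dataset("names", data=np.array(list(names), dtype=_STR))
        _write_provenance(f, provenance)
    return CovariateStore(out_path)


# ---------------------------------------------------------------------------
# converters
# ---------------------------------------------------------------------------

def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Delimited table, first column = sample id; TSV/CSV by extension."""
    sep = "," if str(path).endswith(".csv") else r"\s+"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     na_values=["NA", "nan", "."], keep_default_na=True)
    df.index = df.index.astype(str)
    return df


def _numeric_matrix(df: pd.DataFrame, what: str) -> np.ndarray:
    out = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        try:
            out[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(np.float64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise StoreError(
                f"non-numeric {what} value at row {row!r}, column {col!r}")
    return out


def convert_dosage_table(path: str | os.PathLike, out_path: str | os.PathLike,
                         chunk_shape: tuple[int, int] = DEFAULT_CHUNK,
                         strict_dosage: bool = True,
                         provenance: dict | None = None) -> GenotypeStore:
    """Convert a delimited dosage matrix (rows = samples, header = variant ids).

    Values must be additive dosages in [0, 2]; out-of-range values raise
    ``StoreError`` when ``strict_dosage`` is true, otherwise they are clamped
    into range with a logged warning.  Missing entries (NA/.) become NaN.
    """
    df = _read_table(path)
    samples = SampleIndex(tuple(df.index))
    mat = _numeric_matrix(df, "dosage")

    with np.errstate(invalid="ignore"):
        out_of_range = (mat < 0) | (mat > 2)
    if np.any(out_of_range):
        i, j = map(int, np.argwhere(out_of_range)[0])
        msg = (f"dosage {mat[i, j]} outside [0, 2] at row "
               f"{df.index[i]!r}, column {df.columns[j]!r}")
        if strict_dosage:
            raise StoreError(msg)
        logger.warning("%s; clamping %d value(s)", msg, int(out_of_range.sum()))
        mat = np.clip(mat, 0.0, 2.0)

    n_t = mat.shape[1]
    variants = VariantIndex(
        ids=tuple(str(c) for c in df.columns),
        chrom=("0",) * n_t, pos=np.arange(1, n_t + 1, dtype=np.int64),
        ref=("N",) * n_t, alt=("N",) * n_t,
    )
    return write_genotype_store(out_path, mat, samples, variants,
                                chunk_shape, provenance)


def convert_vcf(path: str | os.PathLike, out_path: str | os.PathLike,
                chunk_shape: tuple[int, int] = DEFAULT_CHUNK,
                provenance: dict | None = None) -> GenotypeStore:
    """Convert a VCF to a genotype store of additive dosages.

    Per record the dosage is the DS FORMAT field when present, otherwise the
    count of alternate alleles in GT; missing genotypes become NaN.
    Multiallelic records are skipped (counted in the log).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise StoreError(f"{path}: VCF contains no samples")
    samples = SampleIndex(tuple(sample_ids))

    cols: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ds = rec.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).reshape(len(sample_ids), -1)[:, 0]
        else:
            gts = np.asarray(rec.genotypes, dtype=object)
            a = np.array([g[0] for g in gts], dtype=np.float64)
            b = np.array([g[1] if len(g) > 2 else -1 for g in gts], dtype=np.float64)
            col = a + b
            col[(a < 0) | (b < 0)] = np.nan
        cols.append(col)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        ids.append(vid)
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        refs.append(str(rec.REF))
        alts.append(str(rec.ALT[0]))
    if n_multi:
        logger.info("skipped %d multiallelic record(s)", n_multi)
    if not cols:
        raise StoreError(f"{path}: no biallelic records")

    mat = np.column_stack(cols)
    variants = VariantIndex(tuple(ids), tuple(chroms),
                            np.asarray(poss, dtype=np.int64),
                            tuple(refs), tuple(alts))
    return write_genotype_store(out_path, mat, samples, variants,
                                chunk_shape, provenance)


def convert_phenotype_table(path: str | os.PathLike, out_path: str | os.PathLike,
                            chunk_shape: tuple[int, int] = DEFAULT_CHUNK,
                            provenance: dict | None = None) -> PhenotypeStore:
    df = _read_table(path)
    samples = SampleIndex(tuple(df.index))
    mat = _numeric_matrix(df, "phenotype")
    return write_phenotype_store(out_path, mat, samples,
                                 tuple(str(c) for c in df.columns),
                                 chunk_shape, provenance)


def convert_covariate_table(path: str | os.PathLike, out_path: str | os.PathLike,
                            provenance: dict | None = None) -> CovariateStore:
    df = _read_table(path)
    samples = SampleIndex(tuple(df.index))
    mat = _numeric_matrix(df, "covariate")
    return write_covariate_store(out_path, mat, samples,
                                 tuple(str(c) for c in df.columns), provenance)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(*indices: SampleIndex) -> tuple[SampleIndex, list[np.ndarray]]:
    """Intersect sample indices; order follows the first (genotype) index.

    Returns the common index plus, for each input, the integer row positions
    selecting and ordering its rows to match the common index.
    """
    if not indices:
        raise ValueError("need at least one sample index")
    sets = [set(ix.ids) for ix in indices[1:]]
    common = [s for s in indices[0].ids if all(s in st for st in sets)]
    if not common:
        raise StoreError("no samples in common across inputs")
    maps = []
    for ix in indices:
        pos = {s: i for i, s in enumerate(ix.ids)}
        maps.append(np.array([pos[s] for s in common], dtype=np.intp))
    return SampleIndex(tuple(common)), maps


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResultRecord:
    """One association: phenotype x variant, with OLS statistics."""

    phenotype_id: str
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    df: int


def _fmt(x: float) -> str:
    return "NA" if (x is None or (isinstance(x, float) and np.isnan(x))) else f"{x:.15g}"


def write_results(records: Iterable[ResultRecord], path: str | os.PathLike,
                  p_threshold: float = 1.0,
                  provenance_line: str | None = None) -> int:
    """Write records with p <= p_threshold as a tab-delimited file.

    Returns the number of data rows written.  NA statistics (degenerate
    fits) are written as the literal ``NA`` and always pass the threshold
    filter so that degeneracy remains visible downstream.
    """
    n = 0
    with open(path, "w") as fh:
        if provenance_line:
            fh.write(f"# {provenance_line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in records:
            if not np.isnan(r.p) and r.p > p_threshold:
                continue
            fh.write("\t".join([
                r.phenotype_id, r.variant_id, r.chrom, str(r.pos), r.ref,
                r.alt, str(r.n), _fmt(r.beta), _fmt(r.se), _fmt(r.t),
                _fmt(r.p), str(r.df),
            ]) + "\n")
            n += 1
    return n


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a results file back into a DataFrame (provenance line skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       dtype={"chrom": str, "phenotype_id": str,
                              "variant_id": str})
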