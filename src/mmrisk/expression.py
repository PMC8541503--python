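"""Count-matrix I/O and median-of-ratios normalization.

RNA-seq counts are stored genes-by-samples. Library-size differences are
removed with median-of-ratios size factors: each gene with all-positive
counts contributes the ratio of its count in a sample to its geometric mean
across samples, and a sample's factor is the median of those ratios. This is
the standard size-factor estimator for bulk RNA-seq count data; downstream
cutpoint screening operates on ``log2(count / factor + 1)`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"
LOG_NORMALIZED = "log_normalized"
_SPACES = (RAW_COUNTS, NORMALIZED, LOG_NORMALIZED)


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise DataValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with explicit value space.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique axis labels.
    values
        ``(n_genes, n_samples)`` non-negative array. Integer-valued when
        ``space == "raw_counts"``.
    space
        One of ``raw_counts``, ``normalized``, ``log_normalized``.
    """

    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    values: np.ndarray = None
    space: str = RAW_COUNTS

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.space not in _SPACES:
            raise DataValidationError(f"unknown space {self.space!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise DataValidationError("expression values must be non-negative")
        if self.space == RAW_COUNTS and not np.all(self.values == np.floor(self.values)):
            raise DataValidationError("raw counts must be integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, space: str = RAW_COUNTS) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(), space)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise DataValidationError(f"genes not present: {', '.join(missing[:5])}")
        rows = [idx[g] for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), values=self.values[rows])


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling constants (all positive)."""

    sample_ids: list
    factors: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.sample_ids),):
            raise DataValidationError("one factor per sample required")
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise DataValidationError("size factors must be positive and finite")


def read_counts(path) -> ExpressionMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "gene ids")
    _check_unique(df.columns, "sample ids")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric count at gene {df.index[i]!r}, sample {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    return ExpressionMatrix.from_dataframe(numeric, RAW_COUNTS)


def write_counts(m: ExpressionMatrix, path) -> None:
    df = m.to_dataframe()
    if m.space == RAW_COUNTS:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def size_factors(m: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Only genes with strictly positive counts in every sample enter the
    reference (their geometric mean is well defined on the raw scale); each
    sample's factor is the median of count/geometric-mean ratios over those
    genes.
    """
    if m.space != RAW_COUNTS:
        raise DataValidationError("size factors are computed from raw counts")
    counts = m.values
    reference = np.all(counts > 0, axis=1)
    if not reference.any():
        raise DataValidationError("no reference genes: every gene has a zero count")
    logc = np.log(counts[reference])
    log_geomean = logc.mean(axis=1)
    ratios = np.exp(logc - log_geomean[:, None])
    return SizeFactors(m.sample_ids, np.median(ratios, axis=0))


def normalize(
    m: ExpressionMatrix, sf: SizeFactors, log_transform: bool = True
) -> ExpressionMatrix:
    """Divide counts by size factors; optionally return log2(normalized + 1)."""
    if m.sample_ids != sf.sample_ids:
        raise DataValidationError("sample ids of matrix and size factors differ")
    vals = m.values / sf.factors[None, :]
    if log_transform:
        return ExpressionMatrix(m.gene_ids, m.sample_ids, np.log2(vals + 1.0), LOG_NORMALIZED)
    return ExpressionMatrix(m.gene_ids, m.sample_ids, vals, NORMALIZED)


def filter_low_expression(
    m: ExpressionMatrix, min_expressed_frac: float = 0.2
) -> ExpressionMatrix:
    """Drop genes with zero counts in at least ``1 - min_expressed_frac`` of samples.

    Near-constant genes admit no meaningful survival cutpoint; this filter is
    applied before screening and defines the multiple-testing family.
    """
    zero_frac = np.mean(m.values == 0, axis=1)
    keep = zero_frac < 1.0 - min_expressed_frac
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    kept = [g for g, k in zip(m.gene_ids, keep) if k]
    return replace(m, gene_ids=kept, values=m.values[keep])


def normalize_pipeline(
    m: ExpressionMatrix, log_transform: bool = True, min_expressed_frac: float | None = 0.2
) -> ExpressionMatrix:
    """Convenience: expression filter + size factors + normalization."""
    if min_expressed_frac is not None:
        m = filter_low_expression(m, min_expressed_frac)
    return normalize(m, size_factors(m), log_transform=log_transform)
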