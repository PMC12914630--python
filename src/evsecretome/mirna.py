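"""miRNA post-quantification rules: size factors, expression filter, DE thresholds.

This module implements the screening rules applied *after* small-RNA
quantification: median-of-ratios library-size factors, the
expressed-miRNA filter (kept if at least ``min_samples`` samples show a
normalized count >= ``min_count``), and the joint differential-expression
threshold p_adj <= 0.05 and |fold change| >= 1.5 applied to externally
supplied log2 fold changes and adjusted p-values. The negative-binomial
GLM, dispersion estimation and shrinkage that produce those statistics are
the business of dedicated DE packages and are deliberately not reimplemented.

Count matrices are pandas DataFrames with miRNA ids as the index and sample
ids as columns (TSV on disk, first column ``mirna_id``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DERecord",
    "read_counts",
    "size_factors",
    "filter_expressed",
    "flag_differential",
]

DEFAULT_PADJ_MAX = 0.05
DEFAULT_FOLD_MIN = 1.5


@dataclass(frozen=True)
class DERecord:
    mirna_id: str
    log2_fold_change: float
    p_adj: float
    significant: bool


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix (first column mirna_id, then one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_counts(df)
    return df


def _validate_counts(matrix: pd.DataFrame) -> None:
    arr = matrix.to_numpy()
    if arr.size == 0:
        raise ValueError("count matrix is empty")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("counts must be finite and non-negative")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The reference pseudo-sample is the per-row geometric mean across
    samples, computed over rows with no zero count; each sample's factor is
    the median over those rows of count / reference. Requires at least one
    all-positive row.
    """
    _validate_counts(matrix)
    arr = matrix.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        raise ValueError("size factors need at least one row with all-positive counts")
    logs = np.log(arr[positive])
    log_ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def filter_expressed(matrix: pd.DataFrame, factors: pd.Series,
                     min_count: float = 5.0, min_samples: int = 3) -> list[str]:
    """The expressed-miRNA filter.

    A miRNA is kept iff at least ``min_samples`` samples have a normalized
    count (count / size factor) greater than or equal to ``min_count``.
    Returns kept ids in matrix order.
    """
    _validate_counts(matrix)
    if not matrix.columns.equals(pd.Index(factors.index)):
        raise ValueError("size factors are not aligned with matrix columns")
    if np.any(factors.to_numpy() <= 0):
        raise ValueError("size factors must be positive")
    normalized = matrix.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    keep = (normalized >= min_count).sum(axis=1) >= min_samples
    return [mid for mid, k in zip(matrix.index, keep) if k]


def flag_differential(records, padj_max: float = DEFAULT_PADJ_MAX,
                      fold_min: float = DEFAULT_FOLD_MIN) -> list[DERecord]:
    """Apply the joint DE threshold to (id, log2FC, p_adj) records.

    Significant iff p_adj <= padj_max and |fold change| >= fold_min, i.e.
    |log2FC| >= log2(fold_min); the threshold is two-sided so up- and
    down-regulation are treated symmetrically.
    """
    lfc_min = math.log2(fold_min)
    out = []
    for mirna_id, log2fc, p_adj in records:
        log2fc, p_adj = float(log2fc), float(p_adj)
        if not 0.0 <= p_adj <= 1.0:
            raise ValueError(f"{mirna_id}: p_adj {p_adj} outside [0, 1]")
        sig = p_adj <= padj_max and abs(log2fc) >= lfc_min
        out.append(DERecord(str(mirna_id), log2fc, p_adj, sig))
    return out
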