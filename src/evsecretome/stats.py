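"""Group summaries and the normality-gated comparison scheme.

Secretion-rate groups are summarized by median, interquartile range and
10th/90th percentiles (box-plot whiskers). Two groups are compared with an
unpaired Welch t-test when *both* pass a Shapiro-Wilk normality check, and
with the non-parametric Mann-Whitney U test otherwise; three or more
conditions use a tie-corrected Kruskal-Wallis omnibus test. Effect sizes
are reported as the fold change of group medians (always >= 1, with a
direction label), and multiple comparisons are handled by a Bonferroni
adjustment of the significance level itself (alpha / m).

Quantiles use linear interpolation between order statistics (the common
"type 7" convention); this is a reporting convention fixed here for
reproducibility, not a claim about the instrument software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestPolicy",
    "FoldChange",
    "ComparisonResult",
    "summarize",
    "fold_change",
    "mann_whitney_u",
    "shapiro_wilk",
    "kruskal_wallis",
    "compare",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    iqr: float
    p10: float
    p90: float


@dataclass(frozen=True)
class TestPolicy:
    """How a two-group comparison is run.

    alpha is the nominal level; with bonferroni_m > 1 the effective level is
    alpha / m (e.g. 0.05 / 5 = 0.01). The normality gate sends a pair to the
    Welch t-test only when both groups pass Shapiro-Wilk at gate_alpha.
    """

    alpha: float = 0.05
    use_normality_gate: bool = True
    gate_alpha: float = 0.05
    bonferroni_m: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.gate_alpha < 1:
            raise ValueError("gate_alpha must be in (0, 1)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    @property
    def alpha_effective(self) -> float:
        return self.alpha / self.bonferroni_m


@dataclass(frozen=True)
class FoldChange:
    fold: float  # rounded, >= 1; nan if undefined
    direction: str  # increase | decrease | none
    defined: bool = True


@dataclass(frozen=True)
class ComparisonResult:
    group_labels: tuple[str, ...]
    test_used: str  # mann_whitney | t_unpaired | kruskal_wallis
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    fold_change: FoldChange | None
    summaries: tuple[GroupSummary, ...] = field(default=())


def _as_array(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def summarize(values) -> GroupSummary:
    """Median, IQR and 10th/90th percentiles by linear interpolation."""
    arr = _as_array(values)
    q10, q25, q50, q75, q90 = np.percentile(arr, [10, 25, 50, 75, 90])
    return GroupSummary(n=arr.size, median=float(q50), iqr=float(q75 - q25),
                        p10=float(q10), p90=float(q90))


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(median_a: float, median_b: float, decimals: int = 2) -> FoldChange:
    """Fold change of medians: max/min with a direction label.

    ``median_a`` is the baseline (earlier / untreated) group and ``median_b``
    the comparison group; direction is 'decrease' when the comparison median
    is smaller. Reported folds are rounded half-up to ``decimals`` places.
    Non-positive medians make the fold undefined (flagged, not raised).
    """
    if median_a <= 0 or median_b <= 0:
        return FoldChange(fold=math.nan, direction="none", defined=False)
    if median_a == median_b:
        return FoldChange(fold=1.0, direction="none")
    fold = max(median_a, median_b) / min(median_a, median_b)
    direction = "decrease" if median_b < median_a else "increase"
    return FoldChange(fold=_round_half_up(fold, decimals), direction=direction)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b <= 12) and tie-free; otherwise the tie-corrected normal
    approximation with continuity correction. Returns (U of the first
    group, two-sided p).
    """
    a = _as_array(a, "group a")
    b = _as_array(b, "group b")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # fully tied data carry no ordering information
        return float(a.size * b.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000."""
    arr = _as_array(values)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups, method: str = "asymptotic") -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value.

    ``method='exact'`` enumerates the permutation null of H (tie-free data
    only, feasible for small pooled n) instead of the chi-square
    approximation.
    """
    groups = [_as_array(g, "group") for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.unique(np.concatenate(groups)).size == 1:
        return 0.0, 1.0  # fully tied data: no rank variation
    h, p_asym = sps.kruskal(*groups)
    h, p_asym = float(h), float(p_asym)
    if method == "asymptotic":
        return h, p_asym
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact mode requires tie-free data")
    sizes = [g.size for g in groups]
    n = pooled.size
    ranks = np.arange(1, n + 1, dtype=float)

    def h_stat(rank_groups):
        s = sum(rg.sum() ** 2 / rg.size for rg in rank_groups)
        return 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)

    # enumerate all partitions of the rank set into groups of the given sizes
    count_ge = 0
    total = 0
    idx_all = frozenset(range(n))

    def rec(remaining: frozenset, gi: int, acc):
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            acc2 = acc + [np.array(sorted(remaining))]
            hs = h_stat([ranks[ix] for ix in acc2])
            total += 1
            if hs >= h - 1e-12:
                count_ge += 1
            return
        for comb in combinations(sorted(remaining), sizes[gi]):
            rec(remaining - set(comb), gi + 1, acc + [np.array(comb)])

    rec(idx_all, 0, [])
    return h, count_ge / total


def compare(a, b, policy: TestPolicy | None = None,
            labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Normality-gated two-group comparison.

    If the gate is on and *both* groups pass Shapiro-Wilk at gate_alpha, the
    unpaired Welch t-test is used; otherwise Mann-Whitney U. Groups too
    small for Shapiro-Wilk (n < 3) fail the gate. Significance is judged at
    the Bonferroni-adjusted level alpha / m.
    """
    policy = policy or TestPolicy()
    a = _as_array(a, "group a")
    b = _as_array(b, "group b")
    use_t = False
    if policy.use_normality_gate and a.size >= 3 and b.size >= 3:
        # constant groups make W undefined; treat as failing the gate
        try:
            _, pa = shapiro_wilk(a)
            _, pb = shapiro_wilk(b)
            use_t = pa > policy.gate_alpha and pb > policy.gate_alpha
        except ValueError:
            use_t = False
    if use_t:
        res = sps.ttest_ind(a, b, equal_var=False)
        test_used, stat, p = "t_unpaired", float(res.statistic), float(res.pvalue)
    else:
        stat, p = mann_whitney_u(a, b)
        test_used = "mann_whitney"
    sa, sb = summarize(a), summarize(b)
    alpha_eff = policy.alpha_effective
    return ComparisonResult(
        group_labels=labels,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        alpha=alpha_eff,
        significant=bool(p < alpha_eff),
        fold_change=fold_change(sa.median, sb.median),
        summaries=(sa, sb),
    )
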