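"""The statistical decision tree for comparing dN/dS distributions.

Two-sample comparisons (core vs multiheme cytochrome genes within a
genome) follow a fixed route: Shapiro-Wilk normality on each sample; if
both pass, an F-test routes to Student's or Welch's t-test; if exactly
one fails, both samples are log-transformed (non-positive values are
dropped and counted) and the variance logic re-applied; if both fail,
the Wilcoxon rank-sum test is used.  Localization-class comparisons use
the Kruskal-Wallis omnibus test with Dunn's post hoc pairwise z-tests
(Bonferroni-adjusted by default).  All tests are two-sided.

Significance tiers follow the unusual legend convention preserved
throughout this pipeline: * for P < 0.05, ** for P < 0.001 and *** for
P < 0.0001.

The underlying statistics are delegated to scipy; this module's job is
the routing, transformation bookkeeping and tiering.  Dunn's test is
implemented here (rank-based z statistics with tie correction) since no
installed library provides it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

MIN_SAMPLE = 3


def significance_tier(p: float) -> str:
    """Map a p-value to the legend tiers: ***, **, *, ns."""
    if math.isnan(p):
        return "ns"
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TestResult:
    test: str  # t | Welch-t | Wilcoxon | Kruskal-Wallis | none
    transformed: bool
    p: float
    tier: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    n_dropped_nonpositive: int = 0
    status: str = "ok"  # ok | insufficient_data


def _insufficient(n_a: int, n_b: int) -> TestResult:
    return TestResult(
        test="none", transformed=False, p=math.nan, tier="ns",
        n_a=n_a, n_b=n_b, median_a=math.nan, median_b=math.nan,
        status="insufficient_data",
    )


@dataclass
class TestPlan:
    test: str
    transformed: bool
    normal_a: bool
    normal_b: bool
    n_dropped_nonpositive: int = 0


def _f_test_equal_variance(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Two-sided F-test for equal variances; True = equal at level alpha."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return True
    if vb == 0 or va == 0:
        return False
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return p >= alpha


def choose_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
) -> TestPlan:
    """Walk the decision tree and return the planned test (no p-value).

    Deterministic given the data and alpha.  Raises on samples smaller
    than three values; callers wanting a soft failure should use
    :func:`compare_samples`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < MIN_SAMPLE or b.size < MIN_SAMPLE:
        raise InvalidParameterError("need at least 3 values per sample")
    normal_a = stats.shapiro(a).pvalue >= alpha
    normal_b = stats.shapiro(b).pvalue >= alpha
    if normal_a and normal_b:
        equal = _f_test_equal_variance(a, b, alpha)
        return TestPlan("t" if equal else "Welch-t", False, normal_a, normal_b)
    if normal_a or normal_b:
        dropped = int((a <= 0).sum() + (b <= 0).sum())
        la, lb = np.log(a[a > 0]), np.log(b[b > 0])
        if la.size < MIN_SAMPLE or lb.size < MIN_SAMPLE:
            return TestPlan("none", True, normal_a, normal_b, dropped)
        equal = _f_test_equal_variance(la, lb, alpha)
        return TestPlan(
            "t" if equal else "Welch-t", True, normal_a, normal_b, dropped
        )
    return TestPlan("Wilcoxon", False, normal_a, normal_b)


def compare_samples(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
) -> TestResult:
    """Run the decision-tree comparison of two samples (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < MIN_SAMPLE or b.size < MIN_SAMPLE:
        return _insufficient(a.size, b.size)
    plan = choose_test(a, b, alpha=alpha)
    xa, xb = a, b
    if plan.transformed:
        xa, xb = np.log(a[a > 0]), np.log(b[b > 0])
        if plan.test == "none":
            return _insufficient(xa.size, xb.size)
    if plan.test == "t":
        p = stats.ttest_ind(xa, xb, equal_var=True).pvalue
    elif plan.test == "Welch-t":
        p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
    else:  # Wilcoxon rank-sum
        p = stats.ranksums(xa, xb).pvalue
    p = float(p)
    return TestResult(
        test=plan.test,
        transformed=plan.transformed,
        p=p,
        tier=significance_tier(p),
        n_a=int(xa.size),
        n_b=int(xb.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_dropped_nonpositive=plan.n_dropped_nonpositive,
    )


def compare_core_vs_mhc(
    dnds_table: pd.DataFrame,
    genome_id: str,
    alpha: float = 0.05,
) -> TestResult:
    """Compare core-gene vs MHC-gene omega distributions in one genome.

    ``dnds_table`` needs columns genome_id, gene_class (core/MHC) and
    omega; rows with missing omega are excluded before testing.
    """
    sub = dnds_table[dnds_table["genome_id"] == genome_id]
    core = sub.loc[sub["gene_class"] == "core", "omega"].dropna().to_numpy()
    mhc = sub.loc[sub["gene_class"] == "MHC", "omega"].dropna().to_numpy()
    return compare_samples(core, mhc, alpha=alpha)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    p_adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's post hoc pairwise z-tests on pooled ranks.

    Standard large-sample form with tie correction: for groups i, j
    with pooled-rank means Ri, Rj over N total observations,

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)),
        T = sum(t^3 - t) / (12 (N - 1))   over tie groups of size t.

    Two-sided p-values, Bonferroni-adjusted by default ("none" to skip).
    """
    names = sorted(groups)
    data = {k: np.asarray(groups[k], dtype=float) for k in names}
    pooled = np.concatenate([data[k] for k in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    rank_means = {}
    start = 0
    for k in names:
        n = data[k].size
        rank_means[k] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - ties
    rows = []
    pairs = list(combinations(names, 2))
    m = len(pairs)
    for i, j in pairs:
        ni, nj = data[i].size, data[j].size
        se = math.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = (rank_means[i] - rank_means[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if p_adjust == "bonferroni" else p
        rows.append(
            {
                "group_a": i, "group_b": j, "z": z,
                "p": p, "p_adjusted": p_adj,
                "tier": significance_tier(p_adj),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LocalizationComparison:
    omnibus: TestResult
    pairwise: pd.DataFrame
    dropped_groups: list[str] = field(default_factory=list)


def compare_by_localization(
    dnds_table: pd.DataFrame,
    group_column: str = "localization",
    value_column: str = "omega",
    alpha: float = 0.05,
    p_adjust: str = "bonferroni",
) -> LocalizationComparison:
    """Kruskal-Wallis omnibus across localization classes plus Dunn's
    pairwise table.  Groups with fewer than three non-missing values
    are dropped with a note."""
    groups: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, sub in dnds_table.groupby(group_column):
        vals = sub[value_column].dropna().to_numpy(dtype=float)
        if vals.size < MIN_SAMPLE:
            dropped.append(str(name))
        else:
            groups[str(name)] = vals
    if len(groups) < 2:
        return LocalizationComparison(
            omnibus=_insufficient(0, 0),
            pairwise=pd.DataFrame(),
            dropped_groups=dropped,
        )
    names = sorted(groups)
    stat = stats.kruskal(*[groups[k] for k in names])
    p = float(stat.pvalue)
    sizes = [groups[k].size for k in names]
    omnibus = TestResult(
        test="Kruskal-Wallis",
        transformed=False,
        p=p,
        tier=significance_tier(p),
        n_a=sizes[0],
        n_b=sizes[1] if len(sizes) > 1 else 0,
        median_a=float(np.median(groups[names[0]])),
        median_b=float(np.median(groups[names[1]])),
    )
    pairwise = dunn_posthoc(groups, p_adjust=p_adjust)
    return LocalizationComparison(
        omnibus=omnibus, pairwise=pairwise, dropped_groups=dropped
    )
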