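"""Test-retest reliability statistics.

The battery mirrors a standard repeated-measures workup: a Shapiro-Wilk
normality gate, a two-way mixed-model intraclass correlation
(single-measures, consistency form) with a Shrout-Fleiss 95% confidence
interval and Koo-Li classification, Bland-Altman bias and limits of
agreement between sessions, Friedman's rank test across conditions with
Bonferroni-corrected rank-based post-hoc pairwise comparisons, and the
Wilcoxon signed-rank test for paired sequence comparisons.

The ICC, the tie-corrected Friedman chi-square (which must also cover the
two-condition case) and the post-hoc z construction are implemented here
from the ANOVA/rank decompositions; the Shapiro-Wilk and Wilcoxon
statistics are delegated to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ICCResult",
    "TestResult",
    "PairwiseResult",
    "FriedmanResult",
    "icc_two_way_mixed",
    "classify_icc",
    "bland_altman",
    "friedman_with_posthoc",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    method: str
    df: Optional[float] = None
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class PairwiseResult:
    pair: Tuple[int, int]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class FriedmanResult:
    omnibus: TestResult
    pairwise: List[PairwiseResult]
    mean_ranks: np.ndarray


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci95: Tuple[float, float]
    n_subjects: int
    n_sessions: int
    model: str
    classification: str


def classify_icc(value: float) -> str:
    """Koo-Li reliability band for an ICC value.

    > 0.90 excellent; 0.75-0.90 good (both endpoints included); 0.50-0.75
    moderate; < 0.50 poor.  Values outside [-1, 1] raise.
    """
    if not -1.0 <= value <= 1.0:
        raise ValidationError("ICC must lie in [-1, 1]")
    if value > 0.90:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.50:
        return "moderate"
    return "poor"


def icc_two_way_mixed(data: np.ndarray) -> ICCResult:
    """Two-way mixed, single-measures, consistency ICC — ICC(3,1).

    `data` is a complete subjects x sessions grid.  From the two-way ANOVA
    decomposition, ICC = (MS_subjects - MS_error) /
    (MS_subjects + (k - 1) MS_error); the 95% CI uses the F-quantile
    construction of Shrout and Fleiss.  Consistency form: invariant to a
    constant shift per session.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be a 2-D subjects x sessions grid")
    if np.isnan(data).any():
        raise ValidationError("incomplete grid: missing values")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 sessions")
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    if ss_total == 0:
        raise ValidationError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df_rows, df_err = n - 1, (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    if ms_err == 0:
        ci = (1.0, 1.0)
    else:
        f_obs = ms_rows / ms_err
        f_low = f_obs / stats.f.ppf(1 - ALPHA / 2, df_rows, df_err)
        f_up = f_obs * stats.f.ppf(1 - ALPHA / 2, df_err, df_rows)
        ci = ((f_low - 1) / (f_low + k - 1), (f_up - 1) / (f_up + k - 1))
    return ICCResult(
        estimate=float(icc),
        ci95=(float(ci[0]), float(ci[1])),
        n_subjects=n,
        n_sessions=k,
        model="two-way mixed, single measures, consistency (ICC3,1)",
        classification=classify_icc(float(np.clip(icc, -1.0, 1.0))),
    )


def bland_altman(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    """Mean bias and 1.96-SD limits of agreement of paired measurements."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def friedman_with_posthoc(data: np.ndarray) -> FriedmanResult:
    """Friedman rank test across conditions plus pairwise rank post-hocs.

    The omnibus statistic is the tie-corrected chi-square on within-
    subject mid-ranks (df = k - 1).  Post-hoc pairs use
    z = (mean-rank difference) / sqrt(k (k + 1) / (6 n)) with a two-sided
    normal p, Bonferroni-adjusted by the number of pairs.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be a 2-D subjects x conditions grid")
    if np.isnan(data).any():
        raise ValidationError("incomplete grid: missing values")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 conditions")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    # tie-corrected chi-square on within-subject mid-ranks
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    denom = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denom == 0:  # all conditions tied within every subject
        omnibus = TestResult(statistic=0.0, p_raw=1.0, df=k - 1,
                             method="friedman")
    else:
        chi2 = numer / denom
        omnibus = TestResult(statistic=float(chi2),
                             p_raw=float(stats.chi2.sf(chi2, k - 1)),
                             df=k - 1, method="friedman")
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = comb(k, 2)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            pairwise.append(PairwiseResult(
                pair=(i, j), z=float(z), p_raw=float(p_raw),
                p_adjusted=float(min(1.0, m * p_raw)),
            ))
    return FriedmanResult(omnibus=omnibus, pairwise=pairwise,
                          mean_ranks=mean_ranks)


def wilcoxon_signed_rank(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; with n <= 25 untied differences the p-value is
    exact by sign-pattern enumeration, otherwise the tie- and
    continuity-corrected normal approximation is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all differences are zero")
    exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
        alternative="two-sided",
    )
    return TestResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        method="wilcoxon-exact" if exact else "wilcoxon-normal",
    )


def shapiro_wilk(values: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (Royston's algorithm via scipy)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(v == v[0]):
        raise ValidationError("constant input")
    w, p = stats.shapiro(v)
    return TestResult(statistic=float(w), p_raw=float(p), method="shapiro-wilk")
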