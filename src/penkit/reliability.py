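"""Test-retest reliability pipeline for handwriting indicators.

For each indicator the decision sequence is:

1. a paired-sample test on the test-retest differences — paired t when the
   differences pass a Lilliefors normality gate, Wilcoxon signed-rank
   otherwise; a rejection at ``alpha`` makes the indicator *not reliable*
   regardless of any agreement coefficient (a systematic session shift can
   coexist with a high correlation);
2. otherwise an agreement coefficient: ICC(A,1) — two-way random effects,
   absolute agreement, single measurement — when the pooled values pass the
   normality gate, Kendall's W (the two sessions acting as judges ranking the
   subjects, mid-rank ties) otherwise;
3. an intensity category from the printed cut-offs: not reliable if ICC<0.5
   or W<0.2; fair if 0.2<=W<0.4; moderate if 0.5<=ICC<0.75 or 0.4<=W<0.6;
   good if 0.75<=ICC<0.9 or 0.6<=W<0.8; optimal if ICC>=0.9 or W>=0.8.

Variability indicators (CVs) are excluded from the analysis, subjects who
switched allograph between sessions are dropped, and no multiple-testing
correction is applied across indicators (raw p at 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import ValidationError
from .indicators import VARIABILITY_INDICATORS

__all__ = [
    "ReliabilityResult",
    "normality_gate",
    "icc_a1",
    "kendall_w",
    "categorize",
    "assess_reliability",
    "reliability_table",
]

MIN_N = 8

CATEGORIES = (
    "not_reliable",
    "fair",
    "moderate",
    "good",
    "optimal",
    "excluded_by_paired_test",
)


@dataclass
class ReliabilityResult:
    """Per-indicator reliability decision."""

    indicator: str
    n: int
    normality: int  # 0 normal, 1 nonnormal (routing of the coefficient)
    paired_test: str  # "t" | "wilcoxon"
    paired_p: float
    coef_type: str  # "ICC" | "W" | "undefined"
    coef_value: float
    coef_p: float
    category: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> str:
    """Lilliefors-based normality decision: ``"normal"`` or ``"nonnormal"``.

    Fewer than 8 non-missing values, or a degenerate (constant) series, force
    the conservative ``"nonnormal"`` branch.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_N or np.ptp(x) == 0:
        return "nonnormal"
    _, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return "nonnormal" if p < alpha else "normal"


def icc_a1(test: np.ndarray, retest: np.ndarray) -> tuple[float, float]:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Returns ``(icc, p)`` with the significance from ``F = MS_rows / MS_error``
    on ``(n-1, (n-1)(k-1))`` degrees of freedom.
    """
    x = np.column_stack([test, retest]).astype(float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return np.nan, np.nan
    icc = (msr - mse) / denom
    if mse <= 0:
        p = 0.0 if msr > 0 else np.nan
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def kendall_w(test: np.ndarray, retest: np.ndarray) -> tuple[float, float]:
    """Kendall's coefficient of concordance for 2 sessions, with tie correction.

    The two sessions act as judges ranking the subjects (mid-rank ties);
    significance via the chi-square approximation ``chi2 = k (n-1) W``.
    """
    x = np.column_stack([test, retest]).astype(float)
    n, k = x.shape
    ranks = np.column_stack([stats.rankdata(x[:, j]) for j in range(k)])
    r_i = ranks.sum(axis=1)
    s = np.sum((r_i - r_i.mean()) ** 2)
    ties = 0.0
    for j in range(k):
        _, counts = np.unique(x[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = k**2 * (n**3 - n) - k * ties
    if denom <= 0:
        return np.nan, np.nan
    w = 12.0 * s / denom
    chi2 = k * (n - 1) * w
    p = float(stats.chi2.sf(chi2, n - 1))
    return float(w), p


def categorize(coef_type: str, value: float) -> str:
    """Map a (coefficient type, value) pair to the intensity category.

    The value is clipped at 0 before categorization. 'fair' exists only for
    Kendall's W, mirroring the threshold table.
    """
    if not np.isfinite(value):
        return "not_reliable"
    v = max(0.0, float(value))
    if coef_type == "ICC":
        if v < 0.5:
            return "not_reliable"
        if v < 0.75:
            return "moderate"
        if v < 0.9:
            return "good"
        return "optimal"
    if coef_type == "W":
        if v < 0.2:
            return "not_reliable"
        if v < 0.4:
            return "fair"
        if v < 0.6:
            return "moderate"
        if v < 0.8:
            return "good"
        return "optimal"
    raise ValidationError(f"unknown coefficient type {coef_type!r}")


def assess_reliability(
    test: np.ndarray,
    retest: np.ndarray,
    alpha: float = 0.05,
    indicator: str = "",
) -> ReliabilityResult:
    """Run the full test-retest decision pipeline on one paired series."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    ok = np.isfinite(test) & np.isfinite(retest)
    test, retest = test[ok], retest[ok]
    n = len(test)
    if n < MIN_N:
        raise ValidationError(f"need at least {MIN_N} complete pairs, got {n}")

    diffs = retest - test
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        paired_test, paired_p = "t", 1.0
    elif normality_gate(diffs, alpha) == "normal":
        paired_test = "t"
        paired_p = float(stats.ttest_rel(test, retest).pvalue)
    else:
        paired_test = "wilcoxon"
        try:
            paired_p = float(stats.wilcoxon(test, retest).pvalue)
        except ValueError:  # all differences zero
            paired_p = 1.0

    pooled_gate = normality_gate(np.concatenate([test, retest]), alpha)
    nonnormal = int(pooled_gate == "nonnormal")
    if nonnormal:
        coef_type = "W"
        value, coef_p = kendall_w(test, retest)
    else:
        coef_type = "ICC"
        value, coef_p = icc_a1(test, retest)

    if not np.isfinite(value):
        warnings.warn(
            f"reliability coefficient undefined for {indicator or 'series'} "
            "(zero between-subject variance)",
            stacklevel=2,
        )
        category = "not_reliable"
        coef_type = "undefined"
    elif paired_p < alpha:
        category = "excluded_by_paired_test"
    else:
        category = categorize(coef_type, value)

    return ReliabilityResult(
        indicator=indicator, n=n, normality=nonnormal,
        paired_test=paired_test, paired_p=paired_p,
        coef_type=coef_type, coef_value=float(value), coef_p=float(coef_p)
        if np.isfinite(value) else np.nan,
        category=category,
    )


def reliability_table(
    test_df: pd.DataFrame,
    retest_df: pd.DataFrame,
    task: str | None = None,
    allograph: str | None = None,
    alpha: float = 0.05,
) -> list[ReliabilityResult]:
    """Per-indicator reliability for one (task, allograph) stratum.

    Both inputs are wide indicator tables (``subject, session, task,
    allograph`` id columns plus indicator columns). Subjects whose allograph
    differs between sessions are excluded; variability (CV) indicators are
    excluded; strata with fewer than 8 matched subjects are skipped with a
    warning (empty result).
    """
    def prep(df: pd.DataFrame) -> pd.DataFrame:
        out = df
        if task is not None:
            out = out[out["task"] == task]
        return out

    t, r = prep(test_df), prep(retest_df)
    merged = t.merge(r, on="subject", suffixes=("_t", "_r"))
    # drop allograph switchers before (not after) the stratum filter
    merged = merged[merged["allograph_t"] == merged["allograph_r"]]
    if allograph is not None:
        merged = merged[merged["allograph_t"] == allograph]
    indicator_cols = [
        c for c in test_df.columns
        if c not in ("subject", "session", "task", "allograph")
        and c not in VARIABILITY_INDICATORS
    ]
    if len(merged) < MIN_N:
        warnings.warn(
            f"stratum task={task} allograph={allograph}: only {len(merged)} "
            f"matched subjects (<{MIN_N}), skipped",
            stacklevel=2,
        )
        return []
    results = []
    for col in indicator_cols:
        a = merged[f"{col}_t"].to_numpy(float)
        b = merged[f"{col}_r"].to_numpy(float)
        if np.count_nonzero(np.isfinite(a) & np.isfinite(b)) < MIN_N:
            continue
        results.append(assess_reliability(a, b, alpha=alpha, indicator=col))
    return results
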