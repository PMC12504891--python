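"""Clinical-score correlations and PnP word-type contrasts.

Correlations route through a Lilliefors normality gate: Pearson's r when both
variables look normal, Spearman's rho otherwise, with the usual strength
bands (weak 0.2<=|r|<0.4, moderate 0.4<=|r|<0.6, strong 0.6<=|r|<0.8, very
strong |r|>=0.8). Missing values are deleted pairwise. The per-word-type
contrast uses a one-way repeated-measures ANOVA (normal route; sphericity
uncorrected, Greenhouse-Geisser epsilon reported informationally) or the
Friedman test, followed — only on rejection — by three paired post-hoc
comparisons (R-I, MU-I, R-MU) with Bonferroni adjustment and difference
bounds: t-based confidence intervals after the ANOVA, Hodges-Lehmann
estimates with a signed-rank-based interval after Friedman.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .reliability import normality_gate

__all__ = [
    "CorrelationResult",
    "WordTypeResult",
    "correlation_strength",
    "correlate_clinical",
    "rm_anova",
    "hodges_lehmann",
    "compare_word_types",
    "compare_word_types_table",
]

MIN_N = 8

STRENGTHS = ("below_weak", "weak", "moderate", "strong", "very_strong")

#: post-hoc pair layout: (label, first type, second type)
POSTHOC_PAIRS = (("R-I", "regular", "irregular"),
                 ("MU-I", "made_up", "irregular"),
                 ("R-MU", "regular", "made_up"))


def correlation_strength(value: float) -> str:
    a = abs(value)
    if a < 0.2:
        return "below_weak"
    if a < 0.4:
        return "weak"
    if a < 0.6:
        return "moderate"
    if a < 0.8:
        return "strong"
    return "very_strong"


@dataclass
class CorrelationResult:
    indicator: str
    score: str
    coef_type: str  # "pearson" | "spearman"
    value: float
    p: float
    n: int
    strength: str
    significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _correlate_pair(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[str, float, float]:
    """Gate-routed correlation on pairwise-complete data."""
    if normality_gate(x, alpha) == "normal" and normality_gate(y, alpha) == "normal":
        r = st.pearsonr(x, y)
        return "pearson", float(r.statistic), float(r.pvalue)
    r = st.spearmanr(x, y)
    return "spearman", float(r.statistic), float(r.pvalue)


def correlate_clinical(
    indicators: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    irregular_indicators: pd.DataFrame | None = None,
) -> list[CorrelationResult]:
    """Correlate each indicator with each clinical score.

    Both tables need a ``subject`` column; remaining numeric columns are the
    variables. The per-irregular-word error count (``PnP-errors-I``) is
    special-cased: when ``irregular_indicators`` is given (indicators
    extracted from irregular words only), that table is used for this score
    instead of the whole-task indicators. Constant variables are skipped with
    a warning; pairs with fewer than 8 complete observations are skipped.
    """
    results: list[CorrelationResult] = []
    score_cols = [c for c in clinical.columns if c != "subject"]
    for score in score_cols:
        table = indicators
        if score == "PnP-errors-I" and irregular_indicators is not None:
            table = irregular_indicators
        ind_cols = [
            c for c in table.columns
            if c not in ("subject", "session", "task", "allograph")
        ]
        merged = table.merge(clinical[["subject", score]], on="subject")
        for ind in ind_cols:
            pair = merged[[ind, score]].dropna()
            n = len(pair)
            if n < MIN_N:
                continue
            x = pair[ind].to_numpy(float)
            y = pair[score].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"correlation {ind} vs {score} undefined (constant variable)",
                    stacklevel=2,
                )
                continue
            coef_type, value, p = _correlate_pair(x, y, alpha)
            results.append(
                CorrelationResult(
                    indicator=ind, score=score, coef_type=coef_type,
                    value=value, p=p, n=n,
                    strength=correlation_strength(value),
                    significant=bool(p < alpha),
                )
            )
    return results


# ---------------------------------------------------------------------------
# repeated-measures omnibus + post-hoc
# ---------------------------------------------------------------------------


def rm_anova(data: np.ndarray) -> tuple[float, float, float]:
    """One-way repeated-measures ANOVA on an (n subjects x k conditions) array.

    Returns ``(F, p, gg_epsilon)``; p is sphericity-uncorrected, the
    Greenhouse-Geisser epsilon is informational. Degenerate (zero error
    variance) data returns ``p = 1`` when there is no condition effect.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    cov = np.cov(x, rowvar=False, ddof=1)
    cc = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    tr = np.trace(cc)
    denom = (k - 1) * np.sum(cc**2)
    eps = float(tr**2 / denom) if denom > 0 else 1.0
    if ms_err <= 0:
        return (np.inf, 0.0, eps) if ms_cond > 0 else (0.0, 1.0, eps)
    f = ms_cond / ms_err
    p = float(st.f.sf(f, df_cond, df_err))
    return float(f), p, eps


def hodges_lehmann(d: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate and signed-rank-based CI for paired differences.

    The estimate is the median of the Walsh averages; the interval takes the
    Walsh-average order statistics selected by the normal approximation to the
    signed-rank distribution.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    i, j = np.triu_indices(n)
    walsh = np.sort((d[i] + d[j]) / 2.0)
    est = float(np.median(walsh))
    m = len(walsh)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = st.norm.ppf(0.5 + conf / 2.0)
    k = int(np.floor(mu - z * sigma))
    k = max(0, min(k, m - 1))
    lo = float(walsh[k])
    hi = float(walsh[m - 1 - k])
    return lo, est, hi


@dataclass
class WordTypeResult:
    """Omnibus + post-hoc contrast of one indicator across word types."""

    indicator: str
    omnibus: str  # "rm_anova" | "friedman"
    p: float
    n: int
    gg_epsilon: float | None = None
    posthoc: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_word_types(
    regular: np.ndarray,
    irregular: np.ndarray,
    made_up: np.ndarray,
    alpha: float = 0.05,
    indicator: str = "",
) -> WordTypeResult:
    """Contrast per-word-type indicator means across paired subjects.

    The omnibus is a repeated-measures ANOVA when all three series pass the
    normality gate, a Friedman test otherwise. On rejection, three paired
    post-hoc comparisons follow the omnibus family (paired t after ANOVA,
    signed-rank after Friedman) with Bonferroni-adjusted p (x3, capped at 1)
    and 95% bounds on the difference (type1 minus type2).
    """
    series = {"regular": np.asarray(regular, float),
              "irregular": np.asarray(irregular, float),
              "made_up": np.asarray(made_up, float)}
    ok = np.ones(len(series["regular"]), dtype=bool)
    for v in series.values():
        ok &= np.isfinite(v)
    series = {k: v[ok] for k, v in series.items()}
    n = int(ok.sum())
    if n < MIN_N:
        raise ValueError(f"need at least {MIN_N} subjects with all three means, got {n}")

    x = np.column_stack([series["regular"], series["irregular"], series["made_up"]])
    if np.ptp(x - x[:, :1], axis=None) == 0:
        # all three series identical for every subject
        return WordTypeResult(indicator=indicator, omnibus="rm_anova", p=1.0, n=n)

    normal = all(normality_gate(v, alpha) == "normal" for v in series.values())
    if normal:
        f, p, eps = rm_anova(x)
        result = WordTypeResult(indicator=indicator, omnibus="rm_anova", p=p,
                                n=n, gg_epsilon=eps)
    else:
        try:
            p = float(st.friedmanchisquare(*x.T).pvalue)
        except ValueError:
            p = 1.0
        result = WordTypeResult(indicator=indicator, omnibus="friedman", p=p, n=n)

    if result.p >= alpha:
        return result

    for label, t1, t2 in POSTHOC_PAIRS:
        d = series[t1] - series[t2]
        if result.omnibus == "rm_anova":
            tt = st.ttest_rel(series[t1], series[t2])
            praw = float(tt.pvalue)
            se = d.std(ddof=1) / np.sqrt(n)
            tcrit = st.t.ppf(0.975, n - 1)
            lo, est, hi = float(d.mean() - tcrit * se), float(d.mean()), float(d.mean() + tcrit * se)
        else:
            if np.ptp(d) == 0 and d[0] == 0:
                praw, (lo, est, hi) = 1.0, (0.0, 0.0, 0.0)
            else:
                praw = float(st.wilcoxon(series[t1], series[t2]).pvalue)
                lo, est, hi = hodges_lehmann(d)
        result.posthoc[label] = {
            "diff": est, "lb": lo, "ub": hi,
            "p_raw": praw, "p_adj": min(1.0, 3.0 * praw),
        }
    return result


def compare_word_types_table(
    type_means: pd.DataFrame, alpha: float = 0.05
) -> list[WordTypeResult]:
    """Run the word-type contrast for every indicator column.

    ``type_means`` is long-ish: one row per (subject, word_type) with
    indicator columns; word types ``regular``/``irregular``/``made_up``.
    """
    ind_cols = [c for c in type_means.columns if c not in ("subject", "word_type")]
    wide = {t: type_means[type_means["word_type"] == t].set_index("subject")
            for t in ("regular", "irregular", "made_up")}
    subjects = sorted(set.intersection(*(set(w.index) for w in wide.values())))
    out = []
    for col in ind_cols:
        try:
            res = compare_word_types(
                wide["regular"].loc[subjects, col].to_numpy(float),
                wide["irregular"].loc[subjects, col].to_numpy(float),
                wide["made_up"].loc[subjects, col].to_numpy(float),
                alpha=alpha, indicator=col,
            )
        except ValueError:
            continue
        out.append(res)
    return out
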