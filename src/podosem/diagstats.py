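"""Diagnostic statistics for per-mouse morphometry.

Covers the evaluation layer of a two-group morphometry study: per-mouse
aggregation of image-level measurements, unpaired t-tests, Hedges' g with
its small-sample correction, t-based group confidence intervals, empirical
ROC curves with the Youden-optimal cutoff, Wilson score intervals for
sensitivity/specificity, Pearson correlation, simple linear regression,
and Bland–Altman agreement between repeated ratings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GroupSummary", "EffectSize", "RocResult", "AgreementReport",
    "CorrelationResult",
    "aggregate_per_mouse", "group_summary", "two_sample_test", "hedges_g",
    "mean_ci", "empirical_roc", "youden_optimal", "wilson_ci",
    "pearson_corr", "linear_fit", "bland_altman",
]


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class EffectSize:
    """Hedges' g with a normal-approximation CI.

    The correction factor J = 1 − 3/(4N − 9) (N = n1 + n2) shrinks Cohen's
    d toward zero; the default CI is computed on d and then scaled by J.
    """

    g: float
    ci95: tuple[float, float]
    d: float
    pooled_sd: float
    correction: float


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: str  # "lower" => smaller scores indicate the positive class


@dataclass
class AgreementReport:
    bias: float
    loa: tuple[float, float]
    sd_diff: float
    n: int
    pairs: pd.DataFrame  # columns: mean, difference


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------


def aggregate_per_mouse(measurements: pd.DataFrame, study: pd.DataFrame,
                        value_col: str = "value") -> pd.DataFrame:
    """Per-mouse unweighted mean of image-level values, with group labels.

    ``measurements`` must carry ``image_id`` and the value column;
    ``study`` maps ``image_id`` → ``mouse_id`` and ``group``. Result is
    sorted by mouse_id, hence independent of input row order.
    """
    merged = measurements[["image_id", value_col]].merge(
        study[["image_id", "mouse_id", "group"]], on="image_id", how="left")
    if merged["mouse_id"].isna().any():
        missing = merged.loc[merged["mouse_id"].isna(), "image_id"].tolist()
        raise ValueError(f"images without a study record: {missing}")
    per_mouse = (merged.groupby(["mouse_id", "group"], as_index=False)[value_col]
                 .mean().sort_values("mouse_id").reset_index(drop=True))
    return per_mouse


def mean_ci(mean: float, sd: float, n: int, level: float = 0.95,
            ) -> tuple[float, float]:
    """t-based confidence interval for a group mean: mean ± t·sd/√n."""
    if n < 2:
        raise ValueError("need n >= 2 for a mean CI")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    return (mean - half, mean + half)


def group_summary(values: np.ndarray, name: str = "", level: float = 0.95,
                  ) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return GroupSummary(name=name, n=n, mean=mean, sd=sd,
                        ci95=mean_ci(mean, sd, n, level))


def two_sample_test(a: np.ndarray, b: np.ndarray, welch: bool = False,
                    ) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test; pooled-variance Student by default.

    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue)


def hedges_g(n1: int, mean1: float, sd1: float,
             n2: int, mean2: float, sd2: float,
             ci_on_d: bool = True, level: float = 0.95) -> EffectSize:
    """Hedges' g from group summaries.

    d = (mean1 − mean2) / pooled_sd with the pooled SD over n1+n2−2 df;
    g = J·d with J = 1 − 3/(4N − 9). With ``ci_on_d`` (default) the
    normal-approximation CI is computed on d and then scaled by J; the
    alternative computes it directly on g.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (mean1 - mean2) / pooled
    N = n1 + n2
    J = 1.0 - 3.0 / (4.0 * N - 9.0)
    g = J * d
    z = stats.norm.ppf(0.5 + level / 2.0)
    if ci_on_d:
        se = np.sqrt(N / (n1 * n2) + d**2 / (2.0 * N))
        ci = (J * (d - z * se), J * (d + z * se))
    else:
        se = np.sqrt(N / (n1 * n2) + g**2 / (2.0 * N))
        ci = (g - z * se, g + z * se)
    return EffectSize(g=float(g), ci95=(float(ci[0]), float(ci[1])),
                      d=float(d), pooled_sd=float(pooled), correction=float(J))


# ---------------------------------------------------------------------------
# ROC


def empirical_roc(scores: np.ndarray, labels: np.ndarray,
                  direction: str = "lower") -> RocResult:
    """Empirical ROC curve over all distinct score thresholds.

    ``labels`` are 1 for the positive (diseased) class. With
    ``direction="lower"`` smaller scores indicate the positive class (a
    reduced slit fraction marks injury); ``"higher"`` flips that. The AUC
    (trapezoid rule) equals the Mann–Whitney pair statistic with ties
    counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if direction == "lower":
        s = -scores
    elif direction == "higher":
        s = scores
    else:
        raise ValueError("direction must be 'lower' or 'higher'")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = labels[order]
    # cumulative counts at each distinct threshold (classify positive if s >= thr)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[idx]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thresholds,
                     direction=direction)


def youden_optimal(roc: RocResult, scores: np.ndarray | None = None,
                   ) -> tuple[float, float, float, float]:
    """Youden-optimal operating point of an empirical ROC curve.

    Returns ``(threshold, J, sensitivity, specificity)`` where
    J = max(TPR − FPR); ties break toward higher specificity (lower FPR).
    The threshold is reported on the original score scale, as the midpoint
    between the adjacent observed scores straddling the optimal cut when
    ``scores`` is provided, else the internal cut value.
    """
    j_all = roc.tpr - roc.fpr
    best = None
    for i in range(len(j_all)):
        key = (round(float(j_all[i]), 12), -float(roc.fpr[i]))
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    j = float(j_all[i])
    sens = float(roc.tpr[i])
    spec = float(1.0 - roc.fpr[i])
    thr_internal = float(roc.thresholds[i])
    sign = -1.0 if roc.direction == "lower" else 1.0
    if scores is not None and np.isfinite(thr_internal):
        s = sign * np.asarray(scores, dtype=float)
        below = s[s < thr_internal]
        if len(below):
            thr_internal = 0.5 * (thr_internal + below.max())
    threshold = sign * thr_internal
    return threshold, j, sens, spec


def wilson_ci(successes: int, trials: int, level: float = 0.95,
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (bounds in [0, 1])."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level,
                                method="wilson")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# association and agreement


def pearson_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares line fit; returns (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementReport:
    """Bland–Altman agreement between paired measurements.

    bias = mean(a − b); limits of agreement = bias ± 1.96·SD(a − b)
    (sample SD, n−1). The per-pair (mean, difference) rows support the
    usual agreement scatter plot.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired inputs must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    pairs = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return AgreementReport(bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd),
                           sd_diff=sd, n=len(a), pairs=pairs)
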