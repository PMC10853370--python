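"""Formula-level cohort statistics.

Every statistic is computed from its defining formula — between/within
sum-of-squares ANOVA, least-significant-difference (LSD) pairwise t tests
on the pooled ANOVA error, product-moment correlation with Fisher-z
confidence intervals, Pearson chi-squared, pooled-variance two-sample t,
and an ROC/Youden analysis whose trapezoidal AUC equals the Mann–Whitney
pair-counting probability with ties weighted 1/2. Only distribution
functions (F, t, chi², normal quantile) come from scipy.

Conventions: all tests are two-sided; LSD applies no multiplicity
correction (that is its definition); the t test pools variances; the
chi-squared test uses no continuity correction. For ROC, the positive
class is radiation encephalopathy (RE+) and the default orientation is
"lower-positive": a LOWER ALPS index indicates higher RE risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as _dist

__all__ = [
    "AnovaResult",
    "PairwiseTest",
    "CorrelationResult",
    "Chi2Result",
    "TTestResult",
    "RocCurve",
    "YoudenResult",
    "one_way_anova",
    "anova_from_summary",
    "lsd_posthoc",
    "pearson_fisher_ci",
    "ci_from_r_n",
    "chi_square_test",
    "two_sample_t",
    "roc_curve",
    "auc_trapezoid",
    "youden_optimal_cutoff",
    "auc_category",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: Dict[str, float]
    group_ns: Dict[str, int]


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci: Tuple[float, float]
    p: float
    n: int
    alpha: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class RocCurve:
    """Threshold sweep of sensitivity/specificity.

    ``thresholds`` are on the original score scale (midpoints between
    adjacent distinct scores plus ∓∞ sentinels). With orientation
    "lower-positive" a subject is called positive when its score is ≤ the
    threshold; "higher-positive" flips the comparison.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str
    positive_label: object

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    j: float


# ---------------------------------------------------------------------------
# group comparisons


def _split_groups(values, groups) -> Dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out = {}
    for g in unique_in_order(groups):
        out[g] = values[groups == g]
    return out


def unique_in_order(arr) -> list:
    """Unique labels in order of first appearance."""
    seen: dict = {}
    for a in np.asarray(arr).ravel():
        seen.setdefault(a, None)
    return list(seen)


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from raw data."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    ns = {g: v.size for g, v in by.items()}
    means = {g: float(v.mean()) for g, v in by.items()}
    n_total = sum(ns.values())
    grand = sum(ns[g] * means[g] for g in by) / n_total
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in by)
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in by.values())
    df_b = len(by) - 1
    df_w = n_total - len(by)
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / ms_w
    p = float(_dist.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p,
                       ms_within=ms_w, group_means=means, group_ns=ns)


def anova_from_summary(
    ns: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) summaries.

    SS_between = Σ nᵢ(x̄ᵢ − x̄)²; SS_within = Σ (nᵢ−1)sᵢ². Lets printed
    demographic tables be checked without the raw data.
    """
    ns = np.asarray(ns, dtype=int)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.size == means.size == sds.size) or ns.size < 2:
        raise ValueError("need >= 2 groups of equal-length summaries")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(((ns - 1) * sds**2).sum())
    df_b = ns.size - 1
    df_w = n_total - ns.size
    ms_w = ss_w / df_w
    f = (ss_b / df_b) / ms_w if ms_w > 0 else (0.0 if ss_b == 0 else np.inf)
    p = float(_dist.f.sf(f, df_b, df_w))
    labels = [f"group{i}" for i in range(ns.size)]
    return AnovaResult(
        f=float(f), df_between=df_b, df_within=df_w, p=p, ms_within=ms_w,
        group_means=dict(zip(labels, means.tolist())),
        group_ns=dict(zip(labels, ns.tolist())),
    )


def lsd_posthoc(values: Sequence[float], groups: Sequence) -> List[PairwiseTest]:
    """Least-significant-difference pairwise tests.

    Each pair uses t = (x̄ᵢ − x̄ⱼ)/√(MSE·(1/nᵢ + 1/nⱼ)) with the pooled
    ANOVA error and df = N − k. By definition LSD applies no multiplicity
    adjustment.
    """
    anova = one_way_anova(values, groups)
    labels = list(anova.group_means)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = anova.group_means[a] - anova.group_means[b]
            se = np.sqrt(anova.ms_within * (1 / anova.group_ns[a] + 1 / anova.group_ns[b]))
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(2 * _dist.t.sf(abs(t), anova.df_within))
            out.append(PairwiseTest(a, b, float(diff), float(t), anova.df_within, p))
    return out


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance Student t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    diff = a.mean() - b.mean()
    t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
    p = float(2 * _dist.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)


# ---------------------------------------------------------------------------
# correlation


def ci_from_r_n(r: float, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh r ± z_{1−α/2}/√(n−3))."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = np.arctanh(r)
    half = _dist.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_fisher_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Product-moment r with Fisher-z CI and a t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float((xc * yc).sum() / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * _dist.t.sf(abs(t), n - 2))
        ci = ci_from_r_n(r, n, alpha)
    return CorrelationResult(r=r, ci=ci, p=p, n=n, alpha=alpha)


# ---------------------------------------------------------------------------
# contingency


def chi_square_test(table: Sequence[Sequence[float]]) -> Chi2Result:
    """Pearson chi-squared on an r×c count table, no continuity correction.

    Warns when any expected cell is below 5 (small-sample caveat), but
    does not switch to an exact test.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("contingency table has a zero margin")
    expected = np.outer(rows, cols) / total
    if np.any(expected < 5):
        warnings.warn(
            "expected cell count < 5; the chi-squared approximation may be poor",
            stacklevel=2,
        )
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_dist.chi2.sf(chi2, df))
    return Chi2Result(chi2=chi2, df=df, p=p)


# ---------------------------------------------------------------------------
# ROC / Youden


def roc_curve(
    scores: Sequence[float],
    labels: Sequence,
    positive_label,
    orientation: str = "lower-positive",
) -> RocCurve:
    """Threshold sweep over midpoints of adjacent distinct scores.

    With "lower-positive" orientation (the ALPS convention: impaired
    glymphatic transport lowers the index) a score ≤ threshold is called
    positive; sensitivity and specificity follow. ∓∞ sentinels guarantee
    the degenerate operating points (sens, spec) = (0, 1) and (1, 0).
    """
    if orientation not in ("lower-positive", "higher-positive"):
        raise ValueError("orientation must be 'lower-positive' or 'higher-positive'")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    s_pos = scores[pos]
    s_neg = scores[~pos]
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        if orientation == "lower-positive":
            sens[i] = np.mean(s_pos <= c)
            spec[i] = np.mean(s_neg > c)
        else:
            sens[i] = np.mean(s_pos >= c)
            spec[i] = np.mean(s_neg < c)
    return RocCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        orientation=orientation, positive_label=positive_label,
    )


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the (FPR, TPR) curve.

    Equals the probability that a random positive ranks above a random
    negative, counting ties 1/2 (Mann–Whitney).
    """
    order = np.argsort(curve.fpr, kind="stable")
    fpr = curve.fpr[order]
    tpr = curve.tpr[order]
    # collapse duplicate FPR values keeping the full TPR range ordering
    order2 = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order2], fpr[order2]))


def youden_optimal_cutoff(curve: RocCurve) -> YoudenResult:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity, then the lower threshold.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = None
    for i in range(curve.thresholds.size):
        key = (j[i], curve.sensitivity[i], -curve.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return YoudenResult(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        j=float(j[i]),
    )


def auc_category(auc: float) -> str:
    """Qualitative AUC band: ≥0.9 excellent, 0.7–0.9 good, 0.6–0.7 fair,
    else poor."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.7:
        return "good"
    if auc >= 0.6:
        return "fair"
    return "poor"
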