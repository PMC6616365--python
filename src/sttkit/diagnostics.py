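"""Diagnostic evaluation statistics.

Empirical ROC analysis with the distance-to-corner cutoff rule
(minimize (1 - sensitivity)^2 + (1 - specificity)^2), trapezoidal AUC
(identical to the Mann-Whitney pair statistic with ties counted 1/2),
DeLong and stratified-bootstrap 95% confidence intervals, sensitivity and
specificity from confusion counts, Spearman rank correlation, a two-way
single-measure consistency ICC with an F-based interval, and the unpaired
two-sample t-test.

Thresholds are placed at midpoints between consecutive distinct scores
(plus -inf/+inf sentinels), so reported cutoffs generally are not observed
score values.  ``direction`` states which tail is called positive
(diseased): ``lower_is_positive`` for scores where impairment lowers the
value (the 0-100 tracing score), ``higher_is_positive`` otherwise (e.g.
tracing accuracy, where patients accumulate larger deviations).

Reported values are conventionally rounded half-up to 2 decimals
(sens/spec/AUC/ICC/rho) and 1 decimal (means, cutoffs) by
:func:`round_half_up`; full precision is always retained in the result
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "ICCResult",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "sens_spec_from_counts",
    "auc_ci",
    "spearman",
    "icc",
    "two_sample_ttest",
    "round_half_up",
]

DIRECTIONS = ("lower_is_positive", "higher_is_positive")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    cutoff_sens: float
    cutoff_spec: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc must lie in [0, 1], got {self.auc}")
        if not (self.auc_ci[0] - 1e-12 <= self.auc <= self.auc_ci[1] + 1e-12):
            raise ValueError(f"auc_ci {self.auc_ci} does not contain auc {self.auc}")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci: tuple[float, float]
    model: str

    def __post_init__(self) -> None:
        if not (self.ci[0] - 1e-12 <= self.icc <= self.ci[1] + 1e-12):
            raise ValueError(f"ci {self.ci} does not contain icc {self.icc}")


def _check_scores_labels(scores, labels, direction):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = np.isin(labels, ("patient",))
    neg = np.isin(labels, ("healthy", "control"))
    if not np.all(pos | neg):
        bad = set(labels[~(pos | neg)])
        raise ValueError(f"unknown labels {bad}; use patient / healthy / control")
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both classes must be present")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    return scores, pos


def _thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _sens_spec_at(scores, pos, thr, direction):
    if direction == "lower_is_positive":
        called_pos = scores[:, None] <= thr[None, :]
    else:
        called_pos = scores[:, None] >= thr[None, :]
    sens = called_pos[pos].mean(axis=0)
    spec = (~called_pos[~pos]).mean(axis=0)
    return sens, spec


def auc(scores, labels, direction: str = "lower_is_positive") -> float:
    """Trapezoidal area under the empirical ROC.

    Equals the Mann-Whitney pair statistic: the fraction of
    (patient, healthy) pairs ranked in the positive direction, ties 1/2.
    """
    scores, pos = _check_scores_labels(scores, labels, direction)
    thr = _thresholds(scores)
    sens, spec = _sens_spec_at(scores, pos, thr, direction)
    fpr = 1.0 - spec
    # lexicographic: equal-fpr points must ascend in sens for a monotone curve
    order = np.lexsort((sens, fpr))
    return float(np.trapezoid(sens[order], fpr[order]))


def roc_curve(scores, labels, direction: str = "lower_is_positive", ci_method: str = "delong", seed: int | None = None) -> ROCResult:
    """Full empirical ROC with AUC, 95% CI and the distance-to-corner cutoff."""
    scores, pos = _check_scores_labels(scores, labels, direction)
    thr = _thresholds(scores)
    sens, spec = _sens_spec_at(scores, pos, thr, direction)
    area = auc(scores, labels, direction)
    labels_arr = np.where(pos, "patient", "healthy")
    ci = auc_ci(scores, labels_arr, direction, method=ci_method, seed=seed)
    cut_i = _optimal_index(thr, sens, spec)
    return ROCResult(
        thresholds=thr,
        sens=sens,
        spec=spec,
        auc=area,
        auc_ci=ci,
        cutoff=float(thr[cut_i]),
        cutoff_sens=float(sens[cut_i]),
        cutoff_spec=float(spec[cut_i]),
        direction=direction,
    )


def _optimal_index(thr, sens, spec) -> int:
    d2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    # tie-break ladder: distance, then higher sens, then higher spec, then
    # smaller threshold; argmin on the lexicographic key
    best = 0
    for i in range(1, len(thr)):
        key_i = (d2[i], -sens[i], -spec[i], thr[i])
        key_b = (d2[best], -sens[best], -spec[best], thr[best])
        if key_i < key_b:
            best = i
    return best


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold minimizing (1 - sens)^2 + (1 - spec)^2 on the ROC curve."""
    return float(roc.thresholds[_optimal_index(roc.thresholds, roc.sens, roc.spec)])


def sens_spec_from_counts(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """(sensitivity, specificity) from confusion counts, rounded to 2 decimals."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if tp + fn < 1:
        raise ValueError("no positives: tp + fn must be >= 1")
    if tn + fp < 1:
        raise ValueError("no negatives: tn + fp must be >= 1")
    return (
        round_half_up(tp / (tp + fn), 2),
        round_half_up(tn / (tn + fp), 2),
    )


# ---------------------------------------------------------------------------
# AUC confidence intervals


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[float, float]:
    """DeLong point AUC and variance for higher-is-positive orientation."""
    m, n = len(pos_scores), len(neg_scores)
    # placement values via midranks
    v10 = np.array(
        [(np.sum(s > neg_scores) + 0.5 * np.sum(s == neg_scores)) / n for s in pos_scores]
    )
    v01 = np.array(
        [(np.sum(pos_scores > s) + 0.5 * np.sum(pos_scores == s)) / m for s in neg_scores]
    )
    a = v10.mean()
    # a single-member class has no estimable placement variance
    var_pos = np.var(v10, ddof=1) / m if m > 1 else 0.0
    var_neg = np.var(v01, ddof=1) / n if n > 1 else 0.0
    return float(a), float(var_pos + var_neg)


def auc_ci(
    scores,
    labels,
    direction: str = "lower_is_positive",
    method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """95% CI for the AUC, clipped to [0, 1].

    ``delong`` is deterministic; ``bootstrap`` draws seeded stratified
    resamples and takes the percentile interval.
    """
    scores, pos = _check_scores_labels(scores, labels, direction)
    point = auc(scores, labels, direction)
    if method == "delong":
        # orient so the positive class should score higher
        s = -scores if direction == "lower_is_positive" else scores
        _, var = _delong_variance(s[pos], s[~pos])
        if var <= 0:
            warnings.warn(
                "degenerate AUC (no score overlap): DeLong variance is 0; "
                "returning the widest sensible interval",
                stacklevel=2,
            )
            return (0.0, 1.0) if point in (0.0, 1.0) else (point, point)
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        return (max(0.0, point - half), min(1.0, point + half))
    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(pos)
        neg_idx = np.flatnonzero(~pos)
        labels_arr = np.where(pos, "patient", "healthy")
        vals = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
            )
            vals[b] = auc(scores[take], labels_arr[take], direction)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (max(0.0, min(float(lo), point)), min(1.0, max(float(hi), point)))
    raise ValueError(f"unknown CI method {method!r}; use 'delong' or 'bootstrap'")


# ---------------------------------------------------------------------------
# correlation, reliability, group comparison


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: a variable is constant")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def icc(data, model: str = "consistency") -> ICCResult:
    """Two-way mixed, single-measure ICC from the n x k ratings matrix.

    ``consistency`` (default) is ICC(3,1) = (MS_rows - MS_err) /
    (MS_rows + (k-1) MS_err); ``agreement`` is ICC(2,1), which also charges
    systematic column differences.  95% CI by the standard F interval
    (exact for consistency, Satterthwaite approximation for agreement).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n >= 2 by k >= 2 ratings matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratings matrix has missing or non-finite cells")
    n, k = X.shape
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("zero total variance: all ratings identical")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    alpha = 0.05
    if model == "consistency":
        value = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        if ms_err == 0:
            lo = hi = value
        else:
            f_obs = ms_rows / ms_err
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        label = "ICC(3,1) two-way mixed, single measures, consistency"
    elif model == "agreement":
        value = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
        )
        a = k * value / (n * (1 - value)) if value < 1 else np.inf
        b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
        if np.isinf(a) or ms_err == 0:
            lo = hi = value
        else:
            v_num = (a * ms_cols + b * ms_err) ** 2
            v_den = (a * ms_cols) ** 2 / (k - 1) + (b * ms_err) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (ms_rows - f1 * ms_err) / (
                f1 * (k * ms_cols + (k * n - k - n) * ms_err) + n * ms_rows
            )
            hi = n * (f2 * ms_rows - ms_err) / (
                k * ms_cols + (k * n - k - n) * ms_err + n * f2 * ms_rows
            )
        label = "ICC(2,1) two-way random, single measures, absolute agreement"
    else:
        raise ValueError(f"unknown ICC model {model!r}; use 'consistency' or 'agreement'")
    lo, hi = min(lo, value), max(hi, value)
    return ICCResult(icc=float(value), ci=(float(lo), float(hi)), model=label)


def two_sample_ttest(a, b, variant: str = "student") -> tuple[float, float]:
    """Unpaired two-sided t-test; ``student`` pools variance, ``welch`` does not."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            raise ValueError("zero variance in both groups with equal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
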