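"""Reliability and diagnostic-accuracy statistics for qDESH validation.

* **ICC(A,1)** — intraclass correlation, two-way mixed-effects model,
  absolute agreement, single measures, with the F-based 95% confidence
  interval (McGraw & Wong convention). Used for interrater agreement of
  qDESH and its component volumes.
* **Bland–Altman** — mean rater difference, 95% limits of agreement
  (mean +/- 1.96 SD of the differences), and the least-squares slope of
  difference against average (proportional-bias check).
* **ROC / AUC** — the area under the ROC curve in its normalized
  Mann–Whitney U form (ties count one half), with the DeLong
  structural-component variance for confidence intervals and the DeLong
  test for comparing two correlated AUCs measured on the same subjects.
* **Sensitivity / specificity at a cutoff** — positives score at or above
  the cutoff (high qDESH indicates iNPH), negatives below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "IccResult",
    "BlandAltmanResult",
    "ReliabilityResult",
    "ROCResult",
    "icc_a1",
    "bland_altman",
    "assess_reliability",
    "roc_auc",
    "delong_ci",
    "delong_paired_test",
    "sens_spec_at_cutoff",
    "roc_analysis",
]


@dataclass
class RatingsMatrix:
    """n_subjects x n_raters score matrix with labels."""

    values: np.ndarray
    subjects: list[str]
    raters: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2D subjects x raters matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if len(self.subjects) != n or len(self.raters) != k:
            raise ValueError("label lengths do not match matrix shape")


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("ICC outside its confidence interval")


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float

    def __post_init__(self):
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ValueError("mean difference outside limits of agreement")


@dataclass
class ReliabilityResult:
    icc: IccResult
    bland_altman: BlandAltmanResult | None

    def to_dict(self) -> dict:
        out = {
            "icc": self.icc.icc,
            "icc_ci_low": self.icc.ci_low,
            "icc_ci_high": self.icc.ci_high,
            "icc_p_value": self.icc.p_value,
        }
        if self.bland_altman is not None:
            ba = self.bland_altman
            out.update(
                mean_diff=ba.mean_diff,
                loa_low=ba.loa_low,
                loa_high=ba.loa_high,
                slope=ba.slope,
            )
        return out


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float | None
    sensitivity: float | None
    specificity: float | None

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


# ---------------------------------------------------------------------------
# ICC and Bland-Altman


def _mean_squares(values: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters), error."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_a1(ratings: RatingsMatrix | np.ndarray, level: float = 0.95) -> IccResult:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) from the
    two-way mean squares; the confidence interval uses the F-distribution
    construction for this form, and the p-value tests ICC = 0 via
    F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    values = ratings.values if isinstance(ratings, RatingsMatrix) else np.asarray(
        ratings, dtype=float
    )
    if values.ndim != 2 or values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("ICC needs at least 3 subjects and 2 raters")
    msr, msc, mse, n, k = _mean_squares(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined for constant ratings")
    icc = (msr - mse) / denom

    alpha = 1.0 - level
    if mse == 0 and msc == msr:
        # perfect agreement: interval degenerates at 1
        return IccResult(1.0, 1.0, 1.0, float("inf"), 0.0)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else float("inf")
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low = ci_high = icc
    f_value = msr / mse if mse > 0 else float("inf")
    p_value = float(stats.f.sf(f_value, n - 1, (n - 1) * (k - 1))) if mse > 0 else 0.0
    ci_low, ci_high = min(ci_low, icc), max(ci_high, icc)
    return IccResult(float(icc), float(ci_low), float(ci_high), float(f_value), p_value)


def bland_altman(pairs: np.ndarray) -> BlandAltmanResult:
    """Mean difference, 95% limits of agreement, and proportional-bias slope.

    ``pairs`` is an n x 2 array of the two raters' scores; limits are
    mean +/- 1.96 x SD of the paired differences (SD with n-1 denominator),
    and the slope/intercept come from least squares of difference on average.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("Bland-Altman needs an n x 2 array")
    if pairs.shape[0] < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diff = pairs[:, 0] - pairs[:, 1]
    avg = pairs.mean(axis=1)
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(avg) == 0:
        slope, intercept = 0.0, mean_diff
    else:
        slope, intercept = (float(v) for v in np.polyfit(avg, diff, 1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        slope=slope,
        intercept=intercept,
    )


def assess_reliability(ratings: RatingsMatrix, level: float = 0.95) -> ReliabilityResult:
    """ICC(A,1) plus, for exactly two raters, the Bland-Altman quantities."""
    icc = icc_a1(ratings, level=level)
    ba = bland_altman(ratings.values) if ratings.values.shape[1] == 2 else None
    return ReliabilityResult(icc=icc, bland_altman=ba)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic.

    AUC = (# positive-negative pairs with score_pos > score_neg
           + 1/2 x tied pairs) / (n_pos x n_neg).
    """
    pos, neg = _split_scores(scores, labels)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean())


def _delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (per positive) and V01."""
    pos, neg = _split_scores(scores, labels)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for a single AUC, clipped to [0, 1]."""
    auc, v10, v01 = _delong_components(scores, labels)
    if len(v10) < 2 or len(v01) < 2:
        raise ValueError("DeLong CI needs at least 2 members per class")
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns (z, two-sided p) for the null AUC_a = AUC_b, using the
    structural-component covariance between the two score vectors. A zero
    AUC difference with zero estimated variance (e.g. identical or
    monotonically related scores) gives z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("degenerate DeLong variance with nonzero AUC difference")
    z = diff / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def sens_spec_at_cutoff(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity (positives >= cutoff) and specificity (negatives < cutoff)."""
    pos, neg = _split_scores(scores, labels)
    return float((pos >= cutoff).mean()), float((neg < cutoff).mean())


def roc_analysis(
    scores, labels, cutoff: float | None = None, level: float = 0.95
) -> ROCResult:
    """AUC with DeLong CI and, optionally, sensitivity/specificity at a cutoff."""
    auc = roc_auc(scores, labels)
    ci_low, ci_high = delong_ci(scores, labels, level=level)
    sens = spec = None
    if cutoff is not None:
        sens, spec = sens_spec_at_cutoff(scores, labels, cutoff)
    return ROCResult(auc, ci_low, ci_high, cutoff, sens, spec)
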