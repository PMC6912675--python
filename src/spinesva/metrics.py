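"""SVA computation and evaluation statistics.

The sagittal vertical axis (SVA) is the horizontal offset, in millimetres, of
a vertical plumb line dropped from the C7 vertebral-body center relative to
the posterior-superior corner of S1 on a standing lateral radiograph.
Positive SVA means the plumb line falls anterior to the sacral corner
(forward-leaning posture).

Evaluation follows the standard repertoire for automated measurement
studies: the median absolute SVA error with a >10 mm outlier count,
landmark detection rates as a function of a millimetre error threshold,
two-way random-effects intraclass correlation with absolute agreement
(McGraw-Wong ICC(A,1), single measure) for inter-rater comparisons, and
Bland-Altman limits of agreement.

All landmark-based metrics expect points in the ORIGINAL image resolution
(after inverting the canvas transform); pixel offsets are converted to mm
per axis before Euclidean distances, since the resize step is anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .heatmaps import LandmarkPoint
from .preprocess import ImageRecord

__all__ = [
    "BlandAltmanResult",
    "DetectionCurve",
    "ErrorSummary",
    "IccResult",
    "SvaEstimate",
    "bland_altman",
    "compute_sva",
    "detection_curve",
    "detection_rate",
    "icc_two_way_random_absolute",
    "landmark_distances_mm",
    "mae_sva",
]

OUTLIER_THRESHOLD_MM = 10.0


@dataclass(frozen=True)
class SvaEstimate:
    """Signed SVA in millimetres (positive = C7 plumb line anterior to the sacral corner)."""

    value: float


@dataclass(frozen=True)
class ErrorSummary:
    median_abs_error: float
    n: int
    outlier_count: int
    outlier_fraction: float
    outlier_threshold_mm: float = OUTLIER_THRESHOLD_MM


@dataclass(frozen=True)
class DetectionCurve:
    thresholds: tuple[float, ...]
    rates: tuple[float, ...]
    landmark: str = ""


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    median_abs_diff: float
    n: int


def _facing_sign(facing: str) -> float:
    # Anterior is the direction the patient faces: toward increasing x when
    # facing 'right', toward decreasing x when facing 'left'.
    if facing == "right":
        return 1.0
    if facing == "left":
        return -1.0
    raise ValueError(f"facing must be 'left' or 'right', got {facing!r}")


def compute_sva(
    c7: LandmarkPoint, s1: LandmarkPoint, record: ImageRecord
) -> SvaEstimate:
    """Signed SVA in mm from original-frame landmarks and the image's physical scale."""
    if not record.mm_per_pixel_x > 0:
        raise ValueError("record is missing a positive mm_per_pixel_x scale")
    value = (c7.x - s1.x) * record.mm_per_pixel_x * _facing_sign(record.facing)
    return SvaEstimate(value=float(value))


def mae_sva(
    true_mm: Sequence[float],
    pred_mm: Sequence[float],
    outlier_threshold_mm: float = OUTLIER_THRESHOLD_MM,
) -> ErrorSummary:
    """Median absolute SVA error plus the count of absolute errors above threshold.

    The median of an even-length sample is the mean of the two central order
    statistics.  The median is robust, so the outlier count is reported
    alongside it.
    """
    t = np.asarray(true_mm, dtype=float)
    p = np.asarray(pred_mm, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("need at least one pair")
    abs_err = np.abs(t - p)
    outliers = int(np.sum(abs_err > outlier_threshold_mm))
    return ErrorSummary(
        median_abs_error=float(np.median(abs_err)),
        n=int(t.size),
        outlier_count=outliers,
        outlier_fraction=outliers / t.size,
        outlier_threshold_mm=outlier_threshold_mm,
    )


def landmark_distances_mm(
    true_points: Sequence[LandmarkPoint],
    pred_points: Sequence[LandmarkPoint],
    records: Sequence[ImageRecord],
) -> np.ndarray:
    """Physical Euclidean distances sqrt((dx*mm_x)^2 + (dy*mm_y)^2), per pair."""
    if not (len(true_points) == len(pred_points) == len(records)):
        raise ValueError(
            f"mismatched lengths: {len(true_points)} true, {len(pred_points)} "
            f"predicted, {len(records)} records"
        )
    out = np.empty(len(true_points))
    for i, (t, p, r) in enumerate(zip(true_points, pred_points, records)):
        dx = (t.x - p.x) * r.mm_per_pixel_x
        dy = (t.y - p.y) * r.mm_per_pixel_y
        out[i] = np.hypot(dx, dy)
    return out


def detection_rate(
    true_points: Sequence[LandmarkPoint],
    pred_points: Sequence[LandmarkPoint],
    records: Sequence[ImageRecord],
    threshold_mm: float,
) -> float:
    """Fraction of landmark pairs within ``threshold_mm`` physical distance."""
    d = landmark_distances_mm(true_points, pred_points, records)
    return float(np.mean(d <= threshold_mm))


def detection_curve(
    true_points: Sequence[LandmarkPoint],
    pred_points: Sequence[LandmarkPoint],
    records: Sequence[ImageRecord],
    thresholds_mm: Sequence[float],
    landmark: str = "",
) -> DetectionCurve:
    d = landmark_distances_mm(true_points, pred_points, records)
    rates = tuple(float(np.mean(d <= t)) for t in thresholds_mm)
    return DetectionCurve(thresholds=tuple(float(t) for t in thresholds_mm), rates=rates, landmark=landmark)


def icc_two_way_random_absolute(
    ratings: np.ndarray, confidence: float = 0.95
) -> IccResult:
    """Single-measure ICC under a two-way random-effects model with absolute agreement.

    This is McGraw-Wong ICC(A,1): subjects and raters are both random
    effects, and systematic rater offsets count against agreement.  From the
    two-way ANOVA mean squares (MSR rows/subjects, MSC columns/raters, MSE
    residual):

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval follows the F-based method with a Satterthwaite
    degrees-of-freedom approximation.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) array")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.allclose(x, x.flat[0]):
        # All values identical: perfect but variance-free agreement.
        return IccResult(estimate=1.0, ci_low=1.0, ci_high=1.0, degenerate=True)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = (
            n * (msr - f_low * mse)
            / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = (
            n * (f_up * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
        )
    else:
        ci_low, ci_high = icc, icc
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return IccResult(estimate=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Agreement summary of paired measurements via differences a - b.

    Reports the mean difference, its SD, the limits of agreement
    (mean +/- 1.96 SD), and the median absolute difference.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    if av.size < 2:
        raise ValueError("need at least two pairs")
    diff = av - bv
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        median_abs_diff=float(np.median(np.abs(diff))),
        n=int(av.size),
    )
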