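"""Accuracy evaluation for automated cervical alignment measurement.

Covers the downstream analyses of a landmark-measurement validation
study: absolute-error summaries, confidence-threshold exclusion curves,
posture-classification confusion metrics, paired comparison of measurers
with Bonferroni adjustment, and percentile-based outlier flagging of
implausible measured angles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import AngleMeasurement
from .normative import COHORT_STATS, POSTURES

__all__ = [
    "MeasurementRecord",
    "ErrorSummary",
    "ExclusionCurve",
    "ClassificationMetrics",
    "OutlierBounds",
    "OutlierFlags",
    "ComparisonResult",
    "error_summary",
    "exclusion_curve",
    "confusion_metrics",
    "compare_measurers",
    "fit_outlier_bounds",
    "flag_outlier",
    "PostureClassifier",
    "fit_position_classifier",
    "classify_position",
    "round_half_away",
]

QUANTITIES = ("c2_slope", "c7_slope", "c2c7_angle")


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (reporting convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MeasurementRecord:
    """Ground truth paired with a model prediction for one radiograph."""

    image_id: str
    patient_id: str
    posture: str
    truth: AngleMeasurement
    prediction: AngleMeasurement

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def abs_error_angle(self) -> float:
        return abs(self.prediction.c2c7_angle - self.truth.c2c7_angle)

    @property
    def abs_error_c2(self) -> float:
        return abs(self.prediction.c2_slope - self.truth.c2_slope)

    @property
    def abs_error_c7(self) -> float:
        return abs(self.prediction.c7_slope - self.truth.c7_slope)

    @property
    def confidence(self) -> Optional[float]:
        return self.prediction.confidence


@dataclass(frozen=True)
class ErrorSummary:
    """Mean/SD/median/max of a set of absolute errors (degrees)."""

    mean: float
    sd: float
    median: float
    max: float
    n: int


def error_summary(errors: Sequence[float]) -> ErrorSummary:
    """Summarize absolute errors: mean, sample SD (n-1), median, max.

    The SD is undefined (NaN) for a single value.  Raises on an empty
    input or on negative entries (absolute errors are non-negative).
    """
    arr = np.asarray(list(errors), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty error list")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("absolute errors must be finite and non-negative")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return ErrorSummary(
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        max=float(np.max(arr)),
        n=int(arr.size),
    )


@dataclass(frozen=True)
class ExclusionPoint:
    threshold: float
    fraction_excluded: float
    mae: float
    max_error: float
    n_retained: int
    degenerate: bool = False


@dataclass(frozen=True)
class ExclusionCurve:
    """MAE / max error over records retained at increasing confidence cutoffs."""

    points: Tuple[ExclusionPoint, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points])


def exclusion_curve(
    records: Sequence[MeasurementRecord], thresholds: Iterable[float]
) -> ExclusionCurve:
    """Sweep a confidence threshold and report error over retained records.

    At threshold ``t`` a record is retained when its confidence is >= t.
    Reports the excluded fraction, MAE and maximum absolute C2-C7 error
    over the retained set; thresholds that exclude everything are marked
    degenerate (NaN errors).  Because retained sets are nested, the max
    error is non-increasing and the excluded fraction non-decreasing.
    """
    thresholds = sorted(set(float(t) for t in thresholds))
    if not thresholds:
        raise ValueError("at least one threshold is required")
    if not records:
        raise ValueError("no records to evaluate")
    conf = np.array(
        [r.confidence if r.confidence is not None else np.nan for r in records]
    )
    if np.any(np.isnan(conf)):
        raise ValueError("all records must carry a confidence score")
    errors = np.array([r.abs_error_angle for r in records])
    n = len(records)
    points = []
    for t in thresholds:
        keep = conf >= t
        kept = int(keep.sum())
        if kept == 0:
            points.append(
                ExclusionPoint(t, 1.0, float("nan"), float("nan"), 0, True)
            )
            continue
        points.append(
            ExclusionPoint(
                threshold=t,
                fraction_excluded=(n - kept) / n,
                mae=float(errors[keep].mean()),
                max_error=float(errors[keep].max()),
                n_retained=kept,
            )
        )
    return ExclusionCurve(points=tuple(points))


@dataclass(frozen=True)
class ClassificationMetrics:
    """Per-class and macro-averaged posture classification metrics.

    Rows of ``confusion`` are true postures, columns predictions, both in
    flexion/neutral/extension order.  Per-class entries are NaN when the
    corresponding row/column sum is zero; macro means skip NaN entries.
    """

    confusion: np.ndarray
    recall: Dict[str, float]
    precision: Dict[str, float]
    f_measure: Dict[str, float]
    accuracy: float
    macro_recall: float
    macro_precision: float
    macro_f: float


def confusion_metrics(confusion: np.ndarray) -> ClassificationMetrics:
    """Recall/precision/F per posture plus accuracy and macro means."""
    cm = np.asarray(confusion)
    if cm.shape != (3, 3):
        raise ValueError(f"expected a 3x3 confusion matrix, got {cm.shape}")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion counts must be non-negative numbers")
    cm = cm.astype(np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    diag = np.diag(cm)
    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, diag / row_sums, np.nan)
        precision = np.where(col_sums > 0, diag / col_sums, np.nan)
        f = 2 * recall * precision / (recall + precision)
        f = np.where(recall + precision > 0, f, np.nan)
    return ClassificationMetrics(
        confusion=cm.astype(np.int64) if np.allclose(cm, np.round(cm)) else cm,
        recall=dict(zip(POSTURES, recall.tolist())),
        precision=dict(zip(POSTURES, precision.tolist())),
        f_measure=dict(zip(POSTURES, f.tolist())),
        accuracy=float(diag.sum() / total),
        macro_recall=float(np.nanmean(recall)),
        macro_precision=float(np.nanmean(precision)),
        macro_f=float(np.nanmean(f)),
    )


@dataclass(frozen=True)
class MeasurerComparison:
    t_statistic: float
    p_raw: float
    p_adjusted: float
    mean_difference: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    """Per-measurer error summaries and reference-vs-measurer paired tests."""

    summaries: Dict[str, ErrorSummary]
    comparisons: Dict[str, MeasurerComparison]
    reference: str


def compare_measurers(
    errors_by_measurer: Mapping[str, Sequence[float]], reference: str = "AI"
) -> ComparisonResult:
    """Compare a reference measurer's absolute errors against the others.

    All measurers scored the same radiographs in the same order, so a
    two-sided *paired* t-test is applied to (reference - other) error
    differences.  P-values are Bonferroni-adjusted by the number of
    comparisons.  A zero-variance difference returns p = 1.0 with a
    warning (the paired test is undefined there).
    """
    if reference not in errors_by_measurer:
        raise ValueError(f"reference measurer {reference!r} missing")
    lengths = {k: len(v) for k, v in errors_by_measurer.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"error lists must be aligned; got lengths {lengths}")
    n = lengths[reference]
    if n < 2:
        raise ValueError("need at least two paired observations")
    ref = np.asarray(errors_by_measurer[reference], dtype=np.float64)
    summaries = {k: error_summary(v) for k, v in errors_by_measurer.items()}
    others = [k for k in errors_by_measurer if k != reference]
    m = len(others)
    comparisons: Dict[str, MeasurerComparison] = {}
    for name in others:
        other = np.asarray(errors_by_measurer[name], dtype=np.float64)
        diff = ref - other
        if np.ptp(diff) == 0.0:
            warnings.warn(
                f"zero-variance paired differences for {name}; the paired "
                "t-test is undefined, reporting p = 1.0",
                RuntimeWarning,
                stacklevel=2,
            )
            t_stat = 0.0 if diff[0] == 0 else math.nan
            p = 1.0
        else:
            res = stats.ttest_rel(ref, other)
            t_stat, p = float(res.statistic), float(res.pvalue)
        comparisons[name] = MeasurerComparison(
            t_statistic=t_stat,
            p_raw=p,
            p_adjusted=min(1.0, p * m),
            mean_difference=float(diff.mean()),
            n=n,
        )
    return ComparisonResult(summaries=summaries, comparisons=comparisons,
                            reference=reference)


@dataclass(frozen=True)
class OutlierBounds:
    """2.5th/97.5th percentile bounds per (posture, quantity), degrees.

    Measured values strictly outside their bounds are flagged as
    outliers that warrant human confirmation.
    """

    bounds: Dict[Tuple[str, str], Tuple[float, float]]

    def lookup(self, posture: str, quantity: str) -> Tuple[float, float]:
        try:
            return self.bounds[(posture, quantity)]
        except KeyError:
            raise ValueError(
                f"no bounds fitted for ({posture!r}, {quantity!r})"
            ) from None

    @classmethod
    def from_cohort(cls) -> "OutlierBounds":
        """Bounds taken from the normative clinical cohort percentiles."""
        bounds = {}
        for posture in POSTURES:
            for quantity in QUANTITIES:
                qs = getattr(COHORT_STATS[posture], quantity)
                bounds[(posture, quantity)] = (qs.p2_5, qs.p97_5)
        return cls(bounds=bounds)


def fit_outlier_bounds(
    measurements_by_posture: Mapping[str, Sequence[AngleMeasurement]],
) -> OutlierBounds:
    """Fit 2.5th/97.5th percentile outlier bounds per posture and quantity.

    Percentiles use linear interpolation between closest order statistics
    (NumPy's "linear" method).  Each posture group needs >= 2 values.
    """
    bounds: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for posture, measurements in measurements_by_posture.items():
        if posture not in POSTURES:
            raise ValueError(f"unknown posture {posture!r}")
        if len(measurements) < 2:
            raise ValueError(f"need >= 2 measurements for posture {posture!r}")
        for quantity in QUANTITIES:
            values = np.array([getattr(m, quantity) for m in measurements])
            lo, hi = np.percentile(values, [2.5, 97.5], method="linear")
            bounds[(posture, quantity)] = (float(lo), float(hi))
    return OutlierBounds(bounds=bounds)


@dataclass(frozen=True)
class OutlierFlags:
    """Per-quantity outlier flags; any flag recommends human confirmation."""

    c2_slope: bool
    c7_slope: bool
    c2c7_angle: bool

    @property
    def any(self) -> bool:
        return self.c2_slope or self.c7_slope or self.c2c7_angle

    @property
    def recommend_human_confirmation(self) -> bool:
        return self.any


def flag_outlier(
    measurement: AngleMeasurement, posture: str, bounds: OutlierBounds
) -> OutlierFlags:
    """Flag quantities strictly outside their fitted percentile bounds.

    Values exactly equal to a bound are considered inside (only values
    that *exceed* a percentile are outliers).
    """
    flags = {}
    for quantity in QUANTITIES:
        lo, hi = bounds.lookup(posture, quantity)
        v = getattr(measurement, quantity)
        flags[quantity] = bool(v < lo or v > hi)
    return OutlierFlags(**flags)


class PostureClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian class-conditional posture classifier on (C2 slope, C7 slope).

    Fits one bivariate normal per posture with empirical priors and
    predicts the maximum-posterior class.  Exact posterior ties break
    toward the larger prior, then the fixed flexion/neutral/extension
    order.  A singular class covariance falls back to its diagonal (with
    a warning), with a small variance floor.

    The mechanism is deliberately simple: posture separability lives
    almost entirely in the joint slope distribution.
    """

    VAR_FLOOR = 1e-6

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): c2_slope, c7_slope")
        present = [p for p in POSTURES if p in set(y.tolist())]
        extra = set(y.tolist()) - set(POSTURES)
        if extra:
            raise ValueError(f"unknown posture labels: {sorted(extra)}")
        if len(present) < 2:
            raise ValueError("need at least two posture classes to fit")
        self.classes_ = np.array(present)
        self.means_ = np.zeros((len(present), 2))
        self.covariances_ = np.zeros((len(present), 2, 2))
        self.priors_ = np.zeros(len(present))
        for i, cls in enumerate(present):
            xc = X[y == cls]
            if len(xc) < 2:
                raise ValueError(f"class {cls!r} needs >= 2 samples")
            self.means_[i] = xc.mean(axis=0)
            cov = np.cov(xc, rowvar=False, ddof=1)
            if not np.isfinite(np.linalg.cond(cov)) or np.linalg.cond(cov) > 1e12:
                warnings.warn(
                    f"singular covariance for class {cls!r}; using diagonal",
                    RuntimeWarning,
                    stacklevel=2,
                )
                cov = np.diag(np.maximum(np.diag(cov), self.VAR_FLOOR))
            self.covariances_[i] = cov
            self.priors_[i] = len(xc) / len(X)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((len(X), len(self.classes_)))
        for i in range(len(self.classes_)):
            rv = stats.multivariate_normal(self.means_[i], self.covariances_[i])
            out[:, i] = np.log(self.priors_[i]) + rv.logpdf(X)
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=np.float64).reshape(-1, 2)
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=np.float64).reshape(-1, 2)
        jll = self._joint_log_likelihood(X)
        # tie-break: larger prior first, then fixed posture order; argmax
        # returns the first maximum, so evaluate classes in preference order
        order = sorted(
            range(len(self.classes_)),
            key=lambda i: (-self.priors_[i], i),
        )
        ordered = jll[:, order]
        winners = np.argmax(ordered, axis=1)
        return self.classes_[np.array(order)[winners]]


def fit_position_classifier(
    records: Sequence[MeasurementRecord],
) -> PostureClassifier:
    """Fit the posture classifier on ground-truth slopes of the records."""
    X = np.array([[r.truth.c2_slope, r.truth.c7_slope] for r in records])
    y = np.array([r.posture for r in records])
    return PostureClassifier().fit(X, y)


def classify_position(
    classifier: PostureClassifier, measurement: AngleMeasurement
) -> str:
    """Predict the radiograph posture from one angle measurement."""
    return str(
        classifier.predict([[measurement.c2_slope, measurement.c7_slope]])[0]
    )


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Tabulate measurement records (full precision, one row per image)."""
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "posture": [r.posture for r in records],
            "c2_slope_true": [r.truth.c2_slope for r in records],
            "c7_slope_true": [r.truth.c7_slope for r in records],
            "angle_true": [r.truth.c2c7_angle for r in records],
            "c2_slope_pred": [r.prediction.c2_slope for r in records],
            "c7_slope_pred": [r.prediction.c7_slope for r in records],
            "angle_pred": [r.prediction.c2c7_angle for r in records],
            "confidence": [r.confidence for r in records],
            "abs_error_angle": [r.abs_error_angle for r in records],
        }
    )
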