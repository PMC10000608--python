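"""Segmentation metrics, measurement-error summaries and agreement regression.

Segmentation quality is scored per class with intersection-over-union,
IoU = TP / (TP + FP + FN), and pixel accuracy,
PA = (TP + TN) / (TP + TN + FP + FN), plus their means over classes.

Measurement quality is scored by per-sample absolute error against caliper
ground truth and by ordinary least squares of measured on actual values:
R² (squared Pearson correlation for the simple regression), adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2), and the regression F statistic
F = R²(n − 2)/(1 − R²).

A 15-egg measured-vs-caliper table is bundled with the package so the full
error/regression analysis can be reproduced without any image data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRegressionError,
    FixtureCorruptionError,
    ShapeError,
)
from .masks import LabelMask

__all__ = [
    "ConfusionCounts",
    "RegressionReport",
    "ErrorSummary",
    "confusion_counts",
    "iou",
    "pixel_accuracy",
    "mean_over_classes",
    "error_summary",
    "ols_report",
    "load_egg_measurement_table",
]

_FIXTURE_NAME = "egg_measurements.csv"
_FIXTURE_SHA256 = "9f610cae12651ec920b8c80ec32f57d99955ef89b7193e51b97910ccbb22913d"


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts of one class against ground truth."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_counts(pred: LabelMask, truth: LabelMask, cls) -> ConfusionCounts:
    if pred.labels.shape != truth.labels.shape:
        raise ShapeError(
            f"mask shapes differ: {pred.labels.shape} vs {truth.labels.shape}"
        )
    p = pred.class_mask(cls)
    t = truth.class_mask(cls)
    return ConfusionCounts(
        TP=int((p & t).sum()),
        FP=int((p & ~t).sum()),
        FN=int((~p & t).sum()),
        TN=int((~p & ~t).sum()),
    )


def iou(pred: LabelMask, truth: LabelMask, cls) -> float:
    """Intersection over union of one class; NaN if absent from both masks."""
    c = confusion_counts(pred, truth, cls)
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        return float("nan")  # undefined-metric flag
    return c.TP / denom


def pixel_accuracy(pred: LabelMask, truth: LabelMask, cls) -> float:
    """Per-class pixel accuracy (TP + TN) / total; NaN if class absent."""
    c = confusion_counts(pred, truth, cls)
    if c.TP + c.FP + c.FN == 0:
        return float("nan")
    return (c.TP + c.TN) / c.total


def mean_over_classes(values) -> float:
    """Mean of per-class metric values, ignoring undefined (NaN) entries."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


@dataclass
class ErrorSummary:
    per_sample: np.ndarray  # |measured - actual| per sample, mm
    max_error: float
    counts_exceeding: dict[float, int] = field(default_factory=dict)


def error_summary(measured, actual, thresholds=(1.0,)) -> ErrorSummary:
    """Absolute per-sample errors with exceedance counts at given thresholds."""
    m = np.asarray(measured, dtype=float)
    a = np.asarray(actual, dtype=float)
    if m.shape != a.shape or m.ndim != 1 or m.size < 1:
        raise ShapeError("measured and actual must be equal-length 1-D sequences")
    err = np.abs(m - a)
    return ErrorSummary(
        per_sample=err,
        max_error=float(err.max()),
        counts_exceeding={float(t): int((err > t).sum()) for t in thresholds},
    )


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    n: int
    per_sample_errors: np.ndarray

    def __post_init__(self) -> None:
        assert 0.0 <= self.r_squared <= 1.0 + 1e-12


def ols_report(x, y) -> RegressionReport:
    """OLS of measured (y) on actual (x) with agreement statistics.

    R² equals the squared Pearson correlation for this simple regression and
    is therefore direction-invariant; slope and intercept are reported for
    the measured-on-actual direction.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise DegenerateRegressionError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("constant predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    return RegressionReport(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        adj_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        n=n,
        per_sample_errors=np.abs(y - x),
    )


def load_egg_measurement_table(validate: bool = True) -> pd.DataFrame:
    """The bundled 15-egg measured-vs-caliper table (all values in mm).

    Columns: sample_id; minor/major measured, actual and printed absolute
    error.  The file checksum is verified, and (with ``validate``) every
    error cell is checked to equal |measured − actual| within 0.001 mm.
    """
    ref = resources.files("ovometry.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureCorruptionError(
            f"bundled table checksum mismatch: {digest[:12]}..."
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if validate:
        if len(df) != 15:
            raise FixtureCorruptionError(f"expected 15 rows, found {len(df)}")
        for axis in ("minor", "major"):
            recomputed = (
                df[f"{axis}_measured_mm"] - df[f"{axis}_actual_mm"]
            ).abs()
            if (recomputed - df[f"{axis}_error_mm"]).abs().max() > 0.001 + 1e-9:
                raise FixtureCorruptionError(
                    f"{axis}-axis error column inconsistent with its values"
                )
    return df
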