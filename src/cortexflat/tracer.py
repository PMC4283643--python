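"""Tracer-positive classification and manual-count calibration.

A segmented neuron counts as retrograde-tracer positive when its
integrated intensity in the appropriate tracer channel exceeds 250,000
and its maximum pixel intensity exceeds 150 (8-bit scale); both
comparisons are strict, reading "exceeded" literally.  Automated counts
systematically undercount relative to manual counts, so a per-animal
ordinary-least-squares regression of manual (response) on automated
(predictor) is fitted and the magnitude of its negative x-intercept is
added back to every included ROI's automated count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierParams",
    "CalibrationModel",
    "TracerClassifier",
    "CountCalibrator",
    "classify_tracer_positive",
    "fit_calibration",
    "apply_calibration",
]

DEFAULT_INTEGRATED_THRESHOLD = 250_000.0
DEFAULT_MAX_PIXEL_THRESHOLD = 150.0


@dataclass(frozen=True)
class ClassifierParams:
    integrated_threshold: float = DEFAULT_INTEGRATED_THRESHOLD
    max_pixel_threshold: float = DEFAULT_MAX_PIXEL_THRESHOLD
    tracer_channel: str = "tracer_red"

    def __post_init__(self) -> None:
        if self.integrated_threshold <= 0 or self.max_pixel_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_pixel_threshold > 255:
            raise ValueError("max_pixel_threshold cannot exceed 255 (8-bit)")


@dataclass
class CalibrationModel:
    """Manual-vs-automated count regression (manual = response)."""

    slope: float
    intercept: float
    r_value: float
    p_value: float
    stderr: float
    x_intercept: float
    offset_added: float
    usable: bool

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


class TracerClassifier(BaseEstimator):
    """Threshold classifier for retrograde-tracer content.

    ``predict`` flags a cell positive iff, in the tracer channel,
    ``integrated > integrated_threshold`` AND ``max > max_pixel_threshold``
    (strict conjunction).  Monotone: raising either feature never turns a
    positive into a negative.
    """

    def __init__(
        self,
        integrated_threshold: float = DEFAULT_INTEGRATED_THRESHOLD,
        max_pixel_threshold: float = DEFAULT_MAX_PIXEL_THRESHOLD,
        tracer_channel: str = "tracer_red",
    ) -> None:
        self.integrated_threshold = integrated_threshold
        self.max_pixel_threshold = max_pixel_threshold
        self.tracer_channel = tracer_channel

    def fit(self, X=None, y=None) -> "TracerClassifier":
        # fixed-rule classifier: fit only validates parameters
        ClassifierParams(
            self.integrated_threshold, self.max_pixel_threshold, self.tracer_channel
        )
        self.is_fitted_ = True
        return self

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        integ_col = f"{self.tracer_channel}_integrated"
        max_col = f"{self.tracer_channel}_max"
        missing = {integ_col, max_col} - set(cells.columns)
        if missing:
            raise KeyError(
                f"feature table lacks tracer-channel columns: {sorted(missing)}"
            )
        integ = cells[integ_col].to_numpy(dtype=float)
        vmax = cells[max_col].to_numpy(dtype=float)
        return (integ > self.integrated_threshold) & (vmax > self.max_pixel_threshold)


def classify_tracer_positive(
    cells: pd.DataFrame, params: ClassifierParams | None = None
) -> np.ndarray:
    """Boolean tracer-positive flags for a cell feature table."""
    params = params or ClassifierParams()
    clf = TracerClassifier(
        integrated_threshold=params.integrated_threshold,
        max_pixel_threshold=params.max_pixel_threshold,
        tracer_channel=params.tracer_channel,
    ).fit()
    return clf.predict(cells)


class CountCalibrator(BaseEstimator):
    """Per-animal OLS calibration of automated against manual counts.

    ``fit(automated, manual)`` regresses manual counts on automated counts;
    the x-intercept ``-intercept/slope`` is where the fitted line predicts
    zero manual cells.  The paper-style adjustment adds
    ``offset_added = max(0, -x_intercept)`` to every ROI on the inclusion
    list (the automated method undercounts, so the x-intercept is
    negative in practice).
    """

    def fit(self, automated, manual) -> "CountCalibrator":
        automated = np.asarray(automated, dtype=float)
        manual = np.asarray(manual, dtype=float)
        if automated.shape != manual.shape or automated.ndim != 1:
            raise ValueError("automated and manual must be matching 1-D arrays")
        if len(automated) < 3:
            raise ValueError("need at least 3 count pairs to calibrate")
        if np.ptp(automated) == 0:
            raise ValueError("automated counts have zero variance")
        res = sps.linregress(automated, manual)
        usable = res.slope > 0
        if not usable:
            logger.warning(
                "calibration slope %.3g <= 0; model flagged unusable", res.slope
            )
        x_int = -res.intercept / res.slope if res.slope != 0 else np.nan
        offset = max(0.0, -x_int) if usable and np.isfinite(x_int) else 0.0
        if usable and np.isfinite(x_int) and x_int > 0:
            logger.info("positive x-intercept %.3g; applying zero offset", x_int)
        self.model_ = CalibrationModel(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_value=float(res.rvalue),
            p_value=float(res.pvalue),
            stderr=float(res.stderr),
            x_intercept=float(x_int),
            offset_added=float(offset),
            usable=bool(usable),
        )
        return self

    def transform(
        self, counts: pd.Series, included_rois: list[str] | None = None
    ) -> pd.Series:
        """Add the calibration offset to the included ROI counts."""
        model = self.model_
        if not model.usable:
            raise ValueError("calibration model unusable (slope <= 0)")
        adjusted = counts.astype(float).copy()
        rois = list(included_rois) if included_rois is not None else list(counts.index)
        adjusted[rois] = adjusted[rois] + model.offset_added
        return adjusted


def fit_calibration(pairs) -> CalibrationModel:
    """Fit the manual-on-automated regression from (manual, automated) pairs.

    ``pairs`` is an iterable of ``(manual, automated)`` tuples or a
    DataFrame with ``manual`` and ``automated`` columns.
    """
    if isinstance(pairs, pd.DataFrame):
        manual = pairs["manual"].to_numpy(dtype=float)
        automated = pairs["automated"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be (manual, automated) tuples")
        manual, automated = arr[:, 0], arr[:, 1]
    return CountCalibrator().fit(automated, manual).model_


def apply_calibration(
    counts: pd.Series,
    model: CalibrationModel,
    included_rois: list[str] | None = None,
) -> pd.Series:
    """Offset-adjust automated per-ROI counts; never decreases a count."""
    cal = CountCalibrator()
    cal.model_ = model
    return cal.transform(counts, included_rois)
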