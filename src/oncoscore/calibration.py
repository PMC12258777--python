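"""Distribution-matching calibration of the surrogate score.

Uncalibrated image-derived scores often shift in location from one
cohort to another even when their ranking is preserved. The calibration
procedure aligns them to the RS scale without requiring any measured RS
in the new cohort:

1. reserve k patients (default k=100) with complete clinicopathologic
   data (grade, PR, ER, size, age) and surrogate scores;
2. estimate the cohort mean RS as the average prediction of a
   clinicopathologic-only linear model on those k patients;
3. compute the mean of their raw surrogate scores;
4. take the single scaling factor a = mean_rs_est / mean_ai;
5. calibrate any new score by multiplying it by a.

A single multiplicative parameter is preferred for robustness; an affine
(scale-and-shift) variant matching the mean and spread of the clinical
predictions is available as an opt-in mode. The map is strictly
monotone, so AUC and every other ranking-based metric is unchanged by
calibration. Raw model predictions are clipped at zero before averaging
so the estimated mean (and hence a) is always positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import STREAM_CALIBRATION, ConfigError, DataError, substream
from .multimodal_fusion import LinearRSModel, encode_features

__all__ = [
    "CalibrationResult",
    "estimate_mean_rs",
    "compute_scaling_factor",
    "apply_calibration",
    "calibrate_cohort",
    "CALIBRATION_FEATURES",
]

#: Clinicopathologic features the mean-RS estimator relies on.
CALIBRATION_FEATURES = ["grade", "pr", "er", "size_gt_2cm", "age"]


@dataclass
class CalibrationResult:
    """Outcome of the calibration procedure.

    ``consumed_patient_ids`` lists the k calibration patients so callers
    can exclude them from downstream analyses. ``shift`` is zero in the
    default single-parameter mode.
    """

    k: int
    mean_rs_est: float
    mean_ai: float
    a: float
    shift: float = 0.0
    mode: str = "scale"
    consumed_patient_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"k": self.k, "mean_rs_est": self.mean_rs_est,
                "mean_ai": self.mean_ai, "a": self.a, "shift": self.shift,
                "mode": self.mode,
                "consumed_patient_ids": list(self.consumed_patient_ids)}


def estimate_mean_rs(clin_model: LinearRSModel, clinical_rows: pd.DataFrame) -> float:
    """Mean of the clinical model's per-patient RS predictions, clipped at 0.

    Raises a :class:`DataError` naming the offending patient and feature
    when a required clinical value is missing.
    """
    if len(clinical_rows) < 1:
        raise DataError("need at least one calibration patient")
    raw_needed = {"grade": "grade", "pr": "pr", "er": "er",
                  "size_gt_2cm": "tumor_size_cm", "age": "age"}
    for feat in clin_model.feature_names:
        col = raw_needed.get(feat, feat)
        if col in clinical_rows.columns:
            na = clinical_rows[col].isna()
            if na.any():
                pid = clinical_rows.loc[na].index[0]
                if "patient_id" in clinical_rows.columns:
                    pid = clinical_rows.loc[na, "patient_id"].iloc[0]
                raise DataError(f"patient {pid!r} is missing feature {col!r}")
    known = [f for f in clin_model.feature_names if f in raw_needed]
    X = encode_features(clinical_rows, known)
    extra = [f for f in clin_model.feature_names if f not in X.columns]
    for f in extra:
        if f not in clinical_rows.columns:
            raise DataError(f"calibration rows lack model feature {f!r}")
        X[f] = clinical_rows[f].astype(float)
    if clin_model.feature_names:
        pred = clin_model.predict(X)
    else:
        pred = np.full(len(clinical_rows), clin_model.intercept)
    return float(np.mean(np.clip(pred, 0.0, None)))


def compute_scaling_factor(mean_rs_est: float, ai_scores_k) -> float:
    """a = mean_rs_est / mean(ai_scores_k); fails on a non-positive
    denominator or estimate."""
    mean_ai = float(np.mean(np.asarray(ai_scores_k, dtype=float)))
    if not mean_ai > 0:
        raise DataError(f"calibration failure: mean raw score must be "
                        f"positive, got {mean_ai}")
    if not mean_rs_est > 0:
        raise DataError(f"calibration failure: estimated mean RS must be "
                        f"positive, got {mean_rs_est}")
    return mean_rs_est / mean_ai


def apply_calibration(scores, a: float, shift: float = 0.0) -> np.ndarray:
    """CalibratedScore = a * score (+ shift in affine mode); strictly
    monotone, hence rank-preserving."""
    if not a > 0:
        raise ConfigError(f"scaling factor a must be > 0, got {a}")
    return a * np.asarray(scores, dtype=float) + shift


def calibrate_cohort(clin_model: LinearRSModel, patients: pd.DataFrame,
                     k: int = 100, mode: str = "scale",
                     score_column: str = "ai_score",
                     selection: str = "first", seed: int = 0) -> CalibrationResult:
    """Run the calibration procedure on the first ``k`` patients.

    ``selection='first'`` (the default) reserves the first k rows in
    table order — the consecutive-accession recommendation — while
    ``selection='random'`` draws a seeded random subset. ``mode='affine'``
    additionally matches the spread of the clinical predictions.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if len(patients) < k:
        raise DataError(f"need at least k={k} patients, got {len(patients)}")
    if mode not in ("scale", "affine"):
        raise ConfigError(f"mode must be 'scale' or 'affine', got {mode!r}")
    if selection == "first":
        calib = patients.iloc[:k]
    elif selection == "random":
        rng = substream(seed, STREAM_CALIBRATION)
        calib = patients.iloc[rng.choice(len(patients), size=k, replace=False)]
    else:
        raise ConfigError(f"selection must be 'first' or 'random', got {selection!r}")

    mean_rs_est = estimate_mean_rs(clin_model, calib)
    ai = calib[score_column].to_numpy(dtype=float)
    a = compute_scaling_factor(mean_rs_est, ai)
    shift = 0.0
    if mode == "affine":
        known = [f for f in clin_model.feature_names if f in CALIBRATION_FEATURES]
        pred = clin_model.predict(encode_features(calib, known)) \
            if clin_model.feature_names else np.full(k, clin_model.intercept)
        pred = np.clip(pred, 0.0, None)
        sd_ai = float(np.std(ai))
        if sd_ai > 0 and float(np.std(pred)) > 0:
            a = float(np.std(pred)) / sd_ai
            shift = mean_rs_est - a * float(np.mean(ai))
    ids = (calib["patient_id"].tolist() if "patient_id" in calib.columns
           else calib.index.tolist())
    return CalibrationResult(k=k, mean_rs_est=mean_rs_est,
                             mean_ai=float(np.mean(ai)), a=a, shift=shift,
                             mode=mode, consumed_patient_ids=ids)
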