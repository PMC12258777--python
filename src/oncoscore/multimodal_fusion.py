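"""Multimodal fusion of the image score with clinical covariates, and
greedy forward-selection feature attribution.

The fusion model is ordinary (unregularized) least squares predicting RS
from the image-derived slide score plus encoded clinical features. The
contribution of each feature is quantified by sequential forward
selection: starting from a base model, at every step the candidate whose
addition most improves validation-set R^2 is accepted, and its
incremental R^2 (which may be negative on validation data and is
reported as-is) is recorded. Because the greedy path ends with all
candidates included, the base R^2 plus the recorded increments telescope
exactly to the full model's validation R^2.

Encoding convention (the model card documents it alongside coefficients):
grade enters as an ordinal 1-3; ER, PR as 0/1 indicators; tumor size is
dichotomized at 2 cm; menopausal status is 1 for premenopausal; surgery
is 1 for mastectomy; race is one-hot with "White" as the fixed reference
level. Missing clinical values are an error at fit time, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import STREAM_BOOTSTRAP, ConfigError, DataError, substream

__all__ = [
    "ENCODING_SPEC",
    "CLINICAL_FEATURES",
    "encode_features",
    "LinearRSModel",
    "SingularDesignError",
    "fit_linear_rs_model",
    "r_squared",
    "ContributionEntry",
    "ContributionLedger",
    "forward_selection",
    "bootstrap_contribution",
]

#: Documented coding of each clinical feature.
ENCODING_SPEC = {
    "grade": "ordinal 1/2/3",
    "er": "indicator (1 = positive)",
    "pr": "indicator (1 = positive)",
    "size_gt_2cm": "indicator (1 = tumor_size_cm > 2)",
    "age": "years, continuous",
    "surgery_mastectomy": "indicator (1 = mastectomy)",
    "menopausal_pre": "indicator (1 = premenopausal)",
    "race": "one-hot, reference level 'White'",
}

#: Clinical feature names in declaration order (ties in forward selection
#: break by this order).
CLINICAL_FEATURES = ["grade", "pr", "er", "size_gt_2cm", "age",
                     "surgery_mastectomy", "menopausal_pre", "race"]

_RACE_LEVELS = ["Black", "Asian", "Other"]  # reference: White


class SingularDesignError(DataError):
    """Raised when the design matrix is rank deficient; names the
    collinear columns."""


def encode_features(patients: pd.DataFrame, features: list[str],
                    score_column: str | None = None) -> pd.DataFrame:
    """Build the numeric design frame for ``features`` (a subset of
    :data:`CLINICAL_FEATURES`), optionally prepending the image score."""
    cols = {}
    if score_column is not None:
        cols[score_column] = patients[score_column].to_numpy(dtype=float)
    for feat in features:
        if feat == "grade":
            cols["grade"] = patients["grade"].to_numpy(dtype=float)
        elif feat in ("er", "pr"):
            cols[feat] = patients[feat].to_numpy(dtype=float)
        elif feat == "size_gt_2cm":
            cols[feat] = (patients["tumor_size_cm"].to_numpy(dtype=float) > 2.0
                          ).astype(float)
        elif feat == "age":
            cols["age"] = patients["age"].to_numpy(dtype=float)
        elif feat == "surgery_mastectomy":
            cols[feat] = (patients["surgery"].to_numpy() == "mastectomy").astype(float)
        elif feat == "menopausal_pre":
            cols[feat] = (patients["menopausal_status"].to_numpy() == "pre").astype(float)
        elif feat == "race":
            race = patients["race"].astype(str).to_numpy()
            for level in _RACE_LEVELS:
                cols[f"race_{level}"] = (race == level).astype(float)
        else:
            raise ConfigError(f"unknown feature {feat!r}")
    design = pd.DataFrame(cols, index=patients.index)
    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise DataError(f"missing values in encoded columns {bad}; "
                        "imputation is not supported")
    return design


@dataclass
class LinearRSModel:
    """Fitted least-squares RS predictor with its encoding card."""

    intercept: float
    coefficients: dict[str, float]
    encoding_spec: dict = field(default_factory=lambda: dict(ENCODING_SPEC))

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.coefficients if c not in X.columns]
        if missing:
            raise DataError(f"design frame lacks model columns {missing}")
        beta = np.array([self.coefficients[c] for c in self.coefficients])
        return self.intercept + X[list(self.coefficients)].to_numpy(dtype=float) @ beta

    def to_dict(self) -> dict:
        return {"intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "encoding_spec": dict(self.encoding_spec)}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearRSModel":
        return cls(d["intercept"], dict(d["coefficients"]),
                   dict(d.get("encoding_spec", ENCODING_SPEC)))


def _collinear_columns(A: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (scanned left to
    right, so the later duplicate of a collinear pair is the one named)."""
    bad = []
    rank = 0
    for j in range(A.shape[1]):
        new_rank = np.linalg.matrix_rank(A[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    return bad


def fit_linear_rs_model(X: pd.DataFrame, y) -> LinearRSModel:
    """Ordinary least squares of ``y`` on ``X`` plus an intercept.

    Raises :class:`SingularDesignError` naming the collinear columns when
    the augmented design is rank deficient. With zero feature columns the
    model is the intercept-only mean predictor.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise DataError(f"need at least {p + 2} rows to fit {p} features, got {n}")
    if np.isnan(y).any():
        raise DataError("missing values in the target")
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    names = ["(intercept)"] + list(X.columns)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(A, names)}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearRSModel(float(beta[0]),
                         {c: float(b) for c, b in zip(X.columns, beta[1:])})


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("constant target: R^2 undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


@dataclass
class ContributionEntry:
    feature: str
    delta_r2: float
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None


@dataclass
class ContributionLedger:
    """Ordered forward-selection record; base_r2 plus the increments
    telescopes to the full-model validation R^2."""

    base_r2: float
    entries: list[ContributionEntry] = field(default_factory=list)

    @property
    def full_r2(self) -> float:
        return self.base_r2 + sum(e.delta_r2 for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"feature": e.feature, "delta_r2": e.delta_r2,
                              "ci_low": e.ci_low, "ci_high": e.ci_high,
                              "p": e.p} for e in self.entries])


def _encode_or_pass(df: pd.DataFrame, features: list[str],
                    score_column: str | None) -> pd.DataFrame:
    """Features may name raw clinical columns (encoded here) or already
    numeric columns of ``df``."""
    known = [f for f in features if f in CLINICAL_FEATURES]
    passthrough = [f for f in features if f not in CLINICAL_FEATURES]
    parts = []
    if known or score_column is not None:
        parts.append(encode_features(df, known, score_column))
    if passthrough:
        parts.append(df[passthrough].astype(float))
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def _fit_eval(tune: pd.DataFrame, val: pd.DataFrame, tune_y, val_y,
              features: list[str], score_column: str | None
              ) -> tuple[LinearRSModel, np.ndarray]:
    Xt = _encode_or_pass(tune, features, score_column)
    Xv = _encode_or_pass(val, features, score_column)
    model = fit_linear_rs_model(Xt, tune_y)
    if Xv.shape[1] == 0:
        pred = np.full(len(val), model.intercept)
    else:
        pred = model.predict(Xv)
    return model, pred


def forward_selection(candidates: list[str], base_features: list[str],
                      tune: pd.DataFrame, tune_y,
                      val: pd.DataFrame, val_y,
                      score_column: str | None = None) -> ContributionLedger:
    """Greedy forward selection on validation R^2.

    At each step every remaining candidate is added to the current
    feature set, the model is refit on the tune set, and the candidate
    with the largest validation-R^2 gain is accepted (ties break by
    declaration order in ``candidates``). Runs until candidates are
    exhausted, so the increments telescope to the full model's R^2.
    Tune and validation sets must be disjoint by patient.
    """
    val_y = np.asarray(val_y, dtype=float)
    current = list(base_features)
    _, pred = _fit_eval(tune, val, tune_y, val_y, current, score_column)
    base_r2 = r_squared(val_y, pred)
    ledger = ContributionLedger(base_r2=base_r2)
    remaining = list(candidates)
    last_r2 = base_r2
    while remaining:
        best_feat, best_r2 = None, -np.inf
        for feat in remaining:  # declaration order breaks ties
            _, pred = _fit_eval(tune, val, tune_y, val_y,
                                current + [feat], score_column)
            r2 = r_squared(val_y, pred)
            if r2 > best_r2:
                best_feat, best_r2 = feat, r2
        current.append(best_feat)
        remaining.remove(best_feat)
        ledger.entries.append(ContributionEntry(best_feat, best_r2 - last_r2))
        last_r2 = best_r2
    return ledger


def bootstrap_contribution(candidates: list[str], base_features: list[str],
                           tune: pd.DataFrame, tune_y,
                           val: pd.DataFrame, val_y,
                           score_column: str | None = None,
                           B: int = 1000, seed: int = 0) -> ContributionLedger:
    """Forward-selection ledger with percentile bootstrap CIs and p-values.

    The selection order and all model fits are fixed from the point
    estimate; validation rows are resampled with replacement B times and
    the incremental R^2 sequence is recomputed per resample. The 95% CI
    is the 2.5/97.5 percentile band and p is the one-sided fraction of
    resamples with delta R^2 <= 0, floored at 1/B.
    """
    if B < 2:
        raise ConfigError(f"B must be >= 2, got {B}")
    ledger = forward_selection(candidates, base_features, tune, tune_y,
                               val, val_y, score_column)
    val_y = np.asarray(val_y, dtype=float)
    n = len(val_y)
    # nested-model validation predictions, base first then one per accepted feature
    order = [e.feature for e in ledger.entries]
    preds = []
    feats = list(base_features)
    _, pred = _fit_eval(tune, val, tune_y, val_y, feats, score_column)
    preds.append(pred)
    for feat in order:
        feats.append(feat)
        _, pred = _fit_eval(tune, val, tune_y, val_y, feats, score_column)
        preds.append(pred)
    preds = np.asarray(preds)  # (len(order)+1, n)

    rng = substream(seed, STREAM_BOOTSTRAP)
    deltas = np.empty((B, len(order)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        yb = val_y[idx]
        ss_tot = np.sum((yb - yb.mean()) ** 2)
        if ss_tot == 0:
            deltas[b] = np.nan
            continue
        r2s = 1.0 - np.sum((yb - preds[:, idx]) ** 2, axis=1) / ss_tot
        deltas[b] = np.diff(r2s)
    for j, entry in enumerate(ledger.entries):
        d = deltas[:, j]
        d = d[~np.isnan(d)]
        entry.ci_low = float(np.percentile(d, 2.5))
        entry.ci_high = float(np.percentile(d, 97.5))
        entry.p = max(float(np.mean(d <= 0.0)), 1.0 / B)
    return ledger
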