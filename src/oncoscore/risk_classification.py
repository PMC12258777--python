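"""Threshold-based risk categorization and operating-point metrics
against the RS >= 26 genomic high-risk reference.

Risk bands use the half-open convention of the clinical thresholds:
low means score < low_threshold (default 16), high means score >=
high_threshold (default 26), intermediate in between. "Predicted
positive" always means score >= threshold, so ties at a threshold land
on the positive side. The discrimination metric is the Mann-Whitney AUC
(ties get half credit), with percentile-bootstrap confidence intervals
at 1,000 replicates by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._common import STREAM_BOOTSTRAP, ConfigError, DataError, substream

__all__ = [
    "ClassifierConfig",
    "OperatingPoint",
    "classify_risk",
    "operating_metrics",
    "threshold_sweep",
    "AUCResult",
    "auc_point",
    "auc_mann_whitney",
    "paired_bootstrap_compare",
]


@dataclass(frozen=True)
class ClassifierConfig:
    low_threshold: float = 16.0
    high_threshold: float = 26.0
    reference_cutoff: float = 26.0

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ConfigError("low_threshold must be below high_threshold")


@dataclass
class OperatingPoint:
    """Confusion-matrix summary at one threshold; undefined ratios are NaN."""

    threshold: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    prop_flagged: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


def classify_risk(scores, config: ClassifierConfig = ClassifierConfig()):
    """Three-tier categorization: 'low' below the low threshold, 'high' at
    or above the high threshold, 'intermediate' otherwise."""
    arr = np.asarray(scores, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.isfinite(arr).all():
        raise DataError("scores must be finite")
    out = np.full(arr.shape, "intermediate", dtype=object)
    out[arr < config.low_threshold] = "low"
    out[arr >= config.high_threshold] = "high"
    return out[0] if scalar else out


def operating_metrics(scores, rs, threshold: float,
                      reference_cutoff: float = 26.0) -> OperatingPoint:
    """Sensitivity/specificity/NPV/PPV of ``score >= threshold`` against
    the ``rs >= reference_cutoff`` reference.

    Empty denominators yield NaN (reported missing, never zero); an
    all-one-class reference triggers a warning.
    """
    scores = np.asarray(scores, dtype=float)
    rs = np.asarray(rs, dtype=float)
    if scores.shape != rs.shape:
        raise DataError("scores and rs must have equal length")
    if np.isnan(scores).any() or np.isnan(rs).any():
        raise DataError("missing values are not allowed")
    pred = scores >= threshold
    cond = rs >= reference_cutoff
    tp = int(np.sum(pred & cond))
    fp = int(np.sum(pred & ~cond))
    fn = int(np.sum(~pred & cond))
    tn = int(np.sum(~pred & ~cond))
    if cond.all() or not cond.any():
        warnings.warn("reference contains a single class; sensitivity or "
                      "specificity is undefined", stacklevel=2)

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return OperatingPoint(
        threshold=float(threshold),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        npv=ratio(tn, tn + fn),
        ppv=ratio(tp, tp + fp),
        prop_flagged=ratio(tp + fp, scores.size),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def threshold_sweep(scores, rs, grid,
                    reference_cutoff: float = 26.0) -> pd.DataFrame:
    """One operating point per grid threshold (grid sorted ascending)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and (np.diff(grid) < 0).any():
        raise ConfigError("grid must be sorted ascending")
    rows = [operating_metrics(scores, rs, t, reference_cutoff) for t in grid]
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class AUCResult:
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0


def auc_point(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + half the tied pairs) / all pairs,
    computed via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_mann_whitney(scores, labels, B: int = 1000, seed: int = 0) -> AUCResult:
    """AUC with a percentile bootstrap 95% CI over B patient resamples.

    Resamples that lose one of the classes are skipped (they carry no
    AUC); ``n_boot`` reports the replicates actually used.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = auc_point(scores, labels)
    rng = substream(seed, STREAM_BOOTSTRAP)
    n = labels.size
    aucs = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if 0 < lb.sum() < n:
            aucs.append(auc_point(scores[idx], lb))
    if not aucs:
        return AUCResult(point)
    return AUCResult(point, float(np.percentile(aucs, 2.5)),
                     float(np.percentile(aucs, 97.5)), len(aucs))


def paired_bootstrap_compare(scores_a, scores_b, labels,
                             B: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Paired bootstrap comparison of two scores on the same patients.

    Returns (delta_auc, p): delta_auc = AUC(a) - AUC(b); patients are
    resampled jointly and the two-sided p-value is read from the
    bootstrap distribution of the AUC difference around zero, floored at
    1/B.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not scores_a.shape == scores_b.shape == labels.shape:
        raise DataError("paired comparison needs equal-length inputs")
    delta = auc_point(scores_a, labels) - auc_point(scores_b, labels)
    rng = substream(seed, STREAM_BOOTSTRAP)
    n = labels.size
    deltas = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if 0 < lb.sum() < n:
            deltas.append(auc_point(scores_a[idx], lb)
                          - auc_point(scores_b[idx], lb))
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        return float(delta), 1.0
    p = 2.0 * min(float(np.mean(deltas <= 0.0)), float(np.mean(deltas >= 0.0)))
    return float(delta), float(min(max(p, 1.0 / B), 1.0))
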