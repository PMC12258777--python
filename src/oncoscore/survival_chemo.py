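"""Survival estimation, the proportional-hazards counterfactual
correction, chemotherapy-benefit augmentation, and non-inferiority
testing.

The scientific question is whether chemotherapy benefit observed in the
randomized intermediate-RS arms (B: endocrine alone, C: chemo-endocrine)
carries over to the risk groups an image-based surrogate defines. Two
augmentation procedures transplant the randomized comparison onto the
surrogate-defined populations:

* premenopausal high-surrogate-risk: the randomized groups are topped up
  with low-RS (RS < 16) patients until those make up 4.9% of the group
  (the share of RS < 16 among surrogate-high patients once RS >= 26 is
  set aside). Added patients with 11 <= RS < 16 keep their original
  randomized arm; RS < 11 patients (never randomized) are split 1:1.
  Since none of the additions received chemotherapy, the resulting
  benefit estimate is a conservative lower bound.

* postmenopausal low-surrogate-risk: the groups are topped up with
  RS >= 26 patients (all chemo-treated) to a 2.1% share. Additions
  landing in the chemo group keep their observed outcomes; additions in
  the no-chemo group cannot keep them (chemotherapy improved their
  prognosis), so their outcomes are drawn from the counterfactual
  no-chemo survival curve S_noChemo(t) = S_chemo(t) ** (1 / HR), the
  standard proportional-hazards correction, using externally estimated
  chemotherapy hazard ratios (DRFI 0.44, DFS 0.45; RFI bounded below by
  0.44).

Non-inferiority of withholding chemotherapy is declared when the
one-sided (1 - alpha) upper Wald bound of the Cox hazard ratio falls
below a margin of 1.322 (32.2% excess risk) at one-sided alpha = 0.10.

Kaplan-Meier estimation and Cox regression are delegated to lifelines
(Efron tie handling, Wald confidence intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as _stats

from ._common import (
    STREAM_AUGMENT,
    STREAM_SURVIVAL,
    STREAM_TRIALS,
    ConfigError,
    DataError,
    substream,
)

__all__ = [
    "KMCurve",
    "HREstimate",
    "AugmentationSpec",
    "NonInferiorityConfig",
    "NonInferiorityResult",
    "TrialSpec",
    "km_estimate",
    "cox_hr",
    "ph_correct_survival",
    "sample_corrected_times",
    "conditional_share",
    "augmentation_size",
    "augment_premenopausal",
    "augment_postmenopausal",
    "estimate_chemo_benefit",
    "noninferiority_test",
    "noninferiority_type1_sim",
    "CORRECTION_HR",
    "PRE_TARGET_PROP",
    "POST_TARGET_PROP",
]

#: Externally estimated chemotherapy hazard ratios for RS >= 26 patients,
#: used by the counterfactual correction (RFI uses the DRFI value as a
#: lower bound).
CORRECTION_HR = {"DRFI": 0.44, "DFS": 0.45, "RFI": 0.44}

#: Target share of RS < 16 additions in the premenopausal analysis.
PRE_TARGET_PROP = 0.049
#: Target share of RS >= 26 additions in the postmenopausal analysis.
POST_TARGET_PROP = 0.021


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival step function.

    ``times`` are the event (drop) times, ``survival`` the curve value
    just after each drop, ``at_risk`` the risk-set size just before it;
    ``s_tail`` is S(t_max), the mass surviving past the last observed
    time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    t_max: float
    s_tail: float

    def evaluate(self, t) -> np.ndarray:
        """S(t) of the right-continuous step function."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored-only times do not drop the curve; an empty input is an
    error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("cannot estimate a survival curve from no data")
    if (times <= 0).any():
        raise DataError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise DataError("events must be 0/1")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    drops = table[table["observed"] > 0]
    step_times = drops.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival = sf.loc[step_times].to_numpy(dtype=float)
    at_risk = drops["at_risk"].to_numpy(dtype=float)
    t_max = float(times.max())
    s_tail = float(sf.iloc[-1])
    return KMCurve(step_times, survival, at_risk, t_max, s_tail)


# ---------------------------------------------------------------------------
# Cox

@dataclass
class HREstimate:
    """Cox hazard-ratio estimate with Wald 95% CI."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    log_hr: float = 0.0
    se: float = 0.0

    def to_dict(self) -> dict:
        return {"hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "n_events": self.n_events}


def cox_hr(times, events, covariate, name: str = "x") -> HREstimate:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI).

    ``covariate`` may be a 0/1 group indicator or a numeric covariate;
    the returned HR is per unit of it. Complete separation surfaces as a
    lifelines convergence warning with a bounded estimate.
    """
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       name: np.asarray(covariate, dtype=float)})
    if df["event"].sum() < 1:
        raise DataError("Cox model needs at least one event")
    if df[name].nunique() < 2:
        raise DataError("covariate is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc[name]
    return HREstimate(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        n_events=int(df["event"].sum()),
        log_hr=float(row["coef"]),
        se=float(row["se(coef)"]),
    )


# ---------------------------------------------------------------------------
# Counterfactual correction and resampling

def ph_correct_survival(curve: KMCurve, hr: float) -> KMCurve:
    """Counterfactual curve under proportional hazards: S -> S ** (1/hr),
    step times unchanged. With hr < 1 (beneficial treatment) the
    corrected curve is never above the original."""
    if not hr > 0:
        raise DataError(f"hr must be > 0, got {hr}")
    return KMCurve(curve.times.copy(), curve.survival ** (1.0 / hr),
                   curve.at_risk.copy(), curve.t_max, curve.s_tail ** (1.0 / hr))


def sample_corrected_times(curve: KMCurve, n: int,
                           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-transform draws from a KM step function.

    For u ~ U(0,1): if u < S(t_max) the draw is administratively censored
    at t_max (the tail mass never invents late events); otherwise the
    draw is an event at the smallest step time whose survival value is
    <= u.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = substream(seed, STREAM_SURVIVAL)
    u = rng.random(n)
    times = np.full(n, curve.t_max, dtype=float)
    events = np.zeros(n, dtype=int)
    if curve.times.size:
        is_event = u >= curve.s_tail
        # survival is non-increasing; first index with survival <= u
        j = np.searchsorted(-curve.survival, -u[is_event], side="left")
        times[is_event] = curve.times[np.minimum(j, curve.times.size - 1)]
        events[is_event] = 1
    return times, events


# ---------------------------------------------------------------------------
# Augmentation

def conditional_share(part: float, rest: float) -> float:
    """Share of ``part`` after conditioning away everything but
    ``part + rest`` (e.g. the 1.4% RS < 16 slice of surrogate-high
    patients becomes 1.4 / (1.4 + 27.0) = 4.9% once RS >= 26 is set
    aside)."""
    if part < 0 or rest < 0 or part + rest <= 0:
        raise ConfigError("shares must be non-negative with a positive total")
    return part / (part + rest)


def augmentation_size(n_base: int, target_prop: float) -> int:
    """m = round(p * n / (1 - p)), so the m additions make up about a
    ``target_prop`` share of the augmented group of n + m."""
    if not 0 <= target_prop < 1:
        raise ConfigError(f"target_prop must lie in [0, 1), got {target_prop}")
    return int(round(target_prop * n_base / (1.0 - target_prop)))


@dataclass
class AugmentationSpec:
    """Stratum-specific augmentation parameters."""

    stratum: str = "premenopausal"
    target_prop: float | None = None
    correction_hr: dict = field(default_factory=lambda: dict(CORRECTION_HR))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stratum not in ("premenopausal", "postmenopausal"):
            raise ConfigError("stratum must be 'premenopausal' or 'postmenopausal'")
        if self.target_prop is None:
            self.target_prop = (PRE_TARGET_PROP if self.stratum == "premenopausal"
                                else POST_TARGET_PROP)
        if not 0 <= self.target_prop < 1:
            raise ConfigError("target_prop must lie in [0, 1)")
        for e, hr in self.correction_hr.items():
            if not hr > 0:
                raise ConfigError(f"correction_hr[{e}] must be > 0")


_NEEDED_COLS = {"rs", "time", "event"}


def _check_frame(df: pd.DataFrame, what: str, extra: set = frozenset()) -> None:
    missing = (_NEEDED_COLS | extra) - set(df.columns)
    if missing:
        raise DataError(f"{what} is missing columns {sorted(missing)}")


def augment_premenopausal(base_b: pd.DataFrame, base_c: pd.DataFrame,
                          low_rs_pool: pd.DataFrame, spec: AugmentationSpec
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top up the randomized (B, C) groups with RS < 16 patients to a
    ``spec.target_prop`` share.

    Patients sampled with 11 <= RS < 16 keep their original randomized
    arm; RS < 11 patients are split 1:1 by a seeded coin. Base rows are
    returned unmodified with ``augmented=False``.
    """
    for df, what in ((base_b, "base_b"), (base_c, "base_c")):
        _check_frame(df, what)
    _check_frame(low_rs_pool, "low_rs_pool", {"arm"})
    if (low_rs_pool["rs"] >= 16).any():
        raise DataError("low_rs_pool must contain only RS < 16 patients")
    n_base = len(base_b) + len(base_c)
    m = augmentation_size(n_base, spec.target_prop)
    if m > len(low_rs_pool):
        raise DataError(f"pool of {len(low_rs_pool)} cannot supply m={m} additions")
    rng = substream(spec.seed, STREAM_AUGMENT)
    out_b = [base_b.assign(augmented=False)]
    out_c = [base_c.assign(augmented=False)]
    if m > 0:
        picked = low_rs_pool.iloc[rng.choice(len(low_rs_pool), size=m,
                                             replace=False)]
        mid = picked[picked["rs"] >= 11]
        if not mid["arm"].isin(["B", "C"]).all():
            raise DataError("11 <= RS < 16 pool patients must carry arm B or C")
        out_b.append(mid[mid["arm"] == "B"].assign(augmented=True))
        out_c.append(mid[mid["arm"] == "C"].assign(augmented=True))
        low = picked[picked["rs"] < 11]
        if len(low):
            coin = rng.integers(0, 2, size=len(low)).astype(bool)
            out_b.append(low[~coin].assign(augmented=True))
            out_c.append(low[coin].assign(augmented=True))
    return (pd.concat(out_b, ignore_index=True),
            pd.concat(out_c, ignore_index=True))


def augment_postmenopausal(base_b: pd.DataFrame, base_c: pd.DataFrame,
                           high_rs_pool: pd.DataFrame, spec: AugmentationSpec,
                           endpoint: str = "DFS"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top up the randomized (B, C) groups with RS >= 26 chemo-treated
    patients to a ``spec.target_prop`` share.

    Sampled patients are split 1:1; additions to the chemo group (C)
    keep their observed (time, event), additions to the no-chemo group
    (B) receive outcomes drawn from the pool's KM curve after the
    S ** (1/HR) counterfactual correction with the endpoint's external
    chemotherapy HR.
    """
    for df, what in ((base_b, "base_b"), (base_c, "base_c")):
        _check_frame(df, what)
    _check_frame(high_rs_pool, "high_rs_pool")
    if (high_rs_pool["rs"] < 26).any():
        raise DataError("high_rs_pool must contain only RS >= 26 patients")
    if "chemo" in high_rs_pool.columns and not (high_rs_pool["chemo"] == 1).all():
        raise DataError("high_rs_pool must be chemotherapy-treated")
    if endpoint not in spec.correction_hr:
        raise ConfigError(f"no correction HR configured for endpoint {endpoint!r}")
    if high_rs_pool["event"].sum() < 1:
        raise DataError("high_rs_pool has no events; corrected curve is degenerate")
    n_base = len(base_b) + len(base_c)
    m = augmentation_size(n_base, spec.target_prop)
    if m > len(high_rs_pool):
        raise DataError(f"pool of {len(high_rs_pool)} cannot supply m={m} additions")
    rng = substream(spec.seed, STREAM_AUGMENT)
    out_b = [base_b.assign(augmented=False)]
    out_c = [base_c.assign(augmented=False)]
    if m > 0:
        picked = high_rs_pool.iloc[rng.choice(len(high_rs_pool), size=m,
                                              replace=False)]
        coin = rng.integers(0, 2, size=m).astype(bool)  # True -> chemo group
        out_c.append(picked[coin].assign(augmented=True))
        to_nochemo = picked[~coin]
        if len(to_nochemo):
            curve = km_estimate(high_rs_pool["time"], high_rs_pool["event"])
            corrected = ph_correct_survival(curve, spec.correction_hr[endpoint])
            t, e = sample_corrected_times(corrected, len(to_nochemo),
                                          seed=int(rng.integers(2 ** 31)))
            add = to_nochemo.assign(time=t, event=e, augmented=True)
            out_b.append(add)
    return (pd.concat(out_b, ignore_index=True),
            pd.concat(out_c, ignore_index=True))


def estimate_chemo_benefit(group_chemo: pd.DataFrame,
                           group_no_chemo: pd.DataFrame
                           ) -> tuple[HREstimate, KMCurve, KMCurve]:
    """Cox HR of chemo vs no-chemo on an augmented two-group dataset,
    plus both groups' KM curves. HR < 1 means chemotherapy benefit."""
    if len(group_chemo) == 0 or len(group_no_chemo) == 0:
        raise DataError("both groups must be non-empty")
    times = np.concatenate([group_chemo["time"], group_no_chemo["time"]])
    events = np.concatenate([group_chemo["event"], group_no_chemo["event"]])
    indicator = np.r_[np.ones(len(group_chemo)), np.zeros(len(group_no_chemo))]
    est = cox_hr(times, events, indicator, name="chemo")
    km_chemo = km_estimate(group_chemo["time"], group_chemo["event"])
    km_nochemo = km_estimate(group_no_chemo["time"], group_no_chemo["event"])
    return est, km_chemo, km_nochemo


# ---------------------------------------------------------------------------
# Non-inferiority

@dataclass(frozen=True)
class NonInferiorityConfig:
    margin_hr: float = 1.322
    alpha_one_sided: float = 0.10

    def __post_init__(self) -> None:
        if not self.margin_hr > 1:
            raise ConfigError("margin_hr must exceed 1")
        if not 0 < self.alpha_one_sided < 0.5:
            raise ConfigError("alpha_one_sided must lie in (0, 0.5)")


@dataclass
class NonInferiorityResult:
    decision: str  # 'non_inferior' | 'not_established'
    upper_bound: float
    margin_hr: float


def noninferiority_test(est: HREstimate,
                        config: NonInferiorityConfig = NonInferiorityConfig()
                        ) -> NonInferiorityResult:
    """Declare non-inferiority when the one-sided (1 - alpha) upper Wald
    bound of the HR falls below the margin.

    The standard error is recovered from the two-sided 95% CI as
    (log ci_high - log ci_low) / (2 * 1.96).
    """
    if not (est.ci_low > 0 and est.ci_high > est.ci_low):
        raise DataError("degenerate confidence interval")
    se = (np.log(est.ci_high) - np.log(est.ci_low)) / (2.0 * 1.959963984540054)
    z = _stats.norm.ppf(1.0 - config.alpha_one_sided)
    upper = float(np.exp(np.log(est.hr) + z * se))
    decision = "non_inferior" if upper < config.margin_hr else "not_established"
    return NonInferiorityResult(decision, upper, config.margin_hr)


@dataclass(frozen=True)
class TrialSpec:
    """Two-arm exponential trial used for operating-characteristic
    simulation (rates per month)."""

    n_per_arm: int = 2000
    baseline_rate: float = 0.01
    censor_rate: float = 0.0025
    true_hr: float | None = None  # None -> sit exactly on the margin

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if not self.baseline_rate > 0:
            raise ConfigError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")


def simulate_two_arm_trial(spec: TrialSpec, hr: float,
                           rng: np.random.Generator) -> pd.DataFrame:
    """One two-arm trial: control at ``baseline_rate``, experimental arm
    at ``baseline_rate * hr``, independent exponential censoring."""
    n = spec.n_per_arm
    rates = np.r_[np.full(n, spec.baseline_rate), np.full(n, spec.baseline_rate * hr)]
    t_event = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=2 * n)
    else:
        t_cens = np.full(2 * n, np.inf)
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "experimental": np.r_[np.zeros(n), np.ones(n)],
    })


def noninferiority_type1_sim(config: NonInferiorityConfig = NonInferiorityConfig(),
                             trial_spec: TrialSpec = TrialSpec(),
                             reps: int = 1000, seed: int = 0) -> float:
    """Empirical one-sided type-I error of the non-inferiority rule.

    Simulates ``reps`` two-arm exponential trials with the true hazard
    ratio at ``trial_spec.true_hr`` (defaulting to the margin, the
    type-I-error configuration) and returns the fraction of trials
    declared non-inferior.
    """
    if reps < 100:
        raise ConfigError("reps must be >= 100 for a stable rate")
    hr = trial_spec.true_hr if trial_spec.true_hr is not None else config.margin_hr
    rng = substream(seed, STREAM_TRIALS)
    hits = 0
    for _ in range(reps):
        df = simulate_two_arm_trial(trial_spec, hr, rng)
        est = cox_hr(df["time"], df["event"], df["experimental"], name="experimental")
        if noninferiority_test(est, config).decision == "non_inferior":
            hits += 1
    return hits / reps
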