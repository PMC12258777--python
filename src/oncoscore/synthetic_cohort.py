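"""Seeded synthetic cohorts with the statistical structure of a
chemotherapy-randomization trial stratified by the 21-gene recurrence
score (RS).

The generator emulates a trial design in which patients with RS < 11
receive endocrine therapy alone (arm A), patients with 11 <= RS < 26 are
randomized 1:1 between endocrine therapy (arm B) and chemo-endocrine
therapy (arm C), and patients with RS >= 26 all receive chemotherapy
(arm D). Alongside RS each patient carries an uncalibrated image-derived
surrogate score ("AI score") correlated with RS at a configurable Pearson
target, clinical covariates whose distributions track those reported for
such cohorts, multiple digitized slides with tissue-tile counts for QC,
and exponential proportional-hazards event times for five survival
endpoints.

Tables are plain :class:`pandas.DataFrame` objects with fixed column
schemas (:data:`PATIENT_COLUMNS`, :data:`SLIDE_COLUMNS`,
:data:`SURVIVAL_COLUMNS`) and round-trip through UTF-8 RFC 4180 CSV.

Mechanism for the joint (RS, AI) draw: a latent bivariate standard normal
with correlation equal to the Pearson target, transformed affinely per
marginal; RS is then clipped to [0, 100]. Clipping slightly attenuates
the realized correlation, which downstream tolerances absorb. Clinical
covariates are tied to the same latent RS normal through a Gaussian
copula, so configured marginals are preserved exactly in distribution
while grade (strongest), PR, ER and tumor size carry an RS signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._common import (
    ENDPOINTS,
    STREAM_ARMS,
    STREAM_CLINICAL,
    STREAM_SCORES,
    STREAM_SLIDES,
    STREAM_SURVIVAL,
    ConfigError,
    check_proportion,
    substream,
)

__all__ = [
    "CohortConfig",
    "HazardConfig",
    "generate_joint_scores",
    "assign_arms",
    "generate_survival",
    "generate_slides",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "load_config",
    "PATIENT_COLUMNS",
    "SLIDE_COLUMNS",
    "SURVIVAL_COLUMNS",
]

PATIENT_COLUMNS = [
    "patient_id", "age", "menopausal_status", "tumor_size_cm", "grade",
    "er", "pr", "nodal_status", "surgery", "race", "rs", "ai_score",
    "arm", "chemo",
]
SLIDE_COLUMNS = ["slide_id", "patient_id", "n_tissue_tiles", "image_score"]
SURVIVAL_COLUMNS = ["patient_id", "endpoint", "time", "event"]

#: RS cut-points of the trial arm design.
RS_LOW_CUT = 11.0
RS_HIGH_CUT = 26.0


def _default_marginals() -> dict:
    # Category probabilities typical of an HR+/HER2- node-negative trial
    # population; each feature's probabilities sum to 1.
    return {
        "grade": {1: 0.30, 2: 0.52, 3: 0.18},
        "er": {0: 0.03, 1: 0.97},
        "pr": {0: 0.15, 1: 0.85},
        "size": {"<=2cm": 0.72, ">2cm": 0.28},
        "surgery": {"mastectomy": 0.27, "lumpectomy": 0.73},
        "race": {"White": 0.80, "Black": 0.07, "Asian": 0.05, "Other": 0.08},
    }


def _default_assoc() -> dict:
    # Latent-copula loadings on the RS normal score; sign is the direction
    # of association and magnitude the strength. Grade carries the
    # strongest RS signal, then PR status (negatively: PR-negative tumors
    # run higher RS), then ER and size.
    return {"grade": 0.50, "pr": -0.35, "er": -0.20, "size": 0.15,
            "surgery": 0.0, "race": 0.0}


@dataclass
class CohortConfig:
    """Configuration of the simulated cohort.

    Defaults follow the population the analyses assume: mean RS ~18 on the
    0-100 scale (about 17% of patients at RS >= 26), a raw surrogate score
    running systematically higher than RS (uncalibrated models tend to
    overshoot on external data), Pearson correlation target 0.728, 34%
    premenopausal, node-negative.
    """

    n_patients: int = 1000
    rs_mean: float = 18.0
    rs_sd: float = 9.0
    ai_mean: float = 22.0
    ai_sd: float = 10.0
    target_pearson: float = 0.728
    prop_premenopausal: float = 0.34
    prop_node_positive: float = 0.0
    clinical_marginals: dict = field(default_factory=_default_marginals)
    clinical_assoc: dict = field(default_factory=_default_assoc)
    age_mean_pre: float = 45.0
    age_sd_pre: float = 5.0
    age_mean_post: float = 61.0
    age_sd_post: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not self.rs_sd > 0:
            raise ConfigError(f"rs_sd must be > 0, got {self.rs_sd}")
        if not abs(self.target_pearson) < 1:
            raise ConfigError(
                f"target_pearson must lie strictly in (-1, 1), got {self.target_pearson}")
        check_proportion("prop_premenopausal", self.prop_premenopausal)
        check_proportion("prop_node_positive", self.prop_node_positive)
        for feat, probs in self.clinical_marginals.items():
            total = float(sum(probs.values()))
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ConfigError(f"marginal probabilities for {feat!r} must lie in [0, 1]")
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"marginal probabilities for {feat!r} must sum to 1, got {total}")


def _scalar_or_map(value, what: str) -> dict:
    """Normalize scalar-or-per-endpoint input to a dict over ENDPOINTS."""
    if isinstance(value, Mapping):
        out = {e: float(value[e]) for e in ENDPOINTS if e in value}
        missing = [e for e in ENDPOINTS if e not in out]
        if missing:
            raise ConfigError(f"{what} missing endpoints: {missing}")
        return out
    return {e: float(value) for e in ENDPOINTS}


def _default_baseline() -> dict:
    # Events per month at RS = 0; tuned so cumulative incidence over ~9
    # years of follow-up sits in the single-digit-percent range typical of
    # node-negative HR+ disease (DFS highest: it also counts second
    # primaries and death).
    return {"DRFI": 2.5e-4, "RFI": 3.0e-4, "DFS": 6.0e-4,
            "OS": 4.0e-4, "BCSS": 1.5e-4}


def _default_chemo_hr() -> dict:
    # Chemotherapy hazard ratios per (menopausal stratum x endpoint):
    # benefit concentrated in premenopausal patients, none in
    # postmenopausal intermediate-risk patients.
    return {
        "pre": {"DRFI": 0.60, "RFI": 0.62, "DFS": 0.63, "OS": 0.85, "BCSS": 0.75},
        "post": {e: 1.0 for e in ENDPOINTS},
    }


@dataclass
class HazardConfig:
    """Proportional-hazards event model for the five endpoints.

    Event times are exponential with hazard
    ``baseline_rate * exp(log_hr_per_rs_unit * rs) * chemo_hr ** chemo``,
    independently censored at ``censor_rate`` and administratively
    censored at ``max_followup`` months. Endpoints run on independent
    clocks (no multistate coherence).
    """

    baseline_rate: float | Mapping = field(default_factory=_default_baseline)
    log_hr_per_rs_unit: float | Mapping = 0.03
    chemo_hr: float | Mapping = field(default_factory=_default_chemo_hr)
    censor_rate: float = 0.002
    max_followup: float = 108.0

    def __post_init__(self) -> None:
        self.baseline_rate = _scalar_or_map(self.baseline_rate, "baseline_rate")
        self.log_hr_per_rs_unit = _scalar_or_map(self.log_hr_per_rs_unit,
                                                 "log_hr_per_rs_unit")
        if isinstance(self.chemo_hr, Mapping) and set(self.chemo_hr) <= {"pre", "post"}:
            if set(self.chemo_hr) != {"pre", "post"}:
                raise ConfigError("chemo_hr mapping needs both 'pre' and 'post'")
            self.chemo_hr = {s: _scalar_or_map(v, f"chemo_hr[{s}]")
                             for s, v in self.chemo_hr.items()}
        else:
            self.chemo_hr = {s: _scalar_or_map(self.chemo_hr, "chemo_hr")
                             for s in ("pre", "post")}
        for e in ENDPOINTS:
            if not self.baseline_rate[e] > 0:
                raise ConfigError(f"baseline_rate[{e}] must be > 0")
            for s in ("pre", "post"):
                if not self.chemo_hr[s][e] > 0:
                    raise ConfigError(f"chemo_hr[{s}][{e}] must be > 0")
        if not self.censor_rate >= 0:
            raise ConfigError("censor_rate must be >= 0")
        if not self.max_followup > 0:
            raise ConfigError("max_followup must be > 0")


# ---------------------------------------------------------------------------
# Joint score generation

def _joint_latent(n: int, config: CohortConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent RS normal score plus the transformed (rs, ai) marginals."""
    rho = config.target_pearson
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    rs = np.clip(config.rs_mean + config.rs_sd * z1, 0.0, 100.0)
    ai = config.ai_mean + config.ai_sd * z2
    return z1, rs, ai


def generate_joint_scores(n: int, config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` correlated (rs, ai_score) pairs.

    RS is clipped to [0, 100]; at large ``n`` the empirical Pearson
    correlation lands within about +-0.05 of ``config.target_pearson``.
    Deterministic given ``config.seed``.
    """
    if n < 2:
        raise ConfigError(f"n must be >= 2, got {n}")
    _, rs, ai = _joint_latent(n, config, substream(config.seed, STREAM_SCORES))
    return rs, ai


# ---------------------------------------------------------------------------
# Arm assignment

def assign_arms(rs: np.ndarray, seed: int) -> np.ndarray:
    """Assign trial arms from RS: A below 11, D at and above 26, and a
    seeded 1:1 randomization between B and C in between."""
    rs = np.asarray(rs, dtype=float)
    if rs.size and (np.nanmin(rs) < 0 or np.nanmax(rs) > 100 or np.isnan(rs).any()):
        raise ConfigError("rs values must lie in [0, 100]")
    rng = substream(seed, STREAM_ARMS)
    coin = rng.integers(0, 2, size=rs.shape)
    arms = np.where(coin == 0, "B", "C").astype(object)
    arms[rs < RS_LOW_CUT] = "A"
    arms[rs >= RS_HIGH_CUT] = "D"
    return np.asarray(arms, dtype=object)


# ---------------------------------------------------------------------------
# Clinical covariates

def _copula_categorical(z: np.ndarray, probs: Mapping, weight: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a categorical with exact marginals, tied to latent ``z``.

    ``u = Phi(w z + sqrt(1-w^2) eps)`` is uniform whatever ``w``, so
    binning ``u`` at the cumulative marginal probabilities preserves the
    configured marginal while inducing an ordered association with z.
    """
    if not -1.0 <= weight <= 1.0:
        raise ConfigError(f"association weight must lie in [-1, 1], got {weight}")
    cats = list(probs.keys())
    cum = np.cumsum([probs[c] for c in cats])
    eps = rng.standard_normal(z.shape)
    u = stats.norm.cdf(weight * z + np.sqrt(1.0 - weight * weight) * eps)
    idx = np.searchsorted(cum, u, side="left")
    idx = np.clip(idx, 0, len(cats) - 1)
    return np.asarray([cats[i] for i in idx], dtype=object)


def _generate_clinical(z_rs: np.ndarray, config: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = z_rs.size
    m, w = config.clinical_marginals, config.clinical_assoc
    grade = _copula_categorical(z_rs, m["grade"], w.get("grade", 0.0), rng).astype(int)
    er = _copula_categorical(z_rs, m["er"], w.get("er", 0.0), rng).astype(int)
    pr = _copula_categorical(z_rs, m["pr"], w.get("pr", 0.0), rng).astype(int)
    size_cat = _copula_categorical(z_rs, m["size"], w.get("size", 0.0), rng)
    surgery = _copula_categorical(z_rs, m["surgery"], w.get("surgery", 0.0), rng)
    race = _copula_categorical(z_rs, m["race"], w.get("race", 0.0), rng)

    size_cm = np.where(size_cat == "<=2cm",
                       rng.uniform(0.5, 2.0, n), rng.uniform(2.05, 5.0, n))
    size_cm = np.round(size_cm, 2)

    meno = np.where(rng.random(n) < config.prop_premenopausal, "pre", "post")
    nodal = np.where(rng.random(n) < config.prop_node_positive, "positive", "negative")
    age = np.where(meno == "pre",
                   rng.normal(config.age_mean_pre, config.age_sd_pre, n),
                   rng.normal(config.age_mean_post, config.age_sd_post, n))
    age = np.round(np.clip(age, 25.0, 85.0), 1)

    return pd.DataFrame({
        "age": age, "menopausal_status": meno, "tumor_size_cm": size_cm,
        "grade": grade, "er": er, "pr": pr, "nodal_status": nodal,
        "surgery": surgery, "race": race,
    })


# ---------------------------------------------------------------------------
# Survival

def generate_survival(cohort: pd.DataFrame, hazards: HazardConfig,
                      seed: int) -> pd.DataFrame:
    """One exponential proportional-hazards record per patient per endpoint.

    hazard_i = baseline * exp(log_hr_per_rs_unit * rs_i) * chemo_hr ** chemo_i,
    with independent exponential censoring and administrative censoring at
    ``max_followup``.
    """
    required = {"patient_id", "rs", "chemo", "menopausal_status"}
    if not required <= set(cohort.columns):
        raise ConfigError(f"cohort is missing columns {sorted(required - set(cohort.columns))}")
    rng = substream(seed, STREAM_SURVIVAL)
    n = len(cohort)
    rs = cohort["rs"].to_numpy(dtype=float)
    chemo = cohort["chemo"].to_numpy(dtype=int)
    pre = (cohort["menopausal_status"].to_numpy() == "pre")

    frames = []
    for endpoint in ENDPOINTS:
        hr_chemo = np.where(pre, hazards.chemo_hr["pre"][endpoint],
                            hazards.chemo_hr["post"][endpoint])
        hazard = (hazards.baseline_rate[endpoint]
                  * np.exp(hazards.log_hr_per_rs_unit[endpoint] * rs)
                  * hr_chemo ** chemo)
        t_event = rng.exponential(1.0 / hazard)
        if hazards.censor_rate > 0:
            t_cens = rng.exponential(1.0 / hazards.censor_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.round(np.minimum.reduce([t_event, t_cens,
                                           np.full(n, hazards.max_followup)]), 6)
        # rounding must not promote a near-boundary event past the
        # administrative-censoring invariant (time == max_followup -> censored)
        event = (t_event <= t_cens) & (time < hazards.max_followup)
        frames.append(pd.DataFrame({
            "patient_id": cohort["patient_id"].to_numpy(),
            "endpoint": endpoint,
            "time": time,
            "event": event.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Slides

def generate_slides(cohort: pd.DataFrame,
                    slides_per_patient_dist: Mapping[int, float] | None = None,
                    qc_fail_prob: float = 0.001,
                    seed: int = 0,
                    slide_score_sd: float = 2.0) -> pd.DataFrame:
    """Digitized-slide records: every patient gets at least one slide,
    slide scores scatter around the patient's ai_score, and a
    ``qc_fail_prob`` fraction of slides (in expectation) carry fewer than
    100 tissue tiles."""
    if not 0 <= qc_fail_prob < 1:
        raise ConfigError(f"qc_fail_prob must lie in [0, 1), got {qc_fail_prob}")
    if slides_per_patient_dist is None:
        slides_per_patient_dist = {1: 0.88, 2: 0.10, 3: 0.02}
    counts = np.array(list(slides_per_patient_dist.keys()), dtype=int)
    probs = np.array(list(slides_per_patient_dist.values()), dtype=float)
    if counts.min() < 1:
        raise ConfigError("every patient needs at least one slide")
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ConfigError("slides_per_patient_dist probabilities must be a distribution")
    if slide_score_sd < 0:
        raise ConfigError("slide_score_sd must be >= 0")

    rng = substream(seed, STREAM_SLIDES)
    n_slides = rng.choice(counts, size=len(cohort), p=probs)
    pid = np.repeat(cohort["patient_id"].to_numpy(), n_slides)
    ai = np.repeat(cohort["ai_score"].to_numpy(dtype=float), n_slides)
    total = int(n_slides.sum())
    fail = rng.random(total) < qc_fail_prob
    tiles = np.where(fail, rng.integers(10, 100, size=total),
                     rng.integers(100, 3000, size=total))
    score = ai + (rng.standard_normal(total) * slide_score_sd
                  if slide_score_sd > 0 else 0.0)
    return pd.DataFrame({
        "slide_id": [f"{p}_s{i}" for p, i in
                     zip(pid, np.concatenate([np.arange(k) for k in n_slides]))],
        "patient_id": pid,
        "n_tissue_tiles": tiles.astype(int),
        "image_score": np.round(score, 6),
    })


# ---------------------------------------------------------------------------
# Orchestration and I/O

def generate_cohort(config: CohortConfig,
                    hazards: HazardConfig | None = None,
                    slides_per_patient_dist: Mapping[int, float] | None = None,
                    qc_fail_prob: float = 0.001,
                    slide_score_sd: float = 2.0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate internally consistent (patients, slides, survival) tables."""
    if hazards is None:
        hazards = HazardConfig()
    n = config.n_patients
    z1, rs, ai = _joint_latent(n, config, substream(config.seed, STREAM_SCORES))
    clinical = _generate_clinical(z1, config, substream(config.seed, STREAM_CLINICAL))
    arms = assign_arms(rs, config.seed)
    patients = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    patients = pd.concat([patients, clinical], axis=1)
    patients["rs"] = np.round(rs, 4)
    patients["ai_score"] = np.round(ai, 4)
    patients["arm"] = arms
    patients["chemo"] = np.isin(arms, ["C", "D"]).astype(int)
    patients = patients[PATIENT_COLUMNS]

    slides = generate_slides(patients, slides_per_patient_dist, qc_fail_prob,
                             seed=config.seed, slide_score_sd=slide_score_sd)
    survival = generate_survival(patients, hazards, seed=config.seed)
    return patients, slides, survival


def write_cohort(patients: pd.DataFrame, slides: pd.DataFrame,
                 survival: pd.DataFrame, outdir: str | Path) -> dict:
    """Write the three cohort tables as UTF-8 RFC 4180 CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("patients", patients), ("slides", slides),
                     ("survival", survival)):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv")
    slides = pd.read_csv(indir / "slides.csv")
    survival = pd.read_csv(indir / "survival.csv")
    return patients, slides, survival


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
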