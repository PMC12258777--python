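# Methods

`oncoscore` implements the statistical machinery used to evaluate an
image-derived surrogate of the Oncotype DX 21-gene recurrence score
(RS) in a chemotherapy-randomization trial setting. The package does
not train or run any image model; it takes surrogate scores as given
(simulated, or supplied as a column) and provides the downstream
statistics: calibration, operating points, counterfactual
chemotherapy-benefit estimation, non-inferiority testing, and
clinical-risk reclassification. This note records the models, the
defaults, and the design choices behind them.

## The synthetic cohort

All analyses are testable without restricted clinical data because the
`synthetic_cohort` module generates cohorts with the structure the
analyses assume. Its defaults are the study conditions and are not
tuning knobs.

**Joint (RS, surrogate) scores.** A latent bivariate standard normal
with correlation equal to the Pearson target (default 0.728) is
transformed affinely per marginal: RS gets mean 18 and SD 9 on the
0–100 scale (about 17% of patients at RS ≥ 26, about 22% below 11),
then is clipped to [0, 100]; the raw surrogate gets mean 22 and SD 10,
deliberately running high relative to RS because uncalibrated deep
models tend to overshoot on external cohorts — this is exactly the
miscalibration the calibration module exists to remove. Clipping
attenuates the realized correlation by well under 0.01 at these
settings; the ±0.05 test band absorbs it.

**Trial arms.** RS < 11 → arm A (endocrine only); RS ≥ 26 → arm D
(chemo-endocrine); 11 ≤ RS < 26 → a seeded 1:1 coin between arm B
(endocrine) and arm C (chemo-endocrine). `chemo = 1` iff arm ∈ {C, D}.

**Clinical covariates.** Categorical features are drawn through a
Gaussian copula on the latent RS normal score: `u = Φ(w·z + √(1−w²)·ε)`
is uniform for any loading `w`, so binning `u` at the cumulative
marginal probabilities preserves the configured marginals exactly in
distribution while inducing an ordered association with RS. Default
loadings make grade the strongest clinical RS signal (w = 0.50),
followed by PR status (−0.35; PR-negative tumors run higher RS), ER
(−0.20) and size (0.15). Default marginals are typical of an
HR+/HER2− node-negative population (grade 1/2/3 at 30/52/18%, ER+ 97%,
PR+ 85%, ≤2 cm 72%); 34% of patients are premenopausal and the cohort
is node-negative unless configured otherwise. Ages are drawn
conditionally on menopausal status (pre: N(45, 5); post: N(61, 7),
clipped to [25, 85]), putting the overall median in the mid-50s.

**Survival.** Each of the five endpoints (DRFI, RFI, DFS, OS, BCSS)
runs on an independent exponential clock with hazard
`baseline · exp(β·RS) · HR_chemo^chemo`, plus independent exponential
censoring (0.002/month ≈ 20% dropout over 9 years) and administrative
censoring at 108 months. Constant baseline hazards give a closed-form
proportional-hazards truth for parameter-recovery tests. Default
per-month baselines (DRFI 2.5e-4, RFI 3e-4, DFS 6e-4, OS 4e-4, BCSS
1.5e-4, with β = 0.03 per RS unit) put ~9-year cumulative incidence in
the single-digit-percent range typical of node-negative HR+ disease.
Chemotherapy effects are stratum-specific: premenopausal HRs of
0.60–0.85 by endpoint (DFS 0.63) and no effect (HR = 1) in
postmenopausal patients, mirroring the clinical finding the benefit
analyses probe. Endpoints are deliberately incoherent with one another
(no multistate model); nothing downstream relies on cross-endpoint
consistency.

**Slides.** Patients receive 1–3 slides (88/10/2%, ≈1.14 per patient);
slide scores scatter around the patient score with SD 2. A small
configurable fraction (default 0.1%) of slides carries fewer than 100
tissue tiles and is removed by QC.

**Seeding.** Every stochastic routine derives its generator from
`(master seed, fixed stream id)` via `numpy.random.SeedSequence`
entropy mixing, so each stage is independently reproducible and two
stages never share a stream.

What the generator does *not* emulate: real image noise and scanner
variation, covariate-dependent censoring, competing risks, correlated
endpoints, and cohort-level batch shifts beyond a location/scale offset
of the surrogate score. Passing tests therefore demonstrate the
statistical machinery is correct under its stated assumptions, not that
any particular surrogate model performs well on real slides.

## Slide QC and aggregation

A 256 × 256 px tile at 0.5 µm/px spans 128 µm, so 100 tiles cover
1.6384 mm²; quoted areas truncate (not round) to two decimals, hence
"1.63 mm²". Slides with fewer than 100 tissue tiles are excluded
(strict `<`), and a patient's score is the unweighted mean of their
retained slides. Patients who lose every slide to QC are reported
missing with a logged warning, never imputed as zero.

## Multimodal fusion and feature attribution

The fusion model is ordinary least squares (no regularization)
predicting RS from the slide-aggregated image score plus encoded
clinical features. Encoding: grade ordinal 1–3 (grades are ordered, so
one coefficient suffices); ER/PR as 0/1; size dichotomized at 2 cm;
menopausal status and surgery as indicators; race one-hot against a
fixed "White" reference. Missing values are an error at fit time —
imputation is out of scope. A rank-deficient design raises an error
naming the collinear columns (scanned left to right, so the later
member of a collinear pair is flagged).

Feature contributions come from sequential forward selection driven by
**validation-set** R² (not the tuning fit): at each step every
remaining candidate is refit on the tuning set — including the image
score's coefficient, which is re-estimated rather than frozen — and the
candidate with the largest validation-R² gain is accepted; ties break
by declaration order for determinism. The greedy path runs until all
candidates are included, so the base R² plus the recorded increments
telescopes exactly (to 1e-10) to the full model's validation R².
Validation increments can be negative and are reported as-is.

Uncertainty: the selection order and all fits are frozen at the point
estimate; validation rows are resampled with replacement (default
B = 1000), and the increment sequence is recomputed per resample.
CIs are 2.5/97.5 percentiles; the p-value is the one-sided fraction of
resamples with ΔR² ≤ 0, floored at 1/B.

## Risk classification

Three bands with half-open boundaries: low `< 16`, high `≥ 26`,
intermediate between. "Predicted positive" always means
`score ≥ threshold`, so ties at a threshold are positive. Operating
points report sensitivity/specificity/NPV/PPV and flagged proportion
against the `RS ≥ 26` reference; empty denominators are reported
missing (NaN), never zero. AUC is the Mann-Whitney statistic computed
by midranks (ties get half credit) with percentile-bootstrap CIs
(B = 1000) rather than DeLong, matching the package-wide bootstrap
convention; paired model comparisons resample patients jointly and
read a two-sided p from the bootstrap ΔAUC distribution, floored at
1/B. Because calibration is strictly monotone, all ranking metrics are
bit-identical before and after it — a property the tests assert
exactly, not approximately.

## Calibration

Cohorts without RS measurements are calibrated by distribution
matching: a clinicopathologic-only linear model (grade, PR, ER, size,
age) estimates the cohort mean RS as the average of its predictions on
k reserved patients (default k = 100, taken as the first k in
accession order; a seeded random selection is available); the single
scaling factor `a = mean_RS_est / mean(raw score)` is then applied
multiplicatively to every score. Raw predictions are clipped at zero
before averaging so `a` is always positive — negative predicted RS is
meaningless, and the clip makes the procedure safe on small k. The
k calibration patients are recorded and excluded from downstream
analyses. An affine opt-in mode additionally matches the spread of the
clinical predictions; the single-parameter scale is the default for
robustness. Simulation shows the factor is median-unbiased to within
2% at k = 100 under an unbiased clinical model, with spread shrinking
as k grows.

## Counterfactual chemotherapy benefit

The randomized B-vs-C comparison only covers 11 ≤ RS < 26, so benefit
in surrogate-defined groups is bounded by transplanting the randomized
comparison into populations with the surrogate groups' RS composition:

* **Premenopausal, surrogate-high (lower bound).** The randomized
  16 ≤ RS < 26 groups are topped up with RS < 16 patients to a 4.9%
  share — the share of RS < 16 among surrogate-high patients once
  RS ≥ 26 is excluded (1.4 / (1.4 + 27.0)). Additions with
  11 ≤ RS < 16 keep their original randomized arm; RS < 11 additions
  (never randomized, never treated) are split 1:1 by a seeded coin.
  Adding untreated patients to both groups can only dilute the
  observed benefit, making the estimate conservative.

* **Postmenopausal, surrogate-low (upper bound).** The randomized
  11 ≤ RS < 26 groups are topped up with RS ≥ 26 patients (all
  chemo-treated) to a 2.1% share. Additions landing in the chemo group
  keep their observed outcomes. Additions landing in the no-chemo
  group cannot: chemotherapy improved their prognosis. Their outcomes
  are instead drawn from the counterfactual curve
  `S_noChemo(t) = S_chemo(t)^(1/HR)` — the standard proportional-
  hazards correction — estimated by KM on the full RS ≥ 26 pool and
  powered with externally estimated chemotherapy HRs (DRFI 0.44,
  DFS 0.45; RFI uses 0.44 as a lower bound).

Augmentation size is `m = round(p·n/(1−p))` so that `m/(n+m) ≈ p`.
Sampling is without replacement; base rows are passed through
unmodified and flagged `augmented=False`.

Drawing from a KM-derived distribution uses inverse-transform sampling
on the step function: with `u ~ U(0,1)`, a draw with `u < S(t_max)`
becomes an administrative censoring at the last observed time — the
tail mass never invents events beyond follow-up, the conservative
choice — and otherwise an event at the smallest step time whose
survival value is ≤ u. Correcting a curve by HR and then by 1/HR
round-trips to 1e-12.

Cox models use lifelines with Efron tie handling and Wald 95% CIs
throughout; benefit is reported as the HR of chemo vs no-chemo
(HR < 1 = benefit) together with both KM curves.

## Non-inferiority

Withholding chemotherapy is declared non-inferior when the one-sided
(1−α) upper Wald bound of the benefit HR falls below the margin of
1.322 (32.2% excess risk) at one-sided α = 0.10. The standard error is
recovered from the two-sided 95% CI as
`(log ci_high − log ci_low)/(2·z_0.975)`. The bound construction is
validated by simulation: with the true HR exactly on the margin, 1,000
two-arm exponential trials (n = 2000/arm, ~20% random censoring) yield
an empirical one-sided type-I error of ~10%, the nominal level.

## Clinical risk

The MINDACT rule table (modified Adjuvant! Online): node-negative cases
are low risk with grade 1 ≤ 3 cm, grade 2 ≤ 2 cm or grade 3 ≤ 1 cm;
node-positive cases only with grade 1 ≤ 2 cm; boundaries inclusive.
Any missing field makes a case unclassifiable, and unclassifiable rows
are excluded from reclassification tables with a logged count. When
menopausal status is unavailable, stratification falls back to age
(≤ 50 vs > 50).

## Numerical and scale choices

* Problem sizes: the end-to-end report simulates 4,000 patients by
  default; parameter-recovery and coverage tests use 100 replicates at
  n = 5,000 (chemo-HR coverage), 200 replicate draws (calibration
  spread), and 1,000 trials (non-inferiority operating
  characteristic) — sizes at which binomial noise is well inside the
  asserted bands.
* Bootstrap replicates default to 1,000 everywhere; p-values are
  floored at 1/B.
* Degenerate inputs fail loudly: empty survival data, eventless pools,
  single-class references, rank-deficient designs, non-positive rates
  and zero-mean score vectors all raise typed errors rather than
  returning silent defaults.
* All ties break deterministically (declaration order in selection,
  `≥` at thresholds).

## Known limitations

* Endpoint clocks are independent; joint statements across endpoints
  (e.g. a patient's DRFI vs DFS ordering) are not meaningful.
* The counterfactual correction assumes proportional hazards within
  the chemo-treated high-RS pool and transports externally estimated
  HRs; neither assumption is testable from the data the procedure uses.
* The clinical-model-based mean-RS estimate inherits any bias of the
  clinical model; calibration quality on real cohorts depends on that
  model transporting across sites.
* The generator's covariate-RS associations are stylized; absolute
  performance numbers on synthetic cohorts (AUC, R²) characterize the
  machinery, not any real model.
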