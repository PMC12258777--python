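"""Kaplan-Meier/Cox estimation, the S^(1/HR) counterfactual correction,
the two augmentation procedures, and non-inferiority testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncoscore import (
    AugmentationSpec,
    ConfigError,
    DataError,
    HREstimate,
    NonInferiorityConfig,
    TrialSpec,
    augment_postmenopausal,
    augment_premenopausal,
    augmentation_size,
    conditional_share,
    cox_hr,
    estimate_chemo_benefit,
    km_estimate,
    noninferiority_test,
    noninferiority_type1_sim,
    ph_correct_survival,
    sample_corrected_times,
)


def km_oracle(times, events):
    """Hand product-limit: S(t) = prod over event times u <= t of
    (1 - d_u / n_u)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = {}
    s = 1.0
    for u in np.unique(times):
        d = int(np.sum((times == u) & (events == 1)))
        n_at_risk = int(np.sum(times >= u))
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out[float(u)] = s
    return out


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([5, 8, 12], [1, 0, 1])
        np.testing.assert_allclose(curve.times, [5.0, 12.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.evaluate(8.0) == pytest.approx(2 / 3)
        assert curve.evaluate(4.9) == 1.0

    def test_all_censored(self):
        curve = km_estimate([3, 7, 9], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.s_tail == 1.0
        assert curve.evaluate(100.0) == 1.0

    def test_no_censoring_reduces_to_empirical(self, rng):
        times = rng.exponential(10, 200)
        curve = km_estimate(times, np.ones(200, dtype=int))
        grid = np.quantile(times, [0.1, 0.5, 0.9])
        for t in grid:
            assert curve.evaluate(t) == pytest.approx(np.mean(times > t),
                                                      abs=1e-12)

    def test_matches_oracle_on_small_cases(self, rng):
        # exhaustive-style check over random datasets of <= 6 patients,
        # with ties and mixed censoring
        for _ in range(200):
            n = int(rng.integers(1, 7))
            times = rng.integers(1, 5, n).astype(float)
            events = rng.integers(0, 2, n)
            curve = km_estimate(times, events)
            oracle = km_oracle(times, events)
            assert len(curve.times) == len(oracle)
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(oracle[t], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            km_estimate([], [])


class TestCox:
    def test_null_two_groups(self, rng):
        t = rng.exponential(10, 4000)
        est = cox_hr(t, np.ones(4000), np.repeat([0, 1], 2000))
        assert 0.9 <= est.hr <= 1.1
        assert est.ci_low <= est.hr <= est.ci_high

    def test_recovers_rate_ratio_two(self, rng):
        n = 5000
        t = np.r_[rng.exponential(10, n), rng.exponential(5, n)]
        c = rng.exponential(40, 2 * n)  # ~20% censoring
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        est = cox_hr(time, event, np.repeat([0, 1], n))
        assert 1.85 <= est.hr <= 2.15

    def test_reciprocal_under_negation(self, rng):
        t = rng.exponential(10, 500)
        e = rng.integers(0, 2, 500)
        x = rng.normal(size=500)
        est = cox_hr(t, e, x)
        est_neg = cox_hr(t, e, -x)
        assert est.hr == pytest.approx(1 / est_neg.hr, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(DataError):
            cox_hr([1.0, 2.0], [0, 0], [0, 1])


class TestPHCorrection:
    def test_identity_at_hr_one(self, rng):
        curve = km_estimate(rng.exponential(10, 100), np.ones(100, dtype=int))
        corrected = ph_correct_survival(curve, 1.0)
        np.testing.assert_array_equal(corrected.survival, curve.survival)
        np.testing.assert_array_equal(corrected.times, curve.times)

    def test_unit_survival_fixed_point(self):
        curve = km_estimate([5.0], [0])
        corrected = ph_correct_survival(curve, 0.44)
        assert corrected.s_tail == 1.0

    def test_known_power_value(self):
        curve = km_estimate([1.0] * 10, [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        corrected = ph_correct_survival(curve, 0.44)
        assert corrected.survival[0] == pytest.approx(0.9 ** (1 / 0.44),
                                                      abs=1e-12)
        assert corrected.survival[0] == pytest.approx(0.787056125, abs=1e-6)

    def test_round_trip(self, rng):
        t = rng.exponential(10, 300)
        e = rng.integers(0, 2, 300)
        curve = km_estimate(t, e)
        back = ph_correct_survival(ph_correct_survival(curve, 0.44), 1 / 0.44)
        np.testing.assert_allclose(back.survival, curve.survival, atol=1e-12)

    def test_beneficial_hr_never_raises_survival(self, rng):
        curve = km_estimate(rng.exponential(10, 200),
                            rng.integers(0, 2, 200))
        corrected = ph_correct_survival(curve, 0.44)
        assert (corrected.survival <= curve.survival + 1e-15).all()

    def test_invalid_hr(self, rng):
        curve = km_estimate([1.0], [1])
        with pytest.raises(DataError):
            ph_correct_survival(curve, 0.0)


class TestCorrectedSampling:
    def test_degenerate_curve_all_censored(self):
        curve = km_estimate([7.0, 9.0], [0, 0])
        t, e = sample_corrected_times(curve, 50, seed=0)
        assert (t == 9.0).all() and (e == 0).all()

    def test_seeded_determinism(self, rng):
        curve = km_estimate(rng.exponential(10, 100), np.ones(100, dtype=int))
        a = sample_corrected_times(curve, 200, seed=3)
        b = sample_corrected_times(curve, 200, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_identity_correction_reproduces_distribution(self, rng):
        # hr = 1 correction then inverse-transform sampling must match the
        # original (uncensored) event distribution
        times = rng.exponential(10, 5000)
        curve = km_estimate(times, np.ones(5000, dtype=int))
        corrected = ph_correct_survival(curve, 1.0)
        t, e = sample_corrected_times(corrected, 5000, seed=4)
        assert e.mean() > 0.99  # only the single max time can censor
        ks = stats.ks_2samp(times, t)
        assert ks.pvalue > 0.01


class TestAugmentationArithmetic:
    def test_conditional_share_low_rs(self):
        # of surrogate-high patients: 71.6% RS>=26, 27.0% 16<=RS<26,
        # 1.4% RS<16; conditioning away RS>=26 lifts 1.4% to 4.9%
        assert round(100 * conditional_share(1.4, 27.0), 1) == 4.9

    def test_conditional_share_high_rs(self):
        # postmenopausal low-surrogate analysis: 2.1% of RS>=11 had RS>=26
        assert conditional_share(2.1, 97.9) == pytest.approx(0.021)

    def test_augmentation_sizes(self):
        assert augmentation_size(1000, 0.049) == 52
        assert augmentation_size(2000, 0.021) == 43
        assert augmentation_size(500, 0.0) == 0

    def test_final_proportion_close_to_target(self):
        m = augmentation_size(1000, 0.049)
        assert m / (1000 + m) == pytest.approx(0.049, abs=0.001)


def _surv_frame(n, rate, rng, rs_low=16.0, rs_high=26.0, arm=None, chemo=0):
    rs = rng.uniform(rs_low, rs_high, n)
    return pd.DataFrame({
        "patient_id": [f"X{rng.integers(1e9)}_{i}" for i in range(n)],
        "rs": rs,
        "arm": arm if arm is not None else rng.choice(["B", "C"], n),
        "chemo": chemo,
        "time": rng.exponential(1 / rate, n),
        "event": 1,
    })


class TestPremenopausalAugmentation:
    def _setup(self, rng, n_base=1000, pool_n=200):
        base = _surv_frame(n_base, 0.01, rng)
        base_b = base[base["arm"] == "B"]
        base_c = base[base["arm"] == "C"]
        pool = pd.concat([
            _surv_frame(pool_n // 2, 0.01, rng, 0.0, 11.0, arm="A"),
            _surv_frame(pool_n // 2, 0.01, rng, 11.0, 16.0),
        ], ignore_index=True)
        return base_b, base_c, pool

    def test_target_proportion_reached(self, rng):
        base_b, base_c, pool = self._setup(rng)
        spec = AugmentationSpec(stratum="premenopausal", seed=1)
        aug_b, aug_c = augment_premenopausal(base_b, base_c, pool, spec)
        n_added = len(aug_b) + len(aug_c) - 1000
        assert n_added == 52
        frac = n_added / (len(aug_b) + len(aug_c))
        assert frac == pytest.approx(0.049, abs=0.001)

    def test_zero_target_leaves_groups_unchanged(self, rng):
        base_b, base_c, pool = self._setup(rng)
        spec = AugmentationSpec(stratum="premenopausal", target_prop=0.0, seed=1)
        aug_b, aug_c = augment_premenopausal(base_b, base_c, pool, spec)
        assert len(aug_b) == len(base_b) and len(aug_c) == len(base_c)

    def test_arm_fidelity_and_partition(self, rng):
        base_b, base_c, pool = self._setup(rng, pool_n=400)
        spec = AugmentationSpec(stratum="premenopausal", target_prop=0.2, seed=2)
        aug_b, aug_c = augment_premenopausal(base_b, base_c, pool, spec)
        added_b = aug_b[aug_b["augmented"]]
        added_c = aug_c[aug_c["augmented"]]
        # 11 <= RS < 16 additions keep their original randomized arm
        assert (added_b.loc[added_b["rs"] >= 11, "arm"] == "B").all()
        assert (added_c.loc[added_c["rs"] >= 11, "arm"] == "C").all()
        # every added RS < 11 patient appears in exactly one group
        low_ids = pd.concat([added_b, added_c])
        low_ids = low_ids.loc[low_ids["rs"] < 11, "patient_id"]
        assert low_ids.is_unique and len(low_ids) > 0
        # base rows preserved unmodified
        pd.testing.assert_frame_equal(
            aug_b[~aug_b["augmented"]].drop(columns="augmented")
            .reset_index(drop=True),
            base_b.reset_index(drop=True))

    def test_pool_too_small(self, rng):
        base_b, base_c, _ = self._setup(rng)
        tiny_pool = _surv_frame(5, 0.01, rng, 11.0, 16.0)
        spec = AugmentationSpec(stratum="premenopausal", seed=1)
        with pytest.raises(DataError):
            augment_premenopausal(base_b, base_c, tiny_pool, spec)


class TestPostmenopausalAugmentation:
    def _setup(self, rng, n_base=2000, pool_n=400, pool_rate=0.02):
        base = _surv_frame(n_base, 0.005, rng, 11.0, 26.0)
        pool = _surv_frame(pool_n, pool_rate, rng, 26.0, 60.0, arm="D", chemo=1)
        return base[base["arm"] == "B"], base[base["arm"] == "C"], pool

    def test_addition_count(self, rng):
        base_b, base_c, pool = self._setup(rng)
        spec = AugmentationSpec(stratum="postmenopausal", seed=3)
        aug_b, aug_c = augment_postmenopausal(base_b, base_c, pool, spec,
                                              endpoint="DFS")
        assert (len(aug_b) + len(aug_c)) - 2000 == 43

    def test_identity_correction_matches_pool_distribution(self, rng):
        base_b, base_c, pool = self._setup(rng, n_base=600, pool_n=3000)
        spec = AugmentationSpec(stratum="postmenopausal", target_prop=0.45,
                                correction_hr={"DFS": 1.0}, seed=4)
        aug_b, _ = augment_postmenopausal(base_b, base_c, pool, spec,
                                          endpoint="DFS")
        drawn = aug_b[aug_b["augmented"]]
        assert len(drawn) > 100
        ks = stats.ks_2samp(drawn["time"], pool["time"])
        assert ks.pvalue > 0.01

    def test_chemo_side_keeps_observed_outcomes(self, rng):
        base_b, base_c, pool = self._setup(rng)
        spec = AugmentationSpec(stratum="postmenopausal", target_prop=0.1,
                                seed=5)
        _, aug_c = augment_postmenopausal(base_b, base_c, pool, spec,
                                          endpoint="DFS")
        added = aug_c[aug_c["augmented"]]
        merged = added.merge(pool, on="patient_id", suffixes=("", "_pool"))
        assert (merged["time"] == merged["time_pool"]).all()
        assert (merged["event"] == merged["event_pool"]).all()

    def test_eventless_pool_rejected(self, rng):
        base_b, base_c, pool = self._setup(rng)
        pool = pool.assign(event=0)
        spec = AugmentationSpec(stratum="postmenopausal", seed=6)
        with pytest.raises(DataError):
            augment_postmenopausal(base_b, base_c, pool, spec, endpoint="DFS")

    def test_null_generator_covers_unit_hr(self):
        """With no true chemo effect and correction HR = 1, the benefit
        HR's 95% CI covers 1 in >= 90 of 100 replicates."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(20_000 + rep)
            base_b, base_c, pool = self._setup(rng, n_base=500, pool_n=300,
                                               pool_rate=0.005)
            spec = AugmentationSpec(stratum="postmenopausal",
                                    correction_hr={"DFS": 1.0}, seed=rep)
            aug_b, aug_c = augment_postmenopausal(base_b, base_c, pool, spec,
                                                  endpoint="DFS")
            est, _, _ = estimate_chemo_benefit(aug_c, aug_b)
            hits += est.ci_low <= 1.0 <= est.ci_high
        assert hits >= 90


class TestChemoBenefit:
    def test_recovers_generating_hr(self, rng):
        n = 2000
        chemo = pd.DataFrame({"time": rng.exponential(1 / (0.01 * 0.63), n),
                              "event": 1})
        no_chemo = pd.DataFrame({"time": rng.exponential(1 / 0.01, n),
                                 "event": 1})
        est, km_c, km_n = estimate_chemo_benefit(chemo, no_chemo)
        assert 0.5 <= est.hr <= 0.8
        assert est.ci_low <= 0.63 <= est.ci_high
        assert km_c.times.size > 0 and km_n.times.size > 0

    def test_null_effect(self, rng):
        a = pd.DataFrame({"time": rng.exponential(100, 3000), "event": 1})
        b = pd.DataFrame({"time": rng.exponential(100, 3000), "event": 1})
        est, _, _ = estimate_chemo_benefit(a, b)
        assert 0.9 <= est.hr <= 1.1

    def test_label_swap_inverts_hr(self, rng):
        a = pd.DataFrame({"time": rng.exponential(50, 800), "event": 1})
        b = pd.DataFrame({"time": rng.exponential(80, 800), "event": 1})
        est_ab, _, _ = estimate_chemo_benefit(a, b)
        est_ba, _, _ = estimate_chemo_benefit(b, a)
        assert est_ab.hr == pytest.approx(1 / est_ba.hr, rel=1e-6)


def _estimate(hr, one_sided_upper_90):
    """HREstimate whose one-sided 90% upper Wald bound equals the given
    value (back-solve the standard error)."""
    z90 = stats.norm.ppf(0.90)
    z975 = stats.norm.ppf(0.975)
    se = np.log(one_sided_upper_90 / hr) / z90
    return HREstimate(hr=hr, ci_low=float(np.exp(np.log(hr) - z975 * se)),
                      ci_high=float(np.exp(np.log(hr) + z975 * se)),
                      p=0.5, n_events=100)


class TestNonInferiority:
    def test_bound_below_margin(self):
        res = noninferiority_test(_estimate(1.00, 1.30))
        assert res.decision == "non_inferior"
        assert res.upper_bound == pytest.approx(1.30, abs=1e-6)

    def test_bound_above_margin(self):
        res = noninferiority_test(_estimate(1.00, 1.35))
        assert res.decision == "not_established"

    def test_vacuous_margin(self):
        cfg = NonInferiorityConfig(margin_hr=np.inf)
        assert noninferiority_test(_estimate(3.0, 5.0), cfg).decision == \
            "non_inferior"

    def test_degenerate_ci_rejected(self):
        est = HREstimate(hr=1.0, ci_low=1.0, ci_high=1.0, p=0.5, n_events=10)
        with pytest.raises(DataError):
            noninferiority_test(est)

    def test_power_at_null_far_exceeds_alpha(self):
        # true HR = 1 at the 1.322 margin: near-certain declaration
        rate = noninferiority_type1_sim(
            trial_spec=TrialSpec(n_per_arm=500, true_hr=1.0),
            reps=100, seed=7)
        assert rate > 0.5

    def test_half_alpha_gives_half_rate_at_margin(self):
        # with alpha = 0.49 (~the median bound) the margin-true rate is ~1/2
        cfg = NonInferiorityConfig(alpha_one_sided=0.49)
        rate = noninferiority_type1_sim(
            cfg, TrialSpec(n_per_arm=500), reps=200, seed=8)
        assert rate == pytest.approx(0.5, abs=0.12)
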