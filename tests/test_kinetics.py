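import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpet.kinetics import (
    TimeActivityCurve,
    WashoutModel,
    auc_trapezoid,
    batch_kE,
    estimate_kE,
    kE_decay_consistency,
    summarize_kE,
)
from mrpet.nuclides import C11, Nuclide, decay_factor
from mrpet.simulate import (
    TISSUE_DEFAULTS,
    _model_value,
    default_tissue_params,
    simulate_cohort,
    simulate_tissue_tac,
)

PARAMS = dict(zip(TISSUE_DEFAULTS, default_tissue_params()))


class TestExactRecovery:
    @pytest.mark.parametrize("tissue", list(TISSUE_DEFAULTS))
    def test_midpoint_sampling_recovers_truth(self, tissue, extended_schedule):
        p = PARAMS[tissue]
        tac = simulate_tissue_tac(p, extended_schedule, sampling="midpoint")
        res = estimate_kE(tac)
        assert abs(res.k_E_per_h - p.k_E_true_per_h) <= 1e-6
        assert res.r_squared > 1.0 - 1e-9
        assert res.n_frames_used == 8

    @pytest.mark.parametrize("tissue", list(TISSUE_DEFAULTS))
    def test_frame_average_recovers_within_small_bias(self, tissue, extended_schedule):
        p = PARAMS[tissue]
        tac = simulate_tissue_tac(p, extended_schedule, sampling="frame_average")
        res = estimate_kE(tac)
        assert abs(res.k_E_per_h - p.k_E_true_per_h) <= 1e-3 * max(p.k_E_true_per_h, 1.0)


class TestEstimator:
    def test_exact_exponential_input(self):
        times = np.array([16.0, 25.0, 40.0, 60.0, 80.0])
        values = np.exp(-2.0 * times / 60.0)
        tac = TimeActivityCurve.from_samples("x", times, values)
        res = estimate_kE(tac)
        assert res.k_E_per_h == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_curve_convention(self):
        times = np.array([16.0, 30.0, 50.0, 80.0])
        tac = TimeActivityCurve.from_samples("flat", times, np.full(4, 2.0))
        res = estimate_kE(tac)
        assert res.k_E_per_h == 0.0
        assert res.r_squared == 1.0

    def test_rising_curve_flagged(self):
        times = np.array([16.0, 30.0, 50.0, 80.0])
        tac = TimeActivityCurve.from_samples("up", times, np.exp(times / 60.0))
        res = estimate_kE(tac)
        assert res.k_E_per_h == pytest.approx(-1.0, abs=1e-9)
        assert res.negative_slope_flag

    def test_nonpositive_value_error_names_frame(self):
        times = np.array([16.0, 30.0, 50.0, 80.0])
        tac = TimeActivityCurve.from_samples("bad", times, [1.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="frame index"):
            estimate_kE(tac)

    def test_too_few_frames_in_window(self):
        tac = TimeActivityCurve.from_samples("few", [20.0, 40.0], [1.0, 0.5])
        with pytest.raises(ValueError, match="at least 3"):
            estimate_kE(tac)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(scale=st.floats(1e-3, 1e3, allow_nan=False))
    def test_scale_invariance(self, scale, extended_schedule):
        tac = simulate_tissue_tac(PARAMS["liver"], extended_schedule)
        a = estimate_kE(tac).k_E_per_h
        b = estimate_kE(tac.scaled(scale)).k_E_per_h
        assert b == pytest.approx(a, rel=1e-9)

    def test_time_unit_consistency(self, extended_schedule):
        # slope fitted against minutes, times 60, equals the hourly rate
        tac = simulate_tissue_tac(PARAMS["liver"], extended_schedule)
        res = estimate_kE(tac)
        mask = (tac.times_min >= 15) & (tac.times_min < 90)
        slope_min = np.polyfit(tac.times_min[mask], np.log(tac.values[mask]), 1)[0]
        assert -slope_min * 60.0 == pytest.approx(res.k_E_per_h, rel=1e-9)

    def test_results_summary_and_confint(self, extended_schedule):
        tac = simulate_tissue_tac(PARAMS["right_lung"], extended_schedule,
                                  noise_scale=0.02, rng=1)
        res = estimate_kE(tac)
        text = res.summary()
        assert "k_E" in text and "right_lung" in text
        ci = res.conf_int()
        assert ci.loc["k_E_per_h", "lower"] < res.k_E_per_h < ci.loc["k_E_per_h", "upper"]

    def test_monotone_degradation_with_noise(self, extended_schedule):
        p = PARAMS["right_lung"]
        rmse = []
        for ns in (0.0, 0.02, 0.08):
            errs = [
                estimate_kE(
                    simulate_tissue_tac(p, extended_schedule, noise_scale=ns, rng=s)
                ).k_E_per_h - p.k_E_true_per_h
                for s in range(40)
            ]
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[0] <= rmse[1] <= rmse[2]


class TestDecayConsistency:
    def _uncorrected(self, k_E, extended_schedule):
        t = extended_schedule.midpoints_min
        corrected = 2.0 * np.exp(-k_E * t / 60.0)
        df = np.array([decay_factor(C11, x) for x in t])
        return TimeActivityCurve.from_schedule(
            "x", extended_schedule, corrected * df, decay_corrected=False
        )

    @pytest.mark.parametrize("k_E", [0.0, 1.0])
    def test_rate_additivity(self, k_E, extended_schedule):
        tac = self._uncorrected(k_E, extended_schedule)
        res = kE_decay_consistency(tac, C11)
        lam_h = 60.0 * math.log(2.0) / 20.364
        assert res.k_E_per_h == pytest.approx(k_E + lam_h, abs=1e-9)

    def test_infinite_half_life_limit(self, extended_schedule):
        stable = Nuclide("stable-ish", 1e12)
        t = extended_schedule.midpoints_min
        vals = 2.0 * np.exp(-0.5 * t / 60.0)
        corrected = TimeActivityCurve.from_schedule("x", extended_schedule, vals)
        uncorr = TimeActivityCurve.from_schedule("x", extended_schedule, vals,
                                                 decay_corrected=False)
        assert kE_decay_consistency(uncorr, stable).k_E_per_h == pytest.approx(
            estimate_kE(corrected).k_E_per_h, abs=1e-9
        )

    def test_corrected_curve_rejected(self, extended_schedule):
        tac = simulate_tissue_tac(PARAMS["liver"], extended_schedule)
        with pytest.raises(ValueError):
            kE_decay_consistency(tac, C11)
        with pytest.raises(ValueError):
            WashoutModel(
                TimeActivityCurve.from_schedule("x", extended_schedule,
                                                tac.values, decay_corrected=False)
            )


class TestAuc:
    def test_constant_rectangle(self):
        t = np.linspace(0, 90, 10)
        tac = TimeActivityCurve.from_samples("c", t, np.full(10, 2.0))
        assert auc_trapezoid(tac, (0, 90)) == pytest.approx(180.0)

    def test_linear_triangle(self):
        t = np.linspace(0, 90, 10)
        tac = TimeActivityCurve.from_samples("lin", t, 2.0 * t / 90.0)
        assert auc_trapezoid(tac, (0, 90)) == pytest.approx(90.0)

    def test_edge_interpolation(self):
        t = np.array([0.0, 10.0, 20.0])
        tac = TimeActivityCurve.from_samples("c", t, np.full(3, 1.0))
        assert auc_trapezoid(tac, (5.0, 15.0)) == pytest.approx(10.0)

    def test_window_outside_range_rejected(self):
        tac = TimeActivityCurve.from_samples("c", [10.0, 20.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="outside sampled"):
            auc_trapezoid(tac, (0.0, 30.0))

    @pytest.mark.parametrize("tissue, target", [("cerebellum", 265.0),
                                                ("cerebral_cortex", 192.0)])
    def test_brain_exposure_calibration(self, tissue, target):
        # densely sampled model curves integrate to the calibrated exposures
        p = PARAMS[tissue]
        t = np.linspace(0.0, 90.0, 1801)
        tac = TimeActivityCurve.from_samples(tissue, t, _model_value(p, t))
        assert auc_trapezoid(tac, (0.0, 90.0)) == pytest.approx(target, rel=2e-3)


class TestBatch:
    def test_degenerate_cohort_reproduces_sex_means(self):
        cohort = simulate_cohort(2, 2, 0, 0, between_subject_cv=0.0,
                                 noise_scale=0.0, seed=0)
        summary = summarize_kE(batch_kE(cohort)).set_index("tissue")
        for tissue, d in TISSUE_DEFAULTS.items():
            assert summary.loc[tissue, "k_E_mean_M"] == pytest.approx(
                d["k_E_M"], rel=1e-3
            )
            assert summary.loc[tissue, "k_E_mean_F"] == pytest.approx(
                d["k_E_F"], rel=1e-3
            )

    def test_single_subject_sd_is_zero(self):
        cohort = simulate_cohort(1, 0, 0, 0, between_subject_cv=0.0,
                                 noise_scale=0.0, seed=0)
        summary = summarize_kE(batch_kE(cohort))
        assert (summary["k_E_sd"] == 0.0).all()
        assert (summary["n"] == 1).all()

    def test_noisy_cohort_means_near_truth(self):
        cohort = simulate_cohort(7, 6, 0, 0, between_subject_cv=0.15,
                                 noise_scale=0.02, seed=0)
        summary = summarize_kE(batch_kE(cohort)).set_index("tissue")
        z = []
        for tissue, d in TISSUE_DEFAULTS.items():
            truth = (7 * d["k_E_M"] + 6 * d["k_E_F"]) / 13.0
            sem = summary.loc[tissue, "k_E_sd"] / math.sqrt(13)
            z.append(abs(summary.loc[tissue, "k_E_mean"] - truth) / sem)
        z = np.asarray(z)
        # Monte-Carlo agreement: no gross outlier, most tissues within 2 SEM
        assert z.max() < 3.5
        assert (z < 2.0).sum() >= 6

    def test_missing_tissue_warns_and_skips(self):
        cohort = simulate_cohort(1, 0, 0, 0, between_subject_cv=0.0,
                                 noise_scale=0.0, seed=0)
        with pytest.warns(UserWarning, match="missing"):
            df = batch_kE(cohort, tissues=["liver", "no_such_tissue"])
        assert list(df["tissue"].unique()) == ["liver"]
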