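import math

import numpy as np
import pandas as pd
import pytest

from mrpet.dosimetry import (
    DoseReport,
    ResidenceTimeSet,
    SourceRegionCurve,
    SValueMatrix,
    dose_for_administration,
    effective_dose,
    load_svalue_matrix,
    load_tissue_weights,
    organ_doses,
    residence_time,
    rest_of_body,
)
from mrpet.nuclides import C11
from mrpet.pipeline import subject_dose, subject_source_curves
from mrpet.simulate import default_subject_params, simulate_subject

LAM_MIN = C11.decay_constant_per_min
TOTAL_TAU_H = 1.0 / C11.decay_constant_per_h


def _pure_decay_curve(fraction, times_min):
    t = np.asarray(times_min, float)
    return SourceRegionCurve(
        "region", t, fraction * 100.0 * np.exp(-LAM_MIN * t), injected_mbq=100.0
    )


class TestResidenceTime:
    def test_constant_corrected_fraction_closed_form(self, extended_schedule):
        # a region holding 10% of injected activity (decay only), sampled on
        # the schedule's boundary grid: tau = 0.1 / lambda
        tau = residence_time(_pure_decay_curve(0.1, extended_schedule.boundaries_min), C11)
        assert tau == pytest.approx(0.1 * TOTAL_TAU_H, rel=1e-12)
        assert tau == pytest.approx(0.04897, abs=5e-5)

    def test_whole_body_closed_form(self, extended_schedule):
        tau = residence_time(_pure_decay_curve(1.0, extended_schedule.boundaries_min), C11)
        assert tau * 60.0 == pytest.approx(20.364 / math.log(2.0), rel=1e-12)

    def test_zero_activity(self):
        c = SourceRegionCurve("empty", np.array([10.0, 50.0]), np.zeros(2), 100.0)
        assert residence_time(c, C11) == 0.0

    def test_midpoint_sampling_with_implicit_zero_is_close(self, extended_schedule):
        # without a t=0 sample the leading ramp-from-zero loses ~0.2%
        tau = residence_time(_pure_decay_curve(0.1, extended_schedule.midpoints_min), C11)
        assert tau == pytest.approx(0.1 * TOTAL_TAU_H, rel=5e-3)

    def test_converges_with_denser_sampling(self):
        # a biologically clearing source: grid error shrinks as sampling doubles
        k_bio = 0.02  # 1/min

        def grid_part_min(n):
            t = np.linspace(0.0, 90.0, n)
            a = 0.3 * 100.0 * np.exp(-(LAM_MIN + k_bio) * t)
            c = SourceRegionCurve("r", t, a, 100.0)
            tail_min = a[-1] / LAM_MIN / 100.0  # identical on every grid
            return residence_time(c, C11) * 60.0 - tail_min

        true_part = 0.3 * (1 - math.exp(-(LAM_MIN + k_bio) * 90.0)) / (LAM_MIN + k_bio)
        errs = [abs(grid_part_min(n) - true_part) for n in (10, 20, 40)]
        assert errs[0] > errs[1] > errs[2]

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            SourceRegionCurve("r", np.array([5.0, 5.0]), np.array([1.0, 1.0]), 100.0)
        with pytest.raises(ValueError):
            SourceRegionCurve("r", np.array([5.0]), np.array([150.0]), 100.0)
        with pytest.raises(ValueError):
            SourceRegionCurve("r", np.array([]), np.array([]), 100.0)


class TestRestOfBody:
    def test_configured_share(self):
        rest, share = rest_of_body({"a": 0.37 * TOTAL_TAU_H}, C11)
        assert rest == pytest.approx(0.63 * TOTAL_TAU_H, rel=1e-12)
        assert share == pytest.approx(0.37)

    def test_no_sampled_organs(self):
        rest, share = rest_of_body({}, C11)
        assert rest == pytest.approx(TOTAL_TAU_H) and share == 0.0

    def test_boundary_fully_sampled(self):
        rest, share = rest_of_body({"a": TOTAL_TAU_H}, C11)
        assert rest == pytest.approx(0.0, abs=1e-12) and share == pytest.approx(1.0)

    def test_excess_rejected(self):
        with pytest.raises(ValueError):
            rest_of_body({"a": 1.01 * TOTAL_TAU_H}, C11)

    def test_conservation_invariant(self, noiseless_subject):
        curves = subject_source_curves(noiseless_subject)
        rts = ResidenceTimeSet.from_sources(curves, C11)
        total = sum(rts.taus_h.values()) + rts.rest_of_body_tau_h
        assert total == pytest.approx(TOTAL_TAU_H, rel=1e-12)
        assert 0.0 < rts.sampled_share < 1.0

    def test_inconsistent_set_rejected(self):
        with pytest.raises(ValueError):
            ResidenceTimeSet({"a": 0.1}, 0.1, C11)


def _single_source_matrix(s_value=1e-5):
    table = pd.DataFrame(
        {"organ": [s_value, 0.0], "rest_of_body": [0.0, 1e-9]},
        index=["organ", "rest_of_body"],
    )
    return SValueMatrix(table, "adult_male")


class TestOrganDoses:
    def test_single_source_closed_form(self):
        rts = ResidenceTimeSet({"organ": 1.0}, TOTAL_TAU_H - 1.0, C11)
        report = organ_doses(rts, _single_source_matrix())
        assert report.organ_doses_ugy_per_mbq["organ"] == pytest.approx(36.0)

    def test_zero_taus_zero_doses(self):
        rts = ResidenceTimeSet({"organ": 0.0}, TOTAL_TAU_H, C11)
        matrix = load_svalue_matrix(phantom="adult_male")
        # zero everywhere except rest of body; zero the rest contribution too
        rts0 = ResidenceTimeSet(
            {src: 0.0 for src in matrix.sources if src != "rest_of_body"},
            TOTAL_TAU_H, C11,
        )
        report = organ_doses(rts0, matrix)
        rest_only = {t: TOTAL_TAU_H * 3600.0 * 1000.0 * float(matrix.table.loc[t, "rest_of_body"])
                     for t in matrix.targets}
        for t, d in report.organ_doses_ugy_per_mbq.items():
            assert d == pytest.approx(rest_only[t], rel=1e-12)

    def test_linearity_in_residence_times(self, noiseless_subject):
        curves = subject_source_curves(noiseless_subject)
        rts = ResidenceTimeSet.from_sources(curves, C11)
        matrix = load_svalue_matrix(phantom="adult_male")
        base = organ_doses(rts, matrix).organ_doses_ugy_per_mbq
        doubled = ResidenceTimeSet(
            {k: 2 * v for k, v in rts.taus_h.items()},
            2 * rts.rest_of_body_tau_h,
            # nuclide with twice the budget so the invariant still closes
            type(C11)("C-11x2", 2 * 20.364),
        )
        dd = organ_doses(doubled, matrix).organ_doses_ugy_per_mbq
        for t in base:
            assert dd[t] == pytest.approx(2 * base[t], rel=1e-12)

    def test_missing_source_named(self):
        rts = ResidenceTimeSet({"no_such_region": 0.01},
                               TOTAL_TAU_H - 0.01, C11)
        with pytest.raises(KeyError, match="no_such_region"):
            organ_doses(rts, load_svalue_matrix(phantom="adult_male"))


class TestEffectiveDose:
    def test_uniform_dose_recovers_itself(self):
        weights, target_map = load_tissue_weights()
        report = DoseReport({"rest_of_body": 5.0, "lungs": 5.0,
                             "urinary_bladder_wall": 5.0, "liver": 5.0}, "adult_male")
        assert effective_dose(report, weights, target_map) == pytest.approx(5.0)

    def test_two_tissue_weighted_mean(self):
        report = DoseReport({"a": 10.0, "b": 20.0}, "adult_male")
        assert effective_dose(report, {"a": 0.5, "b": 0.5}) == pytest.approx(15.0)

    def test_unnormalised_weights_rejected(self):
        report = DoseReport({"a": 10.0}, "adult_male")
        with pytest.raises(ValueError):
            effective_dose(report, {"a": 0.9})

    def test_unresolvable_tissue_without_surrogate_rejected(self):
        report = DoseReport({"a": 10.0}, "adult_male")
        with pytest.raises(KeyError):
            effective_dose(report, {"a": 0.5, "mystery": 0.5})

    def test_packaged_weights_normalised(self):
        weights, _ = load_tissue_weights()
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-9)


class TestDoseForAdministration:
    @pytest.mark.parametrize("e, injected, expected",
                             [(4.67, 400.0, 1.87), (4.55, 400.0, 1.82),
                              (4.67, 0.0, 0.0)])
    def test_display_values(self, e, injected, expected):
        assert round(dose_for_administration(e, injected), 2) == expected

    def test_full_precision_retained(self):
        assert dose_for_administration(4.67, 400.0) == pytest.approx(1.868)


class TestSubjectDosimetry:
    def test_bladder_wall_receives_highest_dose(self, noiseless_subject):
        svalues = {ph: load_svalue_matrix(phantom=ph)
                   for ph in ("adult_male", "adult_female")}
        weights, target_map = load_tissue_weights()
        report = subject_dose(noiseless_subject, svalues, weights, target_map)
        doses = report.organ_doses_ugy_per_mbq
        assert max(doses, key=doses.get) == "urinary_bladder_wall"
        assert report.effective_dose_usv_per_mbq > 0

    def test_phantom_follows_sex(self):
        svalues = {ph: load_svalue_matrix(phantom=ph)
                   for ph in ("adult_male", "adult_female")}
        weights, target_map = load_tissue_weights()
        ds_f = simulate_subject(default_subject_params(sex="F", noise_scale=0.0))
        assert subject_dose(ds_f, svalues, weights, target_map).phantom == "adult_female"

    def test_source_curves_within_physical_bounds(self, noiseless_subject):
        for curve in subject_source_curves(noiseless_subject).values():
            assert (curve.activity_mbq >= 0).all()
            assert (curve.activity_mbq <= curve.injected_mbq).all()
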