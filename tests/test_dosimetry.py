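"""TIAC, local-deposition dose coefficients, TIs, regimens, organ limits."""

import math

import numpy as np
import pytest

from pritdose.biodist import GroupSummary
from pritdose.dosimetry import (
    LU177,
    DoseTable,
    NuclideData,
    OrganLimit,
    Regimen,
    blood_surrogate_marrow,
    cumulative_dose,
    default_organ_limits,
    dose_coefficient,
    limit_report,
    load_reference_coefficients,
    present_ti,
    reference_dose_table,
    therapeutic_index,
    tiac_from_fit,
    tiac_trapezoid_tail,
    two_sigfigs,
)
from pritdose.errors import UndefinedStatisticError, ValidationError
from pritdose.pk import OnePhaseDecayFit, predict

from oracles import tiac_quadrature


def test_nuclide_delta_consistency():
    assert LU177.delta_Gy_g_per_MBq_h == pytest.approx(
        3.6e9 * 0.1335 * 1.60218e-13 * 1000.0, rel=1e-9
    )
    assert LU177.delta_Gy_g_per_MBq_h == pytest.approx(0.07700, rel=1e-3)


class TestTiacFromFit:
    def test_pure_physical_decay(self):
        # A0 = 100 %ID/g frozen biologically: TIAC = 1/lambda_p = T_phys/ln2
        fit = OnePhaseDecayFit(A0=100, plateau=0, t_half_bio_h=1e12)
        got = tiac_from_fit(fit, LU177).value_MBq_h_per_g_per_MBq
        assert got == pytest.approx(159.6 / math.log(2), rel=1e-9)
        assert got == pytest.approx(230.25, abs=0.05)

    def test_constant_biology(self):
        fit = OnePhaseDecayFit(A0=4.5, plateau=4.5, t_half_bio_h=50)
        got = tiac_from_fit(fit, LU177).value_MBq_h_per_g_per_MBq
        assert got == pytest.approx(0.045 / LU177.lambda_phys_per_h, rel=1e-12)
        assert got == pytest.approx(10.36, abs=0.01)

    def test_against_adaptive_quadrature(self):
        fit = OnePhaseDecayFit(A0=14.5, plateau=4.5, t_half_bio_h=25.4)
        got = tiac_from_fit(fit, LU177).value_MBq_h_per_g_per_MBq
        assert got == pytest.approx(tiac_quadrature(14.5, 4.5, 25.4, 159.6), rel=1e-8)
        assert got == pytest.approx(13.52, abs=0.01)

    def test_oracle_equivalence_randomized(self):
        """Closed form == adaptive quadrature to 1e-6 relative over 100
        random parameter sets."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p = rng.uniform(0, 10)
            a0 = p + rng.uniform(0.01, 30)
            th = rng.uniform(0.5, 400)
            fit = OnePhaseDecayFit(A0=a0, plateau=p, t_half_bio_h=th)
            closed = tiac_from_fit(fit, LU177).value_MBq_h_per_g_per_MBq
            assert closed == pytest.approx(
                tiac_quadrature(a0, p, th, 159.6), rel=1e-6
            )

    def test_monotone_in_plateau_and_half_life(self):
        base = tiac_from_fit(OnePhaseDecayFit(A0=10, plateau=2, t_half_bio_h=20), LU177)
        more_p = tiac_from_fit(OnePhaseDecayFit(A0=10, plateau=3, t_half_bio_h=20), LU177)
        more_th = tiac_from_fit(OnePhaseDecayFit(A0=10, plateau=2, t_half_bio_h=30), LU177)
        assert more_p.value_MBq_h_per_g_per_MBq > base.value_MBq_h_per_g_per_MBq
        assert more_th.value_MBq_h_per_g_per_MBq > base.value_MBq_h_per_g_per_MBq


class TestTiacTrapezoidTail:
    def _summaries_on_curve(self, fit, times=(2.0, 24.0, 48.0, 120.0)):
        return [
            GroupSummary("tumor", t, 5, float(predict(fit, t)), 0.1) for t in times
        ]

    def test_matches_closed_form_on_curve(self, gemini_tumor_fit):
        s = self._summaries_on_curve(gemini_tumor_fit)
        hybrid = tiac_trapezoid_tail(s, gemini_tumor_fit, LU177)
        closed = tiac_from_fit(gemini_tumor_fit, LU177)
        assert hybrid.value_MBq_h_per_g_per_MBq == pytest.approx(
            closed.value_MBq_h_per_g_per_MBq, rel=0.02
        )

    def test_constant_data(self):
        fit = OnePhaseDecayFit(A0=5, plateau=5, t_half_bio_h=100)
        s = self._summaries_on_curve(fit)
        got = tiac_trapezoid_tail(s, fit, LU177).value_MBq_h_per_g_per_MBq
        assert got == pytest.approx(0.05 / LU177.lambda_phys_per_h, rel=0.02)

    def test_tail_positive_when_plateau_positive(self, gemini_tumor_fit):
        s = self._summaries_on_curve(gemini_tumor_fit)
        hybrid = tiac_trapezoid_tail(s, gemini_tumor_fit, LU177)
        body_only = np.trapezoid(
            [predict(gemini_tumor_fit, 0)] + [x.mean_pct_id_g for x in s],
            [0.0] + [x.time_h for x in s],
        ) / 100.0
        assert hybrid.value_MBq_h_per_g_per_MBq > 0
        # the tail adds beyond the (decay-weighted) observed body
        assert hybrid.value_MBq_h_per_g_per_MBq > 0.5 * body_only * math.exp(
            -LU177.lambda_phys_per_h * 120
        )


class TestDoseCoefficient:
    def test_zero_tiac(self):
        from pritdose.dosimetry import TIAC

        assert dose_coefficient(TIAC("t", 0.0, "analytic-from-fit"), LU177) == 0.0

    def test_forward_value(self):
        from pritdose.dosimetry import TIAC

        got = dose_coefficient(TIAC("tumor", 13.52, "analytic-from-fit"), LU177)
        assert got == pytest.approx(13.52 * 0.0770007708 * 100, rel=1e-12)
        assert got == pytest.approx(104.1, abs=0.1)

    def test_linear_in_energy(self):
        from pritdose.dosimetry import TIAC

        hot = NuclideData("x2", 159.6, 2 * 0.1335)
        t = TIAC("tumor", 5.0, "analytic-from-fit")
        assert dose_coefficient(t, hot) == pytest.approx(2 * dose_coefficient(t, LU177))


class TestTherapeuticIndex:
    def test_reference_blood_and_kidney_tis(self):
        gem = reference_dose_table("Gemini", 48)
        assert present_ti(therapeutic_index(gem, "blood")) == 50
        assert present_ti(therapeutic_index(gem, "kidneys")) == 9
        abd = reference_dose_table("ABD", 24)
        assert present_ti(therapeutic_index(abd, "blood")) == 15
        assert present_ti(therapeutic_index(abd, "kidneys")) == 5

    def test_identity_ratio(self):
        t = DoseTable({"tumor": 10.0, "liver": 10.0})
        assert therapeutic_index(t, "liver") == 1.0

    def test_zero_dose_undefined(self):
        t = DoseTable({"tumor": 10.0, "liver": 0.0})
        with pytest.raises(UndefinedStatisticError):
            therapeutic_index(t, "liver")

    def test_scale_invariance(self):
        t1 = DoseTable({"tumor": 119.88, "blood": 2.40})
        t2 = DoseTable({"tumor": 1198.8, "blood": 24.0})
        assert therapeutic_index(t1, "blood") == pytest.approx(
            therapeutic_index(t2, "blood")
        )

    def test_present_ti_half_away_from_zero(self):
        assert present_ti(49.95) == 50
        assert present_ti(4.5) == 5
        assert present_ti(4.49) == 4


class TestRegimenArithmetic:
    def test_single_cycle_tumor(self):
        r = Regimen(n_cycles=1, activity_MBq_per_cycle=44.4)
        assert cumulative_dose(r, 119.88) == pytest.approx(53.23, abs=0.01)
        assert two_sigfigs(cumulative_dose(r, 119.88)) == 53

    def test_three_cycle_kidneys(self):
        r = Regimen(n_cycles=3, activity_MBq_per_cycle=44.4)
        assert cumulative_dose(r, 6.94) == pytest.approx(9.244, abs=0.001)
        assert two_sigfigs(cumulative_dose(r, 6.94)) == 9.2

    def test_zero_coefficient(self):
        r = Regimen(n_cycles=3, activity_MBq_per_cycle=44.4)
        assert cumulative_dose(r, 0.0) == 0.0

    def test_linear_in_activity_and_cycles(self):
        r1 = Regimen(n_cycles=1, activity_MBq_per_cycle=10)
        r3 = Regimen(n_cycles=3, activity_MBq_per_cycle=10)
        assert cumulative_dose(r3, 7.0) == pytest.approx(3 * cumulative_dose(r1, 7.0))
        r2 = Regimen(n_cycles=1, activity_MBq_per_cycle=20)
        assert cumulative_dose(r2, 7.0) == pytest.approx(2 * cumulative_dose(r1, 7.0))


class TestBloodSurrogate:
    @pytest.mark.parametrize("coeff", [2.40, 2.14])
    def test_unit_factor(self, coeff):
        assert blood_surrogate_marrow(coeff, 1.0) == coeff

    def test_zero_factor_rejected(self):
        with pytest.raises(ValidationError):
            blood_surrogate_marrow(2.40, 0)


class TestLimitReport:
    def test_kidney_below(self):
        rep = limit_report({"kidneys": 9.2}, [OrganLimit("kidneys", 23, "hard-limit")])
        row = rep.iloc[0]
        assert row.status == "below"
        assert row.margin_Gy == pytest.approx(13.8)

    def test_marrow_threshold_reached(self):
        rep = limit_report(
            {"bone marrow": 3 * 44.4 * 2.14 / 100},
            [OrganLimit("bone marrow", 2.5, "threshold")],
        )
        assert rep.iloc[0].status == "reached"

    def test_hard_limit_exceeded(self):
        rep = limit_report({"kidneys": 30.0}, [OrganLimit("kidneys", 23, "hard-limit")])
        assert rep.iloc[0].status == "exceeded"

    def test_empty_projections(self):
        rep = limit_report({}, [OrganLimit("kidneys", 23)])
        assert rep.empty

    def test_unconstrained_tissue_listed(self):
        rep = limit_report({"spleen": 2.0}, [OrganLimit("kidneys", 23)])
        assert rep.iloc[0].status == "unconstrained"

    def test_empty_limits_rejected(self):
        with pytest.raises(ValidationError):
            limit_report({"kidneys": 9.2}, [])


def test_reference_table_shape_and_defaults():
    df = load_reference_coefficients()
    assert len(df) == 4 * 14
    assert set(df["radiohapten"]) == {"ABD", "Gemini"}
    limits = default_organ_limits()
    assert any(l.tissue == "kidneys" and l.kind == "hard-limit" for l in limits)
    assert any(l.tissue == "bone marrow" and l.kind == "threshold" for l in limits)
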