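"""Single-time-point TIA estimators, dose conversion, cumulative limit."""

import math

import numpy as np
import pytest

from stpdosim import (
    HANSCHEID_MAX_RATIO,
    AggregationError,
    MonoExpFit,
    PopulationHalfLife,
    ScheduleWarning,
    SValueConfig,
    TiaResult,
    check_cycle1_schedule,
    consistent_teff_tia,
    cumulative_dose,
    hanscheid_tia,
    madsen_tia,
    tia_to_dose,
)

LN2 = math.log(2)


def true_tia(a0, teff):
    return a0 * teff / LN2


def activity(a0, teff, t):
    return a0 * 2.0 ** (-t / teff)


class TestHanscheid:
    def test_exact_when_scan_at_half_life(self):
        # A0=100, T_eff=56: A(56)=50; Hanscheid reproduces the true TIA exactly
        tia = hanscheid_tia(50.0, 56.0)
        assert tia.tia_MBq_h == pytest.approx(true_tia(100.0, 56.0), rel=1e-12)
        assert tia.method == "hanscheid"
        assert tia.t_sc_h == 56.0

    def test_day4_overestimate(self):
        tia = hanscheid_tia(activity(100, 56, 96), 96.0)
        assert tia.tia_MBq_h == pytest.approx(8441.7, rel=1e-4)
        assert tia.tia_MBq_h / true_tia(100, 56) == pytest.approx(
            2 * (96 / 56) * 2 ** (-96 / 56), rel=1e-12
        )

    def test_ratio_bound_over_grid(self):
        # ratio to mono-exponential truth is 2x*2^-x, x = t_sc/T_eff,
        # maximised at x = 1/ln2 with value 2/(e ln2)
        teffs = np.linspace(20, 120, 21)
        tscs = np.linspace(1, 400, 81)
        for teff in teffs:
            for tsc in tscs:
                r = hanscheid_tia(activity(100, teff, tsc), tsc).tia_MBq_h / true_tia(
                    100, teff
                )
                assert r <= HANSCHEID_MAX_RATIO + 1e-12
        # the bound is attained at t_sc = T_eff/ln 2
        r = hanscheid_tia(activity(100, 56, 56 / LN2), 56 / LN2).tia_MBq_h / true_tia(
            100, 56
        )
        assert r == pytest.approx(HANSCHEID_MAX_RATIO, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hanscheid_tia(0.0, 96.0)
        with pytest.raises(ValueError):
            hanscheid_tia(50.0, 0.0)


class TestMadsen:
    def test_exact_when_population_half_life_is_true(self):
        tia = madsen_tia(activity(100, 56, 96), 96.0, PopulationHalfLife(56.0))
        assert tia.tia_MBq_h == pytest.approx(true_tia(100, 56), rel=1e-12)

    def test_mismatched_half_life_bias(self):
        # true T_eff 43 h but population 56 h: Madsen underestimates
        tia = madsen_tia(activity(100, 43, 96), 96.0, PopulationHalfLife(56.0))
        assert tia.tia_MBq_h == pytest.approx(5641.0, rel=1e-3)
        assert tia.tia_MBq_h / true_tia(100, 43) == pytest.approx(0.909, abs=0.001)

    def test_reduces_to_hanscheid_when_tp_equals_tsc(self):
        for a in (5.0, 30.475, 200.0):
            m = madsen_tia(a, 96.0, PopulationHalfLife(96.0)).tia_MBq_h
            h = hanscheid_tia(a, 96.0).tia_MBq_h
            assert m == pytest.approx(h, rel=1e-12)


class TestConsistentTeff:
    def test_scale_then_integrate(self, fit_56):
        tia = consistent_teff_tia(activity(100, 56, 96), 96.0, fit_56)
        assert tia.tia_MBq_h == pytest.approx(true_tia(100, 56), rel=1e-12)
        assert tia.method == "consistent_teff"

    def test_identical_to_madsen_with_cycle1_half_life(self, fit_56):
        a = 21.28
        c = consistent_teff_tia(a, 96.0, fit_56).tia_MBq_h
        m = madsen_tia(a, 96.0, PopulationHalfLife(fit_56.teff_h)).tia_MBq_h
        assert c == pytest.approx(m, rel=1e-12)

    def test_half_life_drift_bias(self, fit_56):
        # cycle 1 fitted 56 h, but true cycle-2 half-life is 43 h
        tia = consistent_teff_tia(activity(100, 43, 96), 96.0, fit_56)
        assert tia.tia_MBq_h / true_tia(100, 43) == pytest.approx(0.909, abs=0.001)

    def test_cycle1_schedule_check(self):
        assert check_cycle1_schedule([4.0, 96.0, 168.0])
        assert check_cycle1_schedule([24.0, 96.0])
        with pytest.warns(ScheduleWarning):
            assert not check_cycle1_schedule([48.0, 168.0])
        with pytest.warns(ScheduleWarning):
            assert not check_cycle1_schedule([4.0, 72.0])


class TestHomogeneity:
    def test_estimators_linear_in_activity(self, fit_56):
        pop = PopulationHalfLife(56.0)
        for f in (
            lambda a: hanscheid_tia(a, 96.0).tia_MBq_h,
            lambda a: madsen_tia(a, 96.0, pop).tia_MBq_h,
            lambda a: consistent_teff_tia(a, 96.0, fit_56).tia_MBq_h,
        ):
            assert f(60.0) == pytest.approx(2 * f(30.0), rel=1e-12)


class TestDose:
    def test_tia_to_dose_multiplication(self):
        tia = TiaResult(tia_MBq_h=8078.6, method="mtp")
        rec = tia_to_dose(tia, SValueConfig(3.5e-4), patient_id="P1")
        assert rec.dose_Gy == pytest.approx(2.83, abs=0.005)
        rec2 = tia_to_dose(tia, SValueConfig(7.0e-4), patient_id="P1")
        assert rec2.dose_Gy == pytest.approx(2 * rec.dose_Gy, rel=1e-12)

    def test_cumulative_dose_under_limit(self):
        tia = TiaResult(tia_MBq_h=1.0, method="mtp")
        recs = [
            tia_to_dose(tia, SValueConfig(2.9), patient_id="P1", cycle=c)
            for c in range(1, 5)
        ]
        total, flag = cumulative_dose(recs)
        assert total == pytest.approx(11.6)
        assert not flag

    def test_cumulative_dose_over_limit(self):
        tia = TiaResult(tia_MBq_h=1.0, method="mtp")
        recs = [
            tia_to_dose(tia, SValueConfig(3.0), patient_id="P1", cycle=c)
            for c in range(1, 9)
        ]
        total, flag = cumulative_dose(recs)
        assert total == pytest.approx(24.0)
        assert flag

    def test_cumulative_dose_empty(self):
        assert cumulative_dose([]) == (0.0, False)

    def test_cumulative_dose_rejects_mixed_kidneys(self):
        tia = TiaResult(tia_MBq_h=1.0, method="mtp")
        recs = [
            tia_to_dose(tia, SValueConfig(1.0), patient_id="P1", kidney="left"),
            tia_to_dose(tia, SValueConfig(1.0), patient_id="P1", kidney="right"),
        ]
        with pytest.raises(AggregationError):
            cumulative_dose(recs)
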