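"""Screen scheduling, pathway-specific error semantics, and count pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pacscreen.states as S
from pacscreen.natural_history import evolve
from pacscreen.screening import (
    ManagementPolicy,
    ScreeningStrategy,
    StudyCounts,
    TestPerformance,
    apply_screen,
    pooled_test_performance,
    screen_ages,
    surgery_outcome,
    surveillance_visit,
)


def dist_at(state: int, mass: float = 1.0) -> np.ndarray:
    d = np.zeros(S.N_STATES)
    d[state] = mass
    d[S.NORMAL] += 1.0 - mass
    return d


class TestScreenAges:
    def test_one_time_at_50(self):
        assert screen_ages(ScreeningStrategy.one_time(50.0)) == [50.0]

    def test_annual_50_to_80_has_31_screens(self):
        ages = screen_ages(ScreeningStrategy.annual(50.0, 80.0))
        assert ages == [float(a) for a in range(50, 81)]

    def test_fractional_interval_rounds_to_month_grid(self):
        strat = ScreeningStrategy(mode="interval", start_age=50.0, stop_age=80.0,
                                  interval_years=1.4)
        ages = screen_ages(strat)
        # independent enumeration on the nearest-month grid
        expected, k = [], 0
        while True:
            a = round((50.0 + 1.4 * k) * 12) / 12
            if a > 80.0 + 1e-9:
                break
            expected.append(a)
            k += 1
        assert ages == expected
        assert ages[1] == pytest.approx(51 + 5 / 12)  # 51.417
        assert ages[2] == pytest.approx(52 + 10 / 12)  # 52.833
        assert ages[-1] <= 80.0

    def test_none_mode_has_no_screens(self):
        assert screen_ages(ScreeningStrategy.none()) == []


class TestSurgeryOutcome:
    @pytest.mark.parametrize(
        "mass,m,expected",
        [(0.5, 0.0, (0.5, 0.0)), (0.5, 1.0, (0.0, 0.5)), (0.2, 0.01, (0.198, 0.002))],
    )
    def test_split_arithmetic(self, mass, m, expected):
        alive, dead = surgery_outcome(mass, m, S.NORMAL)
        assert (alive, dead) == pytest.approx(expected)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            surgery_outcome(-0.1, 0.01, S.NORMAL)


class TestApplyScreen:
    def test_inert_test_changes_nothing(self):
        d = np.full(S.N_STATES, 1.0 / S.N_STATES)
        out, ev = apply_screen(d, TestPerformance(0.0, 1.0), ManagementPolicy(0.01))
        np.testing.assert_array_equal(out, d)
        assert all(v == 0.0 for v in ev.surgeries.values())

    def test_all_normal_false_positive_arithmetic(self):
        """Specificity 0.97, surgical mortality 1%: 3% operated, 3e-4 die."""
        d = dist_at(S.NORMAL)
        out, ev = apply_screen(d, TestPerformance(0.56, 0.97), ManagementPolicy(0.01))
        assert ev.surgeries["solid_false_positive"] == pytest.approx(0.03)
        assert out[S.DEATH_SURGERY] == pytest.approx(3e-4)
        assert out[S.NORMAL] == pytest.approx(1.0 - 3e-4)

    def test_high_risk_cyst_detection(self):
        d = dist_at(S.CYST_HR)
        out, _ = apply_screen(d, TestPerformance(0.56, 0.97), ManagementPolicy(0.0))
        assert out[S.NORMAL] == pytest.approx(0.56)
        assert out[S.CYST_HR] == pytest.approx(0.44)

    def test_low_risk_cyst_splits_surveillance_vs_misclassification(self):
        d = dist_at(S.CYST_LR)
        out, ev = apply_screen(d, TestPerformance(0.5, 0.9), ManagementPolicy(0.0))
        assert ev.detections["low_risk_cyst"] == pytest.approx(0.5)
        assert ev.surgeries["cyst_misclassification"] == pytest.approx(0.05)
        assert out[S.SURVEIL[0]] == pytest.approx(0.45)
        assert out[S.CYST_LR] == pytest.approx(0.5)

    def test_detected_localized_pac_cure_split(self):
        d = dist_at(S.SOLID_PRELOC)
        out, ev = apply_screen(
            d, TestPerformance(1.0, 1.0), ManagementPolicy(0.1), cure_fraction=0.25
        )
        assert out[S.DEATH_SURGERY] == pytest.approx(0.1)
        assert out[S.POSTSURG_CURED] == pytest.approx(0.9 * 0.25)
        assert out[S.POSTSURG_LOC] == pytest.approx(0.9 * 0.75)
        assert ev.surgeries["localized_pac"] == pytest.approx(1.0)

    def test_regional_and_distant_disease_not_screen_detectable(self):
        for state in (S.SOLID_PREREG, S.SOLID_PREDIST):
            d = dist_at(state, 0.4)
            out, _ = apply_screen(d, TestPerformance(1.0, 1.0), ManagementPolicy(0.5))
            assert out[state] == d[state]

    @given(
        masses=st.lists(st.floats(0.0, 1.0), min_size=S.N_STATES, max_size=S.N_STATES),
        sens=st.floats(0.0, 1.0),
        spec=st.floats(0.0, 1.0),
        m=st.floats(0.0, 1.0),
        cure=st.floats(0.0, 1.0),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_occupancy_conserved_exactly(self, masses, sens, spec, m, cure):
        d = np.array(masses)
        total = d.sum()
        out, _ = apply_screen(d, TestPerformance(sens, spec), ManagementPolicy(m),
                              cure_fraction=cure)
        assert out.sum() == pytest.approx(total, abs=1e-12)
        assert np.all(out >= -1e-15)


class TestSurveillance:
    def test_years_advance_and_final_year_exits_to_pool(self):
        d = np.zeros(S.N_STATES)
        d[S.SURVEIL[0]] = 0.3
        d[S.SURVEIL[-1]] = 0.2
        d[S.NORMAL] = 0.5
        out, _ = surveillance_visit(d, ManagementPolicy(0.01))
        assert out[S.SURVEIL[0]] == 0.0
        assert out[S.SURVEIL[1]] == pytest.approx(0.3)
        assert out[S.CYST_LR] == pytest.approx(0.2)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_progression_detected_with_certainty(self):
        d = np.zeros(S.N_STATES)
        d[S.SURV_HR] = 0.5
        d[S.SURV_PRELOC] = 0.5
        out, ev = surveillance_visit(d, ManagementPolicy(0.1), cure_fraction=0.2)
        assert out[S.SURV_HR] == 0.0
        assert out[S.SURV_PRELOC] == 0.0
        assert ev.surgeries["surveillance_progression"] == pytest.approx(1.0)
        assert out[S.NORMAL] == pytest.approx(0.45)  # surviving cyst resections
        assert out[S.DEATH_SURGERY] == pytest.approx(0.1)

    def test_false_positive_harm_accumulates_with_repeat_screens(self, bundle):
        """More annual screens -> strictly more false-positive surgeries."""
        fp = []
        for stop in (60.0, 70.0, 80.0):
            tr = evolve(
                bundle.truth_params, bundle.mortality_adjusted,
                strategy=ScreeningStrategy.annual(50.0, stop),
                test=bundle.test, policy=bundle.policy,
            )
            fp.append(tr.counters.surgeries["solid_false_positive"])
        assert fp[0] < fp[1] < fp[2]


class TestPooledPerformance:
    def test_pooled_counts_reproduce_reported_operating_characteristics(self, bundle):
        perf = pooled_test_performance(bundle.studies)
        assert perf.sensitivity == pytest.approx(5 / 9)
        assert perf.specificity == pytest.approx(739 / 760)
        assert round(100 * perf.sensitivity) == 56
        assert round(100 * perf.specificity) == 97

    def test_perfect_single_study(self):
        perf = pooled_test_performance([StudyCounts("s", 3, 0, 10, 0)])
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            pooled_test_performance([StudyCounts("s", 0, 0, 5, 1)])
        with pytest.raises(ValueError, match="specificity"):
            pooled_test_performance([StudyCounts("s", 1, 1, 0, 0)])
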