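"""Transition-matrix construction, cohort evolution, and the Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pacscreen.states as S
from pacscreen.competing_mortality import AGES, AdjustedMortalitySchedule
from pacscreen.natural_history import (
    AgeBandSchedule,
    NaturalHistoryParams,
    ParameterizationError,
    evolve,
    lifetime_pac_incidence,
    microsimulate,
    transition_matrix,
)
from pacscreen.screening import ScreeningStrategy, TestPerformance


def make_params(**kwargs) -> NaturalHistoryParams:
    base = dict(
        onset_solid=AgeBandSchedule.zero(),
        onset_cyst=AgeBandSchedule.zero(),
        prog_lr_hr=0.0,
        prog_hr_pac=0.0,
        prog_loc_reg=0.0,
        prog_reg_dist=0.0,
        detect_clin_loc=0.0,
        detect_clin_reg=0.0,
        detect_clin_dist=0.0,
        surv_dx_loc=0.0,
        surv_dx_reg=0.0,
        surv_dx_dist=0.0,
    )
    base.update(kwargs)
    return NaturalHistoryParams(**base)


def constant_mortality(q_annual: float) -> AdjustedMortalitySchedule:
    return AdjustedMortalitySchedule(age=AGES.copy(), q=np.full(len(AGES), q_annual))


class TestTransitionMatrix:
    def test_no_events_gives_identity(self):
        M = transition_matrix(make_params(), acm_hazard=0.0, age=50.0)
        np.testing.assert_array_equal(M, np.eye(S.N_STATES))

    def test_death_rows_are_unit_vectors(self):
        params = make_params(
            onset_solid=AgeBandSchedule.constant(0.01), prog_loc_reg=0.1,
            detect_clin_loc=0.05, detect_clin_dist=0.2, surv_dx_dist=0.1,
        )
        M = transition_matrix(params, acm_hazard=0.01, age=60.0)
        for d in S.DEATH_STATES:
            expected = np.zeros(S.N_STATES)
            expected[d] = 1.0
            np.testing.assert_array_equal(M[d], expected)

    def test_normal_row_matches_event_order_enumeration(self):
        """Other-cause death first, then mutually exclusive onset events."""
        onset_solid, onset_cyst, acm = 0.01, 0.002, 0.001
        params = make_params(
            onset_solid=AgeBandSchedule.constant(onset_solid),
            onset_cyst=AgeBandSchedule.constant(onset_cyst),
        )
        M = transition_matrix(params, acm_hazard=acm, age=50.0)

        # independent enumeration of the declared event order
        row = {S.DEATH_OTHER: acm}
        survive = 1.0 - acm
        row[S.SOLID_PRELOC] = survive * onset_solid
        row[S.CYST_LR] = survive * onset_cyst
        row[S.NORMAL] = survive * (1.0 - onset_solid - onset_cyst)

        for dest in range(S.N_STATES):
            assert M[S.NORMAL, dest] == pytest.approx(row.get(dest, 0.0), abs=1e-15)

    @given(
        p=st.lists(st.floats(0.0, 0.15), min_size=9, max_size=9),
        acm=st.floats(0.0, 0.5),
        age=st.floats(20.0, 100.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rows_stochastic_for_random_parameters(self, p, acm, age):
        params = make_params(
            onset_solid=AgeBandSchedule.constant(p[0]),
            onset_cyst=AgeBandSchedule.constant(p[1]),
            prog_lr_hr=p[2],
            prog_hr_pac=p[3],
            prog_loc_reg=p[4],
            prog_reg_dist=p[5],
            detect_clin_loc=p[6],
            detect_clin_reg=p[7],
            detect_clin_dist=max(p[8], p[6]),
            surv_dx_loc=0.01,
            surv_dx_reg=0.02,
            surv_dx_dist=0.05,
        )
        M = transition_matrix(params, acm_hazard=acm, age=age)
        assert np.all(M >= 0)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_rejects_overfull_event_budget(self):
        params = make_params(prog_loc_reg=0.7, detect_clin_loc=0.6, detect_clin_dist=0.6)
        with pytest.raises(ParameterizationError, match="Solid_PreLocalized"):
            transition_matrix(params, acm_hazard=0.0, age=50.0)

    def test_rejects_nonmonotone_stage_mortality(self):
        with pytest.raises(ParameterizationError):
            make_params(surv_dx_loc=0.2, surv_dx_reg=0.1, surv_dx_dist=0.3)


class TestEvolve:
    def test_conservation_and_trace_validity(self, bundle):
        trace = evolve(bundle.truth_params, bundle.mortality_adjusted)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        deaths = sum(trace.counters.deaths.values())
        survivors = trace.alive[-1]
        assert deaths + survivors == pytest.approx(1.0, abs=1e-9)

    def test_no_disease_is_pure_life_table_attrition(self, bundle):
        trace = evolve(make_params(), bundle.mortality_adjusted)
        q = bundle.mortality_adjusted.per_cycle(12)
        surv = np.concatenate([[1.0], np.cumprod(np.repeat(1.0 - q, 12))])
        np.testing.assert_allclose(trace.occupancy[:, S.NORMAL], surv, atol=1e-12)
        disease_cols = [i for i in S.ALIVE_STATES if i != S.NORMAL]
        assert trace.occupancy[:, disease_cols].sum() == 0.0

    def test_constant_hazard_occupancy_is_geometric(self):
        q_annual = 0.05
        trace = evolve(make_params(), constant_mortality(q_annual))
        qc = 1.0 - (1.0 - q_annual) ** (1.0 / 12.0)
        k = np.arange(trace.occupancy.shape[0])
        np.testing.assert_allclose(
            trace.occupancy[:, S.NORMAL], (1.0 - qc) ** k, rtol=1e-12
        )

    def test_inert_screen_is_bitwise_identical_with_screens_counted(self, bundle):
        inert = TestPerformance(sensitivity=0.0, specificity=1.0)
        annual = ScreeningStrategy.annual(50.0, 80.0)
        t_none = evolve(bundle.truth_params, bundle.mortality_adjusted)
        t_scr = evolve(
            bundle.truth_params, bundle.mortality_adjusted,
            strategy=annual, test=inert, policy=bundle.policy,
        )
        assert np.array_equal(t_none.occupancy, t_scr.occupancy)
        assert t_scr.counters.screens_performed > 0
        assert t_none.counters.screens_performed == 0

    def test_more_aggressive_distant_mortality_never_raises_le(self, bundle):
        from pacscreen.outcomes import life_expectancy

        p_lo = bundle.truth_params
        p_hi = p_lo.replace(surv_dx_dist=min(1.0, p_lo.surv_dx_dist * 2))
        le_lo = life_expectancy(evolve(p_lo, bundle.mortality_adjusted))
        le_hi = life_expectancy(evolve(p_hi, bundle.mortality_adjusted))
        assert le_hi <= le_lo


class TestMicrosimulate:
    def test_same_seed_identical(self, bundle):
        kw = dict(n_individuals=300, seed=11)
        a = microsimulate(bundle.truth_params, bundle.mortality_adjusted, None, None, None, **kw)
        b = microsimulate(bundle.truth_params, bundle.mortality_adjusted, None, None, None, **kw)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_single_path_is_legal(self, bundle):
        ms = microsimulate(
            bundle.truth_params, bundle.mortality_adjusted, None, None, None,
            n_individuals=1, seed=3,
        )
        occ = ms.occupancy
        assert np.all((occ == 0.0) | (occ == 1.0))
        path = occ.argmax(axis=1)
        died = False
        for s in path:
            if died:
                assert s in S.DEATH_STATES  # absorbing
            died = died or s in S.DEATH_STATES

    def test_matches_matrix_engine_within_sampling_error(self, bundle):
        n = 4000
        ms = microsimulate(
            bundle.truth_params, bundle.mortality_adjusted, None, None, None,
            n_individuals=n, seed=5,
        )
        tr = evolve(bundle.truth_params, bundle.mortality_adjusted)
        for age in (50.0, 65.0, 80.0):
            p = tr.occupancy_at_age(age)
            p_hat = ms.occupancy_at_age(age)
            se = np.sqrt(p * (1 - p) / n)
            assert np.all(np.abs(p_hat - p) <= 3 * se + 3 / n)


class TestLifetimeIncidence:
    def test_zero_onset_gives_zero(self, bundle):
        trace = evolve(make_params(), bundle.mortality_adjusted)
        assert lifetime_pac_incidence(trace) == 0.0

    def test_equals_cumulative_onset_without_competing_death(self):
        """With no other-cause death and prompt diagnosis, lifetime incidence
        is the cumulative onset probability (hand integral of the schedule)."""
        p_onset = 1e-3
        params = make_params(
            onset_solid=AgeBandSchedule(edges=(20.0, 60.0), values=(p_onset, 0.0)),
            detect_clin_loc=0.3,
            detect_clin_dist=0.3,
            surv_dx_loc=0.0,
            surv_dx_reg=0.0,
            surv_dx_dist=0.0,
        )
        trace = evolve(params, constant_mortality(0.0))
        expected = 1.0 - (1.0 - p_onset) ** (40 * 12)
        assert lifetime_pac_incidence(trace) == pytest.approx(expected, abs=1e-9)

    def test_baseline_fixture_in_plausible_band(self, bundle):
        trace = evolve(bundle.truth_params, bundle.mortality_adjusted)
        assert 0.005 <= lifetime_pac_incidence(trace) <= 0.05
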