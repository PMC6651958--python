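"""Transition structure, annual cycles, aging and the projection loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokesim.ages import AGE_MIN, N_AGES
from smokesim.engine import (
    StateArrays,
    advance_age,
    build_transition_row,
    project,
    step_cycle,
)
from smokesim.errors import ConfigurationError, ContractViolationError
from smokesim.policies import identity_scenario, PolicyScenario

from conftest import uniform_schedule


def ages_array(**at):
    """Zero array with specific values at given ages, e.g. a20=100."""
    arr = np.zeros(N_AGES)
    for key, value in at.items():
        arr[int(key[1:]) - AGE_MIN] = value
    return arr


class TestBuildTransitionRow:
    def test_current_row_is_competing_cessation_and_death(self):
        row = build_transition_row("current", cessation=0.033, pdying=0.01)
        assert row == pytest.approx([0.0, 1 - 0.033 - 0.01, 0.033, 0.01])

    def test_never_row_direct_substitution(self):
        row = build_transition_row("never", initiation=0.05, pdying=0.01)
        assert row == pytest.approx([0.94, 0.05, 0.0, 0.01])

    @pytest.mark.parametrize("state", ["never", "current", "former"])
    def test_no_event_cycle_is_identity(self, state):
        row = build_transition_row(state)
        expected = np.zeros(4)
        expected[["never", "current", "former"].index(state)] = 1.0
        assert row == pytest.approx(expected)

    def test_death_row_is_absorbing(self):
        assert build_transition_row("death") == pytest.approx([0, 0, 0, 1])

    def test_negative_diagonal_rejected(self):
        with pytest.raises(ContractViolationError):
            build_transition_row("current", cessation=0.7, pdying=0.5)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.sampled_from(["never", "current", "former", "death"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_rows_are_stochastic_with_structural_zeros(self, i, c, r, p, state):
        try:
            row = build_transition_row(state, initiation=i, cessation=c, relapse=r, pdying=p)
        except ContractViolationError:
            return
        assert abs(row.sum() - 1.0) < 1e-12
        assert np.all(row >= 0)
        if state == "never":
            assert row[2] == 0.0  # never -> former impossible
        if state in ("current", "former", "death"):
            assert row[0] == 0.0  # nothing flows back to never


class TestStepCycle:
    def test_initiation_moves_never_to_current(self):
        states = StateArrays(never=100.0, current=0.0, former=0.0)
        new, deaths = step_cycle(states, 0.1, 0, 0, 0, 0, 0)
        assert new.never.sum() == pytest.approx(100 * N_AGES * 0.9)
        assert new.current.sum() == pytest.approx(100 * N_AGES * 0.1)
        assert deaths.total() == 0.0

    def test_cessation_and_death_split_current(self):
        states = StateArrays(
            never=np.zeros(N_AGES), current=ages_array(a40=1000.0), former=np.zeros(N_AGES)
        )
        new, deaths = step_cycle(states, 0, 0.033, 0, 0, 0.01, 0)
        assert new.current[40 - AGE_MIN] == pytest.approx(957.0)
        assert new.former[40 - AGE_MIN] == pytest.approx(33.0)
        assert deaths.total() == pytest.approx(10.0)

    @given(
        st.floats(0, 0.5), st.floats(0, 0.5), st.floats(0, 0.5),
        st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_zero_mortality_conserves_alive(self, i, c, r, n0, c0, f0):
        states = StateArrays(never=n0, current=c0, former=f0)
        new, deaths = step_cycle(states, i, c, r, 0, 0, 0)
        assert deaths.total() == 0.0
        assert new.total_alive() == pytest.approx(states.total_alive(), rel=1e-12)

    @given(
        st.floats(0, 0.4), st.floats(0, 0.4), st.floats(0, 0.4),
        st.floats(0, 0.3), st.floats(0, 0.3), st.floats(0, 0.3),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_with_deaths(self, i, c, r, pn, pc, pf):
        states = StateArrays(never=1000.0, current=500.0, former=250.0)
        new, deaths = step_cycle(states, i, c, r, pn, pc, pf)
        assert new.total_alive() + deaths.total() == pytest.approx(
            states.total_alive(), rel=1e-12
        )

    def test_infeasible_flows_rejected_with_ages(self):
        states = StateArrays(never=1.0, current=1.0, former=1.0)
        with pytest.raises(ContractViolationError, match="current"):
            step_cycle(states, 0, 0.8, 0, 0, 0.3, 0)


class TestAdvanceAge:
    def test_entrants_enter_as_never_smokers(self):
        shifted = advance_age(StateArrays.zeros(), entrants=5000.0)
        assert shifted.never[0] == 5000.0
        assert shifted.current[0] == 0.0
        assert shifted.former[0] == 0.0

    def test_zero_entrants_leaves_age15_empty(self):
        states = StateArrays(never=10.0, current=5.0, former=2.0)
        shifted = advance_age(states, entrants=0.0)
        assert shifted.alive[0] == 0.0

    def test_top_age_absorbs_predecessor(self):
        states = StateArrays(never=ages_array(a99=7.0, a100=11.0),
                             current=np.zeros(N_AGES), former=np.zeros(N_AGES))
        shifted = advance_age(states, entrants=0.0)
        assert shifted.never[-1] == pytest.approx(18.0)

    def test_double_shift_translates_counts_two_years(self):
        states = StateArrays(never=ages_array(a20=3.0), current=ages_array(a30=4.0),
                             former=ages_array(a40=5.0))
        twice = advance_age(advance_age(states, 0.0), 0.0)
        assert twice.never[22 - AGE_MIN] == 3.0
        assert twice.current[32 - AGE_MIN] == 4.0
        assert twice.former[42 - AGE_MIN] == 5.0

    def test_negative_entrants_rejected(self):
        with pytest.raises(ContractViolationError):
            advance_age(StateArrays.zeros(), entrants=-1.0)


class TestProject:
    def test_zero_world_is_fixed_point(self, zero_mortality, unit_rr, uniform_entrants):
        initial = StateArrays(never=100.0, current=50.0, former=25.0)
        res = project(
            initial, uniform_schedule(), zero_mortality, unit_rr, uniform_entrants,
            base_year=2015, horizon_end=2020, sex="male",
        )
        # aging shifts counts but with uniform arrays, zero rates and the
        # top-age absorption the aggregate state mix is unchanged
        for year in res.years:
            assert res.prevalence(year) == pytest.approx(res.prevalence(2015))
        assert res.cumulative_deaths() == 0.0

    def test_identity_scenario_bit_equal_to_none(self, flat_mortality, unit_rr,
                                                 fixture_schedule, uniform_entrants):
        initial = StateArrays(never=1000.0, current=800.0, former=100.0)
        kwargs = dict(base_year=2015, horizon_end=2025, sex="male")
        a = project(initial, fixture_schedule, flat_mortality, unit_rr,
                    uniform_entrants, None, **kwargs)
        b = project(initial, fixture_schedule, flat_mortality, unit_rr,
                    uniform_entrants, identity_scenario(), **kwargs)
        for year in a.years:
            assert np.array_equal(a.states[year].never, b.states[year].never)
            assert np.array_equal(a.states[year].current, b.states[year].current)
            assert np.array_equal(a.states[year].former, b.states[year].former)

    def test_missing_entrants_year_is_error(self, flat_mortality, unit_rr, fixture_schedule):
        initial = StateArrays(never=100.0, current=10.0, former=1.0)
        with pytest.raises(ConfigurationError, match="entrant"):
            project(initial, fixture_schedule, flat_mortality, unit_rr,
                    {2016: 0.0}, base_year=2015, horizon_end=2020)

    def test_missing_mortality_year_is_error(self, unit_rr, fixture_schedule,
                                             uniform_entrants, flat_mortality):
        initial = StateArrays(never=100.0, current=10.0, former=1.0)
        with pytest.raises(ConfigurationError, match="mortality"):
            project(initial, fixture_schedule, flat_mortality, unit_rr,
                    dict.fromkeys(range(2015, 2031), 0.0),
                    base_year=2015, horizon_end=2030)

    def test_conservation_each_cycle(self, flat_mortality, unit_rr, fixture_schedule):
        initial = StateArrays(never=1000.0, current=700.0, former=200.0)
        entrants = {y: 1234.5 for y in range(2016, 2026)}
        res = project(initial, fixture_schedule, flat_mortality, unit_rr, entrants,
                      base_year=2015, horizon_end=2025)
        for year in range(2015, 2025):
            expected = (res.states[year].total_alive()
                        - res.deaths[year + 1].total() + entrants[year + 1])
            assert res.states[year + 1].total_alive() == pytest.approx(expected, rel=1e-12)

    def test_cumulative_deaths_nondecreasing(self, flat_mortality, unit_rr, fixture_schedule):
        initial = StateArrays(never=1000.0, current=700.0, former=200.0)
        res = project(initial, fixture_schedule, flat_mortality, unit_rr,
                      dict.fromkeys(range(2016, 2026), 10.0),
                      base_year=2015, horizon_end=2025)
        for year in res.death_years():
            assert res.deaths[year].total() >= 0.0


class TestOracleEquivalence:
    """The engine must agree with explicit dense transition-matrix powering.

    With relative risks fixed at 1, every status shares the all-cause death
    probability, so the full year-step (transitions then aging then entrant
    injection) is a linear map on the stacked state vector and can be
    written as one dense matrix, built here independently of the engine.
    """

    def _dense_year_matrix(self, n_ages, init, cess, rel, pdie):
        # state ordering: [never(a0..), current(a0..), former(a0..), dead]
        dim = 3 * n_ages + 1
        T = np.zeros((dim, dim))  # transition phase, column -> row
        for a in range(n_ages):
            i, c, r, p = init[a], cess[a], rel[a], pdie[a]
            N, C, F = a, n_ages + a, 2 * n_ages + a
            T[N, N] = 1 - i - p
            T[C, N] = i
            T[-1, N] += p
            T[C, C] = 1 - c - p
            T[F, C] = c
            T[-1, C] += p
            T[C, F] = r
            T[F, F] = 1 - r - p
            T[-1, F] += p
        T[-1, -1] = 1.0
        A = np.zeros((dim, dim))  # aging phase: shift, top age absorbs
        for s in range(3):
            base = s * n_ages
            for a in range(n_ages - 1):
                A[base + a + 1, base + a] = 1.0
            A[base + n_ages - 1, base + n_ages - 1] = 1.0
        A[-1, -1] = 1.0
        return A @ T

    def test_trajectory_matches_dense_powering(self, unit_rr):
        import pandas as pd

        from smokesim.ages import BANDS
        from smokesim.mortality import MortalitySchedule
        from smokesim.rates import build_rate_schedule

        rng = np.random.default_rng(42)
        n_sub = 3  # ages 15-17 carry population; the rest of the grid is empty
        init_b = {b: 0.0 for b in BANDS}
        init_b["15-19"] = 0.04
        cess_b = {b: 0.02 for b in BANDS}
        schedule = build_rate_schedule(cess_b, init_b, relapse=0.015, sex="male")
        mort_rows = [
            {"year": y, "sex": "male", "age_group": b, "all_cause_rate": 0.01}
            for y in range(2015, 2021) for b in BANDS
        ]
        mortality = MortalitySchedule(pd.DataFrame(mort_rows))

        never0 = np.zeros(N_AGES)
        current0 = np.zeros(N_AGES)
        former0 = np.zeros(N_AGES)
        never0[:n_sub] = rng.uniform(100, 1000, n_sub)
        current0[:n_sub] = rng.uniform(100, 1000, n_sub)
        former0[:n_sub] = rng.uniform(10, 100, n_sub)

        res = project(
            StateArrays(never0, current0, former0), schedule, mortality, unit_rr,
            dict.fromkeys(range(2016, 2021), 0.0),
            base_year=2015, horizon_end=2020, sex="male",
        )

        M = self._dense_year_matrix(
            N_AGES,
            schedule.initiation("male"), schedule.cessation("male"),
            np.full(N_AGES, 0.015), np.full(N_AGES, 0.01),
        )
        v = np.concatenate([never0, current0, former0, [0.0]])
        for year in range(2016, 2021):
            v = M @ v
            s = res.states[year]
            got = np.concatenate([s.never, s.current, s.former])
            assert np.allclose(got, v[:-1], rtol=1e-10, atol=1e-8)

    def test_two_cycle_toy_equals_matrix_square(self):
        # one stratum, uniform rates: two engine cycles = dense matrix power
        i, c, p = 0.05, 0.02, 0.01
        M = np.array([
            [1 - i - p, 0, 0, 0],
            [i, 1 - c - p, 0.0, 0],
            [0, c, 1 - 0.0 - p, 0],
            [p, p, p, 1],
        ])
        v0 = np.array([1000.0, 500.0, 100.0, 0.0])
        expected = M @ (M @ v0)

        states = StateArrays(never=1000.0, current=500.0, former=100.0)
        for _ in range(2):
            states, deaths = step_cycle(states, i, c, 0.0, p, p, p)
        assert states.never[0] == pytest.approx(expected[0])
        assert states.current[0] == pytest.approx(expected[1])
        assert states.former[0] == pytest.approx(expected[2])


class TestMonotoneCessation:
    def test_higher_cessation_multiplier_never_raises_prevalence(
        self, flat_mortality, unit_rr, fixture_schedule, uniform_entrants
    ):
        initial = StateArrays(never=1000.0, current=800.0, former=100.0)
        lo = PolicyScenario("lo", cessation_mult=np.full(N_AGES, 1.0))
        hi = PolicyScenario("hi", cessation_mult=np.full(N_AGES, 1.5))
        kwargs = dict(base_year=2015, horizon_end=2025, sex="male")
        res_lo = project(initial, fixture_schedule, flat_mortality, unit_rr,
                         uniform_entrants, lo, **kwargs)
        res_hi = project(initial, fixture_schedule, flat_mortality, unit_rr,
                         uniform_entrants, hi, **kwargs)
        for year in res_lo.years:
            assert res_hi.prevalence(year) <= res_lo.prevalence(year) + 1e-12
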