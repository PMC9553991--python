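"""State enumeration and transition-matrix / cohort-engine behaviour."""

import numpy as np
import pytest

from adscreen.markov import build_matrix, initial_distribution, run_cohort
from adscreen.parameters import DISEASE_CONDITIONS
from adscreen.screening import ScreeningPolicy, screening_cycles, apply_screening
from adscreen.states import enumerate_states


class TestEnumeration:
    def test_three_year_tunnel_gives_19_states(self, params):
        # NORMAL + NORMAL-FP + 4 x (1 untreated + 3 treated years) + DEAD
        assert params.drug_effect_years == 3
        assert len(enumerate_states(params)) == 19

    def test_lifetime_effect_gives_11_states(self, params):
        params.drug_effect_years = "lifetime"
        assert len(enumerate_states(params)) == 11

    def test_ordering_is_deterministic(self, params):
        a, b = enumerate_states(params), enumerate_states(params)
        assert a.labels == b.labels
        assert [a.index(s) for s in a] == [b.index(s) for s in b]

    def test_dead_is_last_and_normal_first(self, params):
        space = enumerate_states(params)
        assert space.labels[0] == "NORMAL"
        assert space.labels[1] == "NORMAL_FP"
        assert space.labels[-1] == "DEAD"


def _zero_dynamics(params):
    for k in params.tp_untreated:
        params.tp_untreated[k] = 0.0
    for k in params.tp_treated:
        params.tp_treated[k] = 0.0
    for k in params.natural_mortality:
        params.natural_mortality[k] = 0.0
    for k in params.excess_mortality:
        params.excess_mortality[k] = 0.0
    params.visit_rate_mci = 0.0
    params.visit_rate_ad = 0.0
    return params


class TestBuildMatrix:
    def test_rows_are_stochastic_and_dead_absorbing(self, anchored_params):
        tm = build_matrix(anchored_params, 60)
        assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-9)
        dead = tm.space.dead
        expected = np.zeros(len(tm.space))
        expected[dead] = 1.0
        assert np.array_equal(tm.matrix[dead], expected)
        assert np.all(tm.matrix >= 0)

    def test_all_zero_dynamics_freezes_condition_and_treatment(self, params):
        """With every transition and mortality probability zero, nobody
        changes condition or treatment status; the only remaining motion is
        tunnel bookkeeping (counter advance, FP expiry)."""
        _zero_dynamics(params)
        tm = build_matrix(params, 60)
        M, space = tm.matrix, tm.space
        # FP tunnel expires to plain NORMAL even with zero dynamics
        assert M[space.normal_fp, space.normal] == 1.0
        for i, s in enumerate(space):
            if i == space.normal_fp:
                continue
            j = int(np.argmax(M[i]))
            assert M[i, j] == 1.0
            assert space.condition_of(j) == s.condition
            assert space.is_treated(j) == s.treated
        # untreated, cap-year and terminal states are exactly fixed points
        for idx in (space.normal, space.dead, space.untreated("MCI"),
                    space.treated_idx("MCI", space.n_tunnel)):
            assert M[idx, idx] == 1.0

    def test_uniform_natural_mortality_fills_death_column(self, params):
        # zero transitions/excess, natural mortality of the 70-74 band
        _zero_dynamics(params)
        for k in params.natural_mortality:
            params.natural_mortality[k] = 0.0295
        tm = build_matrix(params, 72)
        M, space = tm.matrix, tm.space
        living = [i for i in range(len(space)) if i != space.dead]
        assert np.allclose(M[living, space.dead], 0.0295, atol=1e-12)

    def test_moderate_mild_regression_not_drug_modified(self, params, caplog):
        import logging

        params.tp_treated["MODERATE->MILD"] = 0.3
        params.tp_untreated["MODERATE->MILD"] = 0.04
        with caplog.at_level(logging.WARNING):
            tm = build_matrix(params, 60)
        assert "MODERATE->MILD" in caplog.text
        space = tm.space
        # treated moderate year 1 regresses at the untreated rate
        i = space.treated_idx("MODERATE", 1)
        j = space.treated_idx("MILD", 2)
        assert tm.matrix[i, j] == pytest.approx(0.04)

    def test_age_outside_horizon_raises(self, params):
        with pytest.raises(ValueError, match="horizon"):
            build_matrix(params, 85)

    def test_treated_cap_rows_match_untreated_condition_marginals(self, params):
        """After the drug-effect window the cap state transits exactly as an
        untreated patient, condition by condition (visit uptake off)."""
        params.visit_rate_mci = 0.0
        params.visit_rate_ad = 0.0
        tm = build_matrix(params, 60)
        M, space = tm.matrix, tm.space
        conds = ("NORMAL", *DISEASE_CONDITIONS, "DEAD")
        for cond in DISEASE_CONDITIONS:
            cap = M[space.treated_idx(cond, space.n_tunnel)]
            untr = M[space.untreated(cond)]
            for dest in conds:
                cap_mass = sum(cap[i] for i in range(len(space))
                               if space.condition_of(i) == dest)
                untr_mass = sum(untr[i] for i in range(len(space))
                                if space.condition_of(i) == dest)
                assert cap_mass == pytest.approx(untr_mass, abs=1e-12), (cond, dest)

    def test_pre_cap_treated_rows_use_treated_probabilities(self, anchored_params):
        tm = build_matrix(anchored_params, 60)
        space = tm.space
        i = space.treated_idx("MCI", 1)
        j = space.treated_idx("MILD", 2)
        assert tm.matrix[i, j] == pytest.approx(
            anchored_params.tp_treated["MCI->MILD"], abs=1e-12
        )


class TestRunCohort:
    def test_zero_dynamics_cohort_is_constant(self, params, once_policy):
        _zero_dynamics(params)
        params.participation = 0.0  # no screening redistribution either
        trace = run_cohort(params, once_policy, "screening")
        for t in range(trace.n_cycles + 1):
            assert np.allclose(trace.occupancy[t], trace.occupancy[0], atol=1e-9)

    def test_certain_death_flushes_cohort_in_one_cycle(self, params, once_policy):
        _zero_dynamics(params)
        for k in params.natural_mortality:
            params.natural_mortality[k] = 1.0
        trace = run_cohort(params, once_policy, "no_screening")
        space = trace.space
        assert trace.occupancy[1, space.dead] == pytest.approx(params.cohort_size)
        assert trace.incident_deaths[0] == pytest.approx(params.cohort_size)

    def test_matrix_product_oracle(self, anchored_params, once_policy):
        """The trace equals the initial distribution pushed through the
        per-cycle matrices (with the screening redistribution), recomputed
        independently here."""
        ps = anchored_params
        trace = run_cohort(ps, once_policy, "screening")
        space = trace.space
        x = initial_distribution(ps, space)
        cycles = set(screening_cycles(once_policy, ps))
        for t in range(ps.n_cycles):
            if t in cycles:
                x = apply_screening(x, ps, space)
            M = build_matrix(ps, ps.start_age + t, "screening", space).matrix
            x = x @ M
        assert np.allclose(trace.occupancy[-1], x, atol=1e-8)

    def test_mass_conservation_and_monotone_deaths(self, anchored_params, once_policy):
        trace = run_cohort(anchored_params, once_policy, "screening")
        totals = trace.occupancy.sum(axis=1)
        assert np.allclose(totals, anchored_params.cohort_size, atol=1e-6)
        assert np.all(np.diff(trace.cumulative_deaths) >= -1e-9)
        assert np.all(trace.incident_untreated_severe >= -1e-9)

    def test_initial_cohort_is_untreated(self, anchored_params, once_policy):
        policy = ScreeningPolicy(start_age=65, interval="once")
        trace = run_cohort(anchored_params, policy, "screening")
        space = trace.space
        treated0 = sum(
            trace.occupancy[0, i] for i in range(len(space)) if space.is_treated(i)
        )
        assert treated0 == 0.0

    def test_trace_dataframe_shape(self, anchored_params, once_policy):
        trace = run_cohort(anchored_params, once_policy, "no_screening")
        df = trace.to_dataframe()
        assert set(df.columns) == {"cycle", "age", "state", "count"}
        assert len(df) == (trace.n_cycles + 1) * len(trace.space)
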