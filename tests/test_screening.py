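"""Screening cascade probabilities, policy schedules and redistribution."""

import itertools

import numpy as np
import pytest

from adscreen.markov import initial_distribution, run_cohort
from adscreen.parameters import DISEASE_CONDITIONS
from adscreen.screening import (
    ScreeningPolicy,
    apply_screening,
    cascade_probabilities,
    screening_cycles,
)
from adscreen.states import enumerate_states


def _enumerate_cascade(participation, sens1, sens2):
    """Brute-force enumeration of the participate -> scale -> diagnose tree
    for a person the tests mark as 'positive-prone' with the given stagewise
    positive probabilities."""
    p = 0.0
    for take, scale, dx in itertools.product([0, 1], repeat=3):
        prob = (
            (participation if take else 1 - participation)
            * (sens1 if scale else 1 - sens1)
            * (sens2 if dx else 1 - sens2)
        )
        if take and scale and dx:
            p += prob
    return p


class TestCascade:
    def test_detection_probability_matches_branch_enumeration(self, default_params):
        c = cascade_probabilities(default_params)
        expected = _enumerate_cascade(0.80, 0.81, 0.90)
        assert c.p_detect_true == pytest.approx(expected, abs=1e-12)
        assert c.p_detect_true == pytest.approx(0.5832, abs=1e-12)

    def test_false_positive_probability_matches_branch_enumeration(self, default_params):
        c = cascade_probabilities(default_params)
        expected = _enumerate_cascade(0.80, 1 - 0.805, 1 - 0.90)
        assert c.p_false_positive == pytest.approx(expected, abs=1e-12)
        assert c.p_false_positive == pytest.approx(0.0156, abs=1e-12)

    def test_zero_participation_kills_both_branches(self, params):
        params.participation = 0.0
        c = cascade_probabilities(params)
        assert c.p_detect_true == 0.0 and c.p_false_positive == 0.0

    def test_detection_bounded_by_participation(self, anchored_params):
        c = cascade_probabilities(anchored_params)
        assert c.p_detect_true <= anchored_params.participation


class TestApplyScreening:
    def test_full_detection_moves_all_mild_mass(self, params):
        params.participation = 1.0
        params.mmse_sens = 1.0
        params.dx_sens = 1.0
        params.treat_rate_after_screening = 1.0
        space = enumerate_states(params)
        x = np.zeros(len(space))
        x[space.untreated("MILD")] = 1000.0
        y = apply_screening(x, params, space)
        assert y[space.untreated("MILD")] == 0.0
        assert y[space.treated_idx("MILD", 1)] == pytest.approx(1000.0)

    def test_perfect_specificity_leaves_normal_untouched(self, params):
        params.mmse_spec = 1.0
        space = enumerate_states(params)
        x = initial_distribution(params, space)
        y = apply_screening(x, params, space)
        assert y[space.normal] == x[space.normal]
        assert y[space.normal_fp] == 0.0

    def test_fractional_detection_arithmetic(self, params):
        # 1,000 untreated MCI at detection 0.5832 and full uptake -> 583.2 move
        params.treat_rate_after_screening = 1.0
        space = enumerate_states(params)
        x = np.zeros(len(space))
        x[space.untreated("MCI")] = 1000.0
        y = apply_screening(x, params, space)
        assert y[space.treated_idx("MCI", 1)] == pytest.approx(583.2)
        assert y[space.untreated("MCI")] == pytest.approx(416.8)

    def test_mass_conservation_exact(self, anchored_params):
        space = enumerate_states(anchored_params)
        x = initial_distribution(anchored_params, space)
        y = apply_screening(x, anchored_params, space)
        assert y.sum() == pytest.approx(x.sum(), abs=1e-9)
        assert np.all(y >= 0)

    def test_shape_mismatch_raises(self, anchored_params):
        space = enumerate_states(anchored_params)
        with pytest.raises(ValueError, match="state space"):
            apply_screening(np.zeros(len(space) + 1), anchored_params, space)

    def test_higher_scale_sensitivity_never_reduces_treated_fraction(self, anchored_params):
        space = enumerate_states(anchored_params)
        x = initial_distribution(anchored_params, space)
        treated = lambda y: sum(y[i] for i in range(len(space)) if space.is_treated(i))
        last = -1.0
        for sens in (0.2, 0.5, 0.81, 0.95):
            ps = anchored_params.with_value("mmse_sens", sens)
            frac = treated(apply_screening(x, ps, space))
            assert frac >= last
            last = frac


class TestSchedule:
    @pytest.mark.parametrize(
        "start,interval,expected",
        [
            (60, "once", [0]),
            (60, "every_5_years", [0, 5, 10, 15]),
            (60, "every_10_years", [0, 10]),
            (65, "every_10_years", [5, 15]),
        ],
    )
    def test_cycle_schedules(self, default_params, start, interval, expected):
        policy = ScreeningPolicy(start_age=start, interval=interval)
        assert screening_cycles(policy, default_params) == expected

    def test_shifted_start_model(self, params):
        # a cohort entering at 65 screened every 10 years: cycles 0 and 10
        params.start_age = 65
        policy = ScreeningPolicy(start_age=65, interval="every_10_years")
        assert screening_cycles(policy, params) == [0, 10]

    def test_disabled_policy_is_empty(self, default_params):
        assert screening_cycles(ScreeningPolicy.none(), default_params) == []

    def test_invalid_start_age_rejected(self):
        with pytest.raises(ValueError):
            ScreeningPolicy(start_age=85, interval="once")


def test_zero_participation_makes_arms_identical(anchored_params, once_policy):
    """With nobody screened the two arms produce cell-for-cell equal traces."""
    ps = anchored_params.with_value("participation", 0.0)
    a = run_cohort(ps, once_policy, "screening")
    b = run_cohort(ps, once_policy, "no_screening")
    assert np.array_equal(a.occupancy, b.occupancy)
    assert np.array_equal(a.incident_deaths, b.incident_deaths)
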