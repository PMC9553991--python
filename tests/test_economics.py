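"""Cost/QALY accumulation, ICER, NMB and averted-event accounting."""

import numpy as np
import pytest

from adscreen.economics import (
    accumulate_costs,
    accumulate_qalys,
    averted_events,
    evaluate,
    icer,
    nmb,
)
from adscreen.markov import CohortTrace, run_cohort
from adscreen.screening import ScreeningPolicy
from adscreen.states import enumerate_states


def _single_state_trace(params, label_idx, n_cycles=1, persons=1.0):
    space = enumerate_states(params)
    occ = np.zeros((n_cycles + 1, len(space)))
    occ[:, label_idx] = persons
    return CohortTrace(
        occupancy=occ,
        incident_deaths=np.zeros(n_cycles),
        incident_untreated_severe=np.zeros(n_cycles),
        space=space,
        arm="no_screening",
        start_age=params.start_age,
        cohort_size=persons,
    )


class TestCosts:
    def test_empty_horizon_costs_nothing(self, params):
        trace = _single_state_trace(params, 0, n_cycles=0)
        trace.occupancy = trace.occupancy[:1]
        assert accumulate_costs(trace, params) == 0.0

    def test_one_treated_mild_person_year(self, params):
        space = enumerate_states(params)
        trace = _single_state_trace(params, space.treated_idx("MILD", 1))
        assert accumulate_costs(trace, params) == pytest.approx(12137.4)

    def test_one_untreated_mci_person_year(self, params):
        space = enumerate_states(params)
        trace = _single_state_trace(params, space.untreated("MCI"))
        assert accumulate_costs(trace, params) == pytest.approx(8.5)

    def test_untreated_ad_cost_is_uniform_across_stages(self, params):
        space = enumerate_states(params)
        costs = [
            accumulate_costs(_single_state_trace(params, space.untreated(c)), params)
            for c in ("MILD", "MODERATE", "SEVERE")
        ]
        assert costs == [pytest.approx(13375.6)] * 3

    def test_false_positive_tunnel_charges_its_single_year(self, params):
        space = enumerate_states(params)
        trace = _single_state_trace(params, space.normal_fp)
        assert accumulate_costs(trace, params) == pytest.approx(155.5)

    def test_cohort_doubling_leaves_per_capita_cost_unchanged(self, anchored_params, once_policy):
        # state-cost accumulation is linear in occupancy; the only nonlinear
        # term is the fixed per-round programme cost, so the comparison uses
        # the no-screening arm (the screening arm's programme overhead per
        # capita halves when the cohort doubles, by design)
        a = run_cohort(anchored_params, once_policy, "no_screening")
        ps2 = anchored_params.copy()
        ps2.cohort_size = 2 * anchored_params.cohort_size
        b = run_cohort(ps2, once_policy, "no_screening")
        assert accumulate_costs(b, ps2, once_policy) == pytest.approx(
            accumulate_costs(a, anchored_params, once_policy), rel=1e-9
        )
        q_a = accumulate_qalys(a, anchored_params)
        q_b = accumulate_qalys(b, ps2)
        assert q_b == pytest.approx(q_a, rel=1e-9)

    def test_discounting_never_raises_totals(self, anchored_params, once_policy):
        trace = run_cohort(anchored_params, once_policy, "screening")
        undisc = accumulate_costs(trace, anchored_params, once_policy)
        ps = anchored_params.with_value("discount_rate", 0.05)
        disc = accumulate_costs(trace, ps, once_policy)
        assert disc < undisc
        q_undisc = accumulate_qalys(trace, anchored_params)
        q_disc = accumulate_qalys(trace, ps)
        assert q_disc < q_undisc


class TestQalys:
    def test_normal_cohort_accrues_one_qaly_per_year(self, params):
        trace = _single_state_trace(params, 0, n_cycles=20)
        assert accumulate_qalys(trace, params) == pytest.approx(20.0)

    def test_dead_cohort_accrues_nothing(self, params):
        space = enumerate_states(params)
        trace = _single_state_trace(params, space.dead, n_cycles=20)
        assert accumulate_qalys(trace, params) == 0.0

    def test_mixed_trace_matches_direct_summation(self, anchored_params, once_policy):
        trace = run_cohort(anchored_params, once_policy, "screening")
        space = trace.space
        expected = 0.0
        for t in range(trace.n_cycles):
            for i in range(len(space)):
                expected += trace.occupancy[t, i] * anchored_params.state_utility(
                    space.condition_of(i)
                )
        expected /= anchored_params.cohort_size
        assert accumulate_qalys(trace, anchored_params) == pytest.approx(expected, abs=1e-9)


class TestIcerNmb:
    def test_rounded_base_increments_ratio(self):
        # direct division of two-decimal increments
        r = icer(289.44, 0.011)
        assert r.flag == "ratio"
        assert r.value == pytest.approx(26312.73, abs=0.01)

    def test_free_health_gain(self):
        assert icer(0.0, 0.5).value == 0.0

    def test_dominance_flags(self):
        assert icer(-100.0, 0.01).flag == "dominant"
        assert icer(100.0, -0.01).flag == "dominated"
        assert icer(5.0, 0.0).flag == "undefined"

    def test_nmb_on_rounded_increments(self):
        assert nmb(289.44, 0.011, 34_106.08) == pytest.approx(85.73, abs=0.01)

    def test_nmb_zero_increments(self):
        assert nmb(0.0, 0.0, 34_106.08) == 0.0

    def test_threshold_is_three_gdp(self, default_params):
        assert default_params.wtp_threshold == pytest.approx(34_106.07, abs=0.005)

    def test_nmb_icer_consistency(self, anchored_params, once_policy):
        res = evaluate(
            run_cohort(anchored_params, once_policy, "screening"),
            run_cohort(anchored_params, once_policy, "no_screening"),
            anchored_params,
            once_policy,
        )
        if res.inc_qaly > 0:
            assert (res.nmb_pp > 0) == (res.icer.value < anchored_params.wtp_threshold)


class TestAvertedEvents:
    def test_identical_traces_avert_nothing(self, anchored_params, once_policy):
        t = run_cohort(anchored_params, once_policy, "no_screening")
        a = averted_events(t, t)
        assert a.deaths == 0.0 and a.untreated_severe == 0.0

    def test_count_and_percent_arithmetic(self, params, once_policy):
        t1 = run_cohort(params, once_policy, "screening")
        t2 = run_cohort(params, once_policy, "no_screening")
        a = averted_events(t1, t2)
        assert a.deaths_pct == pytest.approx(100.0 * a.deaths / params.cohort_size)
        assert a.untreated_severe_pct == pytest.approx(
            100.0 * a.untreated_severe / params.cohort_size
        )

    def test_mismatched_horizons_raise(self, params, anchored_params, once_policy):
        short = params.copy()
        short.start_age = 70
        policy70 = ScreeningPolicy(70, "once")
        t_short = run_cohort(short, policy70, "no_screening")
        t_full = run_cohort(anchored_params, once_policy, "no_screening")
        with pytest.raises(ValueError, match="horizon"):
            averted_events(t_full, t_short)
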