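"""Costs, QALYs, ICER, net monetary benefit and averted events.

Accounting conventions: full-cycle (start-of-cycle) occupancy accrues that
year's state cost and utility; discounting (default rate 0) applies factor
``(1 + r)^-t`` to cycle ``t``.  At each screening round the programme pays a
fixed per-round project cost, the scale test for every participant, and the
diagnostic work-up for the mass referred to step 2.  Already-diagnosed
(treated) patients are not re-screened: the eligible population is normal
plus untreated diseased occupancy.  One treated year of a false positive is
priced through the false-positive tunnel state's annual cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace
from .parameters import DISEASE_CONDITIONS, ParameterSet
from .screening import ScreeningPolicy

__all__ = [
    "EconResult",
    "ICERValue",
    "accumulate_costs",
    "accumulate_qalys",
    "icer",
    "nmb",
    "averted_events",
    "evaluate",
]


@dataclass(frozen=True)
class ICERValue:
    """An incremental cost-effectiveness ratio with its dominance class.

    ``flag`` is ``ratio`` for an interpretable ratio, ``dominant`` when the
    comparator strategy costs less and gains QALYs (negative ratio kept for
    reference), ``dominated`` for the reverse, and ``undefined`` when the
    QALY increment is zero.
    """

    value: float | None
    flag: str  # ratio | dominant | dominated | undefined

    def __float__(self) -> float:
        return float("nan") if self.value is None else self.value

    def __repr__(self) -> str:
        if self.flag == "ratio":
            return f"ICER({self.value:.2f})"
        return f"ICER({self.flag}{'' if self.value is None else f', {self.value:.2f}'})"


def icer(inc_cost: float, inc_qaly: float) -> ICERValue:
    if inc_qaly == 0.0:
        return ICERValue(None, "undefined")
    ratio = inc_cost / inc_qaly
    if inc_cost < 0.0 and inc_qaly > 0.0:
        return ICERValue(ratio, "dominant")
    if inc_cost > 0.0 and inc_qaly < 0.0:
        return ICERValue(ratio, "dominated")
    return ICERValue(ratio, "ratio")


def nmb(inc_cost: float, inc_qaly: float, threshold: float) -> float:
    """Net monetary benefit at willingness-to-pay ``threshold`` per QALY."""
    if threshold < 0.0:
        raise ValueError("willingness-to-pay threshold must be nonnegative")
    return threshold * inc_qaly - inc_cost


def _state_cost_vector(params: ParameterSet, space) -> np.ndarray:
    costs = np.zeros(len(space))
    for i, s in enumerate(space):
        if s.condition in ("NORMAL", "DEAD"):
            costs[i] = params.cost_false_positive if s.fp_tunnel else 0.0
        else:
            treated = s.treated and not (
                params.discontinue_at_severe and s.condition == "SEVERE"
            )
            costs[i] = params.annual_cost(s.condition, treated)
    return costs


def _state_utility_vector(params: ParameterSet, space) -> np.ndarray:
    return np.array([params.state_utility(s.condition) for s in space])


def screening_round_cost(params: ParameterSet, pre_screen: np.ndarray, space) -> float:
    """Programme + scale + diagnostic cost of one screening round."""
    normals = pre_screen[space.normal] + pre_screen[space.normal_fp]
    untreated_diseased = sum(pre_screen[space.untreated(c)] for c in DISEASE_CONDITIONS)
    eligible = normals + untreated_diseased
    referred = params.participation * (
        untreated_diseased * params.mmse_sens + normals * (1.0 - params.mmse_spec)
    )
    return (
        params.cost_program
        + params.participation * params.cost_scale_pp * eligible
        + params.cost_dx_pp * referred
    )


def accumulate_costs(
    trace: CohortTrace, params: ParameterSet, policy: ScreeningPolicy | None = None
) -> float:
    """Discounted total cost per cohort member, USD."""
    costs = _state_cost_vector(params, trace.space)
    r = params.discount_rate
    total = 0.0
    for t in range(trace.n_cycles):
        disc = (1.0 + r) ** -t
        total += disc * float(trace.occupancy[t] @ costs)
        if t in trace.pre_screen:
            total += disc * screening_round_cost(params, trace.pre_screen[t], trace.space)
    return total / trace.cohort_size


def accumulate_qalys(trace: CohortTrace, params: ParameterSet) -> float:
    """Discounted QALYs per cohort member."""
    utils = _state_utility_vector(params, trace.space)
    r = params.discount_rate
    total = sum(
        (1.0 + r) ** -t * float(trace.occupancy[t] @ utils)
        for t in range(trace.n_cycles)
    )
    return total / trace.cohort_size


@dataclass(frozen=True)
class AvertedEvents:
    deaths: float
    deaths_pct: float  # percent of cohort
    untreated_severe: float
    untreated_severe_pct: float


def averted_events(trace_screen: CohortTrace, trace_none: CohortTrace) -> AvertedEvents:
    """Cumulative event differences, no-screening minus screening."""
    if trace_screen.n_cycles != trace_none.n_cycles:
        raise ValueError("traces span different horizons")
    n = trace_screen.cohort_size
    d = float(trace_none.incident_deaths.sum() - trace_screen.incident_deaths.sum())
    s = float(
        trace_none.incident_untreated_severe.sum()
        - trace_screen.incident_untreated_severe.sum()
    )
    return AvertedEvents(d, 100.0 * d / n, s, 100.0 * s / n)


@dataclass(frozen=True)
class EconResult:
    """Per-arm and incremental economics of one two-arm comparison."""

    cost_screen: float
    qaly_screen: float
    cost_none: float
    qaly_none: float
    inc_cost: float
    inc_qaly: float
    icer: ICERValue
    nmb_pp: float  # over the full horizon, per cohort member
    nmb_pp_per_year: float  # same quantity averaged over horizon years
    wtp_threshold: float
    averted: AvertedEvents
    horizon_years: int

    def as_dict(self) -> dict:
        return {
            "cost_screen": self.cost_screen,
            "qaly_screen": self.qaly_screen,
            "cost_none": self.cost_none,
            "qaly_none": self.qaly_none,
            "inc_cost": self.inc_cost,
            "inc_qaly": self.inc_qaly,
            "icer": None if self.icer.value is None else self.icer.value,
            "icer_flag": self.icer.flag,
            "nmb_pp": self.nmb_pp,
            "nmb_pp_per_year": self.nmb_pp_per_year,
            "wtp_threshold": self.wtp_threshold,
            "deaths_averted": self.averted.deaths,
            "deaths_averted_pct": self.averted.deaths_pct,
            "untreated_severe_averted": self.averted.untreated_severe,
            "untreated_severe_averted_pct": self.averted.untreated_severe_pct,
        }


def evaluate(
    trace_screen: CohortTrace,
    trace_none: CohortTrace,
    params: ParameterSet,
    policy: ScreeningPolicy | None = None,
) -> EconResult:
    """Full economic comparison of a screening arm against its comparator."""
    cost_s = accumulate_costs(trace_screen, params, policy)
    cost_n = accumulate_costs(trace_none, params, None)
    qaly_s = accumulate_qalys(trace_screen, params)
    qaly_n = accumulate_qalys(trace_none, params)
    inc_cost, inc_qaly = cost_s - cost_n, qaly_s - qaly_n
    horizon = trace_screen.n_cycles
    benefit = nmb(inc_cost, inc_qaly, params.wtp_threshold)
    return EconResult(
        cost_screen=cost_s,
        qaly_screen=qaly_s,
        cost_none=cost_n,
        qaly_none=qaly_n,
        inc_cost=inc_cost,
        inc_qaly=inc_qaly,
        icer=icer(inc_cost, inc_qaly),
        nmb_pp=benefit,
        nmb_pp_per_year=benefit / horizon,
        wtp_threshold=params.wtp_threshold,
        averted=averted_events(trace_screen, trace_none),
        horizon_years=horizon,
    )
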