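"""Cohort transition engine.

Builds per-cycle row-stochastic transition matrices over the enumerated
state space and propagates a closed cohort through them, recording state
occupancy and incident events (deaths, new entries into untreated severe
AD).

Row construction
----------------
For each origin condition the specified exits are the stage-transition
probabilities (treated or untreated table), death is the multiplicative
combination of age-band natural mortality and disease excess mortality,
``1 - (1 - p_nat) * (1 - p_excess)``, and the residual "stay" probability
closes the row to 1.  A negative residual is rejected at parameter
validation.  Treated tunnel years below the drug-effect cap use the treated
table and advance the counter; the cap year uses the untreated table (the
drug effect has lapsed) while the person remains flagged treated for cost
purposes.  The moderate-to-mild regression probability is never drug
modified.  Untreated diseased states mix in care-seeking uptake: with the
state's annual visit rate the person starts treatment this cycle and
follows the treated entry row instead.  Uptake applies in both arms;
screening acts separately as a start-of-cycle redistribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .parameters import ALLOWED_TRANSITIONS, DISEASE_CONDITIONS, ParameterSet
from .states import HealthState, StateSpace, enumerate_states

__all__ = ["TransitionMatrix", "CohortTrace", "build_matrix", "run_cohort"]

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    matrix: np.ndarray  # (n_states, n_states), row-stochastic
    age: int
    arm: str  # metadata tag; both arms share the same matrix
    space: StateSpace


@dataclass
class CohortTrace:
    """Per-cycle occupancy and incident-event counters for one arm.

    ``occupancy[t]`` is the start-of-cycle-``t`` distribution *after* any
    screening redistribution for that cycle (the distribution that accrues
    that year's costs and utilities); the final row is the end-of-horizon
    distribution.  ``pre_screen`` keeps the distribution immediately before
    each applied screening round, which the cost model needs to price the
    round itself.
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states) person counts
    incident_deaths: np.ndarray  # (n_cycles,)
    incident_untreated_severe: np.ndarray  # (n_cycles,)
    space: StateSpace
    arm: str
    start_age: int
    cohort_size: float
    screening_cycles: list = field(default_factory=list)
    pre_screen: dict = field(default_factory=dict)  # cycle -> occupancy vector

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cumulative_deaths(self) -> np.ndarray:
        return np.cumsum(self.incident_deaths)

    @property
    def cumulative_untreated_severe(self) -> np.ndarray:
        return np.cumsum(self.incident_untreated_severe)

    def alive(self, cycle: int) -> float:
        row = self.occupancy[cycle]
        return float(row.sum() - row[self.space.dead])

    def to_dataframe(self):
        """Tidy (cycle, age, state, count) export."""
        import pandas as pd

        rows = []
        labels = self.space.labels
        for t in range(self.occupancy.shape[0]):
            for j, lab in enumerate(labels):
                rows.append((t, self.start_age + t, lab, self.occupancy[t, j]))
        return pd.DataFrame(rows, columns=["cycle", "age", "state", "count"])


def _exit_probs(params: ParameterSet, cond: str, treated_rows: bool) -> dict:
    """Specified stage exits for an origin condition under one transition table."""
    table = params.tp_treated if treated_rows else params.tp_untreated
    exits = {}
    for dst in ALLOWED_TRANSITIONS[cond]:
        key = f"{cond}->{dst}"
        p = table.get(key, 0.0)
        if treated_rows and cond == "MODERATE" and dst == "MILD":
            untreated = params.tp_untreated.get(key, 0.0)
            if p != untreated:
                logger.warning(
                    "tp_treated.MODERATE->MILD (%g) overridden with the untreated "
                    "value (%g): this regression is not drug-modified", p, untreated,
                )
            p = untreated
        exits[dst] = p
    return exits


def _death_prob(params: ParameterSet, cond: str, age: int) -> float:
    nat = params.natural_mortality_at(age)
    excess = 0.0 if cond == "NORMAL" else params.excess_mortality.get(cond, 0.0)
    return 1.0 - (1.0 - nat) * (1.0 - excess)


def build_matrix(
    params: ParameterSet,
    age: int,
    arm: str = "screening",
    space: StateSpace | None = None,
) -> TransitionMatrix:
    """Assemble the one-cycle transition matrix in effect at ``age``."""
    if not (params.start_age <= age < params.end_age):
        raise ValueError(
            f"age {age} outside model horizon [{params.start_age}, {params.end_age})"
        )
    if space is None:
        space = enumerate_states(params)
    n = len(space)
    M = np.zeros((n, n))

    def fill_row(i: int, cond: str, treated_rows: bool, dest_idx) -> None:
        """dest_idx maps a destination condition (or 'STAY') to a state index."""
        death = _death_prob(params, cond, age)
        exits = _exit_probs(params, cond, treated_rows) if cond != "DEAD" else {}
        stay = 1.0 - death - sum(exits.values())
        if stay < -_ROW_TOL:
            raise ValueError(f"negative stay residual for {cond} at age {age}")
        M[i, space.dead] += death
        for dst, p in exits.items():
            M[i, dest_idx(dst)] += p
        M[i, dest_idx("STAY")] += max(stay, 0.0)

    # NORMAL: progression lands in untreated MCI
    fill_row(
        space.normal, "NORMAL", False,
        lambda d: space.normal if d == "STAY" else space.untreated("MCI"),
    )
    # false-positive tunnel: NORMAL transition behaviour, but the tunnel
    # expires after its single year — staying normal returns to plain NORMAL
    fill_row(
        space.normal_fp, "NORMAL", False,
        lambda d: space.normal if d == "STAY" else space.untreated("MCI"),
    )

    for cond in DISEASE_CONDITIONS:
        # treated tunnel rows
        for year in range(1, space.n_tunnel + 1):
            i = space.treated_idx(cond, year)
            if space.lifetime:
                on_drug, next_year = True, 1
            else:
                on_drug = year < space.n_tunnel
                next_year = min(year + 1, space.n_tunnel)

            def dest(d, cond=cond, next_year=next_year):
                if d == "STAY":
                    return space.treated_idx(cond, next_year)
                if d == "NORMAL":
                    return space.normal
                return space.treated_idx(d, next_year)

            fill_row(i, cond, on_drug, dest)

        # untreated row: mix of staying untreated and care-seeking uptake
        i = space.untreated(cond)

        def dest_untreated(d, cond=cond):
            if d == "STAY":
                return space.untreated(cond)
            if d == "NORMAL":
                return space.normal
            return space.untreated(d)

        fill_row(i, cond, False, dest_untreated)
        v = params.visit_rate(cond)
        if v > 0.0:
            entry_row = M[space.treated_idx(cond, 1)]
            M[i] = (1.0 - v) * M[i] + v * entry_row

    M[space.dead, space.dead] = 1.0

    if params.discontinue_at_severe:
        # treatment stops on progression to severe AD: redirect every flow
        # into treated-severe states onto untreated SEVERE
        sev_cols = [space.treated_idx("SEVERE", y) for y in range(1, space.n_tunnel + 1)]
        for col in sev_cols:
            M[:, space.untreated("SEVERE")] += M[:, col]
            M[:, col] = 0.0

    rowsums = M.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
        bad = int(np.argmax(np.abs(rowsums - 1.0)))
        raise ValueError(
            f"row {space.labels[bad]} sums to {rowsums[bad]:.12f} at age {age}"
        )
    return TransitionMatrix(M, age, arm, space)


def initial_distribution(params: ParameterSet, space: StateSpace) -> np.ndarray:
    """Age-``start_age`` prevalence split over untreated states; no one treated."""
    x = np.zeros(len(space))
    p_mci = params.prevalence_mci_at(params.start_age)
    p_ad = params.prevalence_ad_at(params.start_age)
    mild, moderate, severe = params.severity_split
    x[space.untreated("MCI")] = p_mci
    x[space.untreated("MILD")] = p_ad * mild
    x[space.untreated("MODERATE")] = p_ad * moderate
    x[space.untreated("SEVERE")] = p_ad * severe
    x[space.normal] = 1.0 - p_mci - p_ad
    return x * params.cohort_size


def run_cohort(params: ParameterSet, policy, arm: str) -> CohortTrace:
    """Propagate the cohort over the full horizon for one arm.

    ``arm`` is ``"screening"`` or ``"no_screening"``; only the screening arm
    applies the start-of-cycle cascade redistribution at the policy's cycles.
    """
    from .screening import apply_screening, screening_cycles

    if arm not in ("screening", "no_screening"):
        raise ValueError(f"unknown arm {arm!r}")
    space = enumerate_states(params)
    n_cycles = params.n_cycles
    cycles = screening_cycles(policy, params) if arm == "screening" else []

    occupancy = np.zeros((n_cycles + 1, len(space)))
    deaths = np.zeros(n_cycles)
    new_untreated_severe = np.zeros(n_cycles)
    pre_screen: dict = {}

    x = initial_distribution(params, space)
    matrices: dict = {}
    j_sev = space.untreated("SEVERE")
    for t in range(n_cycles):
        age = params.start_age + t
        if t in cycles:
            pre_screen[t] = x.copy()
            x = apply_screening(x, params, space)
        occupancy[t] = x
        key = params.natural_mortality_at(age)  # matrices differ only by mortality band
        if key not in matrices:
            matrices[key] = build_matrix(params, age, arm, space).matrix
        M = matrices[key]
        deaths[t] = x @ M[:, space.dead] - x[space.dead]
        new_untreated_severe[t] = x @ M[:, j_sev] - x[j_sev] * M[j_sev, j_sev]
        x = x @ M
    occupancy[n_cycles] = x

    trace = CohortTrace(
        occupancy=occupancy,
        incident_deaths=deaths,
        incident_untreated_severe=new_untreated_severe,
        space=space,
        arm=arm,
        start_age=params.start_age,
        cohort_size=float(params.cohort_size),
        screening_cycles=sorted(cycles),
        pre_screen=pre_screen,
    )
    _check_trace(trace)
    return trace


def _check_trace(trace: CohortTrace) -> None:
    totals = trace.occupancy.sum(axis=1)
    if np.any(np.abs(totals - trace.cohort_size) > 1e-6):
        raise AssertionError("cohort mass not conserved across cycles")
    if np.any(trace.occupancy < -1e-9):
        raise AssertionError("negative occupancy")
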