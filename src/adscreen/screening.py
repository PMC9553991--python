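"""Two-step screening cascade and screening policy.

The programme screens the eligible population with a short cognitive scale
(MMSE) and refers scale-positives to a full diagnostic work-up.  A diseased
participant is detected and started on treatment with probability
``participation x scale sensitivity x diagnostic sensitivity x treatment
uptake``; a cognitively normal participant is falsely labelled positive —
and treated for one year — with probability ``participation x (1 - scale
specificity) x (1 - diagnostic specificity)``.  Screening is applied at the
start of a cycle, before that cycle's transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DISEASE_CONDITIONS, ParameterSet
from .states import StateSpace

__all__ = [
    "ScreeningPolicy",
    "CascadeResult",
    "cascade_probabilities",
    "apply_screening",
    "screening_cycles",
]

INTERVALS = {"once": None, "every_5_years": 5, "every_10_years": 10}


@dataclass(frozen=True)
class ScreeningPolicy:
    """When the cascade runs: a start age and an optional repeat interval."""

    start_age: int = 60
    interval: str = "once"
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled:
            if not (60 <= self.start_age < 80):
                raise ValueError(f"screening start_age {self.start_age} outside [60, 80)")
            if self.interval not in INTERVALS:
                raise ValueError(f"unknown screening interval {self.interval!r}")

    @staticmethod
    def none() -> "ScreeningPolicy":
        return ScreeningPolicy(enabled=False)


@dataclass(frozen=True)
class CascadeResult:
    p_detect_true: float  # diseased person screened, scale+, diagnosis+
    p_false_positive: float  # healthy person wrongly positive through both steps

    def __post_init__(self) -> None:
        for v in (self.p_detect_true, self.p_false_positive):
            if not (0.0 <= v <= 1.0):
                raise ValueError("cascade probabilities must lie in [0, 1]")


def cascade_probabilities(params: ParameterSet) -> CascadeResult:
    """Branch probabilities of the participation -> scale -> diagnosis cascade."""
    return CascadeResult(
        p_detect_true=params.participation * params.mmse_sens * params.dx_sens,
        p_false_positive=params.participation
        * (1.0 - params.mmse_spec)
        * (1.0 - params.dx_spec),
    )


def apply_screening(
    dist: np.ndarray, params: ParameterSet, space: StateSpace
) -> np.ndarray:
    """Redistribute occupancy for one screening round (mass conserving).

    Untreated diseased mass moves into the first treated tunnel year with
    probability ``p_detect_true x treat_rate_after_screening``; NORMAL mass
    moves into the one-year false-positive tunnel with probability
    ``p_false_positive``.  Already-treated, tunnel and dead states are left
    untouched.
    """
    if dist.shape != (len(space),):
        raise ValueError(f"occupancy length {dist.shape} does not match state space {len(space)}")
    cascade = cascade_probabilities(params)
    x = dist.astype(float).copy()
    p_treat = cascade.p_detect_true * params.treat_rate_after_screening
    for cond in DISEASE_CONDITIONS:
        i, j = space.untreated(cond), space.treated_idx(cond, 1)
        moved = x[i] * p_treat
        x[i] -= moved
        x[j] += moved
    fp = x[space.normal] * cascade.p_false_positive
    x[space.normal] -= fp
    x[space.normal_fp] += fp
    return x


def screening_cycles(policy: ScreeningPolicy, params: ParameterSet) -> list:
    """Model-cycle indices at which the policy screens (empty when disabled)."""
    if policy is None or not policy.enabled:
        return []
    first = policy.start_age - params.start_age
    if first < 0:
        raise ValueError(
            f"screening start age {policy.start_age} precedes model start {params.start_age}"
        )
    step = INTERVALS[policy.interval]
    if step is None:
        return [first] if first < params.n_cycles else []
    return list(range(first, params.n_cycles, step))
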