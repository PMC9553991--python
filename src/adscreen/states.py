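"""Enumerated Markov state space with treatment-duration and false-positive tunnels.

The chain tracks cognitive condition (normal, MCI, mild/moderate/severe AD,
dead), whether a person is on drug treatment, and — because the drug effect
is time-limited — how many treated years they have accrued.  Tunnel states
make the time-limited effect expressible in a memoryless chain: a treated
person advances through tunnel years 1..N and is then held at the cap, where
the drug no longer modifies transitions.  A separate one-cycle tunnel holds
cognitively normal people falsely labelled positive by the screening cascade
(they incur one treated year's false-positive cost, then return to plain
NORMAL).

Ordering is deterministic: NORMAL, NORMAL-FP, then for each disease
condition in severity order its untreated state followed by treated tunnel
years 1..N, and DEAD last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .parameters import DISEASE_CONDITIONS, ParameterSet

__all__ = ["HealthState", "StateSpace", "enumerate_states"]


@dataclass(frozen=True)
class HealthState:
    condition: str  # NORMAL | MCI | MILD | MODERATE | SEVERE | DEAD
    treated: bool = False
    tunnel_year: int = 0  # years on treatment, 0 for untreated states
    fp_tunnel: bool = False  # NORMAL-only false-positive tunnel

    def __post_init__(self) -> None:
        if self.condition == "DEAD" and (self.treated or self.tunnel_year or self.fp_tunnel):
            raise ValueError("DEAD carries no treatment or tunnel flags")
        if self.fp_tunnel and self.condition != "NORMAL":
            raise ValueError("false-positive tunnel exists only for NORMAL")
        if self.tunnel_year > 0 and not self.treated:
            raise ValueError("tunnel_year > 0 requires treated")

    @property
    def label(self) -> str:
        if self.fp_tunnel:
            return "NORMAL_FP"
        if not self.treated:
            return self.condition
        if self.tunnel_year:
            return f"{self.condition}_TX{self.tunnel_year}"
        return f"{self.condition}_TX"


class StateSpace:
    """Deterministically ordered list of :class:`HealthState` with index maps."""

    def __init__(self, params: ParameterSet):
        self.lifetime = params.lifetime_effect
        self.n_tunnel = 1 if self.lifetime else int(params.drug_effect_years)
        states = [HealthState("NORMAL"), HealthState("NORMAL", fp_tunnel=True)]
        for cond in DISEASE_CONDITIONS:
            states.append(HealthState(cond))
            for year in range(1, self.n_tunnel + 1):
                states.append(
                    HealthState(cond, treated=True, tunnel_year=0 if self.lifetime else year)
                )
        states.append(HealthState("DEAD"))
        self.states: tuple = tuple(states)
        self._index = {s: i for i, s in enumerate(states)}

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[HealthState]:
        return iter(self.states)

    def index(self, state: HealthState) -> int:
        return self._index[state]

    @property
    def normal(self) -> int:
        return 0

    @property
    def normal_fp(self) -> int:
        return 1

    @property
    def dead(self) -> int:
        return len(self.states) - 1

    def untreated(self, condition: str) -> int:
        return self._index[HealthState(condition)]

    def treated_idx(self, condition: str, year: int = 1) -> int:
        """Index of the treated tunnel state for ``year`` (ignored for lifetime effect)."""
        y = 0 if self.lifetime else min(year, self.n_tunnel)
        return self._index[HealthState(condition, treated=True, tunnel_year=y)]

    @property
    def labels(self) -> list:
        return [s.label for s in self.states]

    def condition_of(self, i: int) -> str:
        return self.states[i].condition

    def is_diseased(self, i: int) -> bool:
        return self.states[i].condition in DISEASE_CONDITIONS

    def is_treated(self, i: int) -> bool:
        return self.states[i].treated


def enumerate_states(params: ParameterSet) -> StateSpace:
    """Build the state space implied by ``params.drug_effect_years``."""
    return StateSpace(params)
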