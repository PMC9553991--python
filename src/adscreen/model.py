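"""Model / Results interface for the two-arm screening evaluation.

:class:`ScreeningCEA` holds a validated parameter set and a screening
policy; :meth:`ScreeningCEA.fit` runs both arms of the Markov cohort and
returns :class:`CEAResults`, which carries the traces, the economic
comparison, formatted summary tables, and hooks into the sensitivity and
scenario machinery.

Example
-------
>>> from adscreen import ScreeningCEA
>>> res = ScreeningCEA.from_default().fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import EconResult, evaluate
from .markov import CohortTrace, run_cohort
from .parameters import ParameterSet, load_parameters, paper_default
from .screening import ScreeningPolicy

__all__ = ["ScreeningCEA", "CEAResults"]


class ScreeningCEA:
    """Two-arm (screening vs no screening) cohort cost-effectiveness model.

    Parameters
    ----------
    params : ParameterSet
        Validated model inputs.
    policy : ScreeningPolicy, optional
        Screening schedule for the intervention arm.  Defaults to a single
        round at the cohort's entry age.
    """

    def __init__(self, params: ParameterSet, policy: ScreeningPolicy | None = None):
        self.params = params.validate()
        self.policy = policy if policy is not None else ScreeningPolicy(
            start_age=params.start_age, interval="once"
        )

    @classmethod
    def from_yaml(cls, path, policy: ScreeningPolicy | None = None) -> "ScreeningCEA":
        return cls(load_parameters(path), policy)

    @classmethod
    def from_default(cls, policy: ScreeningPolicy | None = None) -> "ScreeningCEA":
        return cls(paper_default(), policy)

    # ------------------------------------------------------------------ runs
    def fit(self) -> "CEAResults":
        """Run both arms and assemble the economic comparison."""
        trace_s = run_cohort(self.params, self.policy, "screening")
        trace_n = run_cohort(self.params, self.policy, "no_screening")
        econ = evaluate(trace_s, trace_n, self.params, self.policy)
        return CEAResults(self, trace_s, trace_n, econ)

    def run_psa(self, n: int = 10_000, seed: int = 0):
        from .uncertainty import run_psa

        return run_psa(self.params, self.policy, n=n, seed=seed)

    def run_dsa(self):
        from .uncertainty import run_dsa

        return run_dsa(self.params, self.policy)


@dataclass
class CEAResults:
    """Fitted results: traces for both arms plus the economic comparison."""

    model: ScreeningCEA
    trace_screen: CohortTrace
    trace_none: CohortTrace
    econ: EconResult

    # convenience accessors
    @property
    def icer(self):
        return self.econ.icer

    @property
    def nmb_pp(self) -> float:
        return self.econ.nmb_pp

    @property
    def inc_cost(self) -> float:
        return self.econ.inc_cost

    @property
    def inc_qaly(self) -> float:
        return self.econ.inc_qaly

    @property
    def averted(self):
        return self.econ.averted

    # ---------------------------------------------------------------- tables
    def comparison_table(self) -> pd.DataFrame:
        """Arm-by-arm costs/QALYs with incremental columns (base-case layout)."""
        e = self.econ
        return pd.DataFrame(
            {
                "Costs (USD)": [e.cost_screen, e.cost_none],
                "QALYs": [e.qaly_screen, e.qaly_none],
                "Incremental costs (USD)": [e.inc_cost, None],
                "Incremental QALYs": [e.inc_qaly, None],
                "ICER (USD)": [e.icer.value, None],
            },
            index=["Screening", "No screening"],
        )

    def secondary_table(self) -> pd.DataFrame:
        """Averted deaths / untreated severe AD and net monetary benefit."""
        a = self.econ.averted
        return pd.DataFrame(
            {
                "Deaths averted (n)": [a.deaths],
                "Deaths averted (%)": [a.deaths_pct],
                "Untreated severe AD averted (n)": [a.untreated_severe],
                "Untreated severe AD averted (%)": [a.untreated_severe_pct],
                "NMB (USD per capita)": [self.econ.nmb_pp],
                "NMB (USD per capita per year)": [self.econ.nmb_pp_per_year],
            },
            index=["value"],
        )

    def summary(self) -> str:
        """Human-readable report of the two-arm comparison."""
        e = self.econ
        p = self.model.params
        lines = [
            "Two-arm Markov cohort cost-effectiveness analysis",
            "=" * 58,
            f"Cohort: {p.cohort_size:,} persons, ages {p.start_age}-{p.end_age}, "
            f"{e.horizon_years} annual cycles",
            f"Screening: start {self.model.policy.start_age}, "
            f"interval {self.model.policy.interval}",
            f"Drug effect duration: {p.drug_effect_years} | "
            f"discount rate: {p.discount_rate:.1%}",
            "-" * 58,
            f"{'':16s}{'Cost (USD)':>14s}{'QALYs':>10s}",
            f"{'Screening':16s}{e.cost_screen:>14.2f}{e.qaly_screen:>10.3f}",
            f"{'No screening':16s}{e.cost_none:>14.2f}{e.qaly_none:>10.3f}",
            f"{'Incremental':16s}{e.inc_cost:>14.2f}{e.inc_qaly:>10.3f}",
            "-" * 58,
            f"ICER: {e.icer!r}   (WTP threshold {e.wtp_threshold:,.2f} USD/QALY)",
            f"NMB:  {e.nmb_pp:.2f} USD per capita "
            f"({e.nmb_pp_per_year:.2f} per capita-year)",
            f"Averted deaths: {e.averted.deaths:.0f} ({e.averted.deaths_pct:.3f}%)  |  "
            f"averted untreated severe AD: {e.averted.untreated_severe:.0f} "
            f"({e.averted.untreated_severe_pct:.3f}%)",
        ]
        return "\n".join(lines)
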