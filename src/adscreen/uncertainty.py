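"""Deterministic (tornado) and probabilistic sensitivity analysis.

The one-way analysis reruns the full two-arm model with each distributed
parameter pushed to its interval's low and high ends, ranking parameters by
the absolute net-monetary-benefit swing (NMB ranks more robustly than the
ICER, whose sign can flip).  The probabilistic analysis redraws every
distributed parameter jointly and independently per iteration — beta for
probabilities and utilities, gamma for costs — reruns both arms on each
draw, and summarises the incremental (cost, QALY) cloud as a
cost-effectiveness acceptability curve.

Reproducibility: one master seed spawns an independent child RNG stream per
iteration (``numpy.random.SeedSequence(seed).spawn(n)``), so iteration ``k``
can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .economics import EconResult, evaluate, nmb
from .markov import run_cohort
from .parameters import ParameterSet
from .screening import ScreeningPolicy

__all__ = ["TornadoEntry", "PSAOutput", "run_dsa", "run_psa", "ceac"]

logger = logging.getLogger(__name__)


def _evaluate(params: ParameterSet, policy: ScreeningPolicy) -> EconResult:
    trace_s = run_cohort(params, policy, "screening")
    trace_n = run_cohort(params, policy, "no_screening")
    return evaluate(trace_s, trace_n, params, policy)


def varied_parameters(params: ParameterSet) -> list:
    """Names of parameters carrying a non-degenerate distribution."""
    return sorted(n for n, d in params.distributions.items() if d.kind != "fixed")


# ---------------------------------------------------------------------- DSA

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    value_low: float
    value_high: float
    nmb_low: float
    nmb_high: float
    icer_low: float | None
    icer_high: float | None
    swing: float  # |nmb_high - nmb_low|
    non_monotone: bool  # base-case NMB outside [min, max] of the two ends


def run_dsa(params: ParameterSet, policy: ScreeningPolicy) -> list:
    """One-way sensitivity analysis over every bounded parameter.

    Returns :class:`TornadoEntry` rows sorted by descending NMB swing.
    Parameters without a usable interval are skipped with a warning.
    """
    base = _evaluate(params, policy)
    entries = []
    for name in sorted(params.distributions):
        spec = params.distributions[name]
        if spec.kind == "fixed" or spec.low == spec.high:
            logger.warning("DSA: parameter %s has no interval, skipped", name)
            continue
        outcomes = []
        for bound in (spec.low, spec.high):
            ps = params.with_value(name, bound)
            # the moderate->mild regression is structurally tied to the
            # untreated value and must follow it when that value is varied
            ps.tp_treated["MODERATE->MILD"] = ps.tp_untreated["MODERATE->MILD"]
            res = _evaluate(ps, policy)
            outcomes.append(res)
        lo, hi = outcomes
        nmb_lo, nmb_hi = lo.nmb_pp, hi.nmb_pp
        entries.append(
            TornadoEntry(
                parameter=name,
                value_low=spec.low,
                value_high=spec.high,
                nmb_low=nmb_lo,
                nmb_high=nmb_hi,
                icer_low=lo.icer.value,
                icer_high=hi.icer.value,
                swing=abs(nmb_hi - nmb_lo),
                non_monotone=not (
                    min(nmb_lo, nmb_hi) - 1e-9 <= base.nmb_pp <= max(nmb_lo, nmb_hi) + 1e-9
                ),
            )
        )
    entries.sort(key=lambda e: (-e.swing, e.parameter))
    return entries


def tornado_dataframe(entries: list):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.value_low,
                "high": e.value_high,
                "nmb_low": e.nmb_low,
                "nmb_high": e.nmb_high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "swing": e.swing,
                "non_monotone": e.non_monotone,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------- PSA

@dataclass
class PSAOutput:
    """Paired incremental draws plus acceptability summaries."""

    draws: np.ndarray  # (n, 2): inc_cost, inc_qaly
    seed: int
    n_iterations: int
    base: EconResult
    gdp_per_capita: float
    ceac: list = field(default_factory=list)  # (threshold, probability)
    prob_ce_at_1gdp: float = 0.0
    prob_ce_at_3gdp: float = 0.0
    scatter_below_3gdp: float = 0.0  # QALY-gaining draws under the 3xGDP ray

    @property
    def inc_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def inc_qaly(self) -> np.ndarray:
        return self.draws[:, 1]

    def mean_increment(self) -> tuple:
        return float(self.inc_cost.mean()), float(self.inc_qaly.mean())

    def draws_dataframe(self):
        import pandas as pd

        g = self.gdp_per_capita
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "inc_cost": self.inc_cost,
                "inc_qaly": self.inc_qaly,
                "nmb_1gdp": g * self.inc_qaly - self.inc_cost,
                "nmb_3gdp": 3 * g * self.inc_qaly - self.inc_cost,
            }
        )

    def ceac_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.ceac, columns=["threshold", "probability"])

    # ------------------------------------------------------------- plotting
    def plot_ce_plane(self, ax=None):
        """Incremental cost-effectiveness scatter with the 3x-GDP WTP ray."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.inc_qaly, self.inc_cost, s=4, alpha=0.4)
        lam = 3 * self.gdp_per_capita
        q = np.linspace(*ax.get_xlim(), 10)
        ax.plot(q, lam * q, lw=1, color="crimson", label=f"WTP = {lam:,.0f} USD/QALY")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (USD)")
        ax.legend()
        return ax

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        thr, prob = zip(*self.ceac)
        ax.plot(thr, prob)
        ax.set_xlabel("Willingness to pay (USD/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        return ax


def ceac(draws: np.ndarray, thresholds) -> list:
    """Probability of positive NMB at each willingness-to-pay threshold."""
    thresholds = list(thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold grid must be nonempty")
    if len(draws) == 0:
        raise ValueError("need at least one PSA draw")
    cost, qaly = draws[:, 0], draws[:, 1]
    return [
        (float(lam), float(np.mean(lam * qaly - cost > 0.0))) for lam in thresholds
    ]


def run_psa(
    params: ParameterSet,
    policy: ScreeningPolicy,
    n: int = 10_000,
    seed: int = 0,
) -> PSAOutput:
    """Monte-Carlo parameter uncertainty analysis (joint independent draws)."""
    if n < 1:
        raise ValueError("need at least one iteration")
    names = varied_parameters(params)
    specs = [params.distributions[m] for m in names]
    base = _evaluate(params, policy)

    children = np.random.SeedSequence(seed).spawn(n)
    draws = np.empty((n, 2))
    for k in range(n):
        rng = np.random.default_rng(children[k])
        ps = params.copy()
        for name, spec in zip(names, specs):
            ps.set_value(name, spec.sample(rng))
        ps.tp_treated["MODERATE->MILD"] = ps.tp_untreated["MODERATE->MILD"]
        ps.validate()
        res = _evaluate(ps, policy)
        draws[k] = (res.inc_cost, res.inc_qaly)

    g = params.gdp_per_capita
    grid = sorted(set(np.linspace(0.0, 4.0 * g, 41)) | {g, 3.0 * g})
    curve = ceac(draws, grid)
    probs = dict(curve)
    qaly, cost = draws[:, 1], draws[:, 0]
    scatter = float(np.mean((qaly > 0) & (cost < 3.0 * g * qaly)))
    return PSAOutput(
        draws=draws,
        seed=seed,
        n_iterations=n,
        base=base,
        gdp_per_capita=g,
        ceac=curve,
        prob_ce_at_1gdp=probs[g],
        prob_ce_at_3gdp=probs[3.0 * g],
        scatter_below_3gdp=scatter,
    )
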