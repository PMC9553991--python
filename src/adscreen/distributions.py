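"""Parametric uncertainty distributions for model inputs.

Probabilities and utilities carry beta distributions, annual costs carry
gamma distributions, and point values carry a degenerate ``fixed`` spec.
Shapes are fitted by the method of moments from a mean and a (low, high)
interval read as a normal-approximate 95% interval, i.e.
``sd = (high - low) / 3.92``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DistributionSpec",
    "InfeasibleDistributionError",
    "fit_beta_from_interval",
    "fit_gamma_from_interval",
    "fixed",
]

#: width of a central 95% normal interval in standard deviations (2 x 1.96)
CI_WIDTH = 3.92


class InfeasibleDistributionError(ValueError):
    """Raised when no distribution of the requested family matches the moments."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one scalar parameter.

    Parameters
    ----------
    kind : {"beta", "gamma", "fixed"}
        Distribution family. ``fixed`` means the parameter is not sampled.
    mean, low, high : float
        Central value and interval the shapes were fitted from.
    shape_a, shape_b : float
        Beta: (alpha, beta).  Gamma: (shape k, rate).  Fixed: unused (0).
    """

    kind: str
    mean: float
    low: float
    high: float
    shape_a: float = 0.0
    shape_b: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "fixed" and not (self.low == self.mean == self.high):
            raise ValueError("fixed spec requires low == mean == high")
        if self.kind == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError("beta spec requires bounds within [0, 1]")
        if self.kind == "gamma" and self.low < 0.0:
            raise ValueError("gamma spec requires low >= 0")

    # -- analytic moments (method-of-moments oracle hooks) -------------------
    @property
    def analytic_mean(self) -> float:
        if self.kind == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        if self.kind == "gamma":
            return self.shape_a / self.shape_b
        return self.mean

    @property
    def analytic_sd(self) -> float:
        if self.kind == "beta":
            a, b = self.shape_a, self.shape_b
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        if self.kind == "gamma":
            return math.sqrt(self.shape_a) / self.shape_b
        return 0.0

    def sample(self, rng) -> float:
        """Draw one value with a :class:`numpy.random.Generator`."""
        if self.kind == "beta":
            return float(rng.beta(self.shape_a, self.shape_b))
        if self.kind == "gamma":
            return float(rng.gamma(self.shape_a, 1.0 / self.shape_b))
        return self.mean

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean": self.mean,
            "low": self.low,
            "high": self.high,
            "shape_a": self.shape_a,
            "shape_b": self.shape_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(
            kind=d["kind"],
            mean=float(d["mean"]),
            low=float(d["low"]),
            high=float(d["high"]),
            shape_a=float(d.get("shape_a", 0.0)),
            shape_b=float(d.get("shape_b", 0.0)),
        )


def fixed(value: float) -> DistributionSpec:
    """A degenerate spec for a parameter excluded from sampling."""
    return DistributionSpec("fixed", value, value, value)


def fit_beta_from_interval(mean: float, low: float, high: float) -> DistributionSpec:
    """Fit a beta distribution matching ``mean`` exactly and sd = (high-low)/3.92.

    Degenerates to a ``fixed`` spec when low == mean == high.

    Raises
    ------
    InfeasibleDistributionError
        If the implied variance is >= mean*(1-mean), which no beta attains.
    """
    if low == high == mean:
        return fixed(mean)
    if not (0.0 < mean < 1.0):
        raise InfeasibleDistributionError(f"beta mean must lie in (0, 1), got {mean}")
    if not (low <= mean <= high):
        raise ValueError(f"require low <= mean <= high, got ({low}, {mean}, {high})")
    sd = (high - low) / CI_WIDTH
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleDistributionError(
            f"variance {var:.6g} infeasible for beta mean {mean:.6g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec("beta", mean, low, high, shape_a=mean * nu, shape_b=(1.0 - mean) * nu)


def fit_gamma_from_interval(
    mean: float, low: float, high: float, *, strict_interval: bool = True
) -> DistributionSpec:
    """Fit a gamma distribution matching ``mean`` exactly and sd = (high-low)/3.92.

    ``strict_interval=False`` permits a printed mean lying outside its own
    printed bounds (the spread is still taken from the bounds); used for
    source tables shipped verbatim despite internal inconsistency.
    """
    if low == high == mean:
        return fixed(mean)
    if mean <= 0.0:
        raise InfeasibleDistributionError(f"gamma mean must be positive, got {mean}")
    if strict_interval and not (low <= mean <= high):
        raise ValueError(f"require low <= mean <= high, got ({low}, {mean}, {high})")
    sd = (high - low) / CI_WIDTH
    if sd <= 0.0:
        raise InfeasibleDistributionError("gamma interval must have high > low")
    shape = (mean / sd) ** 2
    rate = mean / (sd * sd)
    return DistributionSpec("gamma", mean, low, high, shape_a=shape, shape_b=rate)


def _inconsistent_gamma(mean: float, low: float, high: float) -> DistributionSpec:
    """Gamma spec for a printed row whose mean falls outside its printed bounds."""
    return fit_gamma_from_interval(mean, low, high, strict_interval=False)
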