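"""Fitness functions, selection coefficients, and Kimura fixation probabilities.

Functional isoforms are under stabilizing selection on log abundance,

    w_i = exp(-(ln P_i - ln P_opt)^2 / (2 sigma_i^2)),

toxic isoforms decrease fitness exponentially in abundance,

    w_i = exp(-lambda_i * P_i),

and independent components multiply into the overall fitness.  A new mutation
with selection coefficient ``s = w_M/w_A - 1`` fixes in a diploid population of
effective size Ne with Kimura's probability

    u(s) = (1 - exp(-2 s)) / (1 - exp(-4 Ne s)),

which tends to 1/(2 Ne) as s -> 0 and is monotone increasing in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "PopulationContext",
    "fitness_stabilizing",
    "fitness_toxicity",
    "fitness_trans",
    "overall_fitness",
    "selection_coefficient",
    "fixation_probability",
]

Exponent = Literal["squared", "linear"]


@dataclass(frozen=True)
class PopulationContext:
    """Diploid population of effective size ``Ne``."""

    Ne: float

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")


def _log_deviation(x: float, x_opt: float, sigma: float, exponent: Exponent) -> float:
    d = math.log(x) - math.log(x_opt)
    if exponent == "squared":
        return d * d / (2.0 * sigma * sigma)
    # literal (non-squared) reading, kept as a sensitivity switch; not a true
    # Gaussian and not maximized at the optimum
    return d / (2.0 * sigma * sigma)


def fitness_stabilizing(P: float, P_opt: float, sigma: float, exponent: Exponent = "squared") -> float:
    """Gaussian stabilizing selection on ``ln P`` around ``ln P_opt`` with width ``sigma``."""
    if P <= 0:
        raise ValueError("P must be positive (log-scale fitness undefined at 0)")
    if P_opt <= 0 or sigma <= 0:
        raise ValueError("P_opt and sigma must be positive")
    return math.exp(-_log_deviation(P, P_opt, sigma, exponent))


def fitness_toxicity(P: float, lam: float) -> float:
    """Fitness ``exp(-lambda * P)`` of carrying abundance ``P`` of a toxic isoform."""
    if P < 0:
        raise ValueError("P must be non-negative")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return math.exp(-lam * P)


def fitness_trans(Q: float, Q_opt: float, sigma_Q: float, exponent: Exponent = "squared") -> float:
    """Stabilizing selection on the trans-genotypic value ``Q`` (same form as abundances)."""
    return fitness_stabilizing(Q, Q_opt, sigma_Q, exponent)


def overall_fitness(components: Iterable[float]) -> float:
    """Product of independent fitness components; an empty list is neutral (1)."""
    w = 1.0
    for c in components:
        if not 0.0 < c <= 1.0:
            raise ValueError("fitness components must lie in (0, 1]")
        w *= c
    return w


def selection_coefficient(w_mutant: float, w_ancestor: float) -> float:
    """``s = w_M / w_A - 1``."""
    if w_ancestor <= 0:
        raise ValueError("ancestral fitness must be positive")
    return w_mutant / w_ancestor - 1.0


def fixation_probability(Ne: float, s: float) -> float:
    """Kimura's diploid fixation probability of a new mutation.

    Numerically safe for all ``s >= -1``: the ratio ``expm1(-2s)/expm1(-4*Ne*s)``
    is accurate through the s -> 0 limit 1/(2*Ne); strongly deleterious inputs
    underflow gracefully to 0 instead of overflowing.
    """
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if s < -1:
        raise ValueError("s must be >= -1")
    if s == 0.0 or abs(s) < 1e-14:
        return 1.0 / (2.0 * Ne)
    y = -4.0 * Ne * s
    x = -2.0 * s
    if y > 700.0:
        # deleterious tail: u ~ expm1(x) * exp(-y); underflows to 0 for 4*Ne*s << -700
        return math.expm1(x) * math.exp(-y) if y < 1450.0 else 0.0
    return math.expm1(x) / math.expm1(y)
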