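"""Origin-fixation Markov chain on the cis-genotypic value.

In the sequential-fixation (weak-mutation) regime, valid when ``2*Ne*mu << 1``,
the population is monomorphic and evolves one substitution at a time.  The
cis-genotypic value ``v`` (count of effector alleles among ``l`` loci) then
follows a discrete Markov chain with tridiagonal transition matrix

    T[v, v+1] = 2*(l - v)*Ne*mu01 * u(s_{v -> v+1})
    T[v, v-1] = 2*v*Ne*mu10       * u(s_{v -> v-1})
    T[v, v]   = 1 - T[v, v+1] - T[v, v-1]

where ``u`` is Kimura's fixation probability and ``s`` comes from the fitness
ratio of adjacent genotypic values.  Distributions after ``t`` time steps are
``v_0 T^t`` (binary exponentiation), and long-run behaviour is summarized by the
phylogenetic mean modification level: the level ``f`` evaluated at ``E[v]``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .architecture import CisArchitecture, conversion_rate
from .kinetics import KineticState, equilibrium_branching, equilibrium_two_isoform
from .selection import (
    Exponent,
    PopulationContext,
    fitness_stabilizing,
    fitness_toxicity,
    fixation_probability,
)

__all__ = [
    "SequentialFixationWarning",
    "ValidityError",
    "ModificationModel",
    "CisDistribution",
    "genotype_fitness_profile",
    "build_transition_matrix",
    "markov_matrix_power",
    "evolve_distribution",
    "TransitionPowers",
    "mean_modification_level",
    "scaling_experiment",
]

#: fitness values are floored here so selection coefficients stay finite; a
#: genotype at the floor is effectively lethal (fixation probability ~ 0)
_FITNESS_FLOOR = 1e-300

_ROWSUM_TOL = 1e-12


class SequentialFixationWarning(UserWarning):
    """The sequential-fixation validity condition 2*Ne*mu < 0.01 is violated."""


class ValidityError(ValueError):
    """The parameterization is outside the regime where the model is defined."""


@dataclass(frozen=True)
class CisDistribution:
    """Probability vector over v = 0..l after ``t`` elapsed time steps."""

    probs: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("probs must be a probability vector (sum 1, entries >= 0)")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))

    @classmethod
    def point_mass(cls, v: int, l: int) -> "CisDistribution":
        p = np.zeros(l + 1)
        p[v] = 1.0
        return cls(p, t=0)

    @property
    def l(self) -> int:
        return self.probs.size - 1

    @property
    def mean_v(self) -> float:
        return float(self.probs @ np.arange(self.probs.size))


@dataclass(frozen=True)
class ModificationModel:
    """One modification event: architecture + kinetic constants + selection regime.

    For editing-type events the unmodified isoform I0 is functional (stabilizing
    selection around ``P_opt``, default ``alpha/gamma0``) and I1 is toxic
    (``lam``).  For splicing-type events I1 is functional (``P_opt`` default
    ``alpha/gamma1``) and I2 is toxic.  ``neutral=True`` makes every genotype
    equally fit (pure mutation-drift).
    """

    arch: CisArchitecture
    alpha: float = 1.0
    gamma0: float = 1.0
    gamma1: float = 1.0
    gamma2: float = 20.0
    sigma: float = 10.0
    lam: float = 1e-3
    P_opt: float | None = None
    neutral: bool = False
    exponent: Exponent = "squared"

    @property
    def mode(self) -> str:
        return self.arch.mode

    @property
    def p_opt(self) -> float:
        if self.P_opt is not None:
            return self.P_opt
        if self.mode == "editing":
            return self.alpha / self.gamma0
        return self.alpha / self.gamma1

    def v_hat(self, v: float) -> float:
        l = self.arch.l
        return 0.0 if l == 0 else float(v) / l

    def equilibrium(self, v_hat: float, Q: float) -> KineticState:
        """Equilibrium abundances at normalized cis value ``v_hat`` and trans value ``Q``."""
        beta = conversion_rate(self.arch, v_hat, Q)
        if self.mode == "editing":
            return equilibrium_two_isoform(self.alpha, beta, self.gamma0, self.gamma1)
        b1, b2 = beta
        return equilibrium_branching(
            self.alpha, np.array([b1, b2]), np.array([self.gamma0, self.gamma1, self.gamma2])
        )

    def level(self, v_hat: float, Q: float) -> float:
        """Modification level at (v_hat, Q); closed form, no linear solve."""
        if self.mode == "editing":
            beta = conversion_rate(self.arch, v_hat, Q)
            return beta / (beta + self.gamma1)
        b1, b2 = conversion_rate(self.arch, v_hat, Q)
        p1, p2 = b1 / self.gamma1, b2 / self.gamma2
        total = p1 + p2
        return 0.0 if total == 0.0 else p2 / total

    def fitness(self, v: int, Q: float) -> float:
        if self.neutral:
            return 1.0
        state = self.equilibrium(self.v_hat(v), Q)
        p = state.abundances
        if self.mode == "editing":
            w_func = self._stabilizing(p[0])
            w_tox = fitness_toxicity(p[1], self.lam)
        else:
            w_func = self._stabilizing(p[1])
            w_tox = fitness_toxicity(p[2], self.lam)
        return max(w_func * w_tox, _FITNESS_FLOOR)

    def _stabilizing(self, P: float) -> float:
        if P <= 0.0:
            return 0.0  # limit of the Gaussian as ln P -> -inf
        return fitness_stabilizing(P, self.p_opt, self.sigma, self.exponent)

    def fitness_profile(self, Q: float) -> np.ndarray:
        return np.array([self.fitness(v, Q) for v in range(self.arch.l + 1)])

    def log_fitness_profile(self, Q: float) -> np.ndarray:
        """log of :meth:`fitness_profile`; closed-form vectorized for editing-type."""
        l = self.arch.l
        if self.neutral:
            return np.zeros(l + 1)
        if self.mode != "editing":
            return np.log(self.fitness_profile(Q))
        v_hat = np.arange(l + 1) / l if l else np.zeros(1)
        beta = Q * (self.arch.C * v_hat + self.arch.epsilon)
        p0 = self.alpha / (beta + self.gamma0)
        p1 = self.alpha * beta / (self.gamma1 * (beta + self.gamma0))
        d = np.log(p0) - math.log(self.p_opt)
        dev = d * d if self.exponent == "squared" else d
        logw = -dev / (2.0 * self.sigma**2) - self.lam * p1
        return np.maximum(logw, math.log(_FITNESS_FLOOR))


def genotype_fitness_profile(model: ModificationModel, Q: float) -> np.ndarray:
    """Fitness of every cis-genotypic value v = 0..l at trans value ``Q``."""
    return model.fitness_profile(Q)


def build_transition_matrix(
    arch: CisArchitecture, pop: PopulationContext, fitness_profile: np.ndarray
) -> np.ndarray:
    """Tridiagonal row-stochastic origin-fixation transition matrix over v = 0..l."""
    l = arch.l
    w = np.asarray(fitness_profile, dtype=float)
    if w.size != l + 1:
        raise ValueError("fitness_profile must have length l + 1")
    if np.any(w <= 0):
        raise ValueError("fitness profile must be positive")
    supply = 2.0 * pop.Ne * (arch.mu01 + arch.mu10)
    if supply >= 0.1:
        raise ValidityError(
            f"2*Ne*(mu01+mu10) = {supply:.3g} >= 0.1: sequential-fixation model invalid"
        )
    if supply >= 0.01:
        warnings.warn(
            f"2*Ne*(mu01+mu10) = {supply:.3g} >= 0.01: sequential-fixation approximation is dubious",
            SequentialFixationWarning,
            stacklevel=2,
        )
    T = np.zeros((l + 1, l + 1))
    for v in range(l + 1):
        up = down = 0.0
        if v < l:
            s = w[v + 1] / w[v] - 1.0
            up = 2.0 * (l - v) * pop.Ne * arch.mu01 * fixation_probability(pop.Ne, s)
            T[v, v + 1] = up
        if v > 0:
            s = w[v - 1] / w[v] - 1.0
            down = 2.0 * v * pop.Ne * arch.mu10 * fixation_probability(pop.Ne, s)
            T[v, v - 1] = down
        diag = 1.0 - up - down
        if diag < 0:
            raise ValidityError(
                "off-diagonal transition mass exceeds 1 per time step; "
                "the sequential-fixation validity condition 2*Ne*mu < 0.01 is violated"
            )
        T[v, v] = diag
    return T


def markov_matrix_power(T: np.ndarray, t: int) -> np.ndarray:
    """``T**t`` by binary exponentiation, renormalizing rows when drift exceeds 1e-12."""
    if t < 0:
        raise ValueError("t must be non-negative")
    result = np.eye(T.shape[0])
    base = T.copy()
    while t:
        if t & 1:
            result = _renorm(result @ base)
        t >>= 1
        if t:
            base = _renorm(base @ base)
    return result


def _renorm(M: np.ndarray) -> np.ndarray:
    rowsums = M.sum(axis=1, keepdims=True)
    if np.any(np.abs(rowsums - 1.0) > _ROWSUM_TOL):
        M = M / rowsums
    return M


class TransitionPowers:
    """Cache of ``T**(2**k)`` for repeated propagation under a fixed matrix."""

    def __init__(self, T: np.ndarray):
        self._powers = [_renorm(T.copy())]

    def propagate(self, dist: np.ndarray, t: int) -> np.ndarray:
        """``dist @ T**t`` for a vector or a stack of row distributions."""
        k = 0
        while t:
            if k >= len(self._powers):
                prev = self._powers[-1]
                self._powers.append(_renorm(prev @ prev))
            if t & 1:
                dist = dist @ self._powers[k]
            t >>= 1
            k += 1
        return dist


def evolve_distribution(start: CisDistribution, T: np.ndarray, t: int) -> CisDistribution:
    """Distribution of v after ``t`` time steps: ``v_0 @ T**t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return start
    p = start.probs @ markov_matrix_power(T, t)
    total = p.sum()
    if abs(total - 1.0) > _ROWSUM_TOL:
        p = p / total
    return CisDistribution(np.clip(p, 0.0, None), t=start.t + t)


def mean_modification_level(
    dist: CisDistribution, model: ModificationModel, Q: float
) -> tuple[float, float, float]:
    """``(mean_v, f_of_mean_v, mean_f)`` under a distribution of cis values.

    ``f_of_mean_v`` — the level evaluated at the expected genotypic value — is
    the headline (phylogenetic mean) statistic; ``mean_f = E[f(v)]`` is also
    returned because the two differ whenever f is nonlinear in v.
    """
    l = model.arch.l
    if dist.probs.size != l + 1:
        raise ValueError("distribution length does not match the model's l + 1")
    mean_v = dist.mean_v
    f_of_mean = model.level(model.v_hat(mean_v), Q)
    levels = np.array([model.level(model.v_hat(v), Q) for v in range(l + 1)])
    mean_f = float(dist.probs @ levels)
    return mean_v, f_of_mean, mean_f


def scaling_experiment(
    Ne_grid: Sequence[float],
    l_grid: Sequence[int],
    mu_pairs: Sequence[tuple[float, float]],
    p_opt_grid: Sequence[float],
    mode: Literal["editing", "splicing"] = "editing",
    *,
    t: int = 10**8,
    Q: float | None = None,
    C: float = 1.0,
    epsilon: float = 0.0,
    gamma0: float | None = None,
    gamma1: float = 1.0,
    gamma2_grid: Sequence[float] = (20.0,),
    sigma: float = 10.0,
    lam: float = 1e-3,
) -> pd.DataFrame:
    """Phylogenetic mean modification level over a parameter grid.

    One row per (Ne, l, mutation pair, optimal abundance, gamma2) combination.
    Editing starts from v = 0 (no effector alleles); splicing starts from v = l
    (the genotype maximizing functional-isoform production).  ``p_opt`` is the
    optimal abundance of the functional isoform; alpha is set so that the
    optimum is attainable (``alpha = p_opt*gamma0`` editing, ``p_opt*gamma1``
    splicing).
    """
    if Q is None:
        Q = 1.0 if mode == "editing" else 100.0
    if gamma0 is None:
        gamma0 = 1.0 if mode == "editing" else 0.0
    if mode == "editing":
        gamma2_grid = (gamma2_grid[0],)  # unused by the two-isoform system
    rows = []
    for Ne, l, (mu01, mu10), p_opt, gamma2 in itertools.product(
        Ne_grid, l_grid, mu_pairs, p_opt_grid, gamma2_grid
    ):
        arch = CisArchitecture(l=l, mu01=mu01, mu10=mu10, C=C, epsilon=epsilon, mode=mode)
        alpha = p_opt * gamma0 if mode == "editing" else p_opt * gamma1
        model = ModificationModel(
            arch=arch, alpha=alpha, gamma0=gamma0, gamma1=gamma1, gamma2=gamma2,
            sigma=sigma, lam=lam, P_opt=p_opt,
        )
        T = build_transition_matrix(arch, PopulationContext(Ne), model.fitness_profile(Q))
        v0 = CisDistribution.point_mass(0 if mode == "editing" else l, l)
        dist = evolve_distribution(v0, T, t)
        mean_v, f_mean_v, mean_f = mean_modification_level(dist, model, Q)
        rows.append(
            dict(Ne=Ne, l=l, mu01=mu01, mu10=mu10, p_opt=p_opt, gamma2=gamma2,
                 mean_v=mean_v, f_of_mean_v=f_mean_v, mean_f=mean_f)
        )
    return pd.DataFrame(rows)
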