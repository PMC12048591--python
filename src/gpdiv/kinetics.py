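"""Steady-state isoform abundances for gene product modification systems.

A gene's unmodified product :math:`I_0` is produced at rate ``alpha`` and can be
converted into modified isoforms :math:`I_1 \\dots I_n` (editing, splicing,
multi-step or fully general conversion topologies); each isoform :math:`I_i`
decays at rate ``gamma_i``.  At steady state the abundances :math:`P_i` solve a
linear system; this module solves it directly for every topology and computes
the modification level

* editing-type:  ``f = P1 / (P0 + P1)``  (equivalently ``beta / (beta + gamma1)``)
* splicing-type: ``f = P2 / (P1 + P2)``

All solvers raise :class:`DegenerateSystemError` when the steady-state system is
singular (an isoform with inflow but no outflow), and every returned equilibrium
satisfies the flux balance ``alpha = sum(gamma_i * P_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DegenerateSystemError",
    "KineticState",
    "KineticSystem",
    "AltTranscriptionSpec",
    "equilibrium_two_isoform",
    "equilibrium_branching",
    "equilibrium_chain",
    "equilibrium_multisite",
    "equilibrium_general",
    "equilibrium_alt_transcription",
    "modification_level",
]

#: pivot / conditioning threshold below which the linear system is treated as singular
_SINGULAR_TOL = 1e-12

Mode = Literal["editing", "splicing"]


class DegenerateSystemError(ValueError):
    """Raised when the steady-state linear system is singular (no unique equilibrium)."""


@dataclass(frozen=True)
class KineticState:
    """Equilibrium abundances ``P_0..P_n`` and, when defined, a modification level."""

    abundances: np.ndarray
    level: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))

    @property
    def total(self) -> float:
        return float(self.abundances.sum())


@dataclass
class KineticSystem:
    """Production / conversion / decay rates of one modification system.

    ``conversion`` is interpreted according to ``topology``:

    - ``"single"``:    scalar beta, I0 -> I1
    - ``"branching"``: vector (beta_1..beta_n), I0 -> I_i
    - ``"chain"``:     vector (beta_{0->1}..beta_{n-1->n}), I_{i} -> I_{i+1}
    - ``"multisite"``: scalar per-site beta with ``n_sites`` equivalent sites
    - ``"general"``:   (n+1)x(n+1) matrix beta[i, j], I_i -> I_j
    """

    alpha: float
    conversion: float | Sequence[float] | np.ndarray
    gamma: Sequence[float] | np.ndarray
    topology: str = "single"
    n_sites: int | None = None

    def solve(self) -> KineticState:
        g = np.asarray(self.gamma, dtype=float)
        if self.topology == "single":
            return equilibrium_two_isoform(self.alpha, float(np.asarray(self.conversion)), g[0], g[1])
        if self.topology == "branching":
            return equilibrium_branching(self.alpha, np.asarray(self.conversion, float), g)
        if self.topology == "chain":
            return equilibrium_chain(self.alpha, np.asarray(self.conversion, float), g)
        if self.topology == "multisite":
            if self.n_sites is None:
                raise ValueError("multisite topology requires n_sites")
            return equilibrium_multisite(self.alpha, float(np.asarray(self.conversion)), self.n_sites, g)
        if self.topology == "general":
            return equilibrium_general(self.alpha, np.asarray(self.conversion, float), g)
        raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class AltTranscriptionSpec:
    """Two transcriptional outcomes: I1 transcribed with probability ``error_rate``."""

    alpha: float
    error_rate: float
    gamma0: float
    gamma1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


def _validate_rates(alpha: float, rates: np.ndarray, gammas: np.ndarray) -> None:
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if np.any(rates < 0):
        raise ValueError("conversion rates must be non-negative")
    if np.any(gammas < 0):
        raise ValueError("decay rates must be non-negative")


def equilibrium_two_isoform(alpha: float, beta: float, gamma0: float, gamma1: float) -> KineticState:
    """Closed-form equilibrium of the two-isoform (editing-type) system.

    ``P0 = alpha/(beta+gamma0)``, ``P1 = alpha*beta/(gamma1*(beta+gamma0))`` and
    ``f = beta/(beta+gamma1)``.
    """
    _validate_rates(alpha, np.array([beta]), np.array([gamma0, gamma1]))
    if beta + gamma0 <= _SINGULAR_TOL:
        raise DegenerateSystemError("I0 has no outflow: beta + gamma0 = 0")
    if gamma1 <= _SINGULAR_TOL:
        raise DegenerateSystemError("singular system: gamma1 = 0 (I1 equilibrium undetermined)")
    p0 = alpha / (beta + gamma0)
    p1 = alpha * beta / (gamma1 * (beta + gamma0))
    f = beta / (beta + gamma1) if beta + gamma1 > 0 else 0.0
    return KineticState(np.array([p0, p1]), level=f)


def equilibrium_branching(alpha: float, betas: np.ndarray, gammas: np.ndarray) -> KineticState:
    """Equilibrium when I0 branches into n isoforms at rates ``betas = (beta_1..beta_n)``.

    ``gammas`` has length n+1 (decay of I0..In).  The splicing-type system is the
    n=2 case.  Returns the splicing-type level ``P2/(P1+P2)`` when n >= 2, the
    editing-type level when n == 1.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    gammas = np.asarray(gammas, dtype=float)
    n = betas.size
    if gammas.size != n + 1:
        raise ValueError("gammas must have length len(betas) + 1")
    _validate_rates(alpha, betas, gammas)
    B = np.zeros((n + 1, n + 1))
    B[0, 1:] = betas
    state = equilibrium_general(alpha, B, gammas)
    p = state.abundances
    level = _default_level(p, "splicing" if n >= 2 else "editing")
    return KineticState(p, level=level)


def equilibrium_chain(alpha: float, betas: np.ndarray, gammas: np.ndarray) -> KineticState:
    """Equilibrium of a multi-step chain I0 -> I1 -> ... -> In.

    ``betas = (beta_{0->1}, ..., beta_{n-1->n})``; ``gammas`` has length n+1.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    gammas = np.asarray(gammas, dtype=float)
    n = betas.size
    if gammas.size != n + 1:
        raise ValueError("gammas must have length len(betas) + 1")
    _validate_rates(alpha, betas, gammas)
    B = np.zeros((n + 1, n + 1))
    for i in range(n):
        B[i, i + 1] = betas[i]
    state = equilibrium_general(alpha, B, gammas)
    level = _default_level(state.abundances, "splicing" if n >= 2 else "editing")
    return KineticState(state.abundances, level=level)


def equilibrium_multisite(alpha: float, beta_per_site: float, n_sites: int, gammas: np.ndarray) -> KineticState:
    """Equilibrium when a molecule carries ``n_sites`` equivalent modifiable sites.

    Isoform I_i has i sites modified; per-site rate ``beta`` is position independent,
    so the i -> i+1 conversion rate is ``(n_sites - i) * beta``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    chain = np.array([(n_sites - i) * beta_per_site for i in range(n_sites)])
    return equilibrium_chain(alpha, chain, gammas)


def equilibrium_general(alpha: float, beta_matrix: np.ndarray, gammas: np.ndarray) -> KineticState:
    """Equilibrium of the fully general conversion topology.

    ``beta_matrix[i, j]`` is the per-molecule rate at which I_i is converted to
    I_j (diagonal must be zero).  Solves the mass-balance steady state of

    ``dP_i/dt = alpha*[i==0] + sum_j beta[j, i] P_j - (sum_j beta[i, j] + gamma_i) P_i``.
    """
    B = np.asarray(beta_matrix, dtype=float)
    g = np.asarray(gammas, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("beta_matrix must be square")
    if B.shape[0] != g.size:
        raise ValueError("gammas length must match beta_matrix size")
    if np.any(np.diag(B) != 0):
        raise ValueError("beta_matrix diagonal must be zero (no self-conversion)")
    _validate_rates(alpha, B, g)
    outflow = B.sum(axis=1) + g
    M = np.diag(outflow) - B.T
    b = np.zeros(g.size)
    b[0] = alpha
    # pivot-scale singularity check: near-zero outflow rows or rank deficiency
    if np.linalg.matrix_rank(M, tol=_SINGULAR_TOL * max(1.0, float(np.abs(M).max()))) < g.size:
        raise DegenerateSystemError("steady-state system is singular (an isoform with inflow has no outflow)")
    p = np.linalg.solve(M, b)
    p[np.abs(p) < 1e-300] = 0.0
    if np.any(p < -1e-9 * max(1.0, alpha)):
        raise DegenerateSystemError("steady state has negative abundances; system is not a valid kinetic scheme")
    p = np.clip(p, 0.0, None)
    return KineticState(p)


def equilibrium_alt_transcription(spec: AltTranscriptionSpec) -> KineticState:
    """Equilibrium when two isoforms arise from alternative transcription.

    ``P0 = (1-E)*alpha/gamma0``, ``P1 = E*alpha/gamma1`` where ``E`` is the
    probability that I1 is transcribed.
    """
    if spec.gamma0 <= 0 or spec.gamma1 <= 0:
        raise DegenerateSystemError("alternative-transcription system needs gamma0 > 0 and gamma1 > 0")
    p0 = (1.0 - spec.error_rate) * spec.alpha / spec.gamma0
    p1 = spec.error_rate * spec.alpha / spec.gamma1
    f = modification_level(KineticState(np.array([p0, p1])), "editing")
    return KineticState(np.array([p0, p1]), level=f)


def _default_level(p: np.ndarray, mode: Mode) -> float:
    if mode == "editing":
        denom = p[0] + p[1]
        num = p[1]
    else:
        denom = p[1] + p[2]
        num = p[2]
    if denom <= 0.0:
        return 0.0
    return float(num / denom)


def modification_level(state: KineticState | np.ndarray, mode: Mode = "editing") -> float:
    """Fraction of the gene product that is modified.

    Editing-type: ``P1/(P0+P1)``; splicing-type: ``P2/(P1+P2)``.  A zero
    denominator (all relevant abundances zero) returns 0 with a warning.
    """
    p = state.abundances if isinstance(state, KineticState) else np.asarray(state, dtype=float)
    if mode not in ("editing", "splicing"):
        raise ValueError("mode must be 'editing' or 'splicing'")
    need = 2 if mode == "editing" else 3
    if p.size < need:
        raise ValueError(f"{mode}-type level needs at least {need} abundances")
    if mode == "editing":
        denom, num = p[0] + p[1], p[1]
    else:
        denom, num = p[1] + p[2], p[2]
    if denom <= 0.0:
        warnings.warn("modification level undefined (zero total abundance); returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(num / denom)
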