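"""Genetic architecture mapping cis- and trans-genotypes to conversion rates.

A modification event is controlled by ``l`` biallelic cis-loci (effector vs null
alleles, equal additive effects) and one trans-factor whose aggregate activity is
the trans-genotypic value ``Q``.  With normalized cis-genotypic value
``v_hat = v / l`` the per-molecule conversion rate is

    editing-type:   beta   = Q * (C * v_hat + epsilon)
    splicing-type:  beta_1 = Q * (C * v_hat + epsilon)
                    beta_2 = Q * (C * (1 - v_hat) + epsilon)

``C`` scales whole-molecule features (e.g. RNA secondary structure) and
``epsilon`` is the rate of nonspecific, cis-independent modification.  For the
splicing type the two rates are controlled by the same loci with inversely
correlated effects, so ``beta_1 + beta_2 = Q * (C + 2*epsilon)`` identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "CisArchitecture",
    "CisGenotype",
    "TransFactor",
    "normalized_cis_value",
    "conversion_rate",
]


@dataclass(frozen=True)
class CisArchitecture:
    """Cis-side architecture of one modification event.

    Parameters
    ----------
    l : number of cis-loci (``l = 0`` means purely nonspecific modification).
    mu01, mu10 : per-locus mutation rates null->effector and effector->null,
        per time step.
    C : whole-molecule effect scale (> 0).
    epsilon : nonspecific modification rate (>= 0).
    mode : ``"editing"`` or ``"splicing"``.
    """

    l: int
    mu01: float
    mu10: float
    C: float
    epsilon: float = 0.0
    mode: Literal["editing", "splicing"] = "editing"

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("l must be non-negative")
        if self.mu01 < 0 or self.mu10 < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.mode not in ("editing", "splicing"):
            raise ValueError("mode must be 'editing' or 'splicing'")


@dataclass(frozen=True)
class CisGenotype:
    """Count of effector alleles ``v`` out of ``v_max`` (= l under equal effects)."""

    v: int
    v_max: int

    def __post_init__(self) -> None:
        if not 0 <= self.v <= max(self.v_max, 0):
            raise ValueError(f"v={self.v} outside [0, {self.v_max}]")

    @property
    def v_hat(self) -> float:
        return normalized_cis_value(self.v, self.v_max)


@dataclass(frozen=True)
class TransFactor:
    """Trans-genotypic value and its selection/mutation parameters.

    ``Q`` is the aggregate expression/catalytic activity of the modifying
    enzyme; it is under stabilizing selection toward ``Q_opt`` with width
    ``sigma_Q``.  Mutations hit ``Q`` at rate ``U_Q`` per time step and perturb
    ``ln Q`` by N(0, S_Q).
    """

    Q: float
    Q_opt: float = 2.0
    sigma_Q: float = 2.0
    U_Q: float = 1e-8
    S_Q: float = 0.1

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.Q_opt <= 0:
            raise ValueError("Q and Q_opt must be positive")
        if self.sigma_Q <= 0:
            raise ValueError("sigma_Q must be positive")
        if self.U_Q < 0 or self.S_Q < 0:
            raise ValueError("U_Q and S_Q must be non-negative")


def normalized_cis_value(v: float, v_max: int) -> float:
    """``v / v_max``; defined as 0 when ``v_max = 0`` (no cis-loci, nonspecific only)."""
    if v_max == 0:
        if v != 0:
            raise ValueError("v must be 0 when v_max is 0")
        return 0.0
    if not 0 <= v <= v_max:
        raise ValueError(f"v={v} outside [0, {v_max}]")
    return float(v) / float(v_max)


def conversion_rate(
    arch: CisArchitecture, genotype: CisGenotype | float, Q: float
) -> float | tuple[float, float]:
    """Conversion rate(s) for a genotype under architecture ``arch`` at trans value ``Q``.

    Accepts either a :class:`CisGenotype` or a pre-normalized ``v_hat`` float.
    Returns ``beta`` for editing-type, ``(beta_1, beta_2)`` for splicing-type.
    """
    if Q <= 0:
        raise ValueError("Q must be positive")
    v_hat = genotype.v_hat if isinstance(genotype, CisGenotype) else float(genotype)
    if not 0.0 <= v_hat <= 1.0:
        raise ValueError("v_hat must lie in [0, 1]")
    if arch.mode == "editing":
        return Q * (arch.C * v_hat + arch.epsilon)
    return (
        Q * (arch.C * v_hat + arch.epsilon),
        Q * (arch.C * (1.0 - v_hat) + arch.epsilon),
    )
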