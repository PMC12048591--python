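"""Event-driven simulation of cis-trans coevolution under opposing selection.

A panel of genes is subject to deleterious editing-type modification (functional
I0 under stabilizing selection, toxic I1), while the shared trans-genotypic
value Q is under stabilizing selection toward its own optimum through an
independent fitness component.  Within a lineage of L time steps:

1. the number of trans mutations m ~ Poisson(2*Ne*U_Q*L) (redrawn while m > L)
   is placed at m distinct uniformly chosen time steps;
2. between events every gene's cis-value distribution advances by T(Q)**dt;
3. at each event one v is sampled per gene from its current distribution, the
   mutant (Q*exp(delta), delta ~ N(0, S_Q)) and ancestral fitnesses are compared
   with those same sampled v's, and the mutation fixes with Kimura probability;
   a fixed mutation replaces Q and rebuilds the genes' transition matrices;
4. at the end a final v per gene is sampled and its equilibrium P1 recorded.

Sampling a v for an event's fitness evaluation does not collapse the gene's
distribution (the full distribution is retained), so under a shared genotype
all genes with identical parameters keep identical distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import CisArchitecture, TransFactor
from .cis_markov import (
    ModificationModel,
    TransitionPowers,
    build_transition_matrix,
)
from .selection import PopulationContext, fitness_trans, fixation_probability

__all__ = [
    "LineageConfig",
    "LineageResult",
    "simulate_lineage",
    "qbar",
    "sharing_statistic",
    "coevolution_experiment",
    "DEFAULT_V0",
]

#: starting cis value used for each panel l (the value with the largest genotypic space)
DEFAULT_V0 = {2: 1, 5: 2, 10: 5}


@dataclass(frozen=True)
class LineageConfig:
    """One simulated lineage: a gene panel and a shared trans-factor.

    Defaults are the standard deleterious-editing panel: alpha = gamma0 =
    gamma1 = C = 1, sigma = 10, lambda = 1e-3, epsilon = 1e-3, with
    Q_opt = 2, U_Q = 1e-8 and S_Q = 0.1 for the trans-factor.
    """

    L: int
    Ne: float
    n_genes: int = 100
    l: int = 5
    v0: int | None = None
    mu01: float = 1e-9
    mu10: float = 1e-9
    alpha: float = 1.0
    gamma0: float = 1.0
    gamma1: float = 1.0
    C: float = 1.0
    epsilon: float = 1e-3
    sigma: float = 10.0
    lam: float = 1e-3
    trans: TransFactor = field(default_factory=lambda: TransFactor(Q=2.0))
    Q0: float | None = None  # defaults to the trans optimum
    collapse_on_sample: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        v0 = self.v0 if self.v0 is not None else DEFAULT_V0.get(self.l, self.l // 2)
        if not 0 <= v0 <= self.l:
            raise ValueError("v0 must lie in [0, l]")
        object.__setattr__(self, "v0", v0)

    def model(self) -> ModificationModel:
        arch = CisArchitecture(
            l=self.l, mu01=self.mu01, mu10=self.mu10, C=self.C,
            epsilon=self.epsilon, mode="editing",
        )
        return ModificationModel(
            arch=arch, alpha=self.alpha, gamma0=self.gamma0, gamma1=self.gamma1,
            sigma=self.sigma, lam=self.lam,
        )


@dataclass(frozen=True)
class LineageResult:
    """Endpoint of one lineage."""

    Q_final: float
    v_final: np.ndarray        # per-gene sampled cis value
    P1_final: np.ndarray       # per-gene equilibrium toxic-isoform abundance
    n_proposed: int
    n_fixed: int
    cis_distribution: np.ndarray  # shared (or per-gene) distribution at the end


def _sample_distinct_steps(rng: np.random.Generator, m: int, L: int) -> np.ndarray:
    """m distinct steps in [1, L], sorted (rejection sampling; m << L in practice)."""
    chosen: set[int] = set()
    while len(chosen) < m:
        draw = rng.integers(1, L + 1, size=m - len(chosen))
        chosen.update(draw.tolist())
    return np.sort(np.fromiter(chosen, dtype=np.int64, count=m))


def _sample_rows(rng: np.random.Generator, dists: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a stack of probability rows."""
    cum = np.cumsum(dists, axis=1)
    u = rng.random(dists.shape[0]) * cum[:, -1]
    return (u[:, None] > cum).sum(axis=1)


def simulate_lineage(config: LineageConfig, rng: np.random.Generator) -> LineageResult:
    """Simulate one lineage of cis-trans coevolution; deterministic given ``rng`` state."""
    model = config.model()
    trans = config.trans
    pop = PopulationContext(config.Ne)
    l = config.l
    Q = config.Q0 if config.Q0 is not None else trans.Q_opt

    m = rng.poisson(2.0 * config.Ne * trans.U_Q * config.L)
    while m > config.L:
        m = rng.poisson(2.0 * config.Ne * trans.U_Q * config.L)
    times = _sample_distinct_steps(rng, m, config.L) if m else np.empty(0, dtype=np.int64)

    # shared-row fast path: with collapse_on_sample=False all genes keep
    # identical distributions, so one row suffices
    shared = not config.collapse_on_sample
    dist = np.zeros(l + 1)
    dist[config.v0] = 1.0
    if not shared:
        dist = np.tile(dist, (config.n_genes, 1))

    def rebuild(Q_val: float) -> tuple[TransitionPowers, np.ndarray, float]:
        logw = model.log_fitness_profile(Q_val)
        T = build_transition_matrix(model.arch, pop, np.exp(logw))
        logw_Q = math.log(fitness_trans(Q_val, trans.Q_opt, trans.sigma_Q))
        return TransitionPowers(T), logw, logw_Q

    powers, logw_cur, logwQ_cur = rebuild(Q)
    n_fixed = 0
    t_prev = 0
    for t_event in times:
        dt = int(t_event - t_prev)
        t_prev = int(t_event)
        if dt:
            dist = powers.propagate(dist, dt)
        # sample one v per gene from the current distribution(s)
        if config.n_genes:
            if shared:
                cum = np.cumsum(dist)
                vs = np.searchsorted(cum, rng.random(config.n_genes) * cum[-1], side="right")
                vs = np.minimum(vs, l)
            else:
                vs = _sample_rows(rng, dist)
            counts = np.bincount(vs, minlength=l + 1).astype(float)
        else:
            vs = np.empty(0, dtype=np.int64)
            counts = np.zeros(l + 1)
        delta = rng.normal(0.0, trans.S_Q)
        Q_mut = Q * math.exp(delta)
        logw_mut = model.log_fitness_profile(Q_mut)
        logwQ_mut = math.log(fitness_trans(Q_mut, trans.Q_opt, trans.sigma_Q))
        log_ratio = (logwQ_mut - logwQ_cur) + float(counts @ (logw_mut - logw_cur))
        s = math.expm1(log_ratio)
        if rng.random() < fixation_probability(config.Ne, s):
            Q = Q_mut
            n_fixed += 1
            powers, logw_cur, logwQ_cur = rebuild(Q)
        if config.collapse_on_sample and config.n_genes:
            dist = np.zeros_like(dist)
            dist[np.arange(config.n_genes), vs] = 1.0

    if config.L - t_prev:
        dist = powers.propagate(dist, int(config.L - t_prev))

    if config.n_genes:
        rows = np.broadcast_to(dist, (config.n_genes, l + 1)) if shared else dist
        v_final = _sample_rows(rng, rows)
        p1 = np.array(
            [model.equilibrium(model.v_hat(v), Q).abundances[1] for v in range(l + 1)]
        )[v_final]
    else:
        v_final = np.empty(0, dtype=np.int64)
        p1 = np.empty(0)
    return LineageResult(
        Q_final=Q, v_final=v_final, P1_final=p1,
        n_proposed=int(m), n_fixed=n_fixed,
        cis_distribution=np.array(dist, copy=True),
    )


def qbar(results: list[LineageResult]) -> float:
    """Among-lineage average of the final trans-genotypic value."""
    if not results:
        raise ValueError("qbar needs at least one lineage")
    return float(np.mean([r.Q_final for r in results]))


def sharing_statistic(results: list[LineageResult], threshold: float = 0.005) -> float:
    """Median across genes of the fraction of lineages where P1 exceeds ``threshold``.

    The even-count median is the lower-middle element, so the statistic always
    lies on the lattice of attainable lineage fractions.
    """
    if not results:
        raise ValueError("sharing_statistic needs at least one lineage")
    n_genes = results[0].P1_final.size
    if any(r.P1_final.size != n_genes for r in results):
        raise ValueError("all lineages must share an identical gene panel")
    if n_genes == 0:
        raise ValueError("gene panel is empty")
    P1 = np.stack([r.P1_final for r in results])            # lineages x genes
    frac = (P1 > threshold).mean(axis=0)                    # per-gene lineage fraction
    ordered = np.sort(frac)
    return float(ordered[(n_genes - 1) // 2])


def coevolution_experiment(
    Ne_grid,
    l_grid=(2, 5, 10),
    sigma_Q_grid=(2.0, 20.0),
    *,
    n_lineages: int = 50,
    n_genes: int = 100,
    duration: int = 10**8,
    seed: int = 0,
    **config_kwargs,
) -> pd.DataFrame:
    """Grid of lineage batches; returns Qbar, its Monte-Carlo SE, and sharing.

    Each (Ne, l, sigma_Q) cell simulates ``n_lineages`` independent lineages of
    ``duration`` time steps and reports the among-lineage mean of Q, its
    standard error, and the median sharing statistic.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for sigma_Q in sigma_Q_grid:
        for l in l_grid:
            for Ne in Ne_grid:
                cfg = LineageConfig(
                    L=duration, Ne=Ne, n_genes=n_genes, l=l,
                    trans=TransFactor(Q=2.0, sigma_Q=sigma_Q),
                    **config_kwargs,
                )
                child = np.random.SeedSequence(
                    entropy=ss.entropy,
                    spawn_key=(int(sigma_Q * 1000), l, int(round(math.log10(Ne) * 10))),
                )
                rngs = [np.random.default_rng(s) for s in child.spawn(n_lineages)]
                results = [simulate_lineage(cfg, r) for r in rngs]
                qs = np.array([r.Q_final for r in results])
                rows.append(
                    dict(
                        Ne=Ne, l=l, sigma_Q=sigma_Q, duration=duration,
                        qbar=float(qs.mean()),
                        qbar_se=float(qs.std(ddof=1) / math.sqrt(len(qs))) if len(qs) > 1 else 0.0,
                        sharing_median=sharing_statistic(results),
                        n_lineages=n_lineages,
                        n_fixed_total=int(sum(r.n_fixed for r in results)),
                    )
                )
    return pd.DataFrame(rows)
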