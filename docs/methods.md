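# Methods

## Scope and model structure

`gpdiv` implements a population-genetic framework for gene product diversity
built from four layers:

1. **kinetics** — deterministic steady states of isoform abundances;
2. **architecture** — cis/trans genetic control of conversion rates;
3. **selection + cis_markov** — fitness, fixation probabilities, and the
   origin-fixation Markov chain on the cis-genotypic value;
4. **coevolution + phylosim** — event-driven cis-trans coevolution of many
   genes, and evolution of an editing-site panel along a species tree.

## Steady-state kinetics

All topologies (two-isoform, branching, chain, uniform multi-site, general
matrix, alternative transcription) are solved by a direct linear solve of the
mass-balance system `diag(outflow) − Bᵀ` rather than by ODE integration;
forward integration of the rate equations is retained only as a test oracle.
This is exact, fast, and makes the flux identity α = Σγᵢ Pᵢ hold to solver
precision (asserted at 1e-10 in tests).  For the fully general conversion
matrix, conversion flux back into I₀ is included in I₀'s balance row; the
matrix therefore reduces to the simpler branching/chain forms exactly when no
such back-conversion exists, which is the case in every standard
configuration.

Singularity (an isoform with inflow but no outflow, or β+γ₀ = 0) raises an
explicit `DegenerateSystemError`; the detection threshold is a pivot/rank
tolerance of 1e-12.  γ₀ = 0 is allowed when total outgoing conversion from I₀
is positive — the standard splicing-type setting uses exactly this to make
processing co-transcriptional.  A modification level with an all-zero
denominator returns 0 with a warning instead of raising, so that ε = 0, v = 0
genotypes remain representable.

## Fitness and fixation

Functional isoforms: ω = exp(−(ln P − ln P̃)²/(2σ²)).  The squared deviation
makes this a true Gaussian maximized at the optimum, which is what
"stabilizing selection" requires; an `exponent="linear"` switch preserves the
unsquared variant for sensitivity analysis.  Toxic isoforms: ω = exp(−λP).
Components multiply; the trans value Q uses the same Gaussian form.  Genotype
fitness is floored at 1e-300 so selection coefficients stay finite: a genotype
at the floor is effectively lethal (fixation probability underflows to 0).
For splicing-type genotypes with P₁ = 0 (possible when ε = 0 and v = 0) the
Gaussian limit ω → 0 applies before the floor.

Fixation probabilities use Kimura's diploid form
u(s) = (1−e^(−2s))/(1−e^(−4Nₑs)), evaluated as an `expm1` ratio, which is
accurate through the neutral limit u(0) = 1/(2Nₑ) (relative error < 1e-9);
for 4Nₑs < −700 the deleterious tail underflows gracefully to 0 instead of
overflowing.

Defaults follow the standard conditions throughout: σ = 10, λ = 1e-3, total
per-locus mutation rate μ₀₁+μ₁₀ = 2e-9, C = 1, and Q = 1 (editing) or
Q = 100 with γ₀ = 0, γ₂ ∈ {20, 50, 100} (splicing).  The optimal abundance of
the functional isoform is the value attained in the absence of (mis-)
modification: P̃₀ = α/γ₀ for editing, and analogously P̃₁ = α/γ₁ for splicing
(the P₁ reached at v̂ = 1, ε = 0, γ₀ = 0).

## Origin-fixation chain

In the sequential-fixation regime the cis value v ∈ {0..l} moves one
substitution at a time: T[v, v±1] = (mutation supply) × u(s) with supply
2(l−v)Nₑμ₀₁ upward and 2vNₑμ₁₀ downward.  The validity condition
2Nₑ(μ₀₁+μ₁₀) < 0.01 is enforced as a warning at 0.01 and an error at 0.1.
Tᵗ is computed by binary exponentiation (≤ ~27 squarings for t = 10⁸) with
row renormalization whenever |rowsum − 1| > 1e-12; this matches naive
repeated multiplication to 1e-12 on small instances.

A time step is an abstract unit (a year in the coleoid simulation).  t = 10⁸
steps represents long-term evolution, deliberately *not* the stationary
distribution: at the default μ = 2e-9 the per-locus relaxation rate is 2e-9
per step, so 10⁸ steps is only ~0.2 relaxation times.  The detailed-balance
stationary law of the neutral chain is Binomial(l, μ₀₁/(μ₀₁+μ₁₀)); the test
suite verifies convergence to it (total variation < 1e-6) at μ = 1e-6 per
direction, where 10⁸ steps is ~200 relaxation times while 2Nₑμ remains ≪ 0.01.

The headline summary is the *phylogenetic mean modification level*: f
evaluated at E[v].  Because f is nonlinear in v this differs from E[f];
both are reported in all output tables, with f(E[v]) primary.

## Scaling experiment

The scaling grid evaluates f(E[v]) after 10⁸ steps from v₀ = 0 (editing) or
v₀ = l (splicing) over Nₑ ∈ {10², 10^2.5, …, 10⁵}, l ∈ {2, 5, 10} (editing)
or {10..50} (splicing), mutational bias, and optimal expression.  Where exact
values were open choices: the bias variants are (μ₀₁, μ₁₀) =
(0.5, 1.5), (1, 1), (1.5, 0.5) × 1e-9 at fixed total 2e-9, and the optimal
expression grid is ln P̃ ∈ {0, 1, 2}.  Verified directions: f non-increasing
in Nₑ; effector-ward bias raises f; higher expression lowers f; larger l
raises f at small Nₑ; faster quality-control decay (γ₂ 20 → 100) never raises
the splicing level.

## Cis-trans coevolution

Each lineage spans L time steps.  The number of trans mutations is
m ~ Poisson(2NₑU_Q L), redrawn while m > L, placed at m distinct uniform
steps (sorted).  Between events every gene's cis distribution advances by
T(Q)^Δt using cached binary powers of T.  At an event, one v per gene is
sampled from its current distribution; the mutant Q·e^δ (δ ~ N(0, S_Q)) and
the current Q are compared at those same sampled v's — pairing the genotypes
so the selection coefficient reflects the Q change only — through
ω = ω_Q · Π ωᵢ, and the mutation fixes with Kimura probability.  A fixed
mutation replaces Q and rebuilds the transition matrices.  Sampling for an
event's fitness evaluation does **not** collapse a gene's distribution; a
`collapse_on_sample` switch preserves the alternative reading.  Because all
genes in the standard panel are exchangeable and distributions are never
collapsed, the implementation propagates a single shared distribution row, an
exact optimization.  Trans fixation uses the same Kimura formula as cis
substitutions.  Q starts at its optimum (Q̃ = 2; U_Q = 1e-8, S_Q = 0.1; genes:
α = γ₀ = γ₁ = C = 1, σ = 10, λ = 1e-3, ε = 1e-3; v₀ = 1, 2, 5 for
l = 2, 5, 10).

Reported statistics: Q̄ (among-lineage mean of final Q, with Monte-Carlo SE)
and the sharing statistic — per gene, the fraction of lineages with
P₁ > 0.005; the median across genes, using the lower-middle element for even
counts so the value stays on the attainable lattice.

Problem sizes: the packaged experiments and acceptance checks run 10 lineages
per Nₑ cell over the half-decade grid 10²–10⁵ at full duration 10⁸ steps
(the event-driven design makes this cheap: expected events per lineage are
2NₑU_Q L, i.e. 2×10⁵ at Nₑ = 10⁵).  The qualitative claims verified: Q̄ is
non-monotone in Nₑ, with its minimum at Nₑ = 10⁴ under weak selection on Q
(σ_Q = 20) and at Nₑ ≤ 10³ under strong selection (σ_Q = 2); Q̄ is higher
under strong selection; sharing declines with duration, faster at large Nₑ
and small l.

## Phylogenetic simulation

Site panels draw ln α ~ N(0, 1), l ~ Uniform{0..10}, C ~ Exponential(mean
0.1), with γ₀ = γ₁ = 1, σ = 10, λ = 1e-3, ε = 1e-4 and Q = 1 held constant;
half the sites are neutral (flat fitness over v — the minimal operational
reading of "neutral"), half deleterious (stabilizing + toxicity as above).
l = 0 sites are purely nonspecific (v̂ := 0, β = Qε).  Root genotypes are
uniform over the 2^l allele configurations, i.e. v ~ Binomial(l, 1/2).  Along
each branch the chain starts from a point mass at the parent's value,
advances by Tᵗ, and a child value is sampled; tips report
f = β/(β+γ₁) > 0 (guaranteed by ε > 0; a 1e-300 floor guards the log for
pathological ε = 0 configurations).

The coleoid preset uses four tips (octopus, bimac, squid, cuttlefish) with
1 step = 1 year and the octopus–bimac split at 5 My; the deeper splits
(squid–cuttlefish 120 My, root 270 My) are synthetic placeholders chosen once
within commonly cited ranges and are user-overridable, as are Nₑ (default
10⁴) and μ₀₁ = μ₁₀ = 1e-9, which the underlying study conditions leave open.
Species are compared by Euclidean distance between log editing-level vectors.

Neighbor joining is implemented directly (Saitou–Nei Q-criterion) with a
deterministic lowest-index tie-break; negative branch lengths, which NJ can
produce on non-additive input, are retained.  scikit-bio's `nj` serves as an
independent cross-check in the tests, and NJ exactness on additive matrices
is verified on 100 random 4–8-taxon trees.  The default panel is 20,000 sites
(10,000 neutral + 10,000 deleterious); tests and examples use a few hundred
to a few thousand sites, which already show the right-skewed level
distributions (deleterious sites lower and more skewed than neutral) and
majority-of-seeds recovery of the species topology.

## Randomness and reproducibility

All stochastic components consume `numpy.random.Generator` streams derived
from a single seed through `SeedSequence` with stable named spawn keys
(`gpdiv.rng`), so lineages and sites can be computed in any order with
identical results, and identical seeds give bitwise-identical outputs.

## What the synthetic conditions do and do not show

The generators emulate the study conditions (parameter distributions, equal
additive cis effects, constant environment, free recombination implicit in
sequential fixation).  They do not emulate: unequal cis-locus effects, shared
cis-loci between genes, sequence-specific trans retargeting, within-population
polymorphism, or measurement noise in empirical editing calls.  Passing tests
therefore validate the evolutionary mechanism and its implementation, not the
fit of any particular empirical dataset.

## Known limitations

- Editing- and splicing-type levels are defined only for the named isoforms;
  systems with additional isoforms have no canonical f here.
- The coevolution simulator exposes only Q as the evolving trans parameter
  (the same machinery would apply to α, C, or ε).
- NJ negative branch lengths are reported as-is rather than clamped.
- Divergence times deeper than the octopus pair in the coleoid preset are
  placeholders, not estimates.
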