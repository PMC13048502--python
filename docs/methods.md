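# Methods

## Model and rescaling

The pipeline studies the generalized Lotka–Volterra (GLV) model for S
species.  Abundances are expressed as relative yields x_i = N_i/K_i and
interactions rescaled by self-regulation, A_ij = a_ij K_j/K_i, giving

    dx_i/dt = r_i x_i (1 − x_i + Σ_{j≠i} A_ij x_j).

Self-regulation is the explicit −x_i term; the stored interaction matrix
has an exactly zero diagonal and every consumer of A adds self-regulation
through the model equations, never through the matrix.  With time rescaled
by the growth rate, r drops out of all equilibrium quantities: x\* solves
the linear system (I − A\*) x = 1, and the Jacobian at an interior
equilibrium is J = diag(r x\*) (A\* − I), whose stability verdict is
invariant to positive rescaling of r.  Both facts are asserted in tests.

## Interaction ensembles

Off-diagonal coefficients are i.i.d. 𝒩(μ, σ) (second argument is always a
standard deviation) masked by independent Bernoulli(C) links.  The
connectivity mask is applied per directed entry by default, since A is
generally asymmetric; a paired-mask option ties the two directions of a
pair together, and is forced for the symmetric and antisymmetric
structures, whose defining invariants (A = Aᵀ exactly; centered
antisymmetry) a directed mask would break.  Structured variants:

- **symmetric / antisymmetric** — pairs drawn once; the antisymmetric
  ensemble uses correlation ρ = −1 of centered pairs, with general
  ρ ∈ [−1, 1] exposed for completeness.
- **triangular (nested)** — upper triangle random, lower triangle zero: a
  strict hierarchy in who affects whom, but not in interaction strength.
- **k_correlated** — Ã_ij = a_ij K_j/K_i with K ~ 𝒰[0.5, 1.5]: carrying
  capacity heterogeneity induces row/column correlations (large-K species
  impact others most and are impacted least).
- **crossfeeding** — B_ij = C_ij − 2γ_j/(γ_i + γ_j) − α_ij with
  consumption traits γ ~ 𝒰[0.3, 0.7] sorted in decreasing order (species
  order equals the competitive hierarchy), weak extra competition
  α ~ 𝒩(0.1, 0.01) drawn independently per directed pair, and
  cross-feeding C_ij ~ 𝒰[0, 1].

Positivity-constrained draws (growth rates ~ 𝒩(1, σ_r)) reject and redraw
non-positive values from the same seeded stream; this slightly truncates
the distribution (negligibly for σ_r ≲ 0.3).

## Simulation protocol

A replicate draws a fresh matrix and random initial conditions
x_i(0) ~ 𝒰[0, 1], integrates for Δt₁ = 3000 time units with scipy's
adaptive RK45, then a further Δt₂ = 100, and accepts the state as
stationary when every surviving abundance changed by less than 10⁻³
(relative, with the extinction threshold as a floor) across the window.
A duration stated as a step count would be ambiguous for an adaptive
solver, so Δt₁ and Δt₂ are defined in model-time units with r = 1 setting
the clock.
Species falling below the extinction threshold 10⁻⁶ are hard-zeroed
(abundance and dynamics) at segment boundaries of at most 100 time units —
the solver cannot modify state mid-run, so extinction acts between
segments.  The threshold sits far below any feasible equilibrium at the
parameter ranges studied and far above integrator tolerance (rtol 10⁻⁸,
atol 10⁻¹⁰).  Abundances exceeding 10⁶ flag the run as diverged (the
mutualistic outgrowth regime has no finite attractor); diverged and
bounded-but-non-stationary runs count toward totals but never toward EC
tallies.

The complementary subset-sampling route draws uniform random species
subsets from a pool, keeps those that are feasible (all x\* > 0) and
linearly stable, and measures their statistics.  Stability requires
max Re(λ) < −10⁻⁹; spectra within 10⁻⁹ of zero are reported marginal and
rejected, so neutral directions born of floating-point noise are never
accepted.  Dynamics-found survivor sets are verified to be a subset of the
feasible+stable subsets by exhaustive enumeration on small pools.

## EC detection and analytic boundaries

A pair is *excluding* when A\*_ij < −1 or A\*_ji < −1, strictly: a
coefficient exactly at −1 is not exclusionary (measure-zero under
continuous sampling; deterministic tie-break).  An EC state requires
S\* ≥ 3 — one survivor has no interactions and a stable pair cannot be
exclusionary.

With Φ the standard normal CDF and p = Φ(−(1+μ)/σ), the pool contains an
exclusionary element with probability 1 − (1−p)^{S(S−1)}, whose sharp 0→1
transition in σ gives the boundary σ₁c(μ) (σ₁c → 0 as μ → −1).  A
mutually-coexisting pair (needed to sustain an excluded third species)
exists with probability 1 − (1−q)^{S(S−1)/2}, q = (1−p)²; for μ < −1 this
rises from 0 to 1 with σ and its crossing defines σ₂c(μ), separating
competitive exclusion from the EC regime.  Both crossings are located by
bisection at level 0.5 by default (the transitions are sharp at S = 80, so
the level matters little; 0.05/0.95 are exposed in config).

The maximum-fraction envelope merges two estimates at each (μ, σ): the
largest stable diversity S\*_max, and the pool fraction of excluding pairs
f_max = 1 − q, under the assumption that surviving communities are no more
competitive than their pool (documented heuristic; rare exceedances are
expected and the tests tolerate < 5%).  S\*_max is isolated behind one
swap-point function.  Its default treats stable states in the
strong-competition multistability regime as near-cliques of the
pairwise-coexistence graph: with pair-coexistence probability q, the
clique number of an Erdős–Rényi graph on S vertices concentrates at
2·ln S / ln(1/q), rounded to the nearest integer and capped at S.  At
S = 80 this gives a decaying envelope with f_max ≈ 0.97 at S\*_max = 3 and
≈ 0.60 at S\*_max = 10 — the quantity the acceptance script reports.  EC
states themselves are perturbations of such cliques that do contain
excluding pairs, so the estimate is a maximum-richness scale, not a claim
that stable states are exactly clique-shaped.

## Stability diagnostics

The May-type random-matrix threshold is implemented as
μ_c = √(S\*/2)·σ\* − 1, the bulk condition σ\*√(S\*/2) < 1 + μ\*
rearranged: a community is expected unstable when its mean interaction is
more negative than μ_c, and the threshold rises with diversity and
heterogeneity.  Moderate-size sampled communities routinely remain stable
below it, which is the observation the diagnostic exists to expose.  A
literal linear variant ((S\*/2)·σ\* − 1) is selectable.  Characteristic
polynomial coefficients C₁…C_{S\*} are computed from the Jacobian spectrum
(elementary symmetric polynomials), numerically robust at the community
sizes considered (S\* ≤ 15), and the second Routh–Hurwitz condition
Λ₂ = C₁C₂ − C₃ > 0 is asserted for every accepted community.  The
Jacobian uses the derived signs J_ij = r_i x\*_i A\*_ij (i ≠ j),
J_ii = −r_i x\*_i; a sign-flipped variant is kept behind a flag for
comparison only.

## Collectivity and condition number

φ is the spectral radius of A\*; the Neumann expansion of net effects
converges iff φ < 1 (asserted at tolerance 10⁻⁶ by order 200 for φ ≤ 0.9,
with divergence detected past 1).  The random-matrix estimate
φ̂ = max{(S\*−1)|μ\*|, √(S\*−1)·σ\*} uses circular-law scaling for the
noise term (a linear-in-S\* variant is selectable); it is exact for
uniform matrices and within ~15% of measured φ at S\* ≥ 20.

κ defaults to the condition number of I − A\* — the operator actually
inverted to obtain net effects — with κ(A\*) selectable and both reported
in the community table.  A numerically singular target reports κ = ∞
rather than raising.  The Monte-Carlo lower-envelope for κ at fixed S\*
samples EC-compatible ensembles and takes the smallest observed κ; it is a
calibratable stand-in to be replaced by a closed form.

### Measurement-error experiment

Stable communities with κ(I−A\*) within ±20% of a target are selected;
each replicate perturbs every directed off-diagonal coefficient with
multiplicative Gaussian noise of relative sd 0.1 ("10% measurement
error"; zero entries stay zero, additive noise is a flag), recomputes
feasibility and linear stability from the perturbed matrix, and scores a
success when the perturbed matrix still predicts coexistence of the full
set (true by construction).  The success-vs-κ curve is monotonically
decreasing — the error-amplification mechanism — with roughly 90% success
at κ ≈ 5 and 58% at κ ≈ 20 under this protocol.  Alternative scorers
(precision over predicted-coexisting sets, dynamical truth from random
initial conditions, pool-level composition matching, uninvadability) were
explored and span 0–95% at the same κ; the scorer is pluggable because
the success notion, not the noise, dominates the absolute level.  Only
the community-level default is asserted in tests.

### Assembly from pairs

Random species sets whose every pair coexists in isolation (no coefficient
below −1 between members) are tested for full-set feasibility and
stability, binned by the set's φ.  Success declines with φ: pairwise
coexistence stops predicting community coexistence as collectivity grows.

## Intransitivity

Each excluding pair defines a contest; the excluded species loses.  For
bistable pairs (both directions exclusionary) the model has no co-culture
winner, so orientation is an explicit rule: the default lets the
larger-magnitude coefficient win (the harder-hit species loses; exact ties
go to the lower index), and an `unoriented` rule drops such pairs from
rank/LRE counts while keeping them as triplet members — a sensitivity
axis, not a guess.  Rank is (wins − losses)/(S\*−1), reading "total
interactions" as each species' possible contests; LRE counts edges whose
winner has strictly lower rank (ties are not upsets), with the corrected
variant defined only for communities with ≥ 4 exclusions.  RPS is the
fraction of fully-excluding trios forming a directed 3-cycle; 2 of the 8
orientations of a trio are cyclic, so the null is exactly 0.25.  Scan
summaries report per-community means plus pooled (count-level) fractions;
single communities contribute few triplets, so pooled counts are the
low-variance estimator used in the ordering assertions.  The reshuffled
control permutes the off-diagonal elements of each found random A\*
without re-imposing stability, as a metric control.

## Scale of the shipped runs

The analysis drivers and tests run the full study conditions (S = 80
pools, the (μ, σ) ranges μ ∈ (−2, 0.5), σ ∈ (0, 1)) at reduced budgets
chosen for desk-scale runs: coarser grids (e.g. 6×5 cells at 20 systems
instead of 26×21 at 100) and subset budgets of ~10⁵ per scan instead of
10⁷ per size.  All assertions are statistical or qualitative at those
budgets; the budgets are single config knobs for full-scale runs.

## Known limitations

- The synthetic ensembles emulate the statistical structure of inferred
  microbial interaction matrices (dense, heterogeneous, near-random), not
  any specific empirical community; passing tests show the model's internal
  mechanisms, not that a given real community behaves this way.
- The maximum-diversity estimate and the κ lower envelope are heuristics
  behind swap points; both reproduce qualitative envelopes, not exact
  frontiers.
- Limit cycles and chaotic attractors are labeled non-stationary and
  excluded from EC counting; no global-stability or permanence analysis is
  attempted.
- The measurement-error success levels depend strongly on the pluggable
  scoring protocol (see above); the monotone κ-dependence is the robust
  statement.
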