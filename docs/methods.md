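# Methods

## Model

A gene network is the linear time-invariant triple (A, B, C): state
(kryptotype) κ̇ = Aκ + Bu from κ(0) = 0, phenotype φ = Cκ.  All evolutionary
statements are made about the impulse response h(t) = C e^{At} B, which
determines the response to *every* input by convolution.  The modelling
assumptions inherited from this choice: dynamics are linear (no saturation,
no multiplicative regulation), time-invariant, noise-free, and selection
sees only the input–output map, never the internal state.

Units: entries of A are inverse time; time is measured in units where the
worked oscillator has period 2π.  B and C are dimensionless couplings.

## Phenotypic equivalence

Equality of h(t) for all t ≥ 0 is decided through Markov parameters
C A^k B, k = 0 … n₁+n₂−1.  By Cayley–Hamilton, every higher power of either
A is a linear combination of the first n powers, so agreement of the first
n₁+n₂ parameters implies agreement of both exponential series — the finite
certificate is exact.  Numerically the comparison is relative to the
largest parameter magnitude with tolerance 1e−8 (a single package-wide
constant); the paper-scale fixtures have parameter magnitudes O(1), so this
cleanly separates true equivalence (discrepancies ≲ 1e−12 from round-off)
from a 1e−3 coefficient perturbation (discrepancy ≈ 1e−3).

## Kalman decomposition

Reachable subspace: column span of [B, AB, …, A^{n−1}B]; unobservable
subspace: null space of the stacked [C; CA; …; CA^{n−1}].  Both bases come
from SVDs with singular values below `rank_tol` (default 1e−9) times the
largest treated as zero; values within a factor 10 of the threshold set an
"ambiguous rank" warning on the result rather than failing.  The four
classes are assembled as: block 1 = reachable ∩ unobservable (null space of
the two stacked orthogonal projectors, judged against an *absolute*
threshold √rank_tol since projector singular values are sines of principal
angles), block 2 = orthogonal complement of block 1 within the reachable
subspace, block 3 = its complement within the unobservable subspace,
block 4 = the complement of the union.  Orthonormal bases throughout keep
the change of basis P well conditioned.  Block order
(reachable-unobservable, reachable-observable, unreachable-unobservable,
unreachable-observable); the staircase zero pattern — A maps each invariant
subspace into itself, B lies in the reachable blocks, C vanishes on the
unobservable ones — follows automatically from these invariances and is
asserted in tests to 1e−8 relative.  The reachable-observable block is the
minimal realization; its dimension is independently checked against the
rank of the block-Hankel matrix H[i,j] = C A^{i+j} B.  A system with zero
phenotype (empty minimal block) is represented by a one-dimensional zero
system rather than an empty one.

`pad_nonminimal` inverts the decomposition: extra dimensions are placed in
the three phenotypically inert classes, couplings drawn uniform on [−1, 1]
only in blocks the staircase pattern leaves free, and the result optionally
conjugated by a random orthogonal matrix.  This yields arbitrarily large
networks with exactly the original impulse response.

## Neutral tangent and degrees of freedom

Infinitesimal changes of basis V = I + εZ move the system along
(ZA−AZ, ZB, −CZ) with no first-order phenotype change.  Constraint modes
restrict Z: `fixed_BC` solves {ZB = 0, CZ = 0} as the null space of
stacked Kronecker constraint matrices; the reported dimension is the rank
of the induced generator triples.

A point worth flagging: counting the constraints naively — nm from ZB = 0
plus ln from CZ = 0 — suggests a generic dimension of n(n−l−m).  That
count is wrong: the l·m functionals Z ↦ cᵢᵀ Z bⱼ belong to both constraint
sets, so only n(m+l) − lm constraints are independent and the generic
dimension is (n−m)(n−l) = n(n−l−m) + lm.  Two independent computations
agree: the null-space dimension of the stacked constraints, and the null
space of the Jacobian of the full Markov-parameter map (which never
mentions conjugation).  The two-gene oscillator is the smallest witness:
its fixed-B,C equivalent family is genuinely one-dimensional — the family
A(τ) — matching (2−1)(2−1) = 1, while the naive count gives 0.
`generic_tangent_dimension` returns the corrected value; the computed
per-system dimension is always authoritative.

First-order neutrality is verified behaviourally: stepping ε along any
generator moves the distance-to-optimum with log-log slope 2.  The slope is
fitted on ε ∈ {3e−2, 1e−2, 3e−3, 1e−3}; smaller steps would push D² below
the double-precision floor of the integral (D ≈ 1e−8 gives D² ≈ 1e−16) and
measure only round-off.

## The oscillator family A(τ)

A(τ) = (1/(τ+1)) [[τ, 1], [−(2τ(τ+1)+1), −τ]], τ ≠ −1, with the
oscillator's B = (1,1)ᵀ and C = (1,0).  It is derived as V A(0) V⁻¹ for
V = [[1, 0], [−τ, τ+1]], the general invertible V with VB = B and CV = C,
and is verified three ways in tests: A(0) is the base oscillator, every
member is certificate-equivalent to A(0) with trace 0 and determinant 1,
and the F1 of A(0) × A(−2) has impulse response e^t.

## Genetics

Default architecture: one nonrecombining, unlinked locus per entry of A;
B and C genetically invariant (multi-coefficient loci express cis linkage
of a promoter row, and loci on B/C addresses are accepted).  A diploid
expresses the coefficient-wise *average* of its two haplotypes.  Meiosis
draws one allele per locus independently with probability 1/2.  F2
enumeration: with L loci, the 3^L per-locus states (homozygous-parent-1,
heterozygous, homozygous-parent-2) carry Mendelian product weights
(1/4, 1/2, 1/4)^L by default; uniform class weights are stored alongside
because averaging conventions differ between uses — means reported by the
breakdown and drift experiments use Mendelian weights.

X linkage: males are hemizygous, carrying a single maternal allele at X
loci, expressed with weight dosage/2 (default dosage = 2, equalizing a
hemizygote with a homozygote, as under Drosophila-style dosage
compensation).  Chromosome assignment is per coefficient address, so the
column-on-X layout used in the Haldane experiments coexists with row-linked
(cis) loci; the package does not impose either convention.

Genetic distance between systems is the Frobenius distance between A
matrices (B, C optionally included, off by default).

## Distance to optimum

D(h) = (∫ ρ(t) ‖h(t) − h₀(t)‖² dt)^{1/2}, ρ(t) = e^{−σt}, σ = 1/(4π) by
default so fitness reflects a few multiples of 2π of dynamics.  All
methods operate on the augmented system (block-diagonal A, stacked B,
differenced C) whose impulse response is h − h₀, shifted by σ/2:

- **lyapunov** (unbounded horizon): observability Gramian from the
  continuous-time Lyapunov equation; requires the shifted matrix to be
  Hurwitz.  A non-Hurwitz shifted matrix means the integral diverges:
  policy `infinite` returns +inf (the default — a hybrid whose expression
  explodes has no finite distance), policy `truncate` falls back to the
  truncated functional.
- **gramian** (finite horizon, default when a horizon is set): Van Loan's
  finite-horizon Gramian from one block matrix exponential, with interval
  doubling W(2t) = W(t) + e^{A'ᵗ}W(t)e^{At} so long horizons and unstable
  systems stay well-scaled.  Exact to matrix-exponential accuracy and
  roughly two orders of magnitude faster than quadrature, which is what
  makes the 81-genotype F2 sweeps and the drift experiments cheap; this is
  the package's deliberate numerical choice for truncated horizons, with
  adaptive quadrature retained as the independent reference.
- **quadrature**: adaptive integration of the integrand (abs/rel tolerance
  1e−10), including over [0, ∞).  Used as the cross-check oracle; the three
  methods agree to better than 1e−10 relative on stable fixtures.

Default truncation horizon 40π (weight e^{−10} at the end), used by the
figure-style experiments because moderately diverged F2 hybrids are often
exponentially unstable and have no unbounded-horizon distance; the fraction
of divergent (non-Hurwitz) hybrids is reported next to every mean so
truncation effects stay visible.  Scaling-exponent fits use ε ≤ 3e−2,
where no hybrid is divergent and the slopes are horizon-independent.

## Drift

The neutral walk lives in the symmetry group, not in coefficient space:
the constrained generator algebra {Z} gets an orthonormal (Frobenius)
basis, per-generation increments ξ ~ N(0, V_G/N_e) per direction accumulate
into coordinates s_t, and the population mean at t is the conjugation of
the ancestor by exp(Z(s_t)).  Because conjugation by any V with those
constraints is an exact symmetry of h, every visited system is *exactly*
equivalent to the ancestor — no tangent-step-plus-projection error — and
each coordinate is an exact Gaussian random walk with Var(s_t) = t V_G/N_e
(the accumulated coordinate formulation, rather than composing
per-generation exponentials, is what makes this exact for multi-dimensional
algebras too; for the one-dimensional oscillator algebra the two coincide).
V_G is interpreted as additive variance per neutral direction, so total
displacement variance scales with the algebra dimension.  Populations are
summarized by their mean as homozygous idealizations; segregating
within-population variation is not simulated.

The divergence experiment evolves independent lineage pairs, treats each
mean as a homozygous parent at each checkpoint, builds F1/F2 hybrids and
scores them with the truncated-horizon distance; fitness is the locally
quadratic w = max(0, 1 − cD²), c = 1 by default (an explicit modelling
constant, configurable).  Study conditions for the clock experiment:
V_G = 1e−3, N_e = 1000, checkpoints up to t = 320, 120 replicate pairs —
chosen so the final between-lineage displacement (sd ≈ 0.025) stays inside
the ε ≲ 3e−2 window where F2 distance is linear in displacement; with
larger displacement the exponentially divergent tail of hybrids makes mean
D² superlinear in t, which is a real feature of the model (breakdown
accelerates), not of the estimator.  Variance-law checks use 2000
replicate walks and compare at t ∈ {100, 1000} within three standard
errors of the sample variance.

## Synthetic data

There are no external datasets: all fixtures are built in code — the
two-gene oscillator and its family, randomized non-minimal paddings, and
Gaussian random systems (optionally spectrally shifted to a stability
margin for distance fixtures).  These emulate the desk-scale worked
networks of the theory; they do not emulate real expression data (no noise,
no nonlinearity, no measured coefficients), so passing tests validate the
mathematics and the implementation, not the biological calibration of any
parameter.

## Numerical choices and limitations

- Matrix exponentials via SciPy's scaling-and-squaring Padé `expm`
  (relative accuracy far beyond the 1e−10 target for the n ≤ 50 dense
  matrices used here).
- Coordinate changes reject reciprocal condition numbers below 1e−12.
- Simulation integrates the ODE with DOP853 at rtol 1e−9; delta inputs are
  represented by unit-mass rectangular pulses (default width 1e−3), and
  the pulse response converges to h as the width shrinks.
- Rank decisions: relative tolerance 1e−9 on singular values, absolute
  √rank_tol for subspace intersections/complements; ambiguity within a
  factor 10 of a threshold is surfaced as a warning, not an error.
- Time grids default to 400 points on [0, 4π] (two oscillator periods).
- Limitations: no nonlinear/sigmoid dynamics, no stochastic dynamics, no
  time-varying coefficients, no recombination fractions between linked
  loci, no mutation or segregating within-population variation, no
  dimension-changing evolutionary moves beyond static padding, and no
  empirically calibrated fitness scale.
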