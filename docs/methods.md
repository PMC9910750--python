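# Methods

## The model

A recurrent network of N neurons stores P activity patterns
X\* ∈ 𝒳^{P×N} through a noisy, rectified Hebbian learning rule.  The
noise-free Hebbian signal is the pattern correlation matrix at the
spiked-Wigner scale,

    W = X*ᵀ X* / √N ,

and the observed connectivity is

    J_ij = max(0, W_ij − τ + ζ_ij),       ζ_ij = ζ_ji ~ N(0, ν²),

so J is symmetric, non-negative and sparse (connection probability
p_C = erfc(τ/√2ν)/2).  The diagonal is unobserved and stored as zero.
The 1/√N scaling places the problem exactly at the regime where
recovering the N entries of a pattern from the O(N²) weights is neither
trivial nor impossible; with O(1) noise it is the only scaling for which
the signal and noise contributions to the score field below are of the
same order, and it is enforced empirically by the algorithm↔theory
agreement tests.

Pattern components are i.i.d. from one of three zero-mean priors:

| family      | support          | weights            | m2 = ⟨x²⟩ | ⟨x³⟩            |
|-------------|------------------|--------------------|-----------|-----------------|
| binary      | {−1, +1}         | ½, ½               | 1         | 0               |
| sparse      | {−1, 0, +1}      | ρ/2, 1−ρ, ρ/2      | ρ         | 0               |
| low_coding  | {−ρ, 1−ρ}        | 1−ρ, ρ             | ρ(1−ρ)    | ρ(1−ρ)(1−2ρ)    |

ρ is the coding level: the probability that a neuron is active in a
pattern (low_coding) or the fraction of non-zero components (sparse).

## Channel, score and effective noise

Conditional on the signal w, a weight follows a mixed law: an atom
P(J=0|w) = erfc((w−τ)/√2ν)/2 plus a Gaussian density with mean w−τ and
scale ν on J>0.  Two derived objects drive everything downstream:

* **Fisher score** S_ij = ∂_w log P_out(J_ij|w)|₀, i.e. (J_ij+τ)/ν² on
  present synapses and the negative constant
  −√(2/π)·e^{−τ²/2ν²}/(ν·erfc(−τ/√2ν)) on absent ones.  E[S|w=0] = 0,
  which is what centres the message-passing fields (checked by
  quadrature).
* **Effective noise** Δ, with 1/Δ = E[S²] under the null channel.  Our
  closed-form reduction is

      1/Δ = e^{−τ²/ν²} / (π ν² erfc(−τ/√2ν))            (atom)
          + τ e^{−τ²/2ν²} / (√2π ν³) + erfc(τ/√2ν)/2ν²   (positive part)

  verified against direct quadrature of the defining integral to 1e−8.
  (The atom term is easy to get wrong by a factor of two through an
  erfc-convention slip; the defining integral is treated as authoritative
  and the tests pin the agreement.)  At τ=0, Δ = ν²/(1/2+1/π), which
  gives the exact inversion used
  to parameterise experiments by Δ.  At τ>0, Δ(ν) is non-monotone —
  adding synaptic noise can *enable* recovery (stochastic resonance), so
  root-finding for ν at a target Δ brackets every sign change on a
  geometric grid (up to two roots).

## Reconstruction: Low-RAMP

The posterior over per-neuron tuning curves x_i ∈ R^P is approximated by
iterated Gaussian cavity fields

    b_i = (1/√N) Σ_k S_ki x̂_k − [(1/N) Σ_k S²_ki σ_k] x̂_i^{t−1}
    A_i = (1/N) Σ_k S²_ki x̂_k x̂_kᵀ

followed by the prior's threshold function (x̂_i, σ_i) = (f, ∂_b f) of the
tilted distribution p(x) ∝ p_X(x) exp(b·x − x'Ax/2).  The second term of
b_i is the Onsager memory correction; a regression test asserts that
removing it breaks the agreement with state evolution.  All tilted-
distribution normalisations are computed in log space: b grows like m/Δ
and overflows naive exponentials at low noise.

Two threshold modes:

* **exact** — enumeration over support^P (capped at P ≤ 20 for two-point
  supports, P ≤ 12 for the three-point sparse support, keeping the worst
  case well under a second); covariance by analytic differentiation, not
  finite differences, since it feeds back into every iteration.
* **meanfield** — a factorised tilt with per-component quadratic terms
  a_j = A_jj.  The off-diagonal couplings A_{jq} are *not* discarded:
  with a strictly diagonal tilt the P pattern slots decouple into
  independent rank-1 recursions that all condense onto the same pattern
  and the capacity experiment cannot work.  They enter as a single
  effective field b̃_j = b_j − Σ_{q≠j} Ā_{jq} x̂_q^t evaluated at the
  current estimates, with Ā the self-averaged coupling (S² replaced by
  its mean).  Solving this self-consistency to convergence *within* one
  step is unstable — it breaks symmetry spuriously into saturated
  spin-glass states — so exactly one sweep per AMP iteration is used,
  tied to the algorithmic time index.  At P = 1 the two modes coincide
  to machine precision.

Defaults: random initialisation is a draw from the prior (its O(1/√N)
accidental overlap is the finite-N realisation of the infinitesimal seed
the theory assumes); convergence when the mean squared update per neuron
falls below ε = 1e−8; max 200 iterations; no damping.  Damping
x̂ ← (1−η)x̂_new + ηx̂_old is available and needed in one place: the
many-pattern mean-field runs (P ≳ 10), whose time-lagged slot couplings
otherwise oscillate — capacity scans default to η = 0.3.

**Restarts.** For the skewed low-coding prior, a random start whose
accidental overlap is negative can fall into an anti-correlated
transient that never converges (the asymptotic theory perturbs the zero
state positively and never sees this).  `restarts=k` re-draws the
initialisation up to k times when an attempt fails to converge; default
off.

**Evaluation.**  The posterior is invariant under pattern permutations,
and under per-pattern sign flips for sign-symmetric priors, so errors
are reported after greedy maximum-|overlap| matching (ties by lowest
index; signs only for sign-symmetric priors).  The mean squared error
(1/N)Σ_i‖x̂_i−x*_i‖² is optionally normalized by P·m2, making the
trivial estimate score 1 for every prior.

## State evolution

For uncorrelated patterns the overlap matrix stays ∝ I_P, and AMP's
N→∞ behaviour reduces to one scalar recursion

    m^{t+1} = E_{x0,z}[ f(m/Δ, (m/Δ)x0 + √(m/Δ)z) · x0 ].

The implementation evaluates this generic form for every prior — the
support sum exactly, the z-integral by 201-node Gauss–Hermite quadrature
(overkill by design; doubling the nodes changes results by <1e−9, and
scipy's rule is used because numpy's overflows above ~380 nodes).  The
per-family closed forms serve as independent test oracles only, because
two of their printed renderings are corrupted; the generic route plus
the linearisation m' ≈ (m2²/Δ)m is the arbiter.  Consequences of the
linearisation: the trivial fixed point m=0 destabilises at

    Δ_c = m2²  =  1 (binary),  ρ² (sparse),  ρ²(1−ρ)² (low coding).

Fixed-point iteration runs from m0 = δ·m2 ("random", δ=1e−6) or
m0 = (1−δ)·m2 ("informed"); normalized mse = (m2−m_fixed)/m2.
Divergence of the two branches over a Δ window is the hard-phase
signature (present for sparse ρ=0.05 and for low-coding ρ below the
critical coding level).

**Hard-phase criterion.**  A zero-mean prior with ⟨x³⟩² > 2⟨x²⟩³
produces a first-order transition and hence a hard phase.  For the
low-coding prior the exact moments reduce the equality to
6ρ²−6ρ+1 = 0, i.e. ρ_c = 1/2 − 1/√12 ≈ 0.2113, with the criterion
holding for ρ < ρ_c: *sparser codes are the hard ones*.  This matches
the state-evolution branch computations in the test suite (a gap window
exists for ρ = 0.1 and ρ = 0.05-sparse, none for ρ = 0.3).

## Spectral baselines

PCA takes the top-P eigenvectors of either J or S, rescaled to squared
norm N (the length of a binary pattern) with a deterministic sign.  The
rectified channel has a positive mean weight, so raw J carries a Perron
component ≈ E[J]·11ᵀ with an O(N) eigenvalue that hides the pattern
spike; PCA on connectivity therefore subtracts the mean off-diagonal
entry by default.  The score matrix is already centred.  In the
high-noise limit the rescaled leading eigenvector is an uninformative
unit-sphere vector and the raw error tends to 1+m2 (2, 1+ρ, 1+ρ(1−ρ)).
For P>1 the leading subspace is returned without undoing the rotational
ambiguity of the Hebbian outer product.

## Capacity experiments

At Δ = 0.2Δ_c (τ=0, ν from the exact inversion) and fixed N, the scan
runs 20 mean-field reconstructions per P from random starts; a run
succeeds if its aligned per-pattern error is below 0.2·m2 (20% of the
trivial error).  P_crit is the largest P with ≥ half the runs
successful; the scan proceeds by unit steps (after an optional doubling
phase far below the transition) and stops after 5 consecutive
sub-majority values past the last success.  Per-run seeds derive from
`SeedSequence(seed, spawn_key=(N, P, run))`, so any sub-scan reproduces
the full scan's numbers.  The exponent experiment repeats the scan over
several N and fits log P_crit against log N by least squares; exponents
are sensitive to the noise level, and the full large-N measurement is a
long-running study — the default suite exercises the complete code path
at reduced N and validates the fit on exact synthetic power laws.

## What the generator does and does not emulate

The synthetic model realises exactly the assumptions the theory makes:
i.i.d. patterns, exact symmetry, Gaussian noise, known (τ, ν, P, ρ).
Real connectomes break all of these to some degree — correlated and
non-binary patterns, asymmetric and sign-mixed synapses, unknown
hyper-parameters, measurement noise that is not additive Gaussian.
Passing tests therefore demonstrate correctness of the algorithm and its
theory under the generative model, not performance on measured wiring
diagrams.

## Numerical choices and limitations

* Problem sizes: algorithm↔theory agreement is checked at N=5000 (P=1),
  the capacity experiment at N=1000 with 20 runs per P — the sizes at
  which the reference results are stated.
* Near the transition (Δ ≳ 0.9Δ_c) single runs wander around the weakly
  attracting fixed point; comparisons there use the median of a few
  seeds.
* The skewed low-coding prior at ρ=0.3 close to Δ_c is strongly
  non-self-averaging at N=5000: even informed starts hold the
  informative fixed point only on some instances, and random starts are
  often captured by the anti-correlated transient (hence the restart
  mechanism).  ρ=0.3 lies near the tricritical coding level 0.2113,
  where the informative basin is shallow; comparisons at that point are
  medians over seeds and carry much larger instance-to-instance spread
  than the rest of the grid.
* `J_ij = 0` iff the pre-activation is ≤ 0 (ties rectify to zero).
* Root searches in ν bracket on 400-point geometric grids because Δ(ν)
  is non-monotone at τ>0.
* Rank P is assumed known; hyper-parameter learning (e.g. by expectation
  maximisation), asymmetric or inhibitory connectivity, extensive-rank
  P ~ O(N), and retrieval through network dynamics are out of scope.
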