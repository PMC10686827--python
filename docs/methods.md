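# Methods

`bbdiff` implements the generative machinery of a programmable
denoising-diffusion model for protein backbones: a polymer-structured
Gaussian prior, a correlated forward/reverse diffusion with low-temperature
sampling, a sub-quadratic random-graph denoiser with consensus structure
synthesis, and a composable conditioner framework. This note records the
model, the defaults and why they were chosen, and what the synthetic-data
regime does and does not demonstrate.

## The polymer prior

The prior over a length-N CA trace is a correlated Gaussian built from two
constraints that collapsed polymers satisfy:

* **chain correlation** — coordinates follow a discrete random walk
  (cumulative sum of i.i.d. steps) with the centroid removed, so adjacent
  residues are far more correlated than distant ones;
* **radius-of-gyration scaling** — the walk step δ is set per length from the
  closed form E[Rg²]_walk = δ²(N²−1)/(6N) per spatial dimension so that the
  3-D ensemble satisfies E[Rg²] = r0²·N^(2ν) exactly in expectation.

Defaults are r0 = 2.0 Å and ν = 0.4, the standard globular-protein scaling
regime; both are configurable, and the tests assert self-consistency with
whatever values are set rather than these constants. An optional independent
centroid mode of standard deviation `centroid_sigma` (default 0) models the
global translation; with it at 0 the centroid lies outside the modeled
subspace and whitening maps it to zero.

The latent map is exactly invertible in O(N): cumulative sums forward, first
differences backward. The first latent coordinate is excluded from the walk
(the centered walk is mathematically independent of it) and reserved for the
centroid mode, which also keeps the map well conditioned when
`centroid_sigma` is small. One consequence of centroid removal worth knowing:
row-averaged correlation decreases monotonically with sequence separation out
to about half the chain and then rises slightly for the most distant pairs,
which are coupled through the centering. Chain locality (adjacent ≫ distant
covariance) always holds.

The prior is defined over CA coordinates only. N, C and O are rebuilt
deterministically from the CA trace by an idealized peptide-geometry
construction (N–CA 1.46 Å, CA–C 1.52 Å, N-CA-C 111°, carbonyl O placed off
the C atom), which is equivariant and never degenerate, even on straight
segments. This realizes the rigid-residue-noise idea — the non-CA atoms carry
no independent degrees of freedom during diffusion — at the cost of ideal
(not learned) local geometry in outputs.

## Diffusion and low-temperature sampling

Diffusion runs in the prior's whitened space, where it is the textbook
variance-preserving process z_t = α(t) z₀ + σ(t) ε with α² + σ² = 1. The
schedule makes the log signal-to-noise ratio linear in t between +10 and −10
(natural-log units) — a smooth, common choice; both endpoints are
configurable. The coordinate-space process is the image of the whitened one
under unwhitening, which makes every standard identity (score conversion,
marginal variances) hold exactly and cheaply testable.

The reverse integrator is Euler–Maruyama on a uniform t-grid from 1 down to
1/n_steps, followed by one terminal denoise. Low-temperature sampling
multiplies the score by an inverse temperature λ ≥ 1 in both the predictor
and the ψ Langevin corrector sub-steps run after each grid step. The
corrector's stationary law at fixed t is p_t^λ, so with corrector
equilibration the sampler lands on the tempered target — for Gaussian data,
N(μ, Σ/λ), which the test suite verifies against the analytic optimal
denoiser at λ = 1 (5% band) and λ = 4 (10% band). The corrector step size is
chosen by the signal-to-noise rule ε = 2(r‖ξ‖/(λ‖s‖))² with r = 0.25; the
r² λ-bias this induces on the stationary variance is below the tested
tolerances. λ = 1, ψ = 0 reduces exactly to standard ancestral sampling.

Soft conditioner gradients are added to the score after scaling by α(t)².
They are statements about the clean structure; annealing them in with the
signal amplitude keeps the high-noise regime stable (un-annealed penalty
gradients, amplified through the prior's cumulative-sum adjoint, can blow up
the whitened integration) and delivers full constraint strength as t → 0.

## The graph denoiser and consensus synthesis

The denoiser is built around a sparse geometry graph with a constant per-node
edge budget: chain neighbours (always present), the k_local nearest spatial
neighbours (default 8, chain neighbours counted inside the budget), and
k_random long-range edges (default 4) sampled without replacement with
probability ∝ distance^(−p), p = 2 by default. The total edge count — what
message passing and consensus cost scale with — is therefore strictly linear
in N; the tests assert the doubling ratio stays within ±20% of 2 across
N = 100…800. Candidate weighting scans each node's distance row, so graph
*construction* is quadratic at desk scale; distances are rounded to 1e-6 Å
before ranking and sampling so the graph is reproducible under global rigid
motions of the input. The graph is resampled at every denoiser call, keyed
deterministically by (model seed, t).

Per edge (i, j), the regressor predicts the clean position of CA_j in residue
i's local frame. Features (noisy local position, sequence separation, noise
level) are all rigid-motion invariant and predictions live in local frames,
so the full denoiser is SE(3)-equivariant by construction (verified to
1e-3 Å; in practice it holds to float precision). The regressor is linear in
a tensor-product basis: signed sequence-separation buckets (exact offsets to
±8, where local secondary-structure geometry is deterministic per offset,
then coarse bins) × a noise-level embedding (1, σ, σ², α) × (noisy local
position, 1). Training minimizes the per-edge squared error by streaming
ridge regression — normal equations accumulated over minibatches of noised
structures and re-solved each epoch. The logged epoch loss is evaluated on
each epoch's fresh draws *before* the update, so it is a running held-out
estimate; it is not forced to decrease monotonically, only the first-to-last
drop is asserted. Confidence weights for consensus are inverse residual
variances per (separation bucket, noise bin), calibrated on the final
epoch's residuals.

A deliberately small model: a few hundred parameters, closed-form training in
seconds on one CPU. It learns local geometry statistics (exactly what the
helix-dominated synthetic regime contains) rather than tertiary folding
rules; at t = 0.2 it beats the identity baseline on held-out structures by
shrinkage toward learned per-separation geometry plus consensus averaging.

Consensus synthesis solves for global coordinates given the per-edge local
predictions by alternating two closed-form half-steps of one objective
Σ w‖x_j − x_i − R_i r_ij‖²: (a) each node's rotation is the weighted Kabsch
fit of its predicted offsets onto current displacements; (b) with rotations
fixed, positions solve the sparse weighted-Laplacian least-squares system
(node 0 grounded to fix the translation gauge, solution recentered). Both
half-steps decrease the objective; on noiseless self-consistent inputs the
truth is the global optimum and is recovered from random initialization to
< 1e-2 Å (observed: ~1e-7 Å). A per-node Jacobi update was tried first and
diverges — long-range edges amplify frame errors through their lever arms —
which is why the position half-step is a joint solve.

## Conditioners

Each conditioner may contribute a hard transform (applied after every
predictor/corrector update; idempotent) and/or a soft energy or classifier
log-probability (gradient added to the score before every update).
Composition applies hard transforms in list order and sums energies.

* **Symmetry** — the hard transform pulls every subunit back through its
  group element, averages, and re-tessellates: the orthogonal projection onto
  the G-invariant subspace. Applied after each noise injection this projects
  the noise too, so the stochastic process itself is exactly G-invariant;
  complexes are symmetric to ~1e-13 Å. Rotation sets come from scipy's exact
  point-group constructors with closure and group order re-verified
  numerically at construction. A soft variant (quadratic symmetry-deviation
  energy) is also provided, since projection and penalty are both defensible
  readings of "symmetry in the energy function".
* **Registered substructure** — replacement conditioning: clamped residues
  are overwritten with the reference noised to the current t. The noise draw
  is a deterministic function of (t, conditioner seed), which makes the
  transform idempotent at fixed t; at t = 0 the clamp is exact to the bit.
* **Distance restraints** — harmonic energies on CA-CA distances, analytic
  gradients (finite-difference checked to 1e-5 relative).
* **Shape** — entropy-regularized optimal transport between the CA set and a
  target cloud: log-domain scaling iterations with uniform marginals and
  squared-Euclidean cost; the energy is the converged dual value, whose
  gradient (by Danskin's theorem) is the plan-weighted sum of cost gradients
  — exact at convergence, no differentiation through the iterations.
  Convergence is measured by row-marginal violation; beyond the iteration cap
  a warning is emitted and the last iterate used. Near-degenerate matchings
  (e.g. two well-separated congruent clouds) converge slowly — expected
  Sinkhorn behaviour at small ε — which matters for high-precision gradient
  checks but not for guidance.
* **Classifier guidance** — adds scale × ∇ log p(c | x, t) to the score. A
  toy helix-content classifier ships with the package: a smooth count of
  i,i+4 CA distances near 6.2 Å, with analytic gradient.

## Synthetic data

Generators produce idealized helices (rise 1.5 Å, twist 100°, CA radius
2.3 Å — giving the 3.8 Å virtual bond and the 6.2 Å i,i+4 distance), pleated
strands (~3.35 Å rise, alternating 0.9 Å pleat), hairpins, and self-avoiding
coils (bond 3.8 Å, bend angles 65–130°, a range that is clearly non-extended
and non-helical so the CA-geometry secondary-structure rules separate the
classes). `make_synthetic_set` concatenates randomly oriented segments and
re-draws any placement that brings non-bonded CA pairs closer than 2 Å.
Everything is byte-reproducible from its seed.

What passing tests show — and do not. The synthetic regime exercises the
*machinery*: exact constraints, closed-form sampling limits, equivariance,
scaling, trainability. It does not demonstrate that the desk-scale denoiser
generates native-like tertiary folds: real backbones have Ramachandran
statistics, hydrogen-bonded sheets, side-chain packing and far richer
long-range structure than idealized segments, and a few-hundred-parameter
regressor trained on helices will sample helix-like backbones. Conclusions
about designability or novelty of real proteins are out of reach of this
training regime by construction.

## Numerical choices and edge cases

* Secondary structure is assigned from CA-trace distance windows (helix:
  d(i,i+2) ≈ 5.4, d(i,i+3) ≈ 5.1, d(i,i+4) ≈ 6.2 Å; strand: two consecutive
  near-maximal i,i+2 spans), not hydrogen bonds — pure backbone samples carry
  no hydrogens. The windows are calibrated against the package's own
  generators and only that self-consistency is asserted.
* Contacts default to CA-CA ≤ 8 Å at separation ≥ 3; both configurable.
* Kabsch superposition excludes reflections via the determinant correction.
* Consensus stops at 1e-4 Å maximum per-node move or the iteration cap;
  sampling warm-starts it from x_t with 12 iterations.
* The schedule's t = 0 endpoint has α(0) = 1 − 2e-5 at the default log-SNR
  bounds; `forward_marginal` special-cases t = 0 to return x₀ exactly, and
  the score (undefined at σ = 0) raises at t = 0.
* PDB output writes all residues as glycine (sequence design is out of
  scope), 3-decimal coordinates, TER between chains; coordinates beyond the
  fixed-width field (|x| > 9999.999 Å) are rejected. Insertion codes are
  rejected on input; a missing carbonyl O is rebuilt from peptide geometry.
* Problem sizes in the test suite and acceptance script (20,000 draws for the
  Gaussian suite, 10,000 prior samples at N = 100, 50 training structures,
  8–10 samples per temperature arm) are the package's chosen desk-scale
  defaults: large enough that every Monte-Carlo band tested is several
  standard errors wide, small enough to run on one CPU in about a minute.

## Known limitations

* The denoiser's linear edge regressor cannot express tertiary interactions
  beyond its separation buckets; it is a scaffold for the architecture
  contracts, not a trained generative model of protein space.
* The prior treats multi-chain complexes as a single chain ordering; a
  per-chain covariance is a natural extension.
* The exact tempered limit N(μ, Σ/λ) relies on corrector equilibration; with
  ψ = 0 the predictor alone lands between Σ/λ and Σ/(2λ−1).
* Shape guidance uses fixed-cap scaling iterations during sampling; its
  gradient is slightly stale when the cap binds (warning emitted).
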