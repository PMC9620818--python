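# Methods

## Model

Chromatin in a genomic region of `N` bins is modelled as a Gaussian
polymer network: beads with positions `r_i` in 3D, pairwise harmonic
potentials `(k_ij/2)|r_i − r_j|²`, overdamped Langevin dynamics with
independent friction per bead. Units are dimensionless throughout:
thermal energy `kT = 1`, friction per bead `γ = 1`, contact scale
`σ_c = 1`; one time unit is `γ·length²/energy`. The model is
calibration-free — spectra and trajectories are comparative along the
genome, not calibrated to micrometers or seconds.

Spring constants may be negative (effective repulsion); validity requires
only that the network Laplacian `L(K)` be positive semidefinite with a
one-dimensional kernel spanned by the uniform (center-of-mass) mode.
Under that condition the equilibrium distribution of centered positions is
a degenerate Gaussian with per-axis covariance `Σ = L⁺`.

## The invertible transform

Forward: `K → L → Σ = L⁺ → d²_ij = Σ_ii + Σ_jj − 2Σ_ij →
C_ij = (1 + d²_ij/σ_c²)^(−3/2)`. The `−3/2` kernel is the Gaussian-overlap
contact probability of two beads whose separation is Gaussian with mean
square `3·d²/2` per axis scale; it is the choice that makes the transform
analytically invertible.

Inverse: `d² = σ_c²(C^(−2/3) − 1)`; Gram matrix `G = −½ J d² J` with the
centering projector `J = I − 11ᵀ/N` (classical multidimensional scaling);
`L = G⁺`; `K = −L` off-diagonal. Because `Σ` has zero row sums, the double
centering recovers it exactly, so forward and inverse are mutual bijections
on valid models (round-trip error ~1e-14 in the tests). The smallest
eigenvalue of `G` is reported as a diagnostic: the input is realisable by a
stable network iff it is non-negative (up to `1e-8` of the spectral
radius).

Numerical rank decisions in pseudo-inversion use a relative eigenvalue
floor of `1e-10` times the spectral radius. Contact matrices containing
zeros must be floored (default `c_min = 1e-4`) before inversion, since
`C → 0` maps to infinite distance.

### Projection of non-realisable matrices

A noisy contact matrix generally encodes non-Euclidean distances: `G` has
negative eigenvalues. `project_to_model` floors the non-uniform Gram
eigenvalues at `1e-8` times the largest one before pseudo-inverting.
Flooring on the Gram side turns the offending directions into very stiff,
near-zero-extent modes that barely perturb the contact matrix. The
alternative — inverting first and flooring the resulting *Laplacian*
eigenvalues — creates near-singular soft modes with enormous spurious
distances and was found to destroy the projected matrix; it is used only
in `project_valid`, where the iterate being projected is already close to
valid.

## Optimization

Cost: `½ Σ_{i<j} (C_model,ij − C_input,ij)²`, plain least squares on
probabilities (a logarithmic cost would over-weight the smallest, noisiest
entries). Null bins remain in the sum as zero rows/columns; masking them
out is a possible extension, not implemented. The fit runs in two phases,
both accepting a step only if the cost does not increase (so the recorded
cost history is non-increasing), halving their step on rejection (up to 30
times, then stopping) and doubling it back after acceptance:

1. **Projection phase.** Move the model matrix a fraction `η_c ≤ 1` toward
   the input, `C_target = C_model + η_c(C_input − C_model)`, and pull the
   target back through `project_to_model`. A realisable input is recovered
   in one full step, by exact invertibility; a noisy input converges in
   tens of steps to (near) its projection onto the manifold of realisable
   matrices. This generalises the inverse-transform initialisation and is
   what makes the fit fast.
2. **Descent phase.** Gradient descent `K ← project_valid(K − η ∇cost)`
   with the analytic gradient below, polishing the least-squares optimum
   locally (on the noisy benchmark it further reduces the cost by ~2.5×).

The split exists because descent on `K` from a distant initialisation
(e.g. a bare backbone chain) demonstrably stalls: the landscape contains
an extremely ill-conditioned valley (accepted steps imply local curvature
~5e7 on the N=60 benchmark), and once a step drives a Laplacian eigenvalue
to the validity floor the contact kernel saturates near zero and its
gradient vanishes, leaving the mode unrecoverable. Started near the
optimum by the projection phase, the same descent is well behaved.

**Gradient.** With residual `R = C_model − C_input` (zero diagonal),
weights `W_ij = (3/(2σ_c²)) R_ij (1 + d²_ij/σ_c²)^(−5/2)`, the Laplacian
`L_W` built from `W` like `L` from `K`, and `P = Σ L_W Σ`:

    ∂cost/∂k_mn = P_mm + P_nn − 2 P_mn,

the O(N³) closed form of `Σ_{i<j} W_ij (Σ_im − Σ_in − Σ_jm + Σ_jn)²`,
obtained by differentiating the pseudo-inverse on its range (the kernel,
the uniform mode, is constant in `K`). Verified against central finite
differences to <1e-4 relative on every tested instance.

**Validity projection.** `project_valid` eigendecomposes `L(K)`,
identifies the uniform mode by its overlap with `1`, keeps its eigenvalue
at exactly zero, floors every other eigenvalue at `δ = 1e-8`, and rebuilds
`K`. It is the identity on valid input and idempotent.

**Defaults.** `stop_epsilon = 1e-6` (relative cost change),
`max_iterations = 10000` (shared by both phases), descent rate
`η = 1e-4·N²` (gradient magnitudes shrink roughly as `1/N²`),
`c_min = 1e-4`, `δ = 1e-8`, inverse-transform initialisation. The
optimizer is fully deterministic given its configuration.

**Similarity metrics.** PCC is the Pearson correlation over
upper-triangle off-diagonal entries (valid-bin pairs). The
distance-corrected PCC stratifies entries by separation `s = |i−j|`,
computes a per-stratum Pearson `r_s`, and combines them as
`Σ w_s r_s / Σ w_s` with `w_s = n_s σ_{A,s} σ_{B,s}` (population standard
deviations), so strata with no signal contribute nothing. Strata whose
variance is below `1e-9` (relative to their largest entry) are skipped:
they are constant up to round-off, and correlating their float noise
would poison the sum — a uniform chain, whose contact matrix depends on
`|i−j|` only, makes every stratum degenerate and the metric undefined
(reported as NaN by the optimizer, an error from the metric itself).

## Preprocessing

Input is the three-column `pos1 pos2 score` text of an intra-chromosomal
dump at fixed resolution. Bins are `(pos − start)/resolution`, 0-based,
region half-open. Lines with non-numeric or NaN scores are dropped and
counted; off-resolution positions are format errors. Unobserved pairs are
zeros; a bin whose whole row is zero is a null bin and stays zero through
normalization. The unit-diagonal normalization is the unique symmetric
diagonal rescaling `C_ij / √(C_ii C_jj)`; it is exact on matrices produced
by the forward model scaled by per-bin visibility, idempotent, and clips
values above 1 (probabilities). A bin flagged valid but with zero diagonal
gets the mean nonzero diagonal imputed, with a warning, rather than being
silently dropped.

## Dynamics and sampling

Projecting the Langevin equation onto the Laplacian eigenvectors
decouples it into one Ornstein–Uhlenbeck process per mode and axis with
relaxation rate `λ_p`. The simulator uses the exact OU transition kernel

    x_p(t+dt) = x_p(t) e^(−λ_p dt) + ξ √((1 − e^(−2λ_p dt))/λ_p),

so the stationary distribution is exact for *any* `dt` (default 0.01,
1000 frames); the initial state is drawn from equilibrium, making
statistics stationary from frame 0. The uniform mode is either pinned at
the origin (`fix_com=True`, default) or diffuses with per-axis step
variance `2 dt`. Equilibrium sampling draws mode amplitudes
`x_p ~ Normal(0, 1/λ_p)` directly; every sample has its center of mass at
the origin by construction. Eigenvector ordering (ascending eigenvalue)
and sign (first component above 1e-10 in magnitude made positive) are
fixed for cross-platform reproducibility.

Per-bead mean squared displacement is closed-form:

    MSD_n(t) = 6t/N + Σ_{p≥1} (6 V_np²/λ_p)(1 − e^(−λ_p t)),

with the diffusive term dropped when the center of mass is fixed. Its
short-time slope is 6 (free draining), its long-time plateau (CoM fixed)
is `6 Σ_nn`.

## Rheology

The generalized Stokes–Einstein relation is used with unit prefactor:
`J_n(t) = MSD_n(t)/6`. No probe radius is invented; spectra are
comparative along the genome. Because `J` is an exponential sum, its
Fourier–Laplace transform is analytic: with `s = iω`,

    s·Ĵ(s) = (A/s + Σ_p c_p λ_p/(s + λ_p)) / 6,    G*(ω) = 1/(s·Ĵ(s)),

giving `G′ = Re G*`, `G″ = Im G*`, `tan δ = G″/G′` (reported as +inf where
`G′` vanishes) with no numerical integration, hence Kramers–Kronig
consistent by construction. Default grids: 64 log-spaced times and
frequencies in `[1e-3, 1e3]`. Verified limits: terminal
(`G″ ≈ 6ω/A`, `G′ ∝ ω²`), high-frequency (`G″ ≈ 6ω/(A + Σc_p λ_p)`), the
uniform-chain half-power law (`G′, G″ ∝ ω^{1/2}`, `tan δ ≈ 1` in the
intermediate band), and agreement with an independent oscillatory-
quadrature transform of `J(t)` to <0.1%.

## Synthetic data

The generator produces the structures real intra-chromosomal maps show:
a backbone chain (`k = 1` between neighbours), TAD-like blocks (uniform
extra coupling among all bead pairs in an interval), and loops (single
extra springs). The standard benchmark is `N = 60`, backbone 1, blocks at
beads 5–25 and 35–55 with `k = 0.3`, one loop (10, 50) with `k = 0.5` —
two diagonal squares plus a loop dot, optimizable in seconds. Noise
models: elementwise lognormal (`exp(σξ)`, mirrored, clipped to (0,1],
diagonal reset; σ = 0.1 standard) emulating multiplicative
visibility/sampling noise, and binomial count sampling at a stated depth
emulating finite sequencing. Null bins can be zeroed to emulate
unmappable regions. Every generated model is checked for validity before
release.

What the generator does **not** emulate: GC/mappability biases,
balancing artifacts, inter-chromosomal contacts, and the heavy-tailed
distance decay of real polymers with excluded volume. Passing the
recovery benchmarks therefore shows the estimator is correct and robust
to multiplicative/count noise on *model-generated* structure, not that
real chromatin satisfies the Gaussian-network assumptions.

## Numerical choices and sizes

Monte-Carlo calibration checks use batch-means standard errors (100
batches) to respect autocorrelation; calibration z-scores are expected
within 3 (5 for the elementwise covariance sweep). Benchmarks run at
N = 60 (fit), N = 10 with 1e6 steps (simulator calibration), 1e5 samples
(sampler), 1e3 trajectories (MSD closure), N = 256 (Rouse scaling) —
sizes at which every check completes in seconds on one CPU while leaving
Monte-Carlo errors small enough to be discriminating.

## Known limitations

- Harmonic (Gaussian) interactions only: no excluded volume, confinement,
  or activity; contact probabilities are monotone in mean squared
  distance by construction.
- Null bins bias the fit toward zero contacts in their rows instead of
  being masked out of the cost.
- Negative-eigenvalue directions of noisy inputs are projected to very
  stiff modes, which can leave a few very large spring constants in
  `K_opt`; they have negligible effect on the reproduced contact matrix
  or the spectra, but `K_opt` should be read as a network model, not as
  individually interpretable loop strengths.
- Matrix balancing (ICE/KR) and `.hic` binary parsing are upstream
  concerns; the tool consumes dump text or dense matrices as given.
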