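# Methods

## Forward model

A voxel's microstructure is summarized by a non-negative joint
distribution f(T1, T2, D) over longitudinal relaxation, transverse
relaxation and isotropic diffusivity. An acquisition is a tuple
β = (τᵢ, τₑ, b) of inversion time, echo time and b-value, and the
noiseless signal is the Fredholm integral s(β) = ∫ f(α) k(α; β) dα.
We use the standard separable kernel for an inversion-recovery,
spin-echo, pulsed-gradient experiment with isotropic Gaussian diffusion:

    k(α; β) = (1 − 2 exp(−τᵢ/T1)) · exp(−τₑ/T2) · exp(−b·D).

MD-MRI magnitude reconstruction discards the inversion-recovery sign, so
the default kernel mode takes absolute values; a signed mode is exposed
for completeness. The kernel has a signal null at τᵢ = T1·ln 2 and
reduces to pure e^(−bD) or e^(−τₑ/T2) decay when the other mechanisms
are disabled; these closed forms anchor the unit tests.

**Units.** Internally T1, T2, τᵢ, τₑ are seconds and D is µm²/ms with b
in ms/µm², which keeps b·D of order one. A kernel build warns when
max(b)·max(D) exceeds 10³, the signature of b accidentally supplied in
s/mm².

**Default discretization.** `default_grid(n)` is log-spaced with
T1 ∈ [0.05, 5] s, T2 ∈ [0.005, 0.5] s, D ∈ [0.01, 3] µm²/ms — spanning
fixed ex vivo tissue values — at 20 points per axis (N = 8000 nodes) by
default. `default_scheme()` is a factorial 5 τᵢ × 5 τₑ × 4 b design
(d = 100): times log-spaced across the sensitive ranges, b linearly
spaced from 0 to 4.5 ms/µm². The flat node index runs T1 slowest, D
fastest, and is the single source of truth for feature vectorization.

**Noise.** SNR is defined as (max noiseless signal)/(noise standard
deviation) — stated explicitly because "low SNR" alone is ambiguous.
Gaussian noise adds a real perturbation; rician noise takes the
magnitude of a complex Gaussian perturbation, the correct model for
magnitude MRI, and introduces the familiar positive noise floor at low
SNR. All noise is driven by explicit seeds; identical seeds give
bit-identical signals.

## Inversion

The spectrum estimate solves

    f̂ = argmin_{f ≥ 0} ‖s − K₀f‖₂² + λ‖f‖₂².

The residual norm is fixed at p = 2, the only choice served by a
standard NNLS solver. The solver is Lawson–Hanson active-set NNLS,
specialised in two ways: gradients use the kernel's cached Gram matrix
(computed once per kernel, reused across all voxels and noise
realizations), and the ridge term is folded into the normal equations
of the passive set rather than materialised as an augmented
(d + N) × N matrix. With λ = 0 the inner solves use plain least squares
on the passive kernel columns for full accuracy. The solver is
deterministic, raises a diagnostic error on non-convergence (the
benchmark logs and skips such voxels rather than imputing), and is
cross-checked against `scipy.optimize.nnls` on random augmented systems
in the test suite.

**Self-regularization and λ.** The non-negativity constraint is itself
a strong regularizer: on delta-compartment fixtures at moderate noise
(SNR ≳ 20), unconstrained-in-λ NNLS already returns sparse, accurate
spectra and any λ > 0 only adds shrinkage bias. Ridge regularization
measurably improves recovery only at very low SNR (around 5), which is
where the provided L-curve rule — maximum Menger curvature of the
log-residual vs log-solution-norm curve, ties toward larger λ,
degenerate curves flagged — earns its keep. For benchmark
reproducibility the phantom pipeline fixes λ = 10⁻² rather than tuning
per voxel.

**Performance note.** Active-set NNLS is efficient while solutions are
sparse (support ≲ d). Very large λ drives the solution dense (every
positively-correlated column becomes slightly active), and solve time
grows accordingly; practical λ values (≤ ~1) stay sparse and fast.

**Marginalization.** 3-D spectra are summed over one axis to produce
the three conventional 2-D correlation maps (T1–T2, T1–D, T2–D); mass
conservation is exact and tested to 10⁻¹².

## NLCS classification

For query x*, each class contributes its k nearest training points
(p-norm distances, ties broken by training insertion order); the class
score is the Euclidean distance from x* to the convex hull of that
neighborhood, and the smallest score wins (class-index tie-break). The
hull distance min_{w ∈ simplex} ‖x* − Zᵀw‖₂ is solved by NNLS on an
equality-penalised system (penalty weight 10⁴ × data scale enforcing
Σw = 1) to find the active support, then polished on the exact KKT
system of the equality-constrained least-squares problem, dropping
negative coordinates until feasible. Optimality is certified by the
projection variational inequality ⟨x* − witness, zⱼ − witness⟩ ≤ 0
checked over *all* neighborhood points; violated points are added to the
support and the loop repeats. The returned barycentric weights and
witness point form a verifiable certificate, and the whole routine is
validated against a shrinking dense simplex-grid search that shares no
solver code.

Only p = 2 is implemented for hull distances (the problem is then a
convex QP); other norms raise immediately. k defaults to 5 in
benchmarks; with k = 1 the rule provably reduces to 1-nearest-neighbor,
which the tests check against scikit-learn's implementation. Brute-force
neighbor search is intentional — benchmark datasets are hundreds of
points, far below where tree indices pay off.

## Information-theoretic bounds

For discrete label X and observation Y, plug-in Shannon quantities in
bits (a single `base` parameter keeps the entropy and the log|χ| of the
Fano denominator consistent) feed:

- Fano lower bound (weakened form, as is standard for prediction-error
  arguments): Pe ≥ (H(X|Y) − 1)/log|χ|. The raw value may be negative
  (vacuous); a clamped field is reported alongside.
- Hellman–Raviv upper bound on the MAP predictor: Pe ≤ ½H(X|Y).
- Exact Bayes/MAP error 1 − Σ_y max_x P(x, y), defined only for exact
  joints (empirical data should use holdout error).
- DPI audits: for a chain X → Y → Y′ given as a prior and two
  row-stochastic channels, I(X;Y) and I(X;Y′) are computed exactly and
  the margin is asserted non-negative.

These estimators are for discrete (or explicitly discretized) variables
only; continuous-feature mutual-information estimation is out of scope.

## Synthetic phantom

The phantom emulates the statistical structure of a two-group ex vivo
study — lesion-like tissue versus matched controls — without modelling
histology or image registration. Three shared water pools sit at fixed
grid-snapped locations (T1 s, T2 s, D µm²/ms): myelin-like
(0.3, 0.02, 0.3), intra/extracellular (1.0, 0.08, 0.8) and
free-water-like (3.0, 0.3, 2.0). Control voxels mix them at fractions
(0.30, 0.55, 0.15); the lesion class moves `effect_size` (default 0.15)
of volume from the intra/extracellular to the free-water pool,
mimicking gliosis-driven expansion of fast-diffusing water. Per-voxel
variability perturbs fractions on the logit scale (jitter σ = 0.3 by
default, a visually plausible biological spread chosen once) and
renormalizes. Defaults: 100 voxels per class, SNR 30 rician, a 12³
grid for the per-voxel inversions (desk-scale; the 20³ grid remains the
module default elsewhere), λ = 10⁻², master seed with per-voxel streams
seed + voxel index. Voxels are also tagged with 7 + 7 pseudo-subject
labels (deterministic round-robin) purely as grouping metadata.

Because the 2-D spectrum features are computed from the noisy signals
alone through a fixed inversion configuration, the Markov chain
X → Y → Y′ holds *by construction*, which is what makes DPI-consistent
benchmark outcomes interpretable. What the phantom does **not** emulate:
spatial voxel correlation, partial-volume gradients, graded (non-binary)
labels, cross-subject biological variability, exchange between pools,
anisotropic diffusion, or off-grid compartments (an off-grid stress test
exists in spirit via the snapping machinery but truth lives on grid
nodes to avoid discretization confounds). Passing benchmarks therefore
show that the pipeline and the theory behave as claimed under the
stated generative model — not that any particular κ value transfers to
real tissue.

## Benchmark protocol

Defaults mirror the study protocol: 30 bootstrap repetitions, each a
seeded 50/50 split of the voxel pool (repetition b uses seed
master + b), with the *same* split reused for every cell of the
4 methods × 4 representations grid — the pairing that licenses
within-repetition comparisons. "Bootstrapped samples" is read as
repeated re-splits; a with-replacement mode is available behind a flag.
Splits that leave a class absent from training are redrawn (logged, max
100). Classifiers: 2-NN (Euclidean), MLP (one hidden layer of 64,
max 500 iterations, no early stopping, seeded per repetition), LDA
(eigen solver, Ledoit–Wolf shrinkage, with a nearest-centroid fallback
— the identity-covariance limit of LDA — for exactly singular
within-class scatter), and NLCS (k = 5). Cells are scored by Cohen's κ
with p₀ and pₑ reported; the degenerate pₑ = 1 case (both sequences
constant on one class) is defined as κ = 1. Reports carry the full
per-cell κ distributions, row/column argmax annotations, failure
counts, and the shared test-index lists so the pairing invariant can be
audited byte-exactly.

## Numerical choices, at a glance

| Quantity | Default | Why |
| --- | --- | --- |
| NNLS dual tolerance | 10·eps·max(1, ‖Kᵀs‖∞) | machine-precision stop, scale-aware |
| hull QP tolerance | 10⁻¹⁰ × scale² | certifies 10⁻⁷-level distances |
| ridge λ (phantom) | 10⁻² | fixed for reproducibility; see L-curve note |
| phantom effect size | 0.15 | the experiment's knob; moderate separability |
| fraction jitter | 0.3 (logit) | plausible per-voxel biological spread |
| SNR (phantom) | 30, rician | noisy but invertible regime |
| n_boot / split | 30 / 0.5 | study protocol |
| NLCS k | 5 | declared default; not inferred from any source |

## Known limitations

- The Fano bound is implemented in its weakened printed form; it is
  often vacuous (negative) for easy problems — by design, the clamped
  value is the interpretable one.
- Large-λ inversions are slow (dense active sets); not a practical
  regime here.
- The phantom's binary labels and pooled-voxel splits mean the
  benchmark speaks to within-pool discrimination, not cross-subject
  generalization.
- p ≠ 2 hull distances and anisotropic diffusion kernels are
  intentionally unimplemented and raise clear errors.
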