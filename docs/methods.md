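# Methods

## Model

A mono recording is mapped to a geometric object in four steps.

**Spectrogram surface.** The short-time magnitude spectrogram (or a
mel-weighted power spectrogram for speech-type signals) is converted to
log10 scale with a floor of 1e-10, bilinearly resampled onto a uniform
`grid_n × grid_n` time × frequency grid, and interpreted as the graph surface
z(x, y). Time, frequency and z are each min–max normalised to [0, 1]; z is
then multiplied by an aspect factor α (default 1.0). The normalisation is
recorded in a `ScaleMeta` sidecar so signatures are comparable and
reproducible: distortion values are meaningless without a declared aspect
convention, since the geometry of a graph surface depends on the relative
scale of its axes. Normalisation is idempotent, and a constant-z input maps
to the flat surface z ≡ 0.

**Triangle mesh.** The grid is triangulated in the (x, y) plane and lifted by
the vertex heights, so connectivity never depends on z. On a uniform grid
every quad is co-circular and the Delaunay triangulation is ambiguous; the
tie is broken deterministically toward the "/" diagonal, giving identical
connectivity across runs and platforms. A `grid_n × grid_n` surface yields
`grid_n²` vertices and `2(grid_n−1)²` counter-clockwise triangles with a
single boundary loop (disk topology by construction, as for any graph
surface over a rectangle).

**Flattening.** The planar parametrization minimises the area-weighted mean
symmetric Dirichlet energy (σ₁² + σ₁⁻² + σ₂² + σ₂⁻²)/4 subject to
det df_t > 0 on every triangle. Two stages:

- *Tutte initialisation*: boundary vertices on the unit circle in loop
  order, spaced by 3D boundary edge length; interior vertices are convex
  combinations of their neighbours under mean-value weights (uniform weights
  available for testing). Solving the sparse linear system gives a bijective
  disk embedding — no inverted triangles — which removes any need for
  inversion repair.
- *Projected-Newton descent* with free boundary. The symmetric Dirichlet
  Hessian in Jacobian space has a closed-form eigensystem (two scaling
  modes, a flip mode and a twist mode; only the twist eigenvalue can be
  negative and is clamped at 1e-12 for the PSD projection). Per-triangle
  6×6 blocks are assembled into a sparse system, regularised by a diagonal
  Tikhonov term of 1e-10 × the mean Hessian diagonal (absorbing the
  rigid-motion null space of the free-boundary problem), and solved by
  sparse LU. A backtracking line search (shrink 0.5, Armijo constant 1e-4)
  starts from min(1, 0.9 × s_flip), where s_flip is the smallest positive
  root of det(df_t) = 0 along the direction over all triangles — so no
  accepted iterate can invert a triangle, and the energy trace is monotone
  non-increasing by construction. The solver stops on a gradient
  infinity-norm below 1e-8, a relative energy decrease below 1e-8, or
  2000 iterations; in practice it converges in a few dozen Newton steps to
  near machine precision, which is what makes the distortion features
  numerically rotation invariant (the per-triangle source frames are built
  from edge geometry only, so a rigid motion of the source changes nothing
  but floating-point rounding).
- An L-BFGS direction (memory 8) with the same flip-capped line search is
  available as `method="lbfgs"` and is the solver used for the MIPS
  objective, for which no Hessian eigensystem is implemented. Free-boundary
  minimisation requires a barrier objective (symmetric Dirichlet or MIPS);
  non-barrier energies would allow descent into a triangle collapse.

**Signature.** Per-triangle Jacobians df_t = Q P⁻¹ are expressed between an
orthonormal frame in the source triangle's plane (first axis along the first
edge, second completing a right-handed frame with the orientation normal)
and the plane. Signed singular values use the closed 2×2 form
σ₁ = h₁ + h₂, σ₂ = h₁ − h₂ with h₁ = |(E, H)|, h₂ = |(F, G)|, so
σ₁σ₂ = det df_t exactly and σ₂ < 0 flags an inverted triangle. Eight
energies (ARAP, symmetric Dirichlet, quasi-isometric, quasi-conformal, MIPS,
unsigned area, Dirichlet, conformal factor) are evaluated on the singular
values of **one** length-minimising flattening — the signature describes a
single map, and the configuration records which objective produced it.
Triangles are split at the median centroid frequency (strict `<` to the low
band, `>=` to the high band, so a constant-frequency mesh puts everything in
the high band); the global distortion of each energy over each band is the
mean weighted by the **source 3D triangle areas**, so the weights describe
the signal's own geometry rather than the map being scored. If the low band
is empty, its features fall back to the full-mesh values with a logged
warning, keeping the 16-vector total on degenerate inputs.

## Preprocessing

- **Savitzky–Golay** (lung-type signals): degree-3 polynomial over a
  23-sample window (half-window M = 11), the combination reported to work
  best for stethoscope recordings. Output is the polynomial value at the
  window centre; the first/last M samples use truncated one-sided windows so
  length is preserved. The projection reproduces any polynomial of degree
  ≤ 3 exactly.
- **Undecimated wavelet denoising** (speech-type signals): stationary
  wavelet transform (sym4, 4 levels, norm=True — the shift-invariant,
  maximal-overlap filter bank), per-level universal threshold
  σ·√(2 ln n) with σ from the median absolute deviation of the level's
  detail coefficients, soft thresholding by default (`universal_hard` and
  `none` available; `none` is exact reconstruction). Input is symmetric-
  padded to a multiple of 2^levels and cropped after reconstruction.
- **STFT defaults**: Hann window, 256 samples, 75 % overlap; the window is
  halved (not below 16) until at least `grid_n` frames exist, and a
  too-short signal raises an error naming the minimum length. The mel
  variant uses 64 triangular filters on the standard 2595·log10(1 + f/700)
  scale applied to framewise power.

The MFCC baseline frames at 25 ms / 10 ms hop, takes a 26-band mel log-power
spectrum, an orthonormal DCT-II, keeps the first 12 coefficients, and
summarises each trajectory by mean, standard deviation, min, max, and the
mean and standard deviation of the absolute successive difference
(coefficient-major order, 72 features).

## Classification protocol

The 80/20 split is at the subject-group level so no patient/speaker spans
train and test, and the group draw is stratified per class (each group
carries one class label), guaranteeing both classes appear in the held-out
set. Hyper-parameter search, when enabled, is a seeded randomised search
under grouped 5-fold cross-validation scored by accuracy (multi-class) or
AUROC (binary); class weights are inverse to training class frequencies
(passed as per-sample weights to AdaBoost and gradient boosting; k-NN has no
weighting notion and is left unweighted). The classifier suite is logistic
regression, SVM, random forest, k-NN, AdaBoost and XGBoost, each behind a
standardisation pipeline. Feature selection for the combined 88-feature
model fits its random-forest importance ranking on the training rows only,
avoiding selection leakage. Multi-class recall and Jaccard are macro
averages of per-class one-vs-rest counts; multi-class AUROC is one-vs-rest
macro.

## Synthetic data

The generator emulates class-structured recordings: each class is a carrier
band (uniform random carrier per recording), optional linear chirp, optional
sinusoidal amplitude modulation, optional band-limited noise, and white
noise at a stated SNR; group identifiers are assigned round-robin within a
class so grouped splitting is always exercised. Everything is deterministic
per seed. Three stock scenarios ship: a "lung-like" set (narrowband wheeze
surrogate, AM burst + band-noise crackle surrogate, quiet broadband
normal), a "speech-like" set (formant-style chirps in different bands), and
a "geometry-contrast" pair (a noise-free tone against a rough broadband
class) used for end-to-end classification checks. Mesh fixtures provide
flat, Gaussian-bump and smoothed-random height fields over the unit grid.

What the generator does **not** emulate: real pathology or accent acoustics,
recording-chain artefacts, inter-subject variability beyond the carrier
draw, or non-stationary noise. Passing the end-to-end test therefore shows
that the geometric pipeline separates classes whose spectrogram surfaces
genuinely differ in shape — it does not certify performance on clinical
data, and the within-class spread of real corpora is far larger.

## Numerical choices and degenerate inputs

- Grid ties in the triangulation: "/" diagonal, fixed.
- Zero-area source triangles raise an error naming the triangle; inverted
  initial embeddings are rejected (this solver does not repair them).
- Energies require σ₂ > 0 and raise otherwise; in valid embeddings the
  constraint det df_t > 0 makes all singular values positive.
- Problem sizes in tests and the acceptance script: 32 × 32 grids
  (1,922 triangles), 100 random meshes for the injectivity sweep,
  20 rigid motions for invariance, 120 recordings (two classes, 12 groups
  each) for the end-to-end run — desk-scale sizes chosen so the whole suite
  reproduces quickly on one CPU.
- Silence (all-zero signal) maps to the flat surface; constant MFCC
  trajectories have zero dispersion statistics by definition.

## Open design points, resolved

- The embedding axes have no canonical units; the declared convention is
  unit-cube normalisation with a configurable aspect α recorded in metadata.
- Whether global distortions weight by source or image areas is a free
  choice; source areas were chosen so the weighting is independent of the
  map being scored.
- The exact wavelet threshold function, STFT window parameters and
  hyper-parameter grids are not canonical; all are config-pinned defaults,
  stated above, rather than claims.
- One recording yields one feature vector (no fixed-length chunking).

## Limitations

- The optimisation problem is non-convex; the solver returns a local
  minimum reached from the Tutte embedding, not a certified global optimum.
- Free-boundary flattening admits rigid-motion gauge freedom; features are
  rotation invariant by construction, but the uv coordinates themselves are
  only defined up to a rigid motion of the plane.
- Meshing is uniform; curvature-adaptive sampling, phase-aware
  spectrograms, volumetric (tetrahedral) extensions and pairwise mesh
  matching are out of scope.
- SHAP-based rankings are not implemented; random-forest impurity and
  permutation importance are the available backends.
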