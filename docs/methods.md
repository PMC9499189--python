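# Methods

This note documents the models, parameter choices and numerical
conventions behind `lpbrain`, and what the synthetic experiments do and do
not demonstrate.

## Pipeline overview

An input slice is (1) pre-processed: resized with bilinear interpolation,
reduced to luminance, median-denoised; (2) optionally segmented by K-means
on intensity (k = 3: background, tissue, lesion-candidate), with the
brightest cluster's largest connected component taken as the tumor
candidate; (3) mapped to the log-polar domain about the foreground
centroid; (4) passed through one 2-D discrete wavelet analysis level,
keeping the LL approximation band; (5) summarized by 13 texture/intensity
features; (6) classified by a kernel SVM, or — bypassing (4)–(5) — by a
shallow CNN reading the log-polar image directly.

## Log-polar transform

The output pixel (i, j) samples the source bilinearly at
`center + e^{rho_i}(cos theta_j, sin theta_j)` with `rho` uniform on
`[log r_min, log r_max]` (M rows, endpoints included) and `theta` uniform
on `[0, 2pi)` (N columns, endpoint excluded so the axis is exactly
periodic). Natural logarithms are forced by the inverse map
`x = e^rho cos theta`. Angles are measured from the +x (column) axis
toward the +y (row) axis; since rows grow downward, an on-screen
counter-clockwise rotation by Δ corresponds to a column shift of
`-N·Δ/360`. Samples falling outside the source are filled with 0
(`fill="nearest"` available). Defaults for the bare transform:
M = N = 64, r_min = 1 px, r_max = min(H, W)/2 (the inscribed circle, so a
centered transform never leaves the image), center = geometric center
((W-1)/2, (H-1)/2).

**Feature-path r_min.** Log-radius sampling places half the rows below the
geometric mean `sqrt(r_min · r_max)`; with r_min = 1 and r_max = 128 that
is radius ≈ 11 px, so most rows magnify a few central pixels and the
anatomy occupies a sliver of the output. The feature extractor therefore
uses `r_min = 8 px` (`FeatureConfig.lpt_r_min`), which spreads the rows
across the brain; the bare `lpt()` keeps r_min = 1 for callers who want
the full fovea. This choice was made after inspecting per-feature class
separation on phantoms and is a property of the method configuration, not
of any particular dataset.

**Known non-invariances.** Translation is not invariant (the package
quantifies this with `translate_sensitivity`); re-centering on the
binarized-foreground centroid restores approximate invariance for rigid
shifts. Rotation/scale equivalence to shifts is exact only in the
continuum: bilinear resampling contributes O(h²) error, which is why the
rotation↔shift property is asserted at mean-absolute-difference 0.02 and
row constancy of radially symmetric images only holds to ~5e-3 even for
smooth profiles (an exact 1e-6 match is impossible for any non-bilinear
radial field).

## Wavelet stage

`dwt2`/`idwt2`/`wavedec2` wrap PyWavelets. Default wavelet: orthonormal
Haar (exact rational sub-band values in tests, LL gain 2 for constants);
db4 available. Default boundary mode: **periodization**, the only mode
under which the discrete transform of an orthogonal wavelet is an
orthonormal change of basis at every size — sub-bands are exactly
⌈H/2⌉×⌈W/2⌉ and energy is conserved to machine precision, which the test
suite asserts at 1e-9. Symmetric half-sample extension is accepted as an
option but produces redundant boundary coefficients (≈21% excess energy
for db4 on 64×64), so it is not the default.

## Features

Order is frozen: contrast, correlation, energy, homogeneity, mean,
standard_deviation, entropy, rms, variance, smoothness, kurtosis,
skewness, idm. GLCMs use 8 equal-width bins on [0, 1], the four unit
offsets (0,1), (-1,1), (-1,0), (-1,-1), symmetrized, features averaged
over offsets. Degenerate conventions, all tested: correlation of a
zero-variance GLCM is 1; skewness/kurtosis of a constant image are 0;
entropy is Shannon entropy in bits of the 256-bin histogram on [0, 1].
The working image (after LPT and/or LL) is min-max rescaled to [0, 1]
before feature computation so that quantized texture statistics are
comparable across stages; consequently `rms² = variance + mean²` holds on
the *working* image.

PCA (centering + full SVD) and FastICA (whitening + negentropy fixed
point, seeded) are provided as optional post-extraction reductions of the
13-column matrix. ICA flags two conditions: non-convergence
(`model.converged_ = False`, partial result returned) and all-Gaussian
inputs (unidentifiable beyond whitening; warned via excess-kurtosis
screen at |κ| < 0.2).

## Segmentation

`kmeans` is Lloyd's algorithm with k-means++ seeding, Euclidean metric,
stop when the largest center movement < tol (default 1e-6) or after
max_iter (300). Empty clusters are re-seeded at the point farthest from
its assigned center. The per-iteration inertia trace is returned and is
non-increasing. `segment_image` runs 4 restarts with seeds derived from
the caller's seed and keeps the lowest inertia: a small bright lesion
beside a large tissue cluster is precisely the geometry where a single
run can stall with the lesion merged into tissue. Color inputs are
clustered on CIELAB (sRGB, D65) a\*b\* chromaticity; the grayscale
intensity path is the pipeline default.

## Kernel SVM

Kernels: linear `x·y`; RBF `exp(-γ‖x-y‖²)` with γ defaulting to
1/(d·var(X)); polynomial `(x·y + c₀)^p` with p = 3, c₀ = 1; quadratic is
polynomial with p pinned to 2. Features are z-scored with training-set
statistics (zero-variance columns get unit scale) — without this the RBF
distance is dominated by the largest-scale feature. The dual problem is
solved to tolerance 1e-4 on the precomputed Gram matrix; the decision
function is a pure function of the stored support vectors, dual
coefficients, bias and scaler statistics. Duplicating training rows
preserves the decision function only in the margin-SV regime (no α at the
C bound), and only up to the solver tolerance.

## Shallow CNN

Architecture: four valid (no padding, stride 1) 3×3 convolutions with
32, 32, 64, 64 filters, each followed by ReLU and 2×2 max-pool (stride 2,
no padding); dense 256 (ReLU) → 512 (ReLU) → 512 with 50% inverted
dropout → 2-way softmax. Reference input 224×224×3; grayscale inputs are
replicated to three channels and resized on entry. The filter counts and
3×3 kernels are configurable (they are not dictated by the architecture's
published description); the experiment default shrinks the input to
64×64×3 so training fits in CPU seconds-to-minutes without changing the
layer structure.

Training: categorical cross-entropy (implied by the softmax output),
RMSprop (decay 0.9, ε = 1e-8), learning rate 1e-5, batch size 10. He
initialization. All randomness — init, shuffling, dropout masks — derives
from one seed; two runs with the same seed produce bit-identical weights.
The per-epoch `accuracy` in the history is the end-of-epoch training
accuracy in inference mode (dropout off): the with-dropout running
estimate is a noisy underestimate and never stabilizes even after the
deterministic decision rule is perfect. Implementation is plain NumPy
(im2col convolutions as BLAS matrix products, explicit backward passes);
there is no GPU path.

## Phantom generator (study conditions)

Each phantom is a pure function of its spec (class, modality, size,
lesion geometry, noise, seed): elliptical brain (semi-axes 0.42H, 0.36W)
with a smooth Gaussian-field tissue texture (±0.04 around 0.5), two dark
ventricles (0.22), background 0.02. Lesions are radial-basis blobs: the
boundary radius is modulated by a seeded order-2..6 Fourier series scaled
by `boundary_irregularity`; the interior is offset from tissue by
±`contrast_delta` (default 0.35; + for T2-like, − for T1-like) plus a
short-correlation Gaussian field scaled by `texture_heterogeneity`.
Additive Gaussian noise σ = 0.02. Class invariants: benign requires
irregularity and heterogeneity ≤ 0.2, malignant requires ≥ 0.5 in at
least one; dataset presets draw benign parameters uniformly from
[0, 0.2] and malignant from [0.5, 0.9], lesion radius from
[0.09, 0.14]·min(H, W). Auto-placed lesions shrink by 10% steps until they
fit inside the brain; explicitly placed lesions that protrude raise an
error. Dataset presets reproduce the printed tumor-classification splits
(9/7 train + 2/2 validation simulated; 18/20 + 4/6 T2; 13/5 + 4/2 T1) at
256×256 by default; distortion draws rotation uniform on [−180°, 180°]
and scale uniform on [0.25, 1.5], applied to the validation split unless
configured otherwise. Exact multiples of 90° are applied as lossless grid
rotations.

**What this does and does not show.** The generator emulates the
*geometric and textural contrast* between tumor classes and the
*distortion family* the method targets. It is not a physical MR
simulation: no Bloch dynamics, k-space sampling, bias fields, partial
volume, anatomy variability, or 3-D structure. Passing results
demonstrate that the pipeline's invariance machinery works as designed
and that its stages are numerically correct — not that the reported
accuracies transfer to clinical MRI.

## Experiment statistics and problem sizes

Validation splits of the printed sizes contain 4–10 images, so
single-split accuracy moves in steps of 25–10 pp. Robustness claims are
therefore made on means across master seeds: the rotation-benefit
statistic (DWT+LPT vs. DWT on rotation-distorted validation phantoms)
averages the four kernels and 15 derived master seeds. The test suite and
acceptance script use 256×256 phantoms for feature-path experiments,
64×64 log-polar inputs for the CNN, and 48×48 inputs with reduced filter
counts for per-step optimizer checks; these sizes are the package's
defaults for desk-scale reproducibility.

## Known limitations

- 2-D slices only; no DICOM/NIfTI ingestion (PNG/JPEG/BMP, 8-bit).
- The LPT is evaluated at fixed M×N with bilinear sampling; no foveated
  or area-weighted variants.
- Binary classification only (benign/malignant or normal/abnormal).
- The CNN is CPU-bound NumPy: adequate for the small experiments here,
  not for 224×224 training at scale.
- Feature min-max normalization discards absolute intensity scale; tasks
  that depend on it should disable the normalization stage.
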