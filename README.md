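# lpbrain

Rotation- and scale-invariant classification of brain MR slices into
benign vs. malignant tumor classes (and normal vs. abnormal), built around
the **log-polar transform (LPT)**. The package implements the full
pipeline — pre-processing, K-means segmentation, LPT, 2-D wavelet
sub-bands, a fixed 13-feature texture/intensity vector, PCA/ICA reduction,
kernel SVMs and a shallow 4-conv-layer CNN — together with a synthetic
brain-phantom generator with ground-truth lesion masks, so every stage is
testable offline without patient data.

## Who it is for

Researchers in medical image analysis who want a small, fully
deterministic, pure-Python reference implementation of LPT-based
rotation/scale-robust tumor classification: each stage is an importable
function with a documented contract, and the whole pipeline runs on a
laptop CPU in seconds to minutes.

## The method

A rotation of an image about a center `c` and a uniform scaling about `c`
are awkward for texture features computed on the Cartesian grid. The LPT
resamples the image onto a (log-radius, angle) grid:

    rho   = log sqrt((x - xc)^2 + (y - yc)^2)
    theta = atan2(y - yc, x - xc)            in [0, 2*pi)

with the inverse map `x = e^rho cos(theta)`, `y = e^rho sin(theta)`. Under
this conformal mapping a rotation by `Δ` becomes a **circular shift of the
angle axis** by `N·Δ/2π` columns, and a scaling by `α` becomes a
**translation of the log-radius axis** by `log(α)/Δrho` rows — and
statistics that ignore position (co-occurrence and histogram features) are
therefore nearly unchanged. Translations are *not* invariant; the pipeline
re-centers the transform on the foreground centroid to compensate.

On the (optionally LPT-mapped) image, a single wavelet analysis level
(`LL/LH/HL/HH`, orthonormal Haar by default) supplies the smoothed
approximation band, and 13 features are extracted in a fixed order:
five gray-level co-occurrence matrix (GLCM) statistics — contrast,
correlation, energy, homogeneity, inverse difference moment — averaged
over the four unit offsets (0°, 45°, 90°, 135°), plus eight intensity
statistics: mean, standard deviation, entropy, RMS, variance, smoothness,
kurtosis, skewness. Classification is by soft-margin SVM under four
kernels (RBF, linear, polynomial, quadratic) on z-scored features, or by a
shallow CNN (four valid 3×3 conv + 2×2 max-pool blocks, dense
256→512→512 with 50% dropout, 2-way softmax, RMSprop at lr 1e-5, batch 10)
consuming log-polar images directly.

The phantom generator renders elliptical "brains" with smooth tissue
texture, dark ventricles and an optional lesion whose **boundary
irregularity** and **texture heterogeneity** encode the benign (round,
homogeneous) vs. malignant (lobulated, heterogeneous) axis; T1-like vs.
T2-like contrast flips the lesion-vs-tissue sign. Distortion operators
cover rotations −180°..+180° and scales 0.25–1.5.

## Worked example

```python
from lpbrain.phantom import PhantomSpec, make_phantom
from lpbrain.features import extract_feature_vector, FeatureConfig, FEATURE_NAMES
from lpbrain.pipeline import run_experiment, PipelineConfig

img, mask = make_phantom(PhantomSpec(cls="malignant", boundary_irregularity=0.7,
                                     texture_heterogeneity=0.7, seed=3))
vec = extract_feature_vector(img, FeatureConfig())   # LPT -> Haar LL -> 13 features
print(dict(zip(FEATURE_NAMES, vec.round(4))))

rep = run_experiment("simulated", PipelineConfig(), methods=("DWT", "DWT+LPT"),
                     distortion="rotate", seed=0)
print(rep.table.drop(columns="CNN (%)").to_string(index=False))
```

prints (exact output; the run is deterministic under the seed):

```
{'contrast': 0.9762, 'correlation': 0.8301, 'energy': 0.1129,
 'homogeneity': 0.7889, 'mean': 0.4458, 'standard_deviation': 0.2134,
 'entropy': 6.4262, 'rms': 0.4942, 'variance': 0.0455, 'smoothness': 0.0435,
 'kurtosis': 3.232, 'skewness': -0.1942, 'idm': 0.7736}

 task  method  RBF (%)  Linear (%)  Polynomial (%)  Quadratic (%)
tumor     DWT     75.0        75.0            75.0           75.0
tumor DWT+LPT    100.0       100.0           100.0           75.0
```

The 13-entry vector summarizes one malignant phantom (high GLCM contrast
and entropy, low energy — rough, heterogeneous texture). The grid trains
on 16 undistorted phantoms (9 benign / 7 malignant) and validates on 4
randomly *rotated* ones: the log-polar path keeps its accuracy under
rotation while the plain wavelet path degrades — the ordering the method
exists to produce. Single-split numbers on 4 images are coarse (25 pp
steps); `lpbrain.pipeline.mean_accuracy_over_seeds` averages the grid over
master seeds.

The same flow is available from the shell:

```sh
lpbrain simulate --preset simulated --seed 0 --out ds/
lpbrain extract ds/images/train_benign_000.png --out features.csv
lpbrain experiment --preset simulated --distortion rotate --seed 0 --out report.csv
```

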