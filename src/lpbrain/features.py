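"""The 13-feature texture/intensity vector and PCA/ICA reduction.

Each image is summarized by exactly 13 numbers in a fixed order: five
Haralick-style statistics of the gray-level co-occurrence matrix (GLCM)
averaged over the four standard unit offsets, and eight intensity
statistics of the pixel population.  The working image on which they are
computed may first be passed through the log-polar transform and/or the
wavelet approximation band, which is what makes the vector approximately
rotation- and scale-invariant.

Feature order (immutable):
``contrast, correlation, energy, homogeneity, mean, standard_deviation,
entropy, rms, variance, smoothness, kurtosis, skewness, idm``

Definitions (p = normalized GLCM, x = pixel population):

* contrast      = sum (i-j)^2 p(i,j)
* correlation   = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j); defined
  as 1 when either marginal variance is zero (single-cell GLCM)
* energy        = sum p(i,j)^2
* homogeneity   = sum p(i,j) / (1 + |i-j|)
* idm           = sum p(i,j) / (1 + (i-j)^2)
* mean, variance, standard_deviation: population moments of x
* entropy       = Shannon entropy (bits) of the 256-bin histogram on [0,1]
* rms           = sqrt(mean(x^2))  (so rms^2 = variance + mean^2)
* smoothness    = 1 - 1/(1 + variance)
* skewness, kurtosis: standardized 3rd/4th central moments (0 for a
  constant image, by convention)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from scipy import stats as spstats

FEATURE_NAMES: tuple[str, ...] = (
    "contrast", "correlation", "energy", "homogeneity", "mean",
    "standard_deviation", "entropy", "rms", "variance", "smoothness",
    "kurtosis", "skewness", "idm",
)

#: unit displacements at 0, 45, 90 and 135 degrees, (drow, dcol)
STANDARD_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalized gray-level co-occurrence matrix.

    ``counts[i, j]`` is the probability that a pixel quantized to level
    ``i`` has a neighbor at displacement ``offset`` quantized to level
    ``j`` (symmetrized if ``symmetric``).
    """

    counts: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.shape != (self.levels, self.levels):
            raise ValueError(f"counts must be {self.levels}x{self.levels}, got {c.shape}")
        if c.min() < 0 or abs(c.sum() - 1.0) > 1e-12:
            raise ValueError("counts must be non-negative and sum to 1")
        object.__setattr__(self, "counts", c)


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 1] intensities into integer levels."""
    img = np.asarray(img, dtype=np.float64)
    return np.clip((img * levels).astype(np.intp), 0, levels - 1)


def compute_glcm(
    img: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> GLCMMatrix:
    """Count ordered co-occurring pixel pairs at a fixed displacement.

    Intensities are first quantized into ``levels`` equal-width bins on
    [0, 1].  With ``symmetric=True`` each pair is also counted in reverse,
    making the matrix exactly symmetric.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    dr, dc = int(offset[0]), int(offset[1])
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be non-zero")
    H, W = img.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValueError(f"offset {offset} does not fit image of shape {img.shape}")

    q = quantize(img, levels)
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for this offset")
    return GLCMMatrix(counts / total, levels, (dr, dc), symmetric)


def glcm_features(g: GLCMMatrix) -> tuple[float, float, float, float, float]:
    """``(contrast, correlation, energy, homogeneity, idm)`` of a GLCM."""
    p = g.counts
    idx = np.arange(g.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j

    contrast = float(np.sum(diff ** 2 * p))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    idm = float(np.sum(p / (1.0 + diff ** 2)))

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(idx * pi))
    mu_j = float(np.sum(idx * pj))
    var_i = float(np.sum((idx - mu_i) ** 2 * pi))
    var_j = float(np.sum((idx - mu_j) ** 2 * pj))
    if var_i <= 0.0 or var_j <= 0.0:
        correlation = 1.0  # degenerate single-level GLCM
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    return contrast, correlation, energy, homogeneity, idm


def intensity_features(img: np.ndarray) -> tuple[float, ...]:
    """``(mean, standard_deviation, entropy, rms, variance, smoothness,
    kurtosis, skewness)`` over the pixel population."""
    x = np.asarray(img, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("image is empty")
    mean = float(x.mean())
    variance = float(x.var())  # population variance
    std = float(np.sqrt(variance))
    rms = float(np.sqrt(np.mean(x ** 2)))
    smoothness = 1.0 - 1.0 / (1.0 + variance)

    hist, _ = np.histogram(x, bins=256, range=(0.0, 1.0))
    pk = hist / hist.sum()
    nz = pk[pk > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    if std == 0.0:
        skewness = kurtosis = 0.0  # degenerate constant image
    else:
        z = (x - mean) / std
        skewness = float(np.mean(z ** 3))
        kurtosis = float(np.mean(z ** 4))
    return mean, std, entropy, rms, variance, smoothness, kurtosis, skewness


@dataclass(frozen=True)
class FeatureConfig:
    """Pipeline flags controlling what the 13 features are computed on.

    With both transforms enabled, ``lpt_before_dwt`` selects whether the
    log-polar image feeds the wavelet stage (default) or vice versa.
    ``recenter`` re-centers the LPT on the foreground centroid, restoring
    approximate invariance for off-center subjects.
    """

    use_lpt: bool = True
    use_dwt: bool = True
    lpt_before_dwt: bool = True
    recenter: bool = True
    lpt_M: int = 64
    lpt_N: int = 64
    #: innermost radius of the feature-path LPT.  Log-radius sampling puts
    #: half the rows below sqrt(r_min * r_max); r_min = 8 px spreads them
    #: over the anatomy instead of a magnified few-pixel neighborhood of
    #: the center.
    lpt_r_min: float = 8.0
    wavelet: str = "haar"
    glcm_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = STANDARD_OFFSETS
    glcm_symmetric: bool = True


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def extract_feature_vector(img: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Compute the 13-feature vector of an image under the given flags.

    The working image is the (optionally log-polar transformed, optionally
    wavelet-approximated) input, min-max rescaled to [0, 1].  GLCM features
    are averaged over the four standard offsets; intensity features are
    computed on the same working image.  Output order is `FEATURE_NAMES`.
    """
    from lpbrain.logpolar import foreground_centroid, lpt
    from lpbrain.wavelet import dwt2

    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        from lpbrain.preprocess import to_grayscale
        img = to_grayscale(img)

    def apply_lpt(x: np.ndarray) -> np.ndarray:
        center = foreground_centroid(x) if cfg.recenter else None
        return lpt(x, M=cfg.lpt_M, N=cfg.lpt_N, r_min=cfg.lpt_r_min,
                   center=center).pixels

    def apply_dwt(x: np.ndarray) -> np.ndarray:
        return dwt2(x, cfg.wavelet)[0]

    working = img
    stages = ((apply_lpt, apply_dwt) if cfg.lpt_before_dwt else (apply_dwt, apply_lpt))
    enabled = ((cfg.use_lpt, cfg.use_dwt) if cfg.lpt_before_dwt else (cfg.use_dwt, cfg.use_lpt))
    for stage, on in zip(stages, enabled):
        if on:
            working = stage(working)
    working = _normalize01(np.asarray(working, dtype=np.float64))

    glcm_block = np.zeros(5)
    for off in cfg.glcm_offsets:
        g = compute_glcm(working, cfg.glcm_levels, off, cfg.glcm_symmetric)
        glcm_block += np.array(glcm_features(g))
    glcm_block /= len(cfg.glcm_offsets)

    mean, std, entropy, rms, variance, smoothness, kurtosis, skewness = \
        intensity_features(working)
    contrast, correlation, energy, homogeneity, idm = glcm_block
    vec = np.array([contrast, correlation, energy, homogeneity, mean, std,
                    entropy, rms, variance, smoothness, kurtosis, skewness, idm])
    assert vec.shape == (len(FEATURE_NAMES),) and np.all(np.isfinite(vec))
    return vec


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows of feature vectors with class labels and image provenance."""

    X: np.ndarray
    labels: tuple[str, ...]
    provenance: tuple[str, ...] = ()
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if len(self.labels) != X.shape[0]:
            raise ValueError("one label per row required")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names must match the column count")
        prov = self.provenance or tuple(f"row{r}" for r in range(X.shape[0]))
        if len(prov) != X.shape[0]:
            raise ValueError("one provenance entry per row required")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "provenance", tuple(prov))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.insert(1, "provenance", list(self.provenance))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("label", "provenance"))
        return cls(df[list(names)].to_numpy(dtype=np.float64),
                   tuple(df["label"].astype(str)),
                   tuple(df["provenance"].astype(str)), names)


def extract_feature_matrix(images, labels, cfg: FeatureConfig = FeatureConfig(),
                           provenance=None) -> FeatureMatrix:
    """Stack :func:`extract_feature_vector` over a list of images."""
    X = np.stack([extract_feature_vector(im, cfg) for im in images])
    return FeatureMatrix(X, tuple(labels), tuple(provenance or ()))


def pca_fit_transform(X, n_components: int):
    """Center and project onto the leading principal axes.

    Accepts a :class:`FeatureMatrix` or a plain ``(n, p)`` array; returns
    ``(reduced, model)`` where *model* is a fitted ``sklearn`` PCA holding
    the column means and components for reuse on validation rows.
    """
    fm = X if isinstance(X, FeatureMatrix) else None
    arr = X.X if fm is not None else np.asarray(X, dtype=np.float64)
    n, p = arr.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components must be in [1, min(p={p}, n-1={n - 1})], got {n_components}")
    model = PCA(n_components=n_components, svd_solver="full")
    reduced = model.fit_transform(arr)
    if fm is not None:
        names = tuple(f"pc{i + 1}" for i in range(n_components))
        return FeatureMatrix(reduced, fm.labels, fm.provenance, names), model
    return reduced, model


def ica_fit_transform(X, n_components: int, seed: int = 0, max_iter: int = 1000):
    """Whiten then FastICA (negentropy fixed-point) with a fixed seed.

    Returns ``(reduced, model)``; ``model.converged_`` is False when the
    fixed-point iteration hit ``max_iter`` (partial result still returned).
    Warns when every recovered component looks Gaussian (|excess kurtosis|
    small), in which case the unmixing is unidentifiable beyond whitening.
    """
    fm = X if isinstance(X, FeatureMatrix) else None
    arr = X.X if fm is not None else np.asarray(X, dtype=np.float64)
    n, p = arr.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components must be in [1, min(p={p}, n-1={n - 1})], got {n_components}")
    model = FastICA(n_components=n_components, random_state=int(seed),
                    max_iter=max_iter, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        reduced = model.fit_transform(arr)
    model.converged_ = not any(issubclass(w.category, ConvergenceWarning)
                               for w in caught)
    if not model.converged_:
        warnings.warn("FastICA did not converge; returning partial result",
                      ConvergenceWarning)
    excess_kurt = spstats.kurtosis(reduced, axis=0, fisher=True, bias=True)
    if np.all(np.abs(excess_kurt) < 0.2):
        warnings.warn("all components look Gaussian: independent directions "
                      "are unidentifiable beyond whitening", UserWarning)
    if fm is not None:
        names = tuple(f"ic{i + 1}" for i in range(n_components))
        return FeatureMatrix(reduced, fm.labels, fm.provenance, names), model
    return reduced, model
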