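"""K-means clustering segmentation of MR slices.

Pixels are clustered on intensity (grayscale path, the pipeline default) or
on CIELAB a*b* chromaticity (color path) with Lloyd's algorithm under the
Euclidean metric.  The candidate tumor mask is the brightest cluster
restricted to its largest connected component — lesions are the
hyper-intense structure in T2-like contrast (the T1-like path inverts the
image first if asked).

Lloyd's algorithm is written out here rather than delegated, because the
segmentation contract exposes the per-iteration inertia trace and a
deterministic empty-cluster rule (re-seed at the farthest point) that
library implementations do not guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

DEFAULT_K = 3


class DegenerateSegmentationWarning(UserWarning):
    """Clustering collapsed (e.g. constant image): tumor mask unreliable."""


@dataclass(frozen=True)
class SegmentationResult:
    """Output of :func:`segment_image`.

    Attributes
    ----------
    labels : (H, W) int ndarray
        Cluster index per pixel, in ``{0..k-1}``.
    centers : (k, d) ndarray
        Cluster centers in the clustered feature space.
    inertia : float
        Sum of squared distances of samples to their assigned centers.
    tumor_mask : (H, W) {0,1} ndarray
        Largest connected component of the brightest cluster.
    inertia_trace : tuple of float
        Inertia after each Lloyd assignment step (non-increasing).
    """

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    tumor_mask: np.ndarray
    inertia_trace: tuple[float, ...] = field(default=())


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers with D^2 weighting."""
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    first = rng.integers(n)
    centers[0] = points[first]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[i:] = points[rng.integers(n, size=k - i)]
            break
        probs = d2 / total
        idx = rng.choice(n, p=probs)
        centers[i] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[i]) ** 2, axis=1))
    return centers


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, tuple[float, ...]]:
    """Lloyd's algorithm with k-means++ initialization.

    Iterates assign/update until the largest center movement falls below
    ``tol`` or ``max_iter`` is reached.  An emptied cluster is re-seeded at
    the point farthest from its assigned center.  ``init`` optionally
    supplies explicit ``(k, d)`` starting centers instead of k-means++.

    Returns
    -------
    labels : (n,) int ndarray
    centers : (k, d) ndarray
    inertia : float
        Sum of squared Euclidean distances to assigned centers.
    inertia_trace : tuple of float
        Inertia recorded after every assignment step.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    n, d = points.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if init is not None:
        centers = np.array(init, dtype=np.float64)
        if centers.shape != (k, d):
            raise ValueError(f"init must have shape ({k}, {d}), got {centers.shape}")
    else:
        rng = np.random.default_rng(seed)
        centers = _kmeans_pp_init(points, k, rng)

    trace: list[float] = []
    labels = np.zeros(n, dtype=np.intp)
    for _ in range(max_iter):
        d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        trace.append(inertia)
        new_centers = centers.copy()
        for c in range(k):
            members = labels == c
            if members.any():
                new_centers[c] = points[members].mean(axis=0)
            else:
                # empty cluster: re-seed at the farthest point overall
                farthest = int(np.argmax(d2[np.arange(n), labels]))
                new_centers[c] = points[farthest]
        movement = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if movement < tol:
            break

    d2 = np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    trace.append(inertia)
    return labels, centers, inertia, tuple(trace)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, ncomp = ndimage.label(mask)
    if ncomp == 0:
        return np.zeros_like(mask, dtype=np.float64)
    sizes = ndimage.sum_labels(np.ones_like(mask), labeled, range(1, ncomp + 1))
    best = int(np.argmax(sizes)) + 1
    return (labeled == best).astype(np.float64)


def segment_image(
    img: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 4,
) -> SegmentationResult:
    """Cluster an image into ``k`` regions and extract a tumor candidate.

    Grayscale input is clustered on intensity; RGB input is first converted
    to CIELAB (sRGB, D65) and clustered on the (a*, b*) chromaticity plane.
    The tumor mask is the cluster with the highest mean grayscale intensity,
    restricted to its largest connected component.  If clustering collapses
    to a single populated cluster (no structure), a
    :class:`DegenerateSegmentationWarning` is issued and the mask is empty.

    ``n_init`` k-means++ restarts are run (with seeds derived from
    ``seed``) and the lowest-inertia solution kept: a small lesion next to
    a large tissue cluster is exactly the geometry where a single Lloyd
    run can stall in a merged local minimum.  The result is still a pure
    function of ``(img, k, seed)``.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3 and img.shape[2] == 3:
        lab = skcolor.rgb2lab(img)
        feats = lab[..., 1:3].reshape(-1, 2)
        gray = img @ np.array([0.299, 0.587, 0.114])
    elif img.ndim == 2:
        feats = img.reshape(-1, 1)
        gray = img
    else:
        raise ValueError(f"expected (H, W) or (H, W, 3) image, got {img.shape}")

    H, W = gray.shape
    best = None
    for restart in range(max(1, n_init)):
        result = kmeans(feats, k, seed=seed + restart * 10_007,
                        max_iter=max_iter, tol=tol)
        if best is None or result[2] < best[2]:
            best = result
    labels, centers, inertia, trace = best
    label_map = labels.reshape(H, W)

    populated = np.unique(labels)
    if populated.size < 2:
        warnings.warn("clustering found a single populated cluster; "
                      "tumor mask is empty", DegenerateSegmentationWarning)
        mask = np.zeros((H, W))
    else:
        mean_gray = np.array([gray.reshape(-1)[labels == c].mean()
                              for c in populated])
        bright = populated[int(np.argmax(mean_gray))]
        mask = _largest_component(label_map == bright)
    return SegmentationResult(label_map, centers, inertia, mask, trace)
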