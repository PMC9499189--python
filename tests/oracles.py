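"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration or a double loop,
sharing no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def glcm_brute(img: np.ndarray, levels: int, offset: tuple[int, int],
               symmetric: bool) -> np.ndarray:
    """Double-loop GLCM: quantize then count every pixel pair explicitly."""
    H, W = img.shape
    q = np.minimum((img * levels).astype(int), levels - 1)
    counts = np.zeros((levels, levels))
    dr, dc = offset
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def glcm_features_brute(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Double-loop Haralick statistics of a normalized GLCM."""
    L = p.shape[0]
    contrast = energy = homog = idm = 0.0
    mu_i = mu_j = 0.0
    for i in range(L):
        for j in range(L):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(L):
        for j in range(L):
            contrast += (i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            idm += p[i, j] / (1 + (i - j) ** 2)
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    if var_i <= 0 or var_j <= 0:
        corr = 1.0
    else:
        corr = cov / np.sqrt(var_i * var_j)
    return contrast, corr, energy, homog, idm


def kmeans_1d_brute(points: np.ndarray, k: int) -> tuple[float, list[np.ndarray]]:
    """Optimal 1-D k-means by enumerating contiguous partitions.

    For squared-error clustering in one dimension the optimal partition is
    contiguous in sorted order, so enumerating breakpoint placements is an
    exhaustive search.  Returns (optimal inertia, optimal centers).
    """
    xs = np.sort(np.asarray(points, dtype=float).ravel())
    n = len(xs)
    best = (np.inf, None)
    for breaks in itertools.combinations(range(1, n), k - 1):
        edges = (0, *breaks, n)
        inertia = 0.0
        centers = []
        for a, b in zip(edges[:-1], edges[1:]):
            seg = xs[a:b]
            centers.append(seg.mean())
            inertia += ((seg - seg.mean()) ** 2).sum()
        if inertia < best[0]:
            best = (inertia, np.array(centers))
    return best


def otsu_brute(img: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive Otsu: maximize between-class variance over all cut points."""
    flat = img.ravel()
    hist, edges = np.histogram(flat, bins=nbins, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_sigma = centers[0], -1.0
    for t in range(1, nbins):
        w0, w1 = p[:t].sum(), p[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[:t] * centers[:t]).sum() / w0
        mu1 = (p[t:] * centers[t:]).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, centers[t - 1:t + 1].mean()
    return best_t
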