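"""Log-polar transformation (LPT): the rotation/scale-invariance core.

The LPT resamples an image onto a (log-radius, angle) grid about a center
point.  Under this conformal mapping a rotation of the source image about
the center becomes a circular shift along the angle axis, and a uniform
scaling about the center becomes a translation along the log-radius axis:
``log(alpha * r) = log(alpha) + log(r)``.  Translations of the source are
*not* invariant — they warp the log-polar image nonlinearly — which
:func:`translate_sensitivity` quantifies.

Conventions
-----------
* Natural logarithm throughout (the inverse map is ``x = e^rho cos(theta)``,
  ``y = e^rho sin(theta)``).
* ``theta`` is measured from the +x (column) axis toward the +y (row) axis.
  Because the row axis points *down* in image coordinates, increasing theta
  sweeps clockwise on screen; a counter-clockwise on-screen rotation by
  ``delta`` therefore shifts LPT columns by ``-N * delta / 360``.
* Rows of the output sample ``rho`` uniformly on ``[log r_min, log r_max]``
  (both endpoints included, ``M`` samples); columns sample ``theta``
  uniformly on ``[0, 2*pi)`` (``N`` samples, endpoint excluded so the axis
  is exactly periodic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import math
import os
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LogPolarImage:
    """An image resampled on a (log-radius, angle) grid.

    Attributes
    ----------
    pixels : (M, N) ndarray
        Row ``i`` samples log-radius ``rho_i``, column ``j`` samples angle
        ``theta_j``.
    center : (float, float)
        Source-image center as ``(xc, yc)`` = (column, row) pixel coords.
    r_min, r_max : float
        Radial range of the sampling annulus, in source pixels.
    source_shape : (int, int)
        ``(H, W)`` of the source image.
    """

    pixels: np.ndarray
    center: tuple[float, float]
    r_min: float
    r_max: float
    source_shape: tuple[int, int]
    fill: str = "zero"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"log-polar pixels must be at least 2x2, got {px.shape}")
        if not self.r_min < self.r_max:
            raise ValueError(f"need r_min < r_max, got {self.r_min} >= {self.r_max}")
        object.__setattr__(self, "pixels", px)

    @property
    def M(self) -> int:
        return self.pixels.shape[0]

    @property
    def N(self) -> int:
        return self.pixels.shape[1]

    @property
    def delta_rho(self) -> float:
        """Log-radius spacing between consecutive rows."""
        return (math.log(self.r_max) - math.log(self.r_min)) / (self.M - 1)

    @property
    def rho_grid(self) -> np.ndarray:
        return np.linspace(math.log(self.r_min), math.log(self.r_max), self.M)

    @property
    def theta_grid(self) -> np.ndarray:
        return np.arange(self.N) * (2.0 * math.pi / self.N)

    def save(self, png_path: str | os.PathLike) -> None:
        """Write pixels as 8-bit PNG plus a JSON metadata sidecar."""
        from lpbrain.preprocess import save_image

        png_path = Path(png_path)
        save_image(np.clip(self.pixels, 0, 1), png_path)
        meta = {
            "center": list(self.center),
            "r_min": self.r_min,
            "r_max": self.r_max,
            "source_shape": list(self.source_shape),
            "M": self.M,
            "N": self.N,
            "fill": self.fill,
        }
        png_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


class CenterSingularityError(ValueError):
    """The log-polar map is singular at the center point (log 0)."""


def cart_to_logpolar_coords(
    x: float, y: float, center: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Map a Cartesian point to ``(rho, theta)`` about ``center``.

    ``rho = log sqrt((x-xc)^2 + (y-yc)^2)`` (Euclidean radius) and
    ``theta = atan2(y-yc, x-xc)`` wrapped to ``[0, 2*pi)``.
    """
    xc, yc = center
    dx, dy = x - xc, y - yc
    r2 = dx * dx + dy * dy
    if r2 == 0.0:
        raise CenterSingularityError("log-polar coordinates undefined at the center")
    rho = 0.5 * math.log(r2)
    theta = math.atan2(dy, dx) % (2.0 * math.pi)
    return rho, theta


def logpolar_to_cart(rho: float, theta: float) -> tuple[float, float]:
    """Inverse map: ``(e^rho cos(theta), e^rho sin(theta))``."""
    r = math.exp(rho)
    return r * math.cos(theta), r * math.sin(theta)


def lpt(
    img: np.ndarray,
    M: int = 64,
    N: int = 64,
    r_min: float = 1.0,
    r_max: float | None = None,
    center: tuple[float, float] | None = None,
    fill: str = "zero",
) -> LogPolarImage:
    """Resample a grayscale image onto an M x N (log-radius, angle) grid.

    Each output pixel ``(i, j)`` is the bilinear sample of ``img`` at the
    Cartesian point ``center + e^{rho_i} (cos theta_j, sin theta_j)``.

    Parameters
    ----------
    img : (H, W) ndarray
        Grayscale image in [0, 1].
    M, N : int
        Number of log-radius rows / angle columns (both >= 2).
    r_min : float
        Innermost sampled radius in pixels (>= 0.5; the map is singular at 0).
    r_max : float, optional
        Outermost radius; defaults to ``min(H, W) / 2`` (the inscribed
        circle, so no sample leaves the image for a centered transform).
    center : (xc, yc), optional
        Transform center in (column, row) pixel coordinates; defaults to
        the geometric center ``((W-1)/2, (H-1)/2)``.
    fill : {"zero", "nearest"}
        Value for samples outside the image support.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {img.shape}")
    H, W = img.shape
    if M < 2 or N < 2:
        raise ValueError(f"M and N must both be >= 2, got ({M}, {N})")
    if r_min < 0.5:
        raise ValueError(f"r_min must be >= 0.5 pixel, got {r_min}")
    if r_max is None:
        r_max = min(H, W) / 2.0
    if r_min >= r_max:
        raise ValueError(f"need r_min < r_max, got {r_min} >= {r_max}")
    if center is None:
        center = ((W - 1) / 2.0, (H - 1) / 2.0)
    if fill not in ("zero", "nearest"):
        raise ValueError(f"fill must be 'zero' or 'nearest', got {fill!r}")

    xc, yc = center
    rho = np.linspace(math.log(r_min), math.log(r_max), M)
    theta = np.arange(N) * (2.0 * math.pi / N)
    r = np.exp(rho)[:, None]                        # (M, 1)
    xs = xc + r * np.cos(theta)[None, :]            # (M, N) column coords
    ys = yc + r * np.sin(theta)[None, :]            # (M, N) row coords

    mode = "constant" if fill == "zero" else "nearest"
    out = ndimage.map_coordinates(
        img, np.stack([ys, xs]), order=1, mode=mode, cval=0.0
    )
    return LogPolarImage(out, (xc, yc), float(r_min), float(r_max), (H, W), fill)


def column_shift(lp: LogPolarImage, k: int) -> LogPolarImage:
    """Circularly shift the angle axis by ``k`` columns (metadata kept).

    A shift by ``k`` moves column ``j`` to column ``j + k (mod N)``, i.e. it
    emulates rotating the source by ``-k * 360 / N`` degrees on screen
    (counter-clockwise rotations correspond to negative ``k``).
    """
    return LogPolarImage(
        np.roll(lp.pixels, int(k), axis=1),
        lp.center, lp.r_min, lp.r_max, lp.source_shape, lp.fill,
    )


def row_shift_for_scale(lp: LogPolarImage, alpha: float) -> float:
    """Row displacement (in bins) induced by scaling the source by ``alpha``.

    Content at radius ``r`` moves to ``alpha * r``, so the log-radius axis
    translates by ``log(alpha) / delta_rho`` bins toward larger rho.
    """
    return math.log(alpha) / lp.delta_rho


def translate_sensitivity(
    img: np.ndarray, dx: float, dy: float, M: int = 64, N: int = 64, **lpt_kwargs
) -> float:
    """Mean |LPT(translated image) - LPT(image)| with the center held fixed.

    Quantifies the LPT's lack of translation invariance: shifting the source
    by ``(dx, dy)`` while keeping the transform center warps every ring.
    Returns 0 exactly for ``dx = dy = 0``.
    """
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape
    if abs(dx) >= min(H, W) / 4 or abs(dy) >= min(H, W) / 4:
        raise ValueError("|dx|, |dy| must be < min(H, W)/4")
    base = lpt(img, M=M, N=N, **lpt_kwargs)
    if dx == 0 and dy == 0:
        return 0.0
    # shift by (dx, dy) = (column, row) displacement, bilinear, zero fill
    moved = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
    shifted = lpt(moved, M=M, N=N, **lpt_kwargs)
    return float(np.mean(np.abs(shifted.pixels - base.pixels)))


def foreground_centroid(img: np.ndarray, threshold: float | str = "otsu") -> tuple[float, float]:
    """Intensity centroid ``(xc, yc)`` of the binarized foreground.

    Used to re-center the LPT on the brain before feature extraction, which
    restores approximate invariance when the subject is off-center.  Falls
    back to the geometric center for blank images.
    """
    from lpbrain.preprocess import binarize

    mask = binarize(img, threshold)
    H, W = img.shape
    total = mask.sum()
    if total == 0:
        return ((W - 1) / 2.0, (H - 1) / 2.0)
    rows, cols = np.nonzero(mask)
    return (float(cols.mean()), float(rows.mean()))
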