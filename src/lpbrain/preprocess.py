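"""Image I/O and the pre-processing chain.

All images are float64 arrays with intensities in [0, 1]: grayscale images
are ``(H, W)``, color images ``(H, W, 3)``, row-major with the origin at the
top-left and (row, col) indexing.  On disk, images are 8-bit PNG/JPEG/BMP.

The pre-processing chain for an MR slice is: resize -> RGB-to-grayscale
(luminance only; hue/saturation discarded) -> median denoising -> optional
Otsu binarization for foreground masking.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage import transform as sktransform
from skimage.filters import threshold_otsu

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}

#: ITU-R BT.601 luminance weights for RGB -> grayscale.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class UnsupportedFormatError(ValueError):
    """Raised when a file suffix is not one of png/jpg/bmp."""


def _check_unit_range(pixels: np.ndarray, name: str = "pixels") -> None:
    if pixels.size and (pixels.min() < -1e-12 or pixels.max() > 1 + 1e-12):
        raise ValueError(f"{name} must lie in [0, 1]; got range "
                         f"[{pixels.min():.4g}, {pixels.max():.4g}]")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/JPEG/BMP file as an ``(H, W, 3)`` float array in [0, 1].

    Grayscale files are promoted to three identical channels; alpha channels
    are dropped.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    UnsupportedFormatError
        If the suffix is not one of png/jpg/jpeg/bmp.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r}; "
            f"expected one of {sorted(SUPPORTED_SUFFIXES)}")
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.float64) / 255.0
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return arr


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] gray or RGB array as an 8-bit image file."""
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise UnsupportedFormatError(
            f"unsupported image format {path.suffix!r}")
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    quantized = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(quantized).save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an ``(H, W, 3)`` image to luminance (BT.601 weights).

    Hue and saturation are discarded; a channel-equal (promoted grayscale)
    image maps back to its single channel exactly since the weights sum to 1.
    Already-2-D input is returned unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {img.shape}")
    _check_unit_range(img)
    return img @ LUMA_WEIGHTS


def binarize(img: np.ndarray, threshold: float | str = "otsu") -> np.ndarray:
    """Threshold a grayscale image to {0, 1}: pixel > threshold -> 1.

    ``threshold`` is either a number in (0, 1) or the string ``"otsu"``,
    which picks the threshold maximizing between-class variance over the
    256-bin histogram.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {img.shape}")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        if np.ptp(img) == 0:
            # Degenerate constant image: Otsu undefined; everything below.
            return np.zeros_like(img)
        thr = float(threshold_otsu(img, nbins=256))
    else:
        thr = float(threshold)
        if not 0.0 < thr < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {thr}")
    return (img > thr).astype(np.float64)


def denoise(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter a grayscale image with an odd square window.

    ``window=1`` is the identity.  Median filtering is the standard choice
    for impulsive (salt-and-pepper) noise in MR slices because it preserves
    edges that a linear smoother would blur.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {img.shape}")
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return img.copy()
    return ndimage.median_filter(img, size=window, mode="reflect")


def resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample to exactly ``(out_h, out_w)``, clipped to [0, 1].

    Works on both grayscale ``(H, W)`` and color ``(H, W, 3)`` arrays and
    preserves the kind.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    out_h, out_w = int(out_h), int(out_w)
    if out_h < 1 or out_w < 1:
        raise ValueError(f"output dims must be positive, got ({out_h}, {out_w})")
    if img.shape[:2] == (out_h, out_w):
        return img.copy()
    out_shape = (out_h, out_w) if img.ndim == 2 else (out_h, out_w, img.shape[2])
    out = sktransform.resize(img, out_shape, order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def preprocess_chain(img: np.ndarray, *, size: tuple[int, int] | None = None,
                     denoise_window: int = 3) -> np.ndarray:
    """Full pre-processing: optional resize, grayscale conversion, denoise."""
    if img.ndim == 3:
        img = to_grayscale(img)
    if size is not None:
        img = resize(img, *size)
    return denoise(img, denoise_window)
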