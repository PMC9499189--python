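"""Separable 2-D discrete wavelet transform: LL/LH/HL/HH sub-bands.

One analysis level convolves rows and columns with the low-pass/high-pass
analysis pair and decimates by 2 (the dyadic lattice), yielding four
sub-bands: LL (approximation) and LH/HL/HH (details).  Cascading re-applies
the transform to the LL band.  Backed by PyWavelets.

The default boundary mode is ``"periodization"``: it is the only mode under
which the transform of an orthogonal wavelet (haar, db4, ...) is an
orthonormal change of basis at every size, so sub-bands have exactly
``ceil(H/2) x ceil(W/2)`` samples and total energy is conserved.  Other
PyWavelets modes (e.g. ``"symmetric"``) are accepted and produce redundant
boundary coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

Subbands = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

DEFAULT_WAVELET = "haar"
DEFAULT_MODE = "periodization"


def _check_wavelet(name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet name {name!r}") from exc


@dataclass(frozen=True)
class WaveletDecomposition:
    """A cascaded 2-D DWT: per-level (LL, LH, HL, HH) sub-band images.

    ``levels[l]`` holds the four sub-bands produced at depth ``l+1``; the LL
    stored at each level is the one fed to the next level (the final LL is
    ``levels[-1][0]``).
    """

    levels: tuple[Subbands, ...]
    wavelet_name: str
    boundary_mode: str

    def __post_init__(self) -> None:
        for bands in self.levels:
            if len(bands) != 4:
                raise ValueError("each level must hold exactly 4 sub-bands")

    @property
    def depth(self) -> int:
        return len(self.levels)

    def subband(self, level: int, name: str) -> np.ndarray:
        """Fetch a sub-band by 1-based level and name in {LL, LH, HL, HH}."""
        names = ("LL", "LH", "HL", "HH")
        if name not in names:
            raise ValueError(f"sub-band name must be one of {names}")
        return self.levels[level - 1][names.index(name)]


def dwt2(img: np.ndarray, wavelet: str = DEFAULT_WAVELET,
         mode: str = DEFAULT_MODE) -> Subbands:
    """One analysis level: returns ``(LL, LH, HL, HH)``.

    LH carries horizontal detail (high-pass across columns), HL vertical
    detail, HH diagonal.  For orthonormal Haar a constant image ``c`` maps
    to ``LL = 2c`` (gain sqrt(2) per axis) and zero detail bands.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"expected 2-D image with H, W >= 2, got shape {img.shape}")
    wav = _check_wavelet(wavelet)
    cA, (cH, cV, cD) = pywt.dwt2(img, wav, mode=mode)
    return cA, cH, cV, cD


def idwt2(LL: np.ndarray, LH: np.ndarray, HL: np.ndarray, HH: np.ndarray,
          wavelet: str = DEFAULT_WAVELET, mode: str = DEFAULT_MODE) -> np.ndarray:
    """Synthesis filter bank; perfect reconstruction for orthogonal wavelets.

    Zero-filled detail bands may be passed as arrays of zeros matching LL.
    """
    wav = _check_wavelet(wavelet)
    bands = [np.asarray(b, dtype=np.float64) for b in (LL, LH, HL, HH)]
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"sub-band shapes differ: {sorted(shapes)}")
    return pywt.idwt2((bands[0], tuple(bands[1:])), wav, mode=mode)


def max_levels(shape: tuple[int, int], wavelet: str = DEFAULT_WAVELET) -> int:
    """Deepest useful cascade for an image of the given shape."""
    wav = _check_wavelet(wavelet)
    return min(pywt.dwt_max_level(s, wav.dec_len) for s in shape)


def wavedec2(img: np.ndarray, levels: int = 1, wavelet: str = DEFAULT_WAVELET,
             mode: str = DEFAULT_MODE) -> WaveletDecomposition:
    """Cascade ``levels`` analysis steps, re-applying dwt2 to each LL."""
    img = np.asarray(img, dtype=np.float64)
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    feasible = max_levels(img.shape, wavelet)
    if levels > feasible:
        raise ValueError(
            f"{levels} levels too deep for shape {img.shape} with "
            f"wavelet {wavelet!r} (max {feasible})")
    out: list[Subbands] = []
    current = img
    for _ in range(levels):
        bands = dwt2(current, wavelet, mode)
        out.append(bands)
        current = bands[0]
    return WaveletDecomposition(tuple(out), wavelet, mode)
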