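"""Synthetic brain phantom generator with ground-truth lesion masks.

Each phantom is a 2-D slice-like image: an elliptical "brain" of smoothly
textured tissue with two dark ventricles, on a near-black background, with
an optional lesion.  The class axis is encoded geometrically and
texturally:

* ``normal`` — no lesion;
* ``benign`` — round, homogeneous lesion (low boundary irregularity, low
  internal texture heterogeneity);
* ``malignant`` — irregular, heterogeneous lesion (lobulated boundary,
  strong internal texture).

Modality encodes the lesion contrast sign relative to tissue: ``T2``-like
lesions are brighter than tissue (fluid-bright contrast), ``T1``-like
lesions darker.  This is a simple documented proxy for acquisition
contrast, not a physical MR simulation (no Bloch equations, no k-space).

Distortion operators apply the rotation (-180..+180 degrees) and scaling
(0.25..1.5) ranges the classifier is meant to be invariant to.  Every image
is a pure function of its :class:`PhantomSpec` (including the seed), so a
dataset manifest reproduces the dataset bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

CLASSES = ("normal", "benign", "malignant")
MODALITIES = ("T1", "T2")


class PhantomSpecError(ValueError):
    """Invalid phantom parameters (e.g. lesion outside the brain)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one labeled synthetic brain image.

    Class invariants: benign lesions have ``boundary_irregularity <= 0.2``
    and ``texture_heterogeneity <= 0.2``; malignant lesions have
    irregularity ``>= 0.5`` or heterogeneity ``>= 0.5``; normal phantoms
    have no lesion.  ``lesion_center=None`` auto-places the lesion off the
    ventricles, and ``lesion_radius=None`` defaults to 12% of the image
    side.  ``contrast_delta`` is the unsigned lesion-vs-tissue intensity
    offset (sign set by modality); ``noise_sigma`` is additive Gaussian.
    """

    cls: str = "benign"
    modality: str = "T2"
    size: tuple[int, int] = (256, 256)
    lesion_center: tuple[float, float] | None = None
    lesion_radius: float | None = None
    boundary_irregularity: float = 0.1
    texture_heterogeneity: float = 0.1
    contrast_delta: float = 0.35
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise PhantomSpecError(f"class must be one of {CLASSES}, got {self.cls!r}")
        if self.modality not in MODALITIES:
            raise PhantomSpecError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}")
        irr, het = self.boundary_irregularity, self.texture_heterogeneity
        if not (0 <= irr <= 1 and 0 <= het <= 1):
            raise PhantomSpecError("irregularity/heterogeneity must lie in [0,1]")
        if self.cls == "benign" and (irr > 0.2 or het > 0.2):
            raise PhantomSpecError(
                "benign lesions require irregularity <= 0.2 and heterogeneity <= 0.2")
        if self.cls == "malignant" and not (irr >= 0.5 or het >= 0.5):
            raise PhantomSpecError(
                "malignant lesions require irregularity >= 0.5 or heterogeneity >= 0.5")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom; returns ``(image, lesion_mask)`` in [0, 1] / {0, 1}.

    Deterministic per spec (all randomness from ``spec.seed``).  Raises
    :class:`PhantomSpecError` if any lesion pixel falls outside the brain
    ellipse.
    """
    H, W = spec.size
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ay, ax = 0.42 * H, 0.36 * W

    ell = ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2
    brain = ell <= 1.0

    img = np.full((H, W), 0.02)
    tissue = 0.5 + 0.04 * _smooth_field(rng, (H, W), sigma=H / 24)
    img[brain] = tissue[brain]

    # two dark ventricles flanking the midline, giving the third cluster
    for sx in (-1.0, 1.0):
        vy, vx = cy - 0.05 * H, cx + sx * 0.09 * W
        vent = (((rows - vy) / (0.12 * H)) ** 2
                + ((cols - vx) / (0.045 * W)) ** 2) <= 1.0
        img[vent & brain] = 0.22

    mask = np.zeros((H, W))
    if spec.cls != "normal":
        R = spec.lesion_radius if spec.lesion_radius is not None else 0.12 * min(H, W)
        auto_placed = spec.lesion_center is None
        if auto_placed:
            # off-ventricle placement in the lower half of the brain
            ang = rng.uniform(0.25 * math.pi, 0.75 * math.pi)
            off = 0.15 * min(H, W)
            ly, lx = cy + off * math.sin(ang), cx + off * math.cos(ang) * 1.2
        else:
            lx, ly = spec.lesion_center
        dy, dx = rows - ly, cols - lx
        dist = np.hypot(dy, dx)
        phi = np.arctan2(dy, dx)

        # lobulated boundary: random low-order Fourier perturbation of the radius
        wobble = np.zeros_like(phi)
        for kh in range(2, 7):
            a, b = rng.normal(0, 1.0 / kh, size=2)
            wobble += a * np.cos(kh * phi) + b * np.sin(kh * phi)
        peak = np.abs(wobble).max()
        if peak > 0:
            wobble /= peak

        # auto-placed lesions shrink until they fit inside the brain;
        # an explicit out-of-brain center is a spec error
        for _ in range(30):
            boundary = R * (1.0 + spec.boundary_irregularity * wobble)
            mask = (dist <= boundary).astype(np.float64)
            if not np.any((mask > 0) & ~brain):
                break
            if not auto_placed:
                raise PhantomSpecError("lesion extends outside the brain ellipse")
            R *= 0.9
        else:
            raise PhantomSpecError("could not fit lesion inside the brain ellipse")

        sign = 1.0 if spec.modality == "T2" else -1.0
        lesion_val = np.full((H, W), 0.5 + sign * spec.contrast_delta)
        lesion_val += (0.8 * spec.contrast_delta * spec.texture_heterogeneity
                       * _smooth_field(rng, (H, W), sigma=1.5))
        img = np.where(mask > 0, lesion_val, img)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=(H, W))
    return np.clip(img, 0.0, 1.0), mask


ANGLE_RANGE = (-180.0, 180.0)
SCALE_RANGE = (0.25, 1.5)


def distort(img: np.ndarray, angle_deg: float, scale: float, seed: int = 0) -> np.ndarray:
    """Rotate about the image center, then scale about the center.

    ``angle_deg`` in [-180, 180] (counter-clockwise on screen), ``scale``
    in [0.25, 1.5]; output has the source shape, bilinear interpolation,
    zero fill.  Exact multiples of 90 degrees are applied as lossless grid
    rotations.  ``seed`` is accepted for interface symmetry with the other
    generators; the operator itself is deterministic.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    if not ANGLE_RANGE[0] <= angle_deg <= ANGLE_RANGE[1]:
        raise ValueError(f"angle {angle_deg} outside {ANGLE_RANGE}")
    if not SCALE_RANGE[0] <= scale <= SCALE_RANGE[1]:
        raise ValueError(f"scale {scale} outside {SCALE_RANGE}")

    H, W = img.shape
    if angle_deg % 90 == 0 and H == W:
        out = np.rot90(img, k=int(angle_deg // 90) % 4).copy()
    elif angle_deg % 360 != 0:
        out = sktransform.rotate(img, angle_deg, resize=False, order=1,
                                 mode="constant", cval=0.0, preserve_range=True)
    else:
        out = img.copy()

    if scale != 1.0:
        # input_coord = output_coord / scale + center * (1 - 1/scale)
        c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        out = ndimage.affine_transform(
            out, np.eye(2) / scale, offset=c - c / scale,
            order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


# Tumor-classification presets: per-split benign/malignant counts as printed
# in the source tables for the simulated, T2-weighted and T1-weighted sets.
DATASET_PRESETS: dict[str, dict] = {
    "simulated": {
        "counts": {"train": {"benign": 9, "malignant": 7},
                   "validation": {"benign": 2, "malignant": 2}},
        "modality": "T2",
        "distortion": "rotate+scale",
    },
    "T2": {
        "counts": {"train": {"benign": 18, "malignant": 20},
                   "validation": {"benign": 4, "malignant": 6}},
        "modality": "T2",
        "distortion": "none",
    },
    "T1": {
        "counts": {"train": {"benign": 13, "malignant": 5},
                   "validation": {"benign": 4, "malignant": 2}},
        "modality": "T1",
        "distortion": "none",
    },
}

DISTORTION_POLICIES = ("none", "rotate", "scale", "rotate+scale")


@dataclass(frozen=True)
class LabeledDataset:
    """Images + labels + ground-truth masks + a reproducing manifest.

    The manifest row for image ``i`` holds everything needed to regenerate
    it bit-identically: the phantom spec fields, the per-image seed and the
    applied distortion.
    """

    images: tuple[np.ndarray, ...]
    masks: tuple[np.ndarray, ...]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.masks) == len(self.manifest)):
            raise ValueError("images, masks and manifest rows must align")

    @property
    def n(self) -> int:
        return len(self.images)

    def split(self, which: str) -> tuple[list[np.ndarray], list[str], list[str]]:
        """Return (images, labels, ids) for the 'train' or 'validation' split."""
        sel = self.manifest["split"] == which
        idx = list(np.nonzero(sel.to_numpy())[0])
        labels = list(self.manifest.loc[sel, "cls"])
        ids = list(self.manifest.loc[sel, "image_id"])
        return [self.images[i] for i in idx], labels, ids

    def save(self, directory) -> None:
        """Write a PNG tree (images + masks) and the manifest CSV."""
        from pathlib import Path
        from lpbrain.preprocess import save_image

        directory = Path(directory)
        (directory / "images").mkdir(parents=True, exist_ok=True)
        (directory / "masks").mkdir(parents=True, exist_ok=True)
        for img, msk, iid in zip(self.images, self.masks, self.manifest["image_id"]):
            save_image(img, directory / "images" / f"{iid}.png")
            save_image(msk, directory / "masks" / f"{iid}.png")
        self.manifest.to_csv(directory / "manifest.csv", index=False)


def _spec_for(cls: str, modality: str, size, child_seed: int,
              rng: np.random.Generator) -> PhantomSpec:
    """Draw per-image morphology within the class invariant ranges."""
    if cls == "benign":
        irr = rng.uniform(0.0, 0.2)
        het = rng.uniform(0.0, 0.2)
    elif cls == "malignant":
        irr = rng.uniform(0.5, 0.9)
        het = rng.uniform(0.5, 0.9)
    else:
        irr = het = 0.0
    radius = rng.uniform(0.09, 0.14) * min(size)
    return PhantomSpec(cls=cls, modality=modality, size=tuple(size),
                       lesion_radius=None if cls == "normal" else radius,
                       boundary_irregularity=irr, texture_heterogeneity=het,
                       seed=child_seed)


def make_dataset(
    counts: dict[str, dict[str, int]],
    modality: str = "T2",
    distortion: str = "none",
    distort_split: str = "validation",
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
) -> LabeledDataset:
    """Generate a labeled phantom dataset with exact per-class counts.

    Parameters
    ----------
    counts : dict
        ``{"train": {class: count, ...}, "validation": {...}}``.
    distortion : {"none", "rotate", "scale", "rotate+scale"}
        Which distortion to sample per image (rotation uniform on
        [-180, 180] degrees, scale uniform on [0.25, 1.5]).
    distort_split : {"validation", "train", "all"}
        Which split the distortion applies to.
    seed : int
        Master seed; per-image seeds are derived deterministically from it.
    """
    if distortion not in DISTORTION_POLICIES:
        raise ValueError(f"distortion must be one of {DISTORTION_POLICIES}")
    if distort_split not in ("validation", "train", "all"):
        raise ValueError("distort_split must be 'validation', 'train' or 'all'")

    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    rows: list[dict] = []
    counter = 0
    for split in ("train", "validation"):
        for cls in CLASSES:
            n = int(counts.get(split, {}).get(cls, 0))
            if n < 0:
                raise ValueError(f"negative count for {split}/{cls}")
            for idx in range(n):
                child_seed = (seed * 1_000_003 + counter * 7919 + 1) % (2 ** 31)
                counter += 1
                rng = np.random.default_rng(child_seed)
                spec = _spec_for(cls, modality, size, child_seed, rng)
                img, msk = make_phantom(spec)
                angle, scale = 0.0, 1.0
                if distortion != "none" and (distort_split == "all"
                                             or split == distort_split):
                    if "rotate" in distortion:
                        angle = float(rng.uniform(*ANGLE_RANGE))
                    if "scale" in distortion:
                        scale = float(rng.uniform(*SCALE_RANGE))
                    img = distort(img, angle, scale)
                    msk = distort(msk, angle, scale)
                    msk = (msk > 0.5).astype(np.float64)
                images.append(img)
                masks.append(msk)
                rows.append({
                    "image_id": f"{split}_{cls}_{idx:03d}",
                    "split": split,
                    "cls": cls,
                    "modality": modality,
                    "seed": child_seed,
                    "angle_deg": angle,
                    "scale": scale,
                    "irregularity": spec.boundary_irregularity,
                    "heterogeneity": spec.texture_heterogeneity,
                    "lesion_radius": spec.lesion_radius or 0.0,
                    "height": size[0],
                    "width": size[1],
                })
    return LabeledDataset(tuple(images), tuple(masks), pd.DataFrame(rows))


def make_preset_dataset(preset: str, seed: int = 0, size=(256, 256),
                        distortion: str | None = None,
                        distort_split: str = "validation") -> LabeledDataset:
    """Instantiate one of the named tumor-classification presets."""
    if preset not in DATASET_PRESETS:
        raise ValueError(f"preset must be one of {sorted(DATASET_PRESETS)}")
    p = DATASET_PRESETS[preset]
    return make_dataset(p["counts"], modality=p["modality"],
                        distortion=p["distortion"] if distortion is None else distortion,
                        distort_split=distort_split, seed=seed, size=size)
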