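import hashlib

import numpy as np
import pytest

from lpbrain.features import compute_glcm, glcm_features
from lpbrain.phantom import (
    DATASET_PRESETS, PhantomSpec, PhantomSpecError, distort, make_dataset,
    make_phantom, make_preset_dataset,
)


class TestPhantomSpec:
    def test_benign_morphology_bounds_enforced(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(cls="benign", boundary_irregularity=0.5)

    def test_malignant_needs_irregularity_or_heterogeneity(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(cls="malignant", boundary_irregularity=0.1,
                        texture_heterogeneity=0.1)

    def test_unknown_class_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(cls="weird")


class TestMakePhantom:
    def test_normal_class_has_empty_mask(self):
        img, mask = make_phantom(PhantomSpec(cls="normal", seed=0))
        assert mask.sum() == 0
        assert 0.0 <= img.min() and img.max() <= 1.0

    def test_deterministic_per_spec(self):
        spec = PhantomSpec(cls="malignant", boundary_irregularity=0.8,
                           texture_heterogeneity=0.6, seed=9)
        a, ma = make_phantom(spec)
        b, mb = make_phantom(spec)
        assert np.array_equal(a, b) and np.array_equal(ma, mb)

    def test_zero_irregularity_lesion_is_a_disk(self):
        from skimage.measure import perimeter

        spec = PhantomSpec(cls="benign", boundary_irregularity=0.0,
                           texture_heterogeneity=0.0, seed=3)
        _, mask = make_phantom(spec)
        # 4-connectivity perimeter estimator (the 8-neighborhood count
        # overestimates a rasterized circle's perimeter by ~25%)
        ratio = perimeter(mask, neighborhood=4) ** 2 / (4 * np.pi * mask.sum())
        assert ratio < 1.1

    def test_modality_flips_lesion_contrast(self):
        for modality, brighter in (("T2", True), ("T1", False)):
            spec = PhantomSpec(cls="benign", modality=modality, noise_sigma=0.0,
                               texture_heterogeneity=0.0, seed=5)
            img, mask = make_phantom(spec)
            lesion_mean = img[mask > 0].mean()
            tissue_mean = img[(mask == 0) & (img > 0.1)].mean()
            assert (lesion_mean > tissue_mean) == brighter

    def test_explicit_center_outside_brain_rejected(self):
        spec = PhantomSpec(cls="benign", lesion_center=(5.0, 5.0), seed=0)
        with pytest.raises(PhantomSpecError):
            make_phantom(spec)

    def test_malignant_texture_rougher_than_benign(self, benign_malignant_pairs):
        """Malignant phantoms show higher GLCM contrast and lower
        homogeneity than matched benign ones — the classification task is
        learnable from texture."""
        deltas_c, deltas_h = [], []
        for b, m in benign_malignant_pairs:
            fb = glcm_features(compute_glcm(b, levels=8, offset=(0, 1)))
            fm = glcm_features(compute_glcm(m, levels=8, offset=(0, 1)))
            deltas_c.append(fm[0] - fb[0])   # contrast
            deltas_h.append(fm[3] - fb[3])   # homogeneity
        assert np.mean(deltas_c) > 0
        assert np.mean(deltas_h) < 0


class TestDistort:
    def test_identity_parameters(self, smooth_phantom):
        out = distort(smooth_phantom, 0.0, 1.0)
        assert np.max(np.abs(out - smooth_phantom)) == 0.0

    def test_out_of_range_rejected(self, smooth_phantom):
        with pytest.raises(ValueError):
            distort(smooth_phantom, 360.0, 1.0)
        with pytest.raises(ValueError):
            distort(smooth_phantom, 0.0, 2.0)

    def test_half_turns_agree(self, smooth_phantom):
        a = distort(smooth_phantom, 180.0, 1.0)
        b = distort(smooth_phantom, -180.0, 1.0)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_quarter_turn_is_exact_grid_rotation(self, smooth_phantom):
        out = distort(smooth_phantom, 90.0, 1.0)
        assert np.array_equal(out, np.rot90(smooth_phantom))

    def test_rotation_roundtrip_recovers_image(self, smooth_phantom):
        theta = 37.0
        back = distort(distort(smooth_phantom, theta, 1.0), -theta, 1.0)
        interior = np.s_[40:-40, 40:-40]
        err = np.mean(np.abs(back[interior] - smooth_phantom[interior]))
        assert err < 0.03


class TestMakeDataset:
    COUNTS = {"train": {"benign": 3, "malignant": 2},
              "validation": {"benign": 1, "malignant": 1, "normal": 1}}

    def test_exact_counts_per_class_and_split(self):
        ds = make_dataset(self.COUNTS, seed=0, size=(64, 64))
        got = ds.manifest.groupby(["split", "cls"]).size().to_dict()
        assert got == {("train", "benign"): 3, ("train", "malignant"): 2,
                       ("validation", "benign"): 1,
                       ("validation", "malignant"): 1,
                       ("validation", "normal"): 1}

    def test_manifest_reproduces_dataset(self):
        ds1 = make_dataset(self.COUNTS, seed=42, size=(64, 64),
                           distortion="rotate")
        ds2 = make_dataset(self.COUNTS, seed=42, size=(64, 64),
                           distortion="rotate")
        h1 = hashlib.sha256(b"".join(im.tobytes() for im in ds1.images))
        h2 = hashlib.sha256(b"".join(im.tobytes() for im in ds2.images))
        assert h1.hexdigest() == h2.hexdigest()
        assert ds1.manifest.equals(ds2.manifest)

    def test_distortion_applied_only_to_validation(self):
        ds = make_dataset(self.COUNTS, seed=1, size=(64, 64),
                          distortion="rotate", distort_split="validation")
        m = ds.manifest
        assert (m.loc[m.split == "train", "angle_deg"] == 0).all()
        assert (m.loc[m.split == "validation", "angle_deg"] != 0).any()

    def test_save_writes_png_tree(self, tmp_path):
        ds = make_dataset({"train": {"benign": 1}}, seed=0, size=(32, 32))
        ds.save(tmp_path / "ds")
        assert (tmp_path / "ds" / "manifest.csv").exists()
        assert len(list((tmp_path / "ds" / "images").glob("*.png"))) == 1


class TestPresets:
    @pytest.mark.parametrize("preset,total,splits", [
        ("simulated", 20, (9, 7, 2, 2)),
        ("T2", 48, (18, 20, 4, 6)),
        ("T1", 24, (13, 5, 4, 2)),
    ])
    def test_preset_counts_match_printed_tables(self, preset, total, splits):
        counts = DATASET_PRESETS[preset]["counts"]
        tb, tm = counts["train"]["benign"], counts["train"]["malignant"]
        vb, vm = counts["validation"]["benign"], counts["validation"]["malignant"]
        assert (tb, tm, vb, vm) == splits
        assert tb + tm + vb + vm == total
        ds = make_preset_dataset(preset, seed=0, size=(64, 64))
        assert ds.n == total
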