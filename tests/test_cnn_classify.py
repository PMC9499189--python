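import numpy as np
import pytest

from lpbrain.cnn_classify import (
    CNNConfig, ConfigError, TrainedCNN, build_4lcnn, parameter_count,
    predict_cnn, shape_trace, train_cnn,
)
from lpbrain.phantom import PhantomSpec, make_phantom

SMALL = CNNConfig(input_shape=(48, 48, 3), conv_filters=(4, 4, 8, 8),
                  dense_units=(16, 32, 32), epochs=5, seed=0)


def tiny_dataset(n_per_class=3, size=48):
    imgs, labels = [], []
    for i in range(n_per_class):
        b, _ = make_phantom(PhantomSpec(cls="benign", size=(size, size),
                                        lesion_radius=6.0, seed=i))
        m, _ = make_phantom(PhantomSpec(cls="malignant", size=(size, size),
                                        lesion_radius=6.0,
                                        boundary_irregularity=0.7,
                                        texture_heterogeneity=0.7, seed=50 + i))
        imgs += [b, m]
        labels += ["benign", "malignant"]
    return imgs, labels


class TestArchitecture:
    def test_first_conv_output_dims_224(self):
        trace = dict(shape_trace(CNNConfig()))
        assert trace["conv1"] == (222, 222, 32)
        assert trace["pool1"] == (111, 111, 32)

    def test_full_default_trace_matches_conv_pool_arithmetic(self):
        H = W = 224
        expect = []
        for f in (32, 32, 64, 64):
            H, W = H - 2, W - 2            # 3x3 valid conv
            expect.append((H, W, f))
            H, W = (H - 2) // 2 + 1, (W - 2) // 2 + 1  # 2x2 pool stride 2
            expect.append((H, W, f))
        trace = shape_trace(CNNConfig())
        convpool = [s for name, s in trace if name.startswith(("conv", "pool"))]
        assert convpool == expect

    def test_parameter_count_matches_instantiated_model(self):
        model = build_4lcnn(SMALL)
        assert model.n_parameters() == parameter_count(SMALL)

    def test_parameter_count_closed_form_small_case(self):
        # 1 input channel impossible (3 fixed); verify by direct arithmetic
        cfg = CNNConfig(input_shape=(48, 48, 3), conv_filters=(2, 2, 2, 2),
                        dense_units=(4, 4, 4), n_classes=2)
        # convs: (3*9+1)*2 + (2*9+1)*2*3 ; flatten: 48->46/23->21/10->8/4->2/1 -> 1*1*2
        conv = (3 * 9 + 1) * 2 + 3 * ((2 * 9 + 1) * 2)
        flat = 1 * 1 * 2
        dense = (flat * 4 + 4) + (4 * 4 + 4) + (4 * 4 + 4) + (4 * 2 + 2)
        assert parameter_count(cfg) == conv + dense

    def test_pooling_below_one_rejected(self):
        with pytest.raises(ConfigError):
            shape_trace(CNNConfig(input_shape=(20, 20, 3)))


class TestTraining:
    def test_loss_decreases_after_one_step_across_seeds(self):
        """A single RMSprop step from init reduces the fixed-batch loss in
        nearly all seeded trials at lr 1e-5."""
        from lpbrain.cnn_classify import _softmax, prepare_input

        imgs, labels = tiny_dataset(2)
        classes = tuple(sorted(set(labels)))
        X = np.stack([prepare_input(im, SMALL.input_shape) for im in imgs])
        y = np.array([classes.index(l) for l in labels])

        def batch_loss(model):
            probs = _softmax(model.forward(X, train=False))
            return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

        wins = 0
        n_trials = 100
        for seed in range(n_trials):
            cfg = CNNConfig(input_shape=(48, 48, 3), conv_filters=(4, 4, 8, 8),
                            dense_units=(16, 32, 32), dropout=0.0, seed=seed)
            model = build_4lcnn(cfg)
            before = batch_loss(model)
            train_cnn(model, imgs, labels, epochs=1, seed=seed)
            assert len(imgs) <= cfg.batch_size  # single optimizer step
            after = batch_loss(model)
            wins += after < before
        assert wins >= 0.95 * n_trials

    def test_same_seed_identical_weights(self):
        imgs, labels = tiny_dataset(2)
        runs = []
        for _ in range(2):
            model = build_4lcnn(SMALL)
            trained = train_cnn(model, imgs, labels, epochs=3, seed=11)
            runs.append(trained.weights)
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])

    def test_history_schema_and_epochs(self):
        imgs, labels = tiny_dataset(2)
        trained = train_cnn(build_4lcnn(SMALL), imgs, labels, epochs=4, seed=0)
        assert list(trained.history.columns) == ["epoch", "loss", "accuracy"]
        assert len(trained.history) == 4

    def test_empty_class_rejected(self):
        imgs, _ = tiny_dataset(1)
        with pytest.raises(ValueError):
            train_cnn(build_4lcnn(SMALL), imgs, ["benign"] * len(imgs))


@pytest.fixture(scope="module")
def trained():
    imgs, labels = tiny_dataset(2)
    return train_cnn(build_4lcnn(SMALL), imgs, labels, epochs=2, seed=3)


class TestPrediction:

    def test_probabilities_sum_to_one(self, trained):
        rng = np.random.default_rng(0)
        for _ in range(5):
            _, probs = predict_cnn(trained, rng.random((48, 48)))
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert probs.shape == (2,)

    def test_inference_deterministic_despite_dropout(self, trained):
        img = np.random.default_rng(1).random((48, 48))
        l1, p1 = predict_cnn(trained, img)
        l2, p2 = predict_cnn(trained, img)
        assert l1 == l2 and np.array_equal(p1, p2)

    def test_save_load_predict_bit_stable(self, trained, tmp_path):
        img = np.random.default_rng(2).random((48, 48))
        _, before = predict_cnn(trained, img)
        trained.save(tmp_path / "model")
        loaded = TrainedCNN.load(tmp_path / "model")
        label, after = predict_cnn(loaded, img)
        assert np.array_equal(before, after)
        assert label in loaded.classes
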