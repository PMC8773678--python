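"""The 17-layer patch CNN: architecture, gradients, training, metrics."""

import numpy as np
import pytest

import ctinfarct as ci
from ctinfarct.metrics import ConfusionMatrix, compute_metrics
from ctinfarct.nn import (CNNConfig, PatchCNN, TrainConfig, predict_classes,
                          predict_patches, train_cnn)
from ctinfarct.patches import Patch, PatchDataset, split_dataset
from ctinfarct.preprocess import ContractError


def separable_dataset(n=40, delta=3.0, seed=0, train_fraction=0.8):
    """Two clearly separated classes of t-score patches (means -delta vs 0)."""
    rng = np.random.default_rng(seed)
    patches = []
    for i in range(n):
        label = "infarcted" if i % 2 else "non_infarcted"
        mu = -delta if label == "infarcted" else 0.0
        patches.append(Patch(rng.normal(mu, 1.0, (16, 16)).astype(np.float32),
                             slice_index=i, row0=0, col0=0, label=label))
    return split_dataset(PatchDataset(patches), train_fraction, seed=seed)


class TestArchitecture:
    def test_layer_enumeration_counts_seventeen(self):
        model = ci.build_cnn()
        layers = model.enumerate_layers()
        assert len(layers) == 17
        assert layers[0] == "input" and layers[-1] == "classification_output"
        assert sum(1 for name in layers if name.startswith("conv")) == 3

    def test_probabilities_sum_to_one(self):
        model = ci.build_cnn()
        rng = np.random.default_rng(0)
        probs = model.forward(rng.normal(size=(5, 16, 16)))
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_three_poolings_leave_2x2_spatial_size(self):
        model = ci.build_cnn(CNNConfig(conv_filters=(8, 16, 32)))
        dense = model.layers[13]
        assert dense.w.shape == (2 * 2 * 32, 2)

    def test_wrong_input_shape_rejected(self):
        with pytest.raises(ContractError):
            ci.build_cnn().forward(np.zeros((2, 8, 8)))

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        model = ci.build_cnn(CNNConfig(seed=3))
        model.trained = True
        x = np.random.default_rng(1).normal(size=(4, 16, 16))
        model.save(tmp_path / "m.npz")
        back = PatchCNN.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.forward(x), model.forward(x))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central-difference check on a thinned float64 copy of the net."""
        model = ci.build_cnn(CNNConfig(conv_filters=(2, 3, 4),
                                       dropout_rate=0.0, seed=0))
        for layer in model.layers:
            for p in layer.params:
                setattr(layer, p, getattr(layer, p).astype(np.float64))
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, size=(3, 16, 16))
        y = np.array([0, 1, 1])

        def loss():
            probs = model.forward(x, train=True)
            return float(-np.log(probs[np.arange(3), y]).sum())

        model.loss_and_grad(x, y)
        checks = [(0, "w"), (0, "b"), (1, "gamma"), (1, "beta"),
                  (4, "w"), (8, "w"), (13, "w"), (13, "b")]
        for li, pname in checks:
            layer = model.layers[li]
            param = getattr(layer, pname)
            grad = getattr(layer, "d" + pname)
            flat = param.ravel()
            idx = rng.integers(flat.size, size=min(3, flat.size))
            for i in idx:
                eps = 1e-5
                orig = flat[i]
                flat[i] = orig + eps
                up = loss()
                flat[i] = orig - eps
                down = loss()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                assert grad.ravel()[i] == pytest.approx(numeric, rel=1e-3, abs=1e-6), \
                    f"layer {li} param {pname} index {i}"


class TestTraining:
    def test_overfits_separable_patches(self):
        ds = separable_dataset(n=40, delta=3.0, seed=0)
        model = ci.build_cnn(CNNConfig(seed=0))
        tc = TrainConfig(max_iterations=400, seed=0, eval_every=100)
        train_cnn(model, ds, tc)
        x, y = ds.arrays("train")
        assert (predict_classes(model, x) == y).mean() == 1.0

    def test_iteration_cap_binds_before_epoch_cap(self):
        ds = separable_dataset(n=30, seed=1)
        model = ci.build_cnn(CNNConfig(seed=1))
        # 24 train patches, batch 10 -> 3 iterations/epoch; cap at 7 iterations
        tc = TrainConfig(batch_size=10, max_iterations=7, max_epochs=1000,
                         seed=1, eval_every=1)
        hist = train_cnn(model, ds, tc)
        assert len(hist) == 3  # ceil(7/3) epochs actually run

    def test_geometric_schedule_spans_initial_to_final_rate(self):
        ds = separable_dataset(n=30, seed=2)
        model = ci.build_cnn(CNNConfig(seed=2))
        tc = TrainConfig(batch_size=24, max_iterations=50, max_epochs=50,
                         seed=2, eval_every=25)
        hist = train_cnn(model, ds, tc)
        assert hist["lr"].iloc[0] == pytest.approx(1e-5, rel=0.01)
        assert hist["lr"].iloc[-1] == pytest.approx(1e-7, rel=0.01)
        ratios = hist["lr"].values[1:] / hist["lr"].values[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_loss_trend_decreases_on_separable_data(self):
        ds = separable_dataset(n=40, seed=3)
        model = ci.build_cnn(CNNConfig(seed=3))
        hist = train_cnn(model, ds, TrainConfig(max_iterations=300, seed=3,
                                                eval_every=100))
        smoothed = hist["train_loss"].rolling(25).mean().dropna().values
        assert smoothed[-1] < smoothed[0]

    def test_seeded_training_is_reproducible(self):
        ds = separable_dataset(n=20, seed=4)
        out = []
        for _ in range(2):
            model = ci.build_cnn(CNNConfig(seed=4))
            train_cnn(model, ds, TrainConfig(max_iterations=30, seed=4,
                                             eval_every=10))
            out.append(model.forward(ds.arrays("validation")[0]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_single_class_training_set_rejected(self):
        rng = np.random.default_rng(5)
        pats = [Patch(rng.normal(size=(16, 16)).astype(np.float32), i, 0, 0,
                      label="infarcted") for i in range(10)]
        ds = split_dataset(PatchDataset(pats), seed=5)
        with pytest.raises(ContractError):
            train_cnn(ci.build_cnn(), ds, TrainConfig(max_iterations=5, seed=5))

    def test_missing_split_rejected(self):
        ds = PatchDataset(separable_dataset(10).patches)
        with pytest.raises(ContractError):
            train_cnn(ci.build_cnn(), ds, TrainConfig(max_iterations=5))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ContractError):
            TrainConfig(lr_initial=1e-7, lr_final=1e-5)


class TestInference:
    def test_eval_mode_is_deterministic(self):
        model = ci.build_cnn(CNNConfig(seed=6))
        model.trained = True
        patch = Patch(np.random.default_rng(6).normal(size=(16, 16)), 0, 0, 0)
        a = predict_patches(model, [patch, patch])
        assert a[0] == a[1]
        b = predict_patches(model, [patch])
        assert a[0] == b[0]

    def test_all_zero_patch_gets_a_probability_vector(self):
        model = ci.build_cnn(CNNConfig(seed=7))
        model.trained = True
        (label, prob), = predict_patches(model, [Patch(np.zeros((16, 16)), 0, 0, 0)])
        assert label in ("infarcted", "non_infarcted")
        assert 0.0 <= prob <= 1.0

    def test_untrained_model_rejected(self):
        with pytest.raises(ContractError):
            predict_patches(ci.build_cnn(), [Patch(np.zeros((16, 16)), 0, 0, 0)])


class TestMetrics:
    def test_counts_and_percentages_agree(self):
        counts = ConfusionMatrix(tp=463, fn=7, fp=54, tn=476)
        pct = ConfusionMatrix(tp=46.3, fn=0.7, fp=5.4, tn=47.6)
        assert compute_metrics(counts) == compute_metrics(pct)

    def test_perfect_classifier(self):
        out = compute_metrics(ConfusionMatrix(tp=1, fn=0, fp=0, tn=1))
        assert out == {"accuracy": 100.0, "sensitivity": 100.0,
                       "specificity": 100.0}

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ContractError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_from_predictions_counts(self):
        cm = ConfusionMatrix.from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 1)
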