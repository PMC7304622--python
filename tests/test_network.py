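"""Introspectable CNN: forward exactness, augmentation, training."""

import numpy as np
import pytest

from conftest import make_tiny_model, naive_forward
from otolens import network
from otolens.classifier import OtolithAgeClassifier
from otolens.network import NetworkModel, TrainConfig


class TestForward:
    def test_dense_identity_returns_input(self):
        model = NetworkModel(
            layers=[network.dense(3, 3)],
            params=[{"W": np.eye(3), "b": np.zeros(3)}],
            class_labels=[1, 2, 3])
        v = np.array([[0.3, -1.2, 2.0]])
        trace = network.forward(model, v)
        assert np.allclose(trace.logits, v)

    def test_conv_all_ones_kernel_interior(self):
        """2x2 all-ones kernel, stride 1, no padding, all-ones 3x3 input:
        every output is 4 (brute-force convolution oracle)."""
        spec = network.conv(1, 1, kernel=2, stride=1, padding=0)
        model = NetworkModel(
            layers=[spec],
            params=[{"W": np.ones((1, 1, 2, 2)), "b": np.zeros(1)}],
            class_labels=[1])
        out = network.forward(model, np.ones((3, 3))).outputs[0]
        # oracle: explicit loops
        x = np.ones((3, 3))
        expected = np.array([[sum(x[i + a, j + b] for a in range(2)
                                  for b in range(2))
                              for j in range(2)] for i in range(2)])
        assert np.allclose(out[0, 0], expected)
        assert np.all(out == 4.0)

    def test_relu_zeroes_negatives(self):
        model = NetworkModel(layers=[network.relu()], params=[{}],
                             class_labels=[1])
        out = network.forward(model, np.array([[-1.0, 2.0, -3.0, 0.5]]))
        assert np.allclose(out.outputs[0], [[0.0, 2.0, 0.0, 0.5]])

    def test_forward_matches_per_neuron_oracle(self, rng):
        """Vectorized forward equals the naive per-neuron loop on random
        tiny models to 1e-9."""
        for trial in range(5):
            model = make_tiny_model(np.random.default_rng(trial))
            image = np.random.default_rng(100 + trial).uniform(-1, 1, (6, 6))
            trace = network.forward(model, image)
            records = naive_forward(model, image)
            for got, rec in zip(trace.outputs, records):
                assert np.max(np.abs(got.ravel() - rec["a_out"])) < 1e-9

    def test_shape_mismatch_raises(self, rng):
        model = make_tiny_model(rng)
        with pytest.raises(ValueError):
            network.forward(model, np.ones((7, 7)))


class TestAugment:
    def test_forced_identity(self, rng):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        out = network.augment(img, rng, angle=0.0, flip_h=False,
                              flip_v=False, shift=0)
        assert np.array_equal(out, img)

    def test_all_zero_image_stays_zero(self, rng):
        out = network.augment(np.zeros((20, 20)), rng)
        assert np.all(out == 0.0)

    def test_full_turn_equals_four_quarter_turns(self, rng):
        img = np.zeros((15, 15))
        img[4:8, 6:10] = 1.0
        quarter = img.copy()
        for _ in range(4):
            quarter = network.augment(quarter, rng, angle=90.0, order=0,
                                      flip_h=False, flip_v=False, shift=0)
        full = network.augment(img, rng, angle=360.0, order=0,
                               flip_h=False, flip_v=False, shift=0)
        assert np.allclose(full, quarter)

    def test_output_in_unit_interval(self, rng):
        img = np.random.default_rng(1).uniform(0, 1, (24, 24))
        for _ in range(5):
            out = network.augment(img, rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestNormalize:
    def test_training_set_becomes_zero_mean_unit_sd(self, rng):
        imgs = rng.uniform(0, 1, (10, 8, 8))
        stats = network.compute_normalization(imgs)
        normed = network.normalize(imgs, stats)
        assert abs(normed.mean()) < 1e-6
        assert abs(normed.std() - 1.0) < 1e-6

    def test_constant_image_at_mean_maps_to_zero(self):
        out = network.normalize(np.full((4, 4), 0.3), (0.3, 0.1))
        assert np.all(out == 0.0)

    def test_test_set_mean_generally_nonzero_with_train_stats(self, rng):
        train = rng.uniform(0, 0.5, (10, 8, 8))
        test = rng.uniform(0.5, 1.0, (10, 8, 8))
        stats = network.compute_normalization(train)
        assert abs(network.normalize(test, stats).mean()) > 0.1

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            network.normalize(np.ones((4, 4)), (0.5, 0.0))
        with pytest.raises(ValueError):
            network.compute_normalization(np.ones((3, 4, 4)))


def _toy_two_class(n=20, size=12, seed=0):
    """Linearly separable toy: class 1 bright top-left, class 2 bottom-right."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n):
        img = rng.uniform(0, 0.2, (size, size))
        if i % 2 == 0:
            img[:4, :4] += 0.8
            y.append(1)
        else:
            img[-4:, -4:] += 0.8
            y.append(2)
        X.append(np.clip(img, 0, 1))
    return np.stack(X), np.array(y)


class TestTrain:
    def test_separable_toy_reaches_full_accuracy(self):
        X, y = _toy_two_class()
        clf = OtolithAgeClassifier(conv_channels=(4,), dense_units=8,
                                   epochs=20, augment=False, random_state=0)
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        X, y = _toy_two_class(n=8)
        model = network.build_model(12, [1, 2], conv_channels=(4,),
                                    dense_units=8, seed=0)
        before = [{k: v.copy() for k, v in p.items()} for p in model.params]
        cfg = TrainConfig(epochs=2, learning_rate=0.0, augment=False, seed=0)
        network.train(model, X, y, cfg)
        for p, q in zip(model.params, before):
            for k in p:
                assert np.array_equal(p[k], q[k])

    def test_same_seed_identical_final_weights(self):
        X, y = _toy_two_class(n=10)
        runs = []
        for _ in range(2):
            model = network.build_model(12, [1, 2], conv_channels=(4,),
                                        dense_units=8, seed=3)
            cfg = TrainConfig(epochs=3, seed=3, augment=True)
            network.train(model, X, y, cfg)
            runs.append(model.params)
        for p, q in zip(*runs):
            for k in p:
                assert np.array_equal(p[k], q[k])

    def test_loss_decreases_on_recipe(self):
        X, y = _toy_two_class(n=16)
        model = network.build_model(12, [1, 2], conv_channels=(4,),
                                    dense_units=8, seed=1)
        cfg = TrainConfig(epochs=10, seed=1, augment=False)
        _, hist = network.train(model, X, y, cfg)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_empty_training_set_rejected(self):
        model = network.build_model(12, [1, 2], conv_channels=(4,), seed=0)
        with pytest.raises(ValueError):
            network.train(model, np.zeros((0, 12, 12)), np.zeros(0),
                          TrainConfig())


class TestPredict:
    def test_argmax_tie_breaks_to_lowest_age(self):
        W = np.zeros((2, 3))
        model = NetworkModel(
            layers=[network.dense(2, 3)],
            params=[{"W": W, "b": np.array([1.0, 1.0, 0.0])}],
            class_labels=[4, 7, 9])
        age, logits = network.predict_age(model, np.array([[0.0, 0.0]]))
        assert age == 4
        assert np.allclose(logits, [1.0, 1.0, 0.0])

    def test_unique_maximum_wins(self):
        model = NetworkModel(
            layers=[network.dense(1, 3)],
            params=[{"W": np.array([[0.0, 1.0, 0.0]]), "b": np.zeros(3)}],
            class_labels=[5, 7, 11])
        age, _ = network.predict_age(model, np.array([[1.0]]))
        assert age == 7

    def test_untrained_model_predicts_valid_age(self, rng):
        model = make_tiny_model(rng, n_classes=5)
        model.class_labels = [1, 5, 10, 20, 26]
        age, _ = network.predict_age(model, rng.uniform(0, 1, (6, 6)))
        assert age in model.class_labels


def test_checkpoint_roundtrip(tmp_path, rng):
    model = make_tiny_model(rng)
    model.normalization_stats = (0.4, 0.2)
    network.save_checkpoint(model, tmp_path / "m.npz")
    back = network.load_checkpoint(tmp_path / "m.npz")
    assert [s.kind for s in back.layers] == [s.kind for s in model.layers]
    assert back.class_labels == model.class_labels
    assert back.normalization_stats == model.normalization_stats
    x = rng.uniform(0, 1, (6, 6))
    assert np.allclose(network.forward(model, x).logits,
                       network.forward(back, x).logits)


def test_easy_regime_accuracy_beats_chance_fivefold():
    """On an easy-regime synthetic dataset the default recipe reaches
    test accuracy at least 5x above the 1/n_classes chance level."""
    from otolens.synthetic import generate_dataset
    ds = generate_dataset(24, ages=list(range(1, 9)), canvas_size=48,
                          split_fraction=0.2, seed=5, separability=8.0)
    Xtr = np.stack([s.image for s in ds.train])
    ytr = np.array([s.age for s in ds.train])
    Xte = np.stack([s.image for s in ds.test])
    yte = np.array([s.age for s in ds.test])
    clf = OtolithAgeClassifier(epochs=80, random_state=0)
    clf.fit(Xtr, ytr)
    acc = float(np.mean(clf.predict(Xte) == yte))
    assert acc >= 5.0 / 8.0
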