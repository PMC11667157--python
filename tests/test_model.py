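"""Network construction, gradients, training behavior, persistence."""

import numpy as np
import pytest

from mitopo import nn
from mitopo.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    forward,
    nll_loss,
    train,
)

#: Small geometry that exercises every layer quickly.
TINY = ModelConfig(
    input_shape=(16, 12, 10),
    n_filters_block1=2,
    n_filters_block2=3,
    fc_units=8,
)


def conv_pool_out(d, k=2, s=2):
    return (d - k) // s + 1


class TestBuildModel:
    def test_default_head_widths(self):
        model = build_model()
        dense = [l for l in model.layers if isinstance(l, nn.Dense)]
        assert dense[0].weight.value.shape[1] == 256
        assert dense[1].weight.value.shape[1] == 2

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(TINY, seed=0)
        probs = forward(model, rng.random((4, 16, 12, 10)))
        assert probs.shape == (4, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_layer_shapes_match_arithmetic(self):
        """Same-padded convs keep size; each stride-2/no-padding
        conv-pool maps d -> floor((d - 2) / 2) + 1 on every axis."""
        model = build_model()
        shapes = dict_of_last = {}
        for name, shape in model.layer_shapes:
            shapes[name] = shape
        x, y, z = 110, 100, 10
        assert shapes["conv1_spatial1"] == (x, y, z, 16)
        assert shapes["conv2_spectral1"] == (x, y, z, 16)
        x, y, z = (conv_pool_out(d) for d in (x, y, z))
        assert shapes["conv3_pool1"] == (x, y, z, 16)
        assert shapes["conv4_spatial2"] == (x, y, z, 32)
        x, y, z = (conv_pool_out(d) for d in (x, y, z))
        assert shapes["conv6_pool2"] == (x, y, z, 32)
        assert shapes["flatten"] == (x * y * z * 32,)

    def test_parameter_count_matches_hand_calculation(self):
        cfg = ModelConfig()
        model = build_model(cfg)
        f1, f2, fc, k = 16, 32, 256, 2
        expected = (
            (5 * 5 * 1 * 1 * f1 + f1)        # spatial 1
            + (1 * 1 * 5 * f1 * f1 + f1)     # spectral 1
            + 2 * f1                          # bn after conv 2
            + (2 * 2 * 2 * f1 * f1 + f1)     # conv-pool 1
            + (5 * 5 * 1 * f1 * f2 + f2)     # spatial 2
            + (1 * 1 * 5 * f2 * f2 + f2)     # spectral 2
            + (2 * 2 * 2 * f2 * f2 + f2)     # conv-pool 2
            + 2 * f2                          # bn after conv 6
            + (27 * 25 * 2 * f2 * fc + fc)   # hidden dense
            + (fc * k + k)                   # output dense
        )
        assert model.n_parameters == expected

    def test_too_small_input_names_offending_layer(self):
        with pytest.raises(ValueError, match="conv"):
            build_model(ModelConfig(input_shape=(8, 8, 2)))

    def test_eval_forward_deterministic_for_duplicates(self, rng):
        model = build_model(TINY, seed=1)
        x = rng.random((1, 16, 12, 10))
        batch = np.concatenate([x, x], axis=0)
        probs = forward(model, batch)
        np.testing.assert_array_equal(probs[0], probs[1])


class TestNllLoss:
    def test_uniform_prediction_is_ln2(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert nll_loss(probs, np.array([0, 1])) == pytest.approx(np.log(2))

    def test_perfect_prediction_zero_loss(self):
        assert nll_loss(np.array([[1.0, 0.0]]), np.array([0])) == 0.0

    def test_batch_mean_matches_elementwise(self, rng):
        probs = rng.dirichlet(np.ones(2), size=6)
        labels = rng.integers(0, 2, size=6)
        per_sample = [-np.log(probs[i, labels[i]]) for i in range(6)]
        assert nll_loss(probs, labels) == pytest.approx(np.mean(per_sample))

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            loss = nll_loss(np.array([[0.0, 1.0]]), np.array([0]))
        assert np.isfinite(loss)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of every layer type vs central differences."""
        old_dtype = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            rng = np.random.default_rng(1)
            layers = [
                nn.Conv3D(1, 2, (3, 3, 1), padding="same", rng=rng),
                nn.ReLU(),
                nn.Conv3D(2, 2, (1, 1, 3), padding="same", rng=rng),
                nn.BatchNorm(2),
                nn.Square(),
                nn.Conv3D(2, 2, (2, 2, 2), stride=(2, 2, 2), padding="valid",
                          rng=rng, init="averaging"),
                nn.Log(1e-6),
                nn.Flatten(),
                nn.Dense(2 * 3 * 2 * 2, 5, rng=rng),
                nn.ReLU(),
                nn.Dense(5, 2, rng=rng),
            ]
            x = rng.random((4, 5, 6, 4, 1)) + 0.5
            y = np.array([0, 1, 1, 0])

            def loss_fn():
                h = x
                for l in layers:
                    h = l.forward(h, training=True)
                return nn.cross_entropy_with_logits(h, y)

            _, grad = loss_fn()
            dy = grad
            for l in reversed(layers):
                dy = l.backward(dy)

            for p in [p for l in layers for p in l.params()]:
                flat, g = p.value.ravel(), p.grad.ravel()
                for i in rng.choice(flat.size, size=min(5, flat.size),
                                    replace=False):
                    eps, old = 1e-6, flat[i]
                    flat[i] = old + eps
                    lp, _ = loss_fn()
                    flat[i] = old - eps
                    lm, _ = loss_fn()
                    flat[i] = old
                    numeric = (lp - lm) / (2 * eps)
                    assert abs(numeric - g[i]) < 1e-5 * max(
                        1.0, abs(numeric)
                    ), p.name
        finally:
            nn.DTYPE = old_dtype

    def test_log_power_block_equals_log_mean_square(self, rng):
        """With uniform pool weights the square -> conv-pool -> log chain
        computes log of the local mean of squares (a log-power feature)."""
        pool = nn.Conv3D(1, 1, (2, 2, 2), stride=(2, 2, 2), padding="valid")
        pool.weight.value[:] = 1.0 / 8.0
        pool.bias.value[:] = 0.0
        x = rng.random((2, 4, 4, 4, 1)).astype(np.float32) + 0.1
        out = nn.Log(1e-6).forward(pool.forward(nn.Square().forward(x)))
        manual = np.log(
            (x**2).reshape(2, 2, 2, 2, 2, 2, 2, 1).mean(axis=(2, 4, 6))
        )
        np.testing.assert_allclose(out, manual, rtol=1e-5)


def _separable_dataset(rng, n=24, shape=(16, 12, 10)):
    """Two classes with disjoint constant patterns plus slight noise."""
    half = n // 2
    a = 1.0 + 0.01 * rng.random((half, *shape))
    b = 3.0 + 0.01 * rng.random((half, *shape))
    x = np.concatenate([a, b]).astype(np.float32)
    y = np.array(["left_fist"] * half + ["right_fist"] * half)
    return x, y


class TestTrain:
    def test_separable_data_reaches_full_accuracy(self, rng):
        x, y = _separable_dataset(rng)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(epochs=50, learning_rate=0.01, batch_size=8, seed=0)
        train(model, x, y, cfg)
        assert model.history["accuracy"][-1] == 1.0

    def test_first_epoch_loss_near_ln2(self, rng):
        x, y = _separable_dataset(rng)
        model = build_model(TINY, seed=0)
        train(model, x, y, TrainConfig(epochs=1, learning_rate=1e-4,
                                       batch_size=24, seed=0))
        assert abs(model.history["loss"][0] - np.log(2)) < 0.1

    def test_loss_nonincreasing_with_transient_tolerance(self, rng):
        # full-batch descent with dropout off, so the recorded loss
        # reflects the optimizer rather than minibatch/regularizer noise
        from dataclasses import replace

        x, y = _separable_dataset(rng)
        model = build_model(replace(TINY, dropout_p=0.0), seed=0)
        train(model, x, y, TrainConfig(epochs=30, learning_rate=0.01,
                                       batch_size=24, seed=0))
        losses = model.history["loss"]
        for prev, cur in zip(losses, losses[1:]):
            assert cur <= prev * 1.05 + 1e-3

    def test_training_deterministic_given_seed(self, rng):
        x, y = _separable_dataset(rng, n=12)
        cfg = TrainConfig(epochs=3, learning_rate=0.01, batch_size=6, seed=7)
        m1 = train(build_model(TINY, seed=7), x, y, cfg)
        m2 = train(build_model(TINY, seed=7), x, y, cfg)
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_batch_size_larger_than_dataset_rejected(self, rng):
        x, y = _separable_dataset(rng, n=8)
        with pytest.raises(ValueError):
            train(build_model(TINY), x, y, TrainConfig(batch_size=64))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        x, y = _separable_dataset(rng, n=12)
        model = build_model(TINY, seed=0)
        train(model, x, y, TrainConfig(epochs=2, learning_rate=0.01,
                                       batch_size=6, seed=0))
        path = tmp_path / "model.npz"
        model.save(path)
        from mitopo.model import TrainedModel

        back = TrainedModel.load(path)
        np.testing.assert_allclose(
            model.predict_proba(x), back.predict_proba(x), atol=1e-7
        )


class TestActivations:
    def test_tag_dimensions(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((3, 16, 12, 10))
        assert model.activations(x, "softmax").shape == (3, 2)
        assert model.activations(x, "raw").shape == (3, 16 * 12 * 10)
        assert model.activations(x, "fc").shape == (3, 8)

    def test_export_is_deterministic(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((2, 16, 12, 10))
        a = model.activations(x, "pool1")
        b = model.activations(x, "pool1")
        np.testing.assert_array_equal(a, b)

    def test_unknown_tag_lists_valid_tags(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="raw"):
            model.activations(rng.random((1, 16, 12, 10)), "nope")
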