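"""Feed-forward network: forward pass, analytic gradients, training loop."""

import math

import numpy as np
import pytest

from enzisfet import (
    NetworkParams,
    TrainConfig,
    forward,
    gradients,
    loss_mse,
    train,
)
from enzisfet.exceptions import ConvergenceError, UsageError
from enzisfet.model import FittedNetwork
from enzisfet.preprocess import NormParams


def make_net(layer_sizes, seed=0, init_scale=1.0):
    return NetworkParams.initialize(layer_sizes, init_scale, np.random.default_rng(seed))


def finite_difference_grads(x, y, params, h=1e-6):
    """Central-difference oracle for the MSE gradient."""
    dws, dbs = [], []
    for arrs, store in ((params.weights, dws), (params.biases, dbs)):
        for a in arrs:
            g = np.zeros_like(a)
            it = np.nditer(a, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = a[idx]
                a[idx] = orig + h
                up = loss_mse(y, forward(x, params))
                a[idx] = orig - h
                dn = loss_mse(y, forward(x, params))
                a[idx] = orig
                g[idx] = (up - dn) / (2 * h)
            store.append(g)
    return dws, dbs


class TestForward:
    def test_all_zero_parameters_output_zero(self):
        p = make_net((2, 3, 1))
        p.weights = [np.zeros_like(w) for w in p.weights]
        p.biases = [np.zeros_like(b) for b in p.biases]
        assert forward(np.array([[0.3, 0.9]]), p)[0] == 0.0

    def test_hand_evaluated_chain(self):
        # 1-1-1-1 net, unit weights, zero biases: ReLU(tanh(tanh(1)))
        p = NetworkParams((1, 1, 1, 1), [np.ones((1, 1))] * 3, [np.zeros(1)] * 3)
        expected = math.tanh(math.tanh(1.0))
        assert forward(np.array([[1.0]]), p)[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.6420, abs=5e-5)

    def test_negative_preactivation_clamped(self):
        p = make_net((2, 4, 1))
        p.biases[-1][:] = -100.0
        out = forward(np.random.default_rng(0).uniform(0, 1, (10, 2)), p)
        assert np.all(out == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(UsageError):
            forward(np.ones((5, 3)), make_net((2, 3, 1)))


class TestLoss:
    def test_perfect_prediction(self):
        assert loss_mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_residuals(self):
        assert loss_mse([0.0, 1.0], [1.0, 0.0]) == 1.0

    def test_quadratic_homogeneity(self):
        y = np.array([0.1, 0.4, 0.9])
        yhat = np.array([0.2, 0.1, 1.0])
        base = loss_mse(y, yhat)
        assert loss_mse(3 * y, 3 * yhat) == pytest.approx(9 * base)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            loss_mse([], [])


class TestGradients:
    @pytest.mark.parametrize(
        "layers,seed", [((1, 2, 1), 0), ((2, 3, 1), 1), ((2, 3, 2, 1), 2), ((3, 3, 3, 1), 3)]
    )
    def test_matches_central_finite_differences(self, layers, seed):
        rng = np.random.default_rng(seed)
        p = make_net(layers, seed=seed)
        x = rng.uniform(0, 1, (7, layers[0]))
        y = rng.uniform(0, 1, 7)
        dws, dbs = gradients((x, y), p)
        fdw, fdb = finite_difference_grads(x, y, p)
        for a, b in zip(dws + dbs, fdw + fdb):
            scale = max(np.abs(b).max(), 1e-8)
            assert np.abs(a - b).max() / scale < 1e-5

    def test_zero_residuals_give_zero_gradients(self):
        p = make_net((2, 3, 1))
        p.weights = [np.zeros_like(w) for w in p.weights]
        p.biases = [np.zeros_like(b) for b in p.biases]
        dws, dbs = gradients((np.ones((4, 2)), np.zeros(4)), p)
        for g in dws + dbs:
            assert np.all(g == 0.0)

    def test_dead_output_unit_has_zero_gradients(self):
        p = make_net((2, 3, 1))
        p.biases[-1][:] = -100.0
        x = np.random.default_rng(1).uniform(0, 1, (6, 2))
        dws, dbs = gradients((x, np.full(6, 0.5)), p)
        for g in dws + dbs:
            assert np.all(g == 0.0)


def linear_fixture(n=50, seed=0):
    x = np.linspace(0, 1, n)[:, None]
    y = 0.5 * x[:, 0]
    return x, y


class TestTraining:
    def test_learns_noiseless_linear_target(self):
        x, y = linear_fixture()
        params, history = train(
            (x, y), (x, y), (1, 10, 5, 1), TrainConfig(0.01, 3000, patience=3000, seed=0)
        )
        assert min(history.train_mse) < 1e-3

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        x, y = linear_fixture(10)
        cfg = TrainConfig(learning_rate=0.0, max_epochs=5, patience=10, seed=3)
        params, history = train((x, y), (x, y), (1, 3, 1), cfg)
        # replay the seeded stream, including the live-output redraw
        rng = np.random.default_rng(3)
        while True:
            init = NetworkParams.initialize((1, 3, 1), 1.0, rng)
            if np.any(forward(x, init) > 0):
                break
        for a, b in zip(params.weights + params.biases, init.weights + init.biases):
            np.testing.assert_array_equal(a, b)

    def test_deterministic_history(self):
        x, y = linear_fixture()
        cfg = TrainConfig(0.01, 50, patience=50, seed=5)
        _, h1 = train((x, y), (x, y), (1, 4, 1), cfg)
        _, h2 = train((x, y), (x, y), (1, 4, 1), cfg)
        assert h1.train_mse == h2.train_mse
        assert h1.test_mse == h2.test_mse

    def test_training_mse_monotone_at_small_learning_rate(self):
        x, y = linear_fixture()
        _, history = train(
            (x, y), (x, y), (1, 10, 5, 1), TrainConfig(1e-3, 300, patience=300, seed=0)
        )
        mse = np.array(history.train_mse)
        assert np.all(np.diff(mse) <= 1e-12)

    def test_nonfinite_loss_raises_with_advice(self):
        # targets large enough that the squared residual overflows to inf
        x = np.linspace(0, 1, 10)[:, None]
        y = np.full(10, 1e200)
        with pytest.raises(ConvergenceError, match="learning_rate"):
            train((x, y), (x, y), (1, 3, 1), TrainConfig(0.01, 50, patience=50, seed=0))

    def test_threshold_stop(self):
        x, y = linear_fixture()
        _, history = train(
            (x, y),
            (x, y),
            (1, 10, 5, 1),
            TrainConfig(0.01, 3000, patience=3000, mse_stop_threshold=0.01, seed=0),
        )
        assert history.stop_reason == "threshold"
        assert history.train_mse[-1] <= 0.01


class TestSerialization:
    def test_forward_bit_identical_after_roundtrip(self, tmp_path):
        p = make_net((2, 5, 3, 1), seed=4)
        norm = NormParams(
            ["delta_vgs_mv", "temperature_c", "y"],
            np.array([0.0, 20.0, -7.0]),
            np.array([50.0, 35.0, -3.0]),
        )
        fitted = FittedNetwork(p, norm, ["delta_vgs_mv", "temperature_c"], "y", "log10")
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = FittedNetwork.load(path)
        x = np.random.default_rng(0).uniform(0, 1, (20, 2)) * [50, 15] + [0, 20]
        np.testing.assert_array_equal(fitted.predict(x), loaded.predict(x))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(UsageError):
            NetworkParams((2, 3, 1), [np.zeros((2, 2))], [np.zeros(2)]).validate()
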