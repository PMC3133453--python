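"""Network forward pass, gradients, and the momentum trainer."""

import numpy as np
import pytest

import pepqsar as pq
from pepqsar.network import _loss_and_gradients


def _numerical_gradients(net, X, y, eps=1e-6):
    """Central finite differences over every parameter."""
    def loss(n):
        return _loss_and_gradients(n, X, y)[0]

    grads = {}
    for name in ("iw", "b1", "lw"):
        arr = getattr(net, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            n1, n2 = net.copy(), net.copy()
            getattr(n1, name)[idx] += eps
            getattr(n2, name)[idx] -= eps
            g[idx] = (loss(n1) - loss(n2)) / (2 * eps)
        grads[name] = g
    n1, n2 = net.copy(), net.copy()
    n1.b2 += eps
    n2.b2 -= eps
    grads["b2"] = (loss(n1) - loss(n2)) / (2 * eps)
    return grads


class TestInit:
    def test_same_seed_is_deterministic(self):
        a = pq.init_network(6, 7, seed=3)
        b = pq.init_network(6, 7, seed=3)
        np.testing.assert_array_equal(a.iw, b.iw)
        np.testing.assert_array_equal(a.lw, b.lw)

    def test_different_seeds_differ(self):
        a = pq.init_network(6, 7, seed=3)
        b = pq.init_network(6, 7, seed=4)
        assert not np.array_equal(a.iw, b.iw)

    def test_shapes_for_seven_hidden_neurons(self):
        net = pq.init_network(6, 7, seed=0)
        assert net.iw.shape == (7, 6)
        assert net.lw.shape == (7,)
        assert net.b1.shape == (7,)

    def test_init_scale_bounds(self):
        net = pq.init_network(6, 7, seed=0, init_scale=0.1)
        for arr in (net.iw, net.b1, net.lw):
            assert np.all(np.abs(arr) <= 0.1)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            pq.init_network(0, 3)
        with pytest.raises(ValueError):
            pq.init_network(3, 0)


class TestForward:
    def test_all_zero_network_outputs_zero(self):
        net = pq.BPNetwork(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0.0)
        assert pq.forward(net, [1.0, -2.0]) == 0.0

    def test_zero_hidden_weights_pass_output_bias(self):
        net = pq.BPNetwork(np.zeros((3, 2)), np.zeros(3),
                           np.array([5.0, -1.0, 2.0]), 0.7)
        assert pq.forward(net, [3.0, 4.0]) == pytest.approx(0.7)

    def test_hand_computed_single_hidden_unit(self, toy_net):
        # y = -0.2 + 0.5 * tanh(0.3*1 - 0.7*2 + 0.1)
        x = np.array([1.0, 2.0])
        expected = -0.2 + 0.5 * np.tanh(0.3 - 1.4 + 0.1)
        assert pq.forward(toy_net, x) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self, toy_net):
        with pytest.raises(ValueError):
            pq.forward(toy_net, [1.0, 2.0, 3.0])

    def test_batched_equals_per_sample(self, toy_net):
        X = np.array([[0.1, 0.2], [0.5, -0.3], [2.0, 1.0]])
        batch = pq.forward(toy_net, X)
        singles = [pq.forward(toy_net, x) for x in X]
        np.testing.assert_allclose(batch, singles)


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_backprop_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = pq.init_network(4, 3, seed=seed)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        _, g_iw, g_b1, g_lw, g_b2 = _loss_and_gradients(net, X, y)
        num = _numerical_gradients(net, X, y)
        np.testing.assert_allclose(g_iw, num["iw"], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(g_b1, num["b1"], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(g_lw, num["lw"], rtol=1e-6, atol=1e-9)
        assert g_b2 == pytest.approx(num["b2"], rel=1e-6)


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self, toy_net):
        X = np.array([[0.1, 0.2], [0.3, 0.4]])
        y = np.array([0.5, 0.6])
        cfg = pq.TrainingConfig(learning_rate=0.0, max_epochs=10,
                                mse_goal=1e-12)
        result = pq.train(toy_net, X, y, cfg)
        np.testing.assert_array_equal(result.network.iw, toy_net.iw)
        assert result.network.b2 == toy_net.b2

    def test_constant_target_converges_via_output_bias(self):
        rng = np.random.default_rng(0)
        net = pq.init_network(3, 2, seed=0)
        X = rng.uniform(size=(8, 3))
        y = np.full(8, 0.5)
        result = pq.train(net, X, y,
                          pq.TrainingConfig(learning_rate=0.5, momentum=0.8,
                                            max_epochs=5000, mse_goal=1e-6))
        assert result.converged
        assert result.train_mse <= 1e-6

    def test_loss_nonincreasing_without_momentum_small_step(self, as_printed):
        params = pq.fit_normalizer(as_printed)
        X = params.transform_X(as_printed.X)
        y = params.transform_y(as_printed.y)
        net = pq.init_network(6, 5, seed=2)
        cfg = pq.TrainingConfig(learning_rate=0.01, momentum=0.0,
                                max_epochs=400, mse_goal=1e-9)
        result = pq.train(net, X, y, cfg)
        diffs = np.diff(result.loss_history)
        assert np.all(diffs <= 1e-12)

    def test_convergence_stops_early_and_flags(self):
        rng = np.random.default_rng(1)
        net = pq.init_network(2, 2, seed=1)
        X = rng.uniform(size=(6, 2))
        y = np.full(6, 0.3)
        result = pq.train(net, X, y,
                          pq.TrainingConfig(learning_rate=0.2, momentum=0.5,
                                            max_epochs=5000, mse_goal=1e-4))
        assert result.converged
        assert result.epochs_run < 5000
        assert result.epochs_run <= len(result.loss_history) - 1

    def test_divergence_aborts_with_epoch(self):
        net = pq.init_network(2, 3, seed=0)
        X = np.array([[100.0, -100.0], [50.0, 80.0]])
        y = np.array([0.0, 1.0])
        with pytest.raises(pq.TrainingDivergedError) as exc:
            pq.train(net, X, y, pq.TrainingConfig(learning_rate=50.0,
                                                  momentum=0.9))
        assert exc.value.epoch >= 1

    def test_empty_training_set_rejected(self, toy_net):
        with pytest.raises(ValueError):
            pq.train(toy_net, np.empty((0, 2)), np.empty(0))


class TestEstimator:
    def test_sklearn_facade_fits_and_predicts(self, as_printed):
        params = pq.fit_normalizer(as_printed)
        X = params.transform_X(as_printed.X)
        y = params.transform_y(as_printed.y)
        est = pq.BPNetRegressor(hidden_size=5, max_epochs=800, random_state=0)
        est.fit(X, y)
        assert est.network_.hidden_size == 5
        assert est.n_iter_ <= 800
        preds = est.predict(X)
        assert preds.shape == (58,)
        np.testing.assert_allclose(preds, pq.forward(est.network_, X))

    def test_get_params_round_trip(self):
        est = pq.BPNetRegressor(hidden_size=9, learning_rate=0.1)
        clone_params = est.get_params()
        assert clone_params["hidden_size"] == 9
        est.set_params(momentum=0.5)
        assert est.momentum == 0.5


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"learning_rate": -0.1},
        {"momentum": 1.0},
        {"momentum": -0.1},
        {"max_epochs": 0},
        {"mse_goal": 0.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pq.TrainingConfig(**kwargs)
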