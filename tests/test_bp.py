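import numpy as np
import pytest

from mtuforce import (
    ForceRegressor,
    MlpParams,
    TrainConfig,
    apply_update,
    backprop_gradients,
    forward,
    init_mlp,
    mse_loss,
    predict,
    train,
)


def finite_difference_gradients(params, x, y, h=1e-6):
    """Central-difference oracle for the loss gradients."""
    def loss_at(p):
        out, _, _ = forward(p, x)
        return mse_loss(np.asarray(y).reshape(out.shape), out)

    grad_w = [np.zeros_like(W) for W in params.weights]
    grad_b = [np.zeros_like(b) for b in params.biases]
    for l, W in enumerate(params.weights):
        for idx in np.ndindex(W.shape):
            for sign in (+1, -1):
                W[idx] += sign * h
                val = loss_at(params)
                W[idx] -= sign * h
                grad_w[l][idx] += sign * val / (2 * h)
    for l, b in enumerate(params.biases):
        for idx in np.ndindex(b.shape):
            for sign in (+1, -1):
                b[idx] += sign * h
                val = loss_at(params)
                b[idx] -= sign * h
                grad_b[l][idx] += sign * val / (2 * h)
    return grad_w, grad_b


def rel_err(a, n):
    return np.abs(a - n) / np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-8)


class TestInitMlp:
    def test_deterministic_under_seed(self):
        a = init_mlp([5, 5, 5, 1], seed=7)
        b = init_mlp([5, 5, 5, 1], seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_default_topology_shapes(self):
        p = init_mlp([5, 5, 5, 1])
        assert [w.shape for w in p.weights] == [(5, 5), (5, 5), (5, 1)]
        assert all(np.all(b == 0) for b in p.biases)

    def test_fan_in_bound_respected(self):
        p = init_mlp([9, 4, 1], seed=0)
        assert np.all(np.abs(p.weights[0]) < 1 / 3)
        assert np.all(np.abs(p.weights[1]) < 1 / 2)

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            init_mlp([3, 1])


class TestForward:
    def test_zero_network_closed_form(self):
        p = init_mlp([2, 3, 1], seed=0)
        p.weights = [np.zeros_like(w) for w in p.weights]
        out, activations, _ = forward(p, np.zeros(2))
        assert out.ravel()[0] == 0.0
        np.testing.assert_allclose(activations[1], 0.5)  # sigma(0)

    def test_affine_arithmetic_single_linear_layer(self):
        p = MlpParams(
            [1, 1, 1],
            [np.array([[1.0]]), np.array([[2.0]])],
            [np.array([0.0]), np.array([1.0])],
            hidden_activation="linear",
        )
        out, _, _ = forward(p, np.array([3.0]))
        assert out.ravel()[0] == pytest.approx(7.0)

    def test_batch_equals_per_sample(self):
        p = init_mlp([3, 5, 5, 1], seed=1)
        X = np.random.default_rng(0).standard_normal((6, 3))
        batch = predict(p, X)
        singles = np.array([predict(p, x[None, :])[0] for x in X])
        np.testing.assert_allclose(batch, singles, atol=1e-14)


class TestMseLoss:
    def test_direct_evaluation(self):
        assert mse_loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(2.5)

    def test_zero_at_perfect_fit_and_nonnegative(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(10)
        assert mse_loss(y, y) == 0.0
        assert mse_loss(y, y + rng.standard_normal(10)) >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestBackpropGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [rng.integers(1, 4), rng.integers(2, 6), rng.integers(1, 3)]
        p = init_mlp(sizes, seed=seed)
        X = rng.standard_normal((4, sizes[0]))
        y = rng.standard_normal((4, sizes[-1]))
        gw, gb = backprop_gradients(p, X, y)
        nw, nb = finite_difference_gradients(p, X, y)
        for a, n in zip(gw + gb, nw + nb):
            assert np.max(rel_err(a, n)) < 1e-5

    def test_output_bias_gradient_zero_at_perfect_fit(self):
        p = init_mlp([2, 3, 1], seed=3)
        X = np.random.default_rng(4).standard_normal((5, 2))
        y, _, _ = forward(p, X)
        _, gb = backprop_gradients(p, X, y)
        np.testing.assert_allclose(gb[-1], 0.0, atol=1e-14)

    def test_sample_duplication_preserves_mean_gradient(self):
        p = init_mlp([2, 3, 1], seed=5)
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 2))
        y = rng.standard_normal((4, 1))
        gw1, _ = backprop_gradients(p, X, y)
        gw2, _ = backprop_gradients(p, np.vstack([X, X]), np.vstack([y, y]))
        for a, b in zip(gw1, gw2):
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestApplyUpdate:
    def _scalar_params(self, w):
        return MlpParams(
            [1, 1, 1],
            [np.array([[w]]), np.array([[1.0]])],
            [np.zeros(1), np.zeros(1)],
        )

    def test_zero_gradient_leaves_params_unchanged(self):
        p = init_mlp([2, 3, 1], seed=0)
        zeros = ([np.zeros_like(w) for w in p.weights], [np.zeros_like(b) for b in p.biases])
        q, _ = apply_update(p, zeros, None, 0.1, 0.9)
        for a, b in zip(p.weights, q.weights):
            np.testing.assert_array_equal(a, b)

    def test_plain_gradient_descent_at_zero_momentum(self):
        p = self._scalar_params(0.5)
        grads = ([np.array([[1.0]]), np.zeros((1, 1))], [np.zeros(1), np.zeros(1)])
        q, _ = apply_update(p, grads, None, 0.1, momentum=0.0)
        assert q.weights[0][0, 0] == pytest.approx(0.4)

    def test_momentum_accumulates_over_two_steps(self):
        # constant gradient g: after two steps velocity = -eta*g*(1+m)
        p = self._scalar_params(0.0)
        g = 2.0
        eta, m = 0.1, 0.9
        grads = ([np.array([[g]]), np.zeros((1, 1))], [np.zeros(1), np.zeros(1)])
        p, v = apply_update(p, grads, None, eta, m)
        p, v = apply_update(p, grads, v, eta, m)
        assert v[0][0][0, 0] == pytest.approx(-eta * g * (1 + m))


class TestTrain:
    def test_noiseless_linear_task_reaches_target_error(self):
        x = np.linspace(0, 1, 64).reshape(-1, 1)
        y = 0.5 * x.ravel()
        params, hist = train(x, y, TrainConfig(seed=0))
        assert hist.stop_reason == "target_error_reached"
        assert hist.n_epochs <= 1000
        assert hist.loss[-1] <= 0.001

    def test_infinite_target_stops_immediately(self):
        x = np.linspace(0, 1, 10).reshape(-1, 1)
        params, hist = train(x, x.ravel(), TrainConfig(target_error=np.inf))
        assert hist.n_epochs == 1

    def test_deterministic_history(self):
        x = np.linspace(0, 1, 32).reshape(-1, 1)
        y = x.ravel() ** 2
        _, h1 = train(x, y, TrainConfig(seed=3, max_epochs=50))
        _, h2 = train(x, y, TrainConfig(seed=3, max_epochs=50))
        assert h1.loss == h2.loss

    def test_loss_non_increasing_without_momentum(self):
        x = np.linspace(0, 1, 32).reshape(-1, 1)
        y = 0.3 * x.ravel() + 0.1
        _, hist = train(
            x, y, TrainConfig(learning_rate=0.3, momentum=0.0, max_epochs=200,
                              target_error=0.0, seed=1)
        )
        assert np.all(np.diff(hist.loss) <= 1e-12)

    def test_converged_fit_predicts_training_targets(self):
        x = np.linspace(0, 1, 64).reshape(-1, 1)
        y = 0.5 * x.ravel()
        params, hist = train(x, y, TrainConfig(seed=0))
        rmse = np.sqrt(mse_loss(y, predict(params, x)))
        assert rmse <= np.sqrt(0.001) * 1.01


class TestForceRegressor:
    def test_round_trip_units(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 2, size=(80, 3))
        y = 40.0 * X[:, 0] + 25.0 * X[:, 1] + 5.0
        reg = ForceRegressor(TrainConfig(seed=0)).fit(X, y)
        pred = reg.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.99
        assert pred.min() > 0  # predictions come back in newtons, not [0,1]

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            ForceRegressor().predict(np.zeros((2, 3)))
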