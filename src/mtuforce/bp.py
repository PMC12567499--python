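"""From-scratch backpropagation network for muscle-force regression.

A small fully connected feed-forward network (default: two hidden layers of
five logistic-sigmoid units, linear output) maps windowed EMG-source
features to force.  Training is full-batch gradient descent on the
mean-squared-error loss with classical momentum:

    forward:   o^(l) = f^(l)(W^(l)T o^(l-1) + b^(l))
    loss:      L = (1/n) sum_i (y_i - yhat_i)^2
    backprop:  dL/dw via the chain rule through the cached pre-activations
    update:    v' = momentum * v - eta * grad;  w <- w + v'

With momentum = 0 the update reduces to plain gradient descent
w <- w - eta * dL/dw.  Training stops when the epoch loss reaches
``target_error`` or after ``max_epochs`` epochs.

Everything here is hand-rolled on purpose: the exactness of the analytic
gradients is verified against central finite differences in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_ACTIVATIONS = {
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda z, o: o * (1.0 - o)),
    "linear": (lambda z: z, lambda z, o: np.ones_like(z)),
    "tanh": (np.tanh, lambda z, o: 1.0 - o**2),
}


@dataclass
class MlpParams:
    """Layer weights and biases.

    ``weights[l]`` has shape (fan_in, fan_out); ``biases[l]`` has shape
    (fan_out,).  Hidden layers share one activation, the output layer has
    its own (default linear, for an unbounded regression target).
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "sigmoid"
    output_activation: str = "linear"

    def activation(self, layer: int) -> str:
        return (
            self.output_activation
            if layer == len(self.weights) - 1
            else self.hidden_activation
        )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: learning rate 0.3, momentum 0.9, target error 0.001,
    at most 1000 epochs.
    """

    learning_rate: float = 0.3
    momentum: float = 0.9
    target_error: float = 0.001
    max_epochs: int = 1000
    seed: int = 0
    validation_fraction: float = 0.0


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"   # or "target_error_reached"

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def init_mlp(
    layer_sizes: Sequence[int],
    hidden_activation: str = "sigmoid",
    output_activation: str = "linear",
    seed: int = 0,
) -> MlpParams:
    """Seeded uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) weights, zero biases."""
    sizes = list(layer_sizes)
    if len(sizes) < 3:
        raise ValueError("need at least input, one hidden and output layer")
    if any(s < 1 for s in sizes):
        raise ValueError("all layer sizes must be >= 1")
    for act in (hidden_activation, output_activation):
        if act not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {act!r}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MlpParams(sizes, weights, biases, hidden_activation, output_activation)


def forward(
    params: MlpParams, x: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass caching per-layer outputs and pre-activations.

    ``x`` is a single feature vector or an (n, d) batch.  Returns
    (output, activations o^(0..L), pre-activations z^(1..L)); the output of
    a single-output network is squeezed to shape (n,) for batches and a
    scalar-like (1,) vector for single samples.
    """
    X = np.atleast_2d(np.asarray(x, float))
    if X.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} != network input size {params.layer_sizes[0]}"
        )
    activations = [X]
    preacts = []
    for l, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = activations[-1] @ W + b
        f, _ = _ACTIVATIONS[params.activation(l)]
        activations.append(f(z))
        preacts.append(z)
    return activations[-1], activations, preacts


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error L = (1/n) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size == 0:
        raise ValueError("empty target vector")
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def backprop_gradients(
    params: MlpParams, x: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact chain-rule gradients of the MSE loss w.r.t. weights and biases.

    Full-batch mean formulation: duplicating every sample leaves the
    gradients unchanged.
    """
    X = np.atleast_2d(np.asarray(x, float))
    Y = np.asarray(y, float).reshape(X.shape[0], -1)
    out, activations, preacts = forward(params, X)
    out = activations[-1]
    if out.shape != Y.shape:
        raise ValueError(f"target shape {Y.shape} != output shape {out.shape}")
    n = X.shape[0]
    L = len(params.weights)
    grad_w = [np.empty_like(W) for W in params.weights]
    grad_b = [np.empty_like(b) for b in params.biases]
    # dL/d(output) for L = mean over all n*K output elements (matches mse_loss)
    _, dact = _ACTIVATIONS[params.activation(L - 1)]
    delta = (2.0 / out.size) * (out - Y) * dact(preacts[-1], activations[-1])
    for l in range(L - 1, -1, -1):
        grad_w[l] = activations[l].T @ delta
        grad_b[l] = delta.sum(axis=0)
        if not (np.all(np.isfinite(grad_w[l])) and np.all(np.isfinite(grad_b[l]))):
            raise FloatingPointError("non-finite gradient encountered")
        if l > 0:
            _, dact = _ACTIVATIONS[params.activation(l - 1)]
            delta = (delta @ params.weights[l].T) * dact(
                preacts[l - 1], activations[l]
            )
    return grad_w, grad_b


def apply_update(
    params: MlpParams,
    gradients: tuple[list[np.ndarray], list[np.ndarray]],
    velocity: tuple[list[np.ndarray], list[np.ndarray]] | None,
    learning_rate: float,
    momentum: float = 0.0,
) -> tuple[MlpParams, tuple[list[np.ndarray], list[np.ndarray]]]:
    """Momentum gradient step: v' = m v - eta g; w <- w + v'.

    At momentum = 0 this is exactly plain gradient descent.  Returns new
    params and velocity without mutating the inputs.
    """
    grad_w, grad_b = gradients
    if velocity is None:
        vel_w = [np.zeros_like(W) for W in params.weights]
        vel_b = [np.zeros_like(b) for b in params.biases]
    else:
        vel_w, vel_b = velocity
    new_w, new_b, nvw, nvb = [], [], [], []
    for W, b, gW, gb, vW, vb in zip(
        params.weights, params.biases, grad_w, grad_b, vel_w, vel_b
    ):
        if gW.shape != W.shape or gb.shape != b.shape:
            raise ValueError("gradient shapes do not match parameters")
        vW2 = momentum * vW - learning_rate * gW
        vb2 = momentum * vb - learning_rate * gb
        new_w.append(W + vW2)
        new_b.append(b + vb2)
        nvw.append(vW2)
        nvb.append(vb2)
    out = MlpParams(
        list(params.layer_sizes), new_w, new_b,
        params.hidden_activation, params.output_activation,
    )
    return out, (nvw, nvb)


def train(
    features: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
    hidden_layers: Sequence[int] = (5, 5),
    params: MlpParams | None = None,
) -> tuple[MlpParams, TrainHistory]:
    """Full-batch momentum gradient descent until target error or max epochs.

    Features should be standardized or in [0, 1] (the :class:`ForceRegressor`
    wrapper handles scaling).  Deterministic given ``config.seed``.
    """
    cfg = config or TrainConfig()
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[0] == 1 and np.asarray(targets).size > 1:
        X = X.T
    y = np.asarray(targets, float).reshape(X.shape[0], -1)
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if params is None:
        sizes = [X.shape[1], *hidden_layers, y.shape[1]]
        params = init_mlp(sizes, seed=cfg.seed)
    n_val = int(round(cfg.validation_fraction * X.shape[0]))
    if n_val > 0:
        idx = np.random.default_rng(cfg.seed).permutation(X.shape[0])
        val_idx, fit_idx = idx[:n_val], idx[n_val:]
        Xv, yv = X[val_idx], y[val_idx]
        X, y = X[fit_idx], y[fit_idx]
    history = TrainHistory()
    velocity = None
    for _ in range(cfg.max_epochs):
        out, _, _ = forward(params, X)
        loss = mse_loss(y, out)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (NaN loss); retry with a smaller learning_rate"
            )
        history.loss.append(loss)
        if n_val > 0:
            vout, _, _ = forward(params, Xv)
            history.validation_loss.append(mse_loss(yv, vout))
        if loss <= cfg.target_error:
            history.stop_reason = "target_error_reached"
            break
        grads = backprop_gradients(params, X, y)
        params, velocity = apply_update(
            params, grads, velocity, cfg.learning_rate, cfg.momentum
        )
    else:
        history.stop_reason = "max_epochs"
    return params, history


def predict(params: MlpParams, features: np.ndarray) -> np.ndarray:
    """Forward-pass predictions for a batch of feature vectors."""
    out, _, _ = forward(params, np.atleast_2d(np.asarray(features, float)))
    return out.ravel() if out.shape[1] == 1 else out


class ForceRegressor:
    """Min-max-scaled MLP force regressor.

    Fits min-max scalers for features and target on the training data only,
    trains the backprop network on the [0, 1]-scaled problem, and inverts
    the target scaling at prediction time so outputs are in newtons.
    """

    def __init__(
        self, config: TrainConfig | None = None, hidden_layers: Sequence[int] = (5, 5)
    ):
        self.config = config or TrainConfig()
        self.hidden_layers = tuple(hidden_layers)
        self.params: MlpParams | None = None
        self.history: TrainHistory | None = None
        self._x_min = self._x_range = None
        self._y_min = self._y_range = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForceRegressor":
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and np.asarray(y).size > 1:
            X = X.T
        y = np.asarray(y, float).ravel()
        self._x_min = X.min(axis=0)
        x_ptp = np.ptp(X, axis=0)
        self._x_range = np.where(x_ptp > 0, x_ptp, 1.0)
        self._y_min = y.min()
        y_ptp = float(np.ptp(y))
        self._y_range = y_ptp if y_ptp > 0 else 1.0
        Xs = (X - self._x_min) / self._x_range
        ys = (y - self._y_min) / self._y_range
        self.params, self.history = train(
            Xs, ys, self.config, hidden_layers=self.hidden_layers
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("regressor is not fitted")
        X = np.atleast_2d(np.asarray(X, float))
        Xs = (X - self._x_min) / self._x_range
        ys = predict(self.params, Xs)
        return ys * self._y_range + self._y_min
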