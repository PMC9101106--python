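"""From-scratch feed-forward regression networks.

Architecture: affine layers with hyperbolic-tangent activations on every
hidden layer and a ReLU on the (scalar) output — the output of interest
(a normalized concentration or reference voltage) is non-negative by
construction.  Loss is the mean squared error; optimization is plain
full-batch gradient descent with analytically backpropagated gradients
(d tanh/dz = 1 - tanh^2 z, ReLU subgradient 0 at z = 0).

Two named presets mirror the deployed sensor scheme: the multiple-input
concentration model (2-20-16-1) and the single-input temperature-to-
reference model (1-10-5-1).

No momentum, adaptivity, regularization or mini-batching: the training
procedure itself is deliberately the plain algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, UsageError

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "TrainHistory",
    "forward",
    "loss_mse",
    "gradients",
    "train",
    "MULTI_INPUT_LAYERS",
    "SINGLE_INPUT_LAYERS",
    "multi_input_config",
    "single_input_config",
]

#: layer sizes of the two deployed models
MULTI_INPUT_LAYERS = (2, 20, 16, 1)
SINGLE_INPUT_LAYERS = (1, 10, 5, 1)


@dataclass
class NetworkParams:
    """Weights and biases of a feed-forward network.

    ``weights[i]`` has shape (layer_sizes[i], layer_sizes[i+1]) and
    ``biases[i]`` shape (layer_sizes[i+1],).
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @classmethod
    def initialize(
        cls,
        layer_sizes,
        init_scale: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> "NetworkParams":
        """Seeded uniform(-0.5, 0.5) * init_scale initialization."""
        layer_sizes = tuple(int(s) for s in layer_sizes)
        if len(layer_sizes) < 2 or any(s < 1 for s in layer_sizes):
            raise UsageError(f"invalid layer sizes {layer_sizes}")
        if rng is None:
            rng = np.random.default_rng(0)
        weights, biases = [], []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            weights.append(rng.uniform(-0.5, 0.5, size=(fan_in, fan_out)) * init_scale)
            biases.append(rng.uniform(-0.5, 0.5, size=fan_out) * init_scale)
        return cls(layer_sizes, weights, biases)

    def validate(self) -> None:
        expect = list(zip(self.layer_sizes[:-1], self.layer_sizes[1:]))
        if len(self.weights) != len(expect) or len(self.biases) != len(expect):
            raise UsageError("weight/bias count does not match layer_sizes")
        for w, b, (fi, fo) in zip(self.weights, self.biases, expect):
            if w.shape != (fi, fo) or b.shape != (fo,):
                raise UsageError(f"shape mismatch: W{w.shape}, B{b.shape}, expected ({fi},{fo})")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise UsageError("non-finite parameter values")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.layer_sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],  # row-major, fan_in x fan_out
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        p = cls(
            tuple(d["layer_sizes"]),
            [np.asarray(w, dtype=float) for w in d["weights"]],
            [np.asarray(b, dtype=float) for b in d["biases"]],
        )
        p.validate()
        return p


@dataclass
class TrainConfig:
    """Hyperparameters of full-batch gradient-descent training.

    ``patience`` operationalizes the "stop on train/test divergence"
    rule: training halts after that many consecutive epochs of rising
    test MSE.  ``mse_stop_threshold``, when set, stops as soon as the
    training MSE falls to or below it.
    """

    learning_rate: float = 0.01
    max_epochs: int = 5000
    patience: int = 20
    mse_stop_threshold: float | None = None
    init_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise UsageError("learning_rate must be >= 0")
        if self.max_epochs < 1 or self.patience < 1:
            raise UsageError("max_epochs and patience must be >= 1")


def multi_input_config(**overrides) -> TrainConfig:
    """Training settings of the deployed multiple-input model."""
    cfg = dict(learning_rate=0.01, max_epochs=5000, patience=20)
    cfg.update(overrides)
    return TrainConfig(**cfg)


def single_input_config(**overrides) -> TrainConfig:
    """Training settings of the deployed single-input reference model."""
    cfg = dict(learning_rate=0.01, max_epochs=3000, patience=20, mse_stop_threshold=0.01)
    cfg.update(overrides)
    return TrainConfig(**cfg)


@dataclass
class TrainHistory:
    """Per-epoch training/testing MSE and why training stopped."""

    train_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    best_test_mse: float = float("nan")

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)

    def to_dict(self) -> dict:
        return {
            "train_mse": [float(v) for v in self.train_mse],
            "test_mse": [float(v) for v in self.test_mse],
            "stop_reason": self.stop_reason,
            "best_epoch": int(self.best_epoch),
            "best_test_mse": float(self.best_test_mse),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainHistory":
        return cls(
            list(d["train_mse"]),
            list(d["test_mse"]),
            d["stop_reason"],
            int(d["best_epoch"]),
            float(d["best_test_mse"]),
        )


def _as_matrix(x, n_inputs: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None] if n_inputs == 1 else x[None, :]
    if x.ndim != 2 or x.shape[1] != n_inputs:
        raise UsageError(f"expected feature matrix with {n_inputs} column(s), got shape {x.shape}")
    return x


def _forward_cache(x: np.ndarray, params: NetworkParams):
    """Forward pass keeping pre-activations and activations per layer."""
    zs, acts = [], [x]
    a = x
    last = params.n_layers - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ w + b
        zs.append(z)
        a = np.maximum(z, 0.0) if i == last else np.tanh(z)
        acts.append(a)
    return zs, acts


def forward(x, params: NetworkParams) -> np.ndarray:
    """Predict: tanh hidden layers, ReLU output; vectorized over rows.

    Returns an (n,) vector for single-output networks, else (n, k).
    """
    xm = _as_matrix(x, params.layer_sizes[0])
    _, acts = _forward_cache(xm, params)
    out = acts[-1]
    return out[:, 0] if params.layer_sizes[-1] == 1 else out


def loss_mse(y, yhat) -> float:
    """Mean squared error, 1/n * sum (y - yhat)^2."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise UsageError("MSE of an empty vector is undefined")
    if y.shape != yhat.shape:
        raise UsageError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return float(np.mean((y - yhat) ** 2))


def _backprop(x: np.ndarray, y: np.ndarray, params: NetworkParams):
    """Analytic gradient of the MSE loss; returns (loss, dWs, dBs)."""
    n = x.shape[0]
    zs, acts = _forward_cache(x, params)
    yhat = acts[-1]
    resid = yhat - y.reshape(yhat.shape)
    loss = float(np.mean(resid**2))
    # dL/dyhat through the ReLU; subgradient at exactly 0 taken as 0
    delta = (2.0 / n) * resid * (zs[-1] > 0)
    dws = [np.empty(0)] * params.n_layers
    dbs = [np.empty(0)] * params.n_layers
    for i in range(params.n_layers - 1, -1, -1):
        dws[i] = acts[i].T @ delta
        dbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params.weights[i].T) * (1.0 - acts[i] ** 2)
    return loss, dws, dbs


def gradients(batch, params: NetworkParams):
    """Exact analytic gradients of the MSE over a (features, targets) batch.

    ``batch`` is a (x, y) pair; returns (dWs, dBs) lists matching the
    parameter shapes.
    """
    x, y = batch
    xm = _as_matrix(x, params.layer_sizes[0])
    y = np.asarray(y, dtype=float)
    _, dws, dbs = _backprop(xm, y, params)
    return dws, dbs


def _as_xy(data, n_inputs: int) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "xy"):
        x, y = data.xy()
    else:
        x, y = data
    return _as_matrix(x, n_inputs), np.asarray(y, dtype=float).ravel()


def train(
    train_data,
    test_data,
    layer_sizes,
    config: TrainConfig | None = None,
) -> tuple[NetworkParams, TrainHistory]:
    """Full-batch gradient descent from a seeded random initialization.

    ``train_data``/``test_data`` are :class:`~enzisfet.preprocess.Dataset`
    objects or plain (X, y) pairs with values already normalized to
    [0, 1].  Each epoch performs one full-batch parameter update and
    records post-update train/test MSE.  Stopping: epoch cap, training
    MSE at or below ``mse_stop_threshold`` (when set), or test MSE rising
    for ``patience`` consecutive epochs ("divergence").  The parameters
    with the lowest recorded test MSE are returned.
    """
    config = config or TrainConfig()
    layer_sizes = tuple(int(s) for s in layer_sizes)
    x, y = _as_xy(train_data, layer_sizes[0])
    xt, yt = _as_xy(test_data, layer_sizes[0])
    rng = np.random.default_rng(config.seed)
    # The ReLU output unit has an exactly-zero gradient while its
    # pre-activation is negative on every row, so a draw that starts
    # fully dead can never train.  Redraw (deterministically, from the
    # same stream) until the unit fires on at least one training row.
    for _ in range(1000):
        params = NetworkParams.initialize(layer_sizes, config.init_scale, rng)
        if np.any(forward(x, params) > 0):
            break
    else:
        raise ConvergenceError(
            "could not find an initialization with a live output unit; "
            "check input scaling or increase init_scale"
        )

    history = TrainHistory()
    best = params.copy()
    best_test = np.inf
    rising = 0
    prev_test = np.inf
    stop = "epoch_cap"
    for epoch in range(config.max_epochs):
        loss, dws, dbs = _backprop(x, y, params)
        if not np.isfinite(loss):
            raise ConvergenceError(
                f"training diverged to a non-finite loss at epoch {epoch}; "
                f"reduce learning_rate (currently {config.learning_rate})"
            )
        for w, b, dw, db in zip(params.weights, params.biases, dws, dbs):
            w -= config.learning_rate * dw
            b -= config.learning_rate * db
        train_mse = loss_mse(y, forward(x, params))
        test_mse = loss_mse(yt, forward(xt, params))
        if not (np.isfinite(train_mse) and np.isfinite(test_mse)):
            raise ConvergenceError(
                f"training diverged to a non-finite loss at epoch {epoch}; "
                f"reduce learning_rate (currently {config.learning_rate})"
            )
        history.train_mse.append(train_mse)
        history.test_mse.append(test_mse)
        if test_mse < best_test:
            best_test = test_mse
            best = params.copy()
            history.best_epoch = epoch
        rising = rising + 1 if test_mse > prev_test else 0
        prev_test = test_mse
        if config.mse_stop_threshold is not None and train_mse <= config.mse_stop_threshold:
            stop = "threshold"
            break
        if rising >= config.patience:
            stop = "divergence"
            break
    history.stop_reason = stop
    history.best_test_mse = best_test
    best.validate()
    return best, history
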