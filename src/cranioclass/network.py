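"""Sigmoid multilayer perceptron with momentum and L2 weight decay.

The model is the classical three-layer feed-forward network
``[M inputs; Q hidden; L outputs]`` with the unipolar sigmoid
f(x) = 1/(1+e^-x) on both the hidden and output layers and no bias
terms: net_j = sum_i w_ij x_i. Training is per-sample (online) gradient
descent on the squared error E = 1/2 sum_k (d_k - y_k)^2, augmented with

* a momentum term — each applied weight change is
  delta(n+1) = alpha * delta(n) + eta * gradient term — which smooths
  oscillations and speeds convergence, and
* L2 regularization — adding (lambda/2) * ||w||^2 to the objective,
  realised as a weight-decay term -eta*lambda*w in every update.

For sex classification the output layer has two neurons, female and
male, with one-hot targets female = (1, 0), male = (0, 1). The reported
MSE is the mean over samples of the summed squared output error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from . import _kernels
from .data import FEMALE, MALE, MeasurementDataset, Normalization, one_hot
from .errors import DataFormatError, DivergenceError

MODEL_FORMAT = "cranioclass-model/1"


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one network.

    layer_sizes : (M, Q, L) neuron counts; the study uses (6, 6, 2) and
        (6, 12, 2).
    eta : learning rate, > 0.
    alpha : momentum coefficient in [0, 1).
    lambda_reg : L2 coefficient, >= 0 (weight decay eta*lambda per update).
    max_epochs : training epoch budget.
    mse_goal : stop early once epoch MSE falls to this level (0 disables).
    seed : controls weight initialization and epoch shuffling.
    init_scale : weights start uniform in [-init_scale, +init_scale].
    """

    layer_sizes: tuple[int, int, int] = (6, 12, 2)
    eta: float = 0.5
    alpha: float = 0.9
    lambda_reg: float = 2.0 ** -25
    max_epochs: int = 100_000
    mse_goal: float = 0.0
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))
        if len(self.layer_sizes) != 3 or min(self.layer_sizes) < 1:
            raise DataFormatError(f"layer_sizes must be a positive triple, got {self.layer_sizes}")
        if self.eta <= 0:
            raise DataFormatError(f"eta must be > 0, got {self.eta}")
        if not 0 <= self.alpha < 1:
            raise DataFormatError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.lambda_reg < 0:
            raise DataFormatError(f"lambda_reg must be >= 0, got {self.lambda_reg}")
        if self.max_epochs < 0:
            raise DataFormatError("max_epochs must be nonnegative")
        if self.mse_goal < 0:
            raise DataFormatError("mse_goal must be nonnegative")
        if self.init_scale <= 0:
            raise DataFormatError("init_scale must be > 0")

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "eta": self.eta,
            "alpha": self.alpha,
            "lambda_reg": self.lambda_reg,
            "max_epochs": self.max_epochs,
            "mse_goal": self.mse_goal,
            "seed": self.seed,
            "init_scale": self.init_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise DataFormatError(f"unknown config keys: {sorted(extra)}")
        d = dict(d)
        if "layer_sizes" in d:
            d["layer_sizes"] = tuple(d["layer_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise DataFormatError("config file must hold a key-value mapping")
        payload.pop("normalization", None)  # datamodel option, not a network field
        return cls.from_dict(payload)


@dataclass
class NetworkState:
    """Weights and momentum memory of one network.

    ``w_ih`` is (M, Q) input-to-hidden, ``w_ho`` is (Q, L) hidden-to-output;
    ``prev_delta_*`` hold the previously applied weight changes that the
    momentum term reuses.
    """

    w_ih: np.ndarray
    w_ho: np.ndarray
    prev_delta_ih: np.ndarray
    prev_delta_ho: np.ndarray
    epoch_counter: int = 0

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w_ih.shape[0], self.w_ih.shape[1], self.w_ho.shape[1])

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.w_ih.copy(), self.w_ho.copy(),
            self.prev_delta_ih.copy(), self.prev_delta_ho.copy(),
            self.epoch_counter,
        )


@dataclass(frozen=True)
class ForwardTrace:
    """All intermediate quantities of one forward pass."""

    hidden_net: np.ndarray
    hidden_out: np.ndarray
    output_net: np.ndarray
    output_out: np.ndarray


@dataclass(frozen=True)
class TrainingReport:
    mse_history: np.ndarray
    final_mse: float | None
    train_accuracy_pct: float
    stop_reason: str  # "epoch_budget" | "mse_goal"


@dataclass(frozen=True)
class EvalMetrics:
    accuracy_pct: float
    mse: float


def sigmoid(x):
    """Unipolar sigmoid 1/(1+e^-x); derivative f(x)(1-f(x))."""
    return expit(x)


def init_state(config: NetworkConfig) -> NetworkState:
    """Seeded uniform weight initialization on [-init_scale, +init_scale]."""
    M, Q, L = config.layer_sizes
    rng = np.random.default_rng(config.seed)
    return NetworkState(
        w_ih=rng.uniform(-config.init_scale, config.init_scale, size=(M, Q)),
        w_ho=rng.uniform(-config.init_scale, config.init_scale, size=(Q, L)),
        prev_delta_ih=np.zeros((M, Q)),
        prev_delta_ho=np.zeros((Q, L)),
    )


def forward(state: NetworkState, x: np.ndarray) -> ForwardTrace:
    """Single-sample forward pass through both sigmoid layers."""
    x = np.asarray(x, dtype=float)
    M = state.w_ih.shape[0]
    if x.shape != (M,):
        raise DataFormatError(f"input must have shape ({M},), got {x.shape}")
    hidden_net = x @ state.w_ih
    hidden_out = sigmoid(hidden_net)
    output_net = hidden_out @ state.w_ho
    output_out = sigmoid(output_net)
    return ForwardTrace(hidden_net, hidden_out, output_net, output_out)


def network_outputs(state: NetworkState, X: np.ndarray) -> np.ndarray:
    """Vectorized forward over rows of ``X`` -> (n, L) output activations."""
    return sigmoid(sigmoid(np.asarray(X, float) @ state.w_ih) @ state.w_ho)


def compute_mse(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples of the summed squared output error."""
    outputs = np.asarray(outputs, float)
    targets = np.asarray(targets, float)
    if outputs.shape != targets.shape:
        raise DataFormatError(f"shape mismatch {outputs.shape} vs {targets.shape}")
    if outputs.ndim != 2 or outputs.shape[0] == 0:
        raise DataFormatError("compute_mse needs at least one (n, L) sample")
    return float(np.sum((targets - outputs) ** 2) / outputs.shape[0])


def backprop_update(
    state: NetworkState,
    x: np.ndarray,
    d: np.ndarray,
    config: NetworkConfig,
    scale: float = 1.0,
) -> NetworkState:
    """One online update from a single (sample, target) pair.

    The applied change per weight is

        delta = alpha * prev_delta + eta * scale * grad - eta * lambda * w

    where grad is the squared-error gradient term
    (d_k - O_k) O_k (1 - O_k) O_j for hidden-to-output weights and its
    backpropagated counterpart for input-to-hidden weights. ``scale``
    carries AdaBoost's N*D(i) reweighting (1.0 = unweighted). Momentum
    memory is replaced by the applied deltas.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    tr = forward(state, x)
    h, o = tr.hidden_out, tr.output_out
    delta_k = (d - o) * o * (1.0 - o)
    grad_ho = np.outer(h, delta_k)
    delta_j = h * (1.0 - h) * (state.w_ho @ delta_k)
    grad_ih = np.outer(x, delta_j)

    eta, alpha, lam = config.eta, config.alpha, config.lambda_reg
    d_ih = alpha * state.prev_delta_ih + eta * scale * grad_ih - eta * lam * state.w_ih
    d_ho = alpha * state.prev_delta_ho + eta * scale * grad_ho - eta * lam * state.w_ho
    w_ih = state.w_ih + d_ih
    w_ho = state.w_ho + d_ho
    if not (np.isfinite(w_ih).all() and np.isfinite(w_ho).all()):
        raise DivergenceError(f"weights became non-finite (eta={eta}); reduce the learning rate")
    return NetworkState(w_ih, w_ho, d_ih, d_ho, state.epoch_counter)


def _gradient_scale(n: int, sample_weights: np.ndarray | None) -> np.ndarray:
    if sample_weights is None:
        return np.ones(n)
    w = np.asarray(sample_weights, dtype=float)
    if w.shape != (n,) or (w < 0).any():
        raise DataFormatError("sample_weights must be nonnegative with one entry per training row")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise DataFormatError("sample_weights must sum to 1 over the training rows")
    s = w * n
    # A uniform distribution is the unweighted case by definition; snap
    # roundoff so boosting round 1 reproduces plain training exactly.
    if np.all(np.abs(s - 1.0) < 1e-9):
        return np.ones(n)
    return s


def train_bpnn(
    dataset: MeasurementDataset,
    config: NetworkConfig,
    sample_weights: np.ndarray | None = None,
) -> tuple[NetworkState, TrainingReport]:
    """Train one network on the dataset's training rows.

    Each epoch visits the training rows in a freshly shuffled order
    (seeded) and applies the online update per row. Stops at the epoch
    budget or as soon as the epoch MSE reaches ``mse_goal``. With
    ``sample_weights`` (an AdaBoost distribution D over training rows)
    each row's gradient term is scaled by N*D(i).
    """
    X, sex = dataset.subset_arrays("train")
    Y = one_hot(sex)
    n = X.shape[0]
    M, Q, L = config.layer_sizes
    if X.shape[1] != M:
        raise DataFormatError(f"network expects {M} inputs, data has {X.shape[1]}")
    scale = _gradient_scale(n, sample_weights)

    state = init_state(config)
    shuffle_rng = np.random.default_rng([config.seed, 0x5EED])
    X = np.ascontiguousarray(X)
    Y = np.ascontiguousarray(Y)

    history: list[float] = []
    stop_reason = "epoch_budget"
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        _kernels.train_epoch(
            X, Y, scale, order,
            state.w_ih, state.w_ho, state.prev_delta_ih, state.prev_delta_ho,
            config.eta, config.alpha, config.lambda_reg,
        )
        state.epoch_counter = epoch + 1
        mse = _kernels.epoch_mse(X, Y, state.w_ih, state.w_ho)
        if not np.isfinite(mse):
            raise DivergenceError(
                f"epoch MSE became non-finite at epoch {epoch + 1} (eta={config.eta})"
            )
        history.append(mse)
        if config.mse_goal > 0 and mse <= config.mse_goal:
            stop_reason = "mse_goal"
            break

    outputs = network_outputs(state, X)
    correct = (_labels_from_outputs(outputs) == sex).mean()
    report = TrainingReport(
        mse_history=np.asarray(history),
        final_mse=history[-1] if history else None,
        train_accuracy_pct=float(100.0 * correct),
        stop_reason=stop_reason,
    )
    return state, report


def _labels_from_outputs(outputs: np.ndarray) -> np.ndarray:
    """Female iff the female neuron strictly exceeds the male one; ties -> male."""
    return np.where(outputs[..., 0] > outputs[..., 1], FEMALE, MALE)


def predict(state: NetworkState, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one sample; returns (label, raw output vector)."""
    out = forward(state, x).output_out
    return int(_labels_from_outputs(out)), out


def evaluate(state: NetworkState, dataset: MeasurementDataset, split: str) -> EvalMetrics:
    """Accuracy (%) and MSE of the network on one split of the dataset."""
    X, sex = dataset.subset_arrays(split)
    outputs = network_outputs(state, X)
    accuracy = 100.0 * float((_labels_from_outputs(outputs) == sex).mean())
    return EvalMetrics(accuracy_pct=accuracy, mse=compute_mse(outputs, one_hot(sex)))


# -- persistence -------------------------------------------------------


def _norm_to_dict(norm: Normalization | None) -> dict | None:
    if norm is None:
        return None
    return {"mode": norm.mode, "loc": norm.loc.tolist(), "scale": norm.scale.tolist()}


def _norm_from_dict(d: dict | None) -> Normalization | None:
    if d is None:
        return None
    return Normalization(mode=d["mode"], loc=np.array(d["loc"]), scale=np.array(d["scale"]))


def save_model(
    state: NetworkState,
    config: NetworkConfig,
    path,
    normalization: Normalization | None = None,
) -> None:
    """Versioned self-describing text serialization (JSON) for exact reload."""
    payload = {
        "format": MODEL_FORMAT,
        "config": config.to_dict(),
        "layer_sizes": list(state.layer_sizes),
        "epoch_counter": state.epoch_counter,
        "w_ih": state.w_ih.tolist(),
        "w_ho": state.w_ho.tolist(),
        "prev_delta_ih": state.prev_delta_ih.tolist(),
        "prev_delta_ho": state.prev_delta_ho.tolist(),
        "normalization": _norm_to_dict(normalization),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> tuple[NetworkState, NetworkConfig, Normalization | None]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != MODEL_FORMAT:
        raise DataFormatError(f"unrecognized model format {payload.get('format')!r}")
    state = NetworkState(
        w_ih=np.array(payload["w_ih"]),
        w_ho=np.array(payload["w_ho"]),
        prev_delta_ih=np.array(payload["prev_delta_ih"]),
        prev_delta_ho=np.array(payload["prev_delta_ho"]),
        epoch_counter=int(payload["epoch_counter"]),
    )
    return state, NetworkConfig.from_dict(payload["config"]), _norm_from_dict(payload["normalization"])
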