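"""AdaBoost integration of backpropagation networks.

The ensemble trains T networks sequentially. Round t trains a network
under a sample-weight distribution D_t over the training rows (uniform
at t = 1), scores it by the weighted misclassification error
eps_t = sum_i D_t(i) * eps_i with eps_i the 0/1 error indicator, gives
it the vote weight

    W_t = 1/2 * ln((1 - eps_t) / eps_t),

and re-weights the samples by u_i = D_t(i) * beta^(1 - eps_i) with
beta = eps_t / (1 - eps_t), normalized — correctly classified rows
shrink, so the next network concentrates on the hard rows (the
classical two-class AdaBoost update). A round whose weighted error
reaches 0.5 is no better than chance; it aborts and truncates the
ensemble. Prediction sums W_t-weighted raw output vectors and takes the
argmax, ties broken toward male.

Sample weights enter network training by scaling each row's gradient
contribution by N*D(i) (deterministic reweighting, not resampling), so a
uniform distribution reproduces unweighted training exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import FEMALE, MALE, MeasurementDataset
from .errors import BoostAbortSignal, DataFormatError, NoUsableLearnerError
from .network import (
    MODEL_FORMAT,
    NetworkConfig,
    NetworkState,
    network_outputs,
    train_bpnn,
)

ENSEMBLE_FORMAT = "cranioclass-ensemble/1"

#: eps_t is clamped to [EPS_FLOOR, 1 - EPS_FLOOR] before the log-odds.
EPS_FLOOR = 1e-10


@dataclass
class BoostState:
    """Mutable bookkeeping carried across boosting rounds."""

    sample_weights: np.ndarray
    learners: list[NetworkState]
    learner_weights: list[float]
    avg_errors: list[float]


@dataclass(frozen=True)
class EnsembleModel:
    """T trained networks with their vote weights W_1..W_T.

    ``final_distribution`` is the sample-weight distribution D_{T+1}
    left after the last completed round; ``avg_errors`` the per-round
    weighted errors eps_t.
    """

    learners: tuple[NetworkState, ...]
    weights: np.ndarray
    avg_errors: np.ndarray
    final_distribution: np.ndarray
    config: NetworkConfig

    def __post_init__(self) -> None:
        if len(self.learners) < 1:
            raise DataFormatError("an ensemble needs at least one learner")
        if len(self.learners) != len(self.weights) or len(self.weights) != len(self.avg_errors):
            raise DataFormatError("learner, weight and error counts must agree")
        if not np.isfinite(self.weights).all():
            raise DataFormatError("learner weights must be finite")


def init_sample_weights(n: int) -> np.ndarray:
    """Uniform initial distribution D_1(i) = 1/N."""
    if n < 1:
        raise DataFormatError("cannot initialize sample weights for an empty sample")
    return np.full(n, 1.0 / n)


def learner_error(
    learner: NetworkState,
    dataset: MeasurementDataset,
    weights: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-row 0/1 error indicators eps_i and the weighted error eps_t.

    Both are computed on the training rows, under the distribution the
    learner was trained with.
    """
    X, sex = dataset.subset_arrays("train")
    weights = np.asarray(weights, float)
    if weights.shape != sex.shape:
        raise DataFormatError("weights must have one entry per training row")
    outputs = network_outputs(learner, X)
    predicted = np.where(outputs[:, 0] > outputs[:, 1], FEMALE, MALE)
    eps_i = (predicted != sex).astype(float)
    return eps_i, float(weights @ eps_i)


def learner_weight(eps_t: float) -> float:
    """Vote weight W_t = 1/2 ln((1-eps)/eps): positive for better-than-chance
    learners, zero at chance level, antisymmetric about eps = 0.5."""
    eps = min(max(float(eps_t), EPS_FLOOR), 1.0 - EPS_FLOOR)
    return 0.5 * float(np.log((1.0 - eps) / eps))


def update_sample_weights(
    weights: np.ndarray,
    eps_i: np.ndarray,
    eps_t: float,
) -> np.ndarray:
    """Next-round distribution: shrink correctly classified rows by
    beta = eps_t/(1-eps_t) and renormalize.

    Requires 0 < eps_t < 0.5 (the boosting precondition); eps_t >= 0.5
    raises :class:`BoostAbortSignal`. At eps_t = 0 every row is correct
    and the common beta factor cancels, leaving the distribution
    unchanged.
    """
    weights = np.asarray(weights, float)
    eps_i = np.asarray(eps_i, float)
    if eps_t >= 0.5:
        raise BoostAbortSignal(f"weighted error {eps_t:.4f} >= 0.5; round aborted")
    if eps_t < 0:
        raise DataFormatError("weighted error cannot be negative")
    eps = max(float(eps_t), EPS_FLOOR)
    beta = eps / (1.0 - eps)
    u = weights * beta ** (1.0 - eps_i)
    return u / u.sum()


def train_adaboost(
    dataset: MeasurementDataset,
    T: int = 4,
    config: NetworkConfig | None = None,
) -> EnsembleModel:
    """Boost T networks on the dataset's training rows.

    Round t trains with seed ``config.seed + t`` so learners differ even
    when the distribution barely moves. Rounds whose weighted error
    reaches 0.5 truncate the ensemble at t-1 learners; if the very first
    round aborts there is no usable learner and
    :class:`NoUsableLearnerError` is raised.
    """
    if T < 1:
        raise DataFormatError("T must be at least 1")
    config = config if config is not None else NetworkConfig()
    _, sex = dataset.subset_arrays("train")
    n = sex.shape[0]

    state = BoostState(
        sample_weights=init_sample_weights(n),
        learners=[], learner_weights=[], avg_errors=[],
    )
    for t in range(1, T + 1):
        round_config = NetworkConfig(**{**config.to_dict(), "seed": config.seed + t})
        learner, _ = train_bpnn(dataset, round_config, sample_weights=state.sample_weights)
        eps_i, eps_t = learner_error(learner, dataset, state.sample_weights)
        if eps_t >= 0.5:
            break  # chance-level round: truncate the ensemble here
        state.learners.append(learner)
        state.learner_weights.append(learner_weight(eps_t))
        state.avg_errors.append(eps_t)
        state.sample_weights = update_sample_weights(state.sample_weights, eps_i, eps_t)
    if not state.learners:
        raise NoUsableLearnerError(
            "every boosting round had weighted error >= 0.5; no usable learner"
        )
    return EnsembleModel(
        learners=tuple(state.learners),
        weights=np.asarray(state.learner_weights),
        avg_errors=np.asarray(state.avg_errors),
        final_distribution=state.sample_weights,
        config=config,
    )


def ensemble_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Weighted vote H(x) = sum_t W_t h_t(x) over the (female, male) neurons."""
    X = np.asarray(X, float)
    scores = np.zeros((X.shape[0], model.learners[0].w_ho.shape[1]))
    for w, learner in zip(model.weights, model.learners):
        scores += w * network_outputs(learner, X)
    return scores


def ensemble_outputs(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Vote scores rescaled by the total vote weight, so they live on the
    same (0, 1) scale as a single network's outputs (used for ensemble MSE)."""
    return ensemble_scores(model, X) / model.weights.sum()


def ensemble_predict(model: EnsembleModel, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one sample by weighted vote; returns (label, score vector)."""
    scores = ensemble_scores(model, np.asarray(x, float).reshape(1, -1))[0]
    label = FEMALE if scores[0] > scores[1] else MALE
    return label, scores


def ensemble_labels(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    scores = ensemble_scores(model, X)
    return np.where(scores[:, 0] > scores[:, 1], FEMALE, MALE)


# -- persistence -------------------------------------------------------


def save_ensemble(model: EnsembleModel, path) -> None:
    """Versioned JSON container embedding every learner plus the vote weights."""
    payload = {
        "format": ENSEMBLE_FORMAT,
        "config": model.config.to_dict(),
        "weights": model.weights.tolist(),
        "avg_errors": model.avg_errors.tolist(),
        "final_distribution": model.final_distribution.tolist(),
        "learners": [
            {
                "w_ih": s.w_ih.tolist(),
                "w_ho": s.w_ho.tolist(),
                "prev_delta_ih": s.prev_delta_ih.tolist(),
                "prev_delta_ho": s.prev_delta_ho.tolist(),
                "epoch_counter": s.epoch_counter,
            }
            for s in model.learners
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_ensemble(path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != ENSEMBLE_FORMAT:
        raise DataFormatError(f"unrecognized ensemble format {payload.get('format')!r}")
    learners = tuple(
        NetworkState(
            w_ih=np.array(d["w_ih"]),
            w_ho=np.array(d["w_ho"]),
            prev_delta_ih=np.array(d["prev_delta_ih"]),
            prev_delta_ho=np.array(d["prev_delta_ho"]),
            epoch_counter=int(d["epoch_counter"]),
        )
        for d in payload["learners"]
    )
    return EnsembleModel(
        learners=learners,
        weights=np.array(payload["weights"]),
        avg_errors=np.array(payload["avg_errors"]),
        final_distribution=np.array(payload["final_distribution"]),
        config=NetworkConfig.from_dict(payload["config"]),
    )
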