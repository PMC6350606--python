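"""Classical comparators: Fisher discriminant analysis and logistic regression.

These are the standard measurement-based sex-classification methods the
network is compared against. Both are written directly on the linear
algebra (a pooled-covariance Fisher discriminant; an iteratively
reweighted least-squares logistic fit) so the comparison is runnable on
any measurement table without further dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boost import ensemble_labels, train_adaboost
from .data import FEATURES, FEMALE, MALE, MeasurementDataset
from .errors import DataFormatError
from .network import NetworkConfig

#: Diagonal loading factor used when a covariance/design solve is singular.
RIDGE_EPS = 1e-8
#: |coefficient| beyond which the logistic fit is flagged quasi-separated.
SEPARATION_CAP = 30.0


@dataclass(frozen=True)
class LdaModel:
    """A Fisher linear discriminant: project onto ``projection`` and cut at
    ``threshold`` (female side = larger projections)."""

    features: tuple[str, ...]
    projection: np.ndarray
    threshold: float
    class_means: dict[str, float]  # projected means, keys "female"/"male"
    ridged: bool = False

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.projection


@dataclass(frozen=True)
class LogisticModel:
    """Binary logistic regression P(female | x) = expit(b0 + x @ b)."""

    coefficients: np.ndarray  # intercept first
    converged: bool
    iterations: int
    quasi_separated: bool = False

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        z = self.coefficients[0] + X @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-z))


def _feature_indices(features) -> tuple[tuple[str, ...], list[int]]:
    if features is None:
        features = FEATURES
    features = tuple(features)
    unknown = set(features) - set(FEATURES)
    if unknown:
        raise DataFormatError(f"unknown feature(s): {sorted(unknown)}")
    if not features:
        raise DataFormatError("at least one feature is required")
    return features, [FEATURES.index(f) for f in features]


def fit_lda(
    dataset: MeasurementDataset,
    features=None,
    use_priors: bool = False,
) -> LdaModel:
    """Fit a Fisher discriminant on the training rows.

    projection = pooled-within-covariance^-1 @ (mean_F - mean_M); the
    threshold is the midpoint of the projected class means (equal-prior
    rule), shifted by -ln(n_F/n_M) when ``use_priors`` is set. A singular
    pooled covariance is ridge-stabilized by eps*trace/p on the diagonal.
    With one feature this reduces to a cut on that variable.
    """
    names, cols = _feature_indices(features)
    X, sex = dataset.subset_arrays("train")
    X = X[:, cols]
    Xf, Xm = X[sex == FEMALE], X[sex == MALE]
    if len(Xf) < 2 or len(Xm) < 2:
        raise DataFormatError("LDA needs at least two training rows per class")

    mean_f, mean_m = Xf.mean(axis=0), Xm.mean(axis=0)
    pooled = (
        (len(Xf) - 1) * np.cov(Xf, rowvar=False).reshape(len(cols), len(cols))
        + (len(Xm) - 1) * np.cov(Xm, rowvar=False).reshape(len(cols), len(cols))
    ) / (len(Xf) + len(Xm) - 2)
    ridged = False
    try:
        projection = np.linalg.solve(pooled, mean_f - mean_m)
        if not np.isfinite(projection).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridged = True
        loading = RIDGE_EPS * np.trace(pooled) / len(cols)
        projection = np.linalg.solve(
            pooled + loading * np.eye(len(cols)), mean_f - mean_m
        )
    proj_f = float(projection @ mean_f)
    proj_m = float(projection @ mean_m)
    threshold = 0.5 * (proj_f + proj_m)
    if use_priors:
        threshold -= float(np.log(len(Xf) / len(Xm)))
    return LdaModel(
        features=names,
        projection=projection,
        threshold=threshold,
        class_means={"female": proj_f, "male": proj_m},
        ridged=ridged,
    )


def predict_lda(model: LdaModel, x: np.ndarray) -> int:
    """Female iff the projected sample strictly exceeds the threshold."""
    score = float(np.asarray(x, float) @ model.projection)
    return FEMALE if score > model.threshold else MALE


def lda_labels(model: LdaModel, X: np.ndarray) -> np.ndarray:
    return np.where(model.scores(X) > model.threshold, FEMALE, MALE)


def fit_logistic(
    dataset: MeasurementDataset,
    features=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (female = 1) by Newton/IRLS.

    Converged when the largest coefficient change is <= ``tol``.
    Quasi-separation (any |coefficient| above 30 on normalized features)
    is flagged, not errored; rank-deficient inner solves are
    ridge-stabilized.
    """
    names, cols = _feature_indices(features)
    X, sex = dataset.subset_arrays("train")
    if (sex == FEMALE).sum() < 1 or (sex == MALE).sum() < 1:
        raise DataFormatError("logistic regression needs at least one row per class")
    A = np.column_stack([np.ones(len(X)), X[:, cols]])
    y = (sex == FEMALE).astype(float)

    beta = np.zeros(A.shape[1])
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-(A @ beta)))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = A.T @ (y - p)
        hess = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            loading = RIDGE_EPS * np.trace(hess) / hess.shape[0]
            step = np.linalg.solve(hess + loading * np.eye(hess.shape[0]), grad)
        beta = beta + step
        if np.max(np.abs(step)) <= tol:
            converged = True
            break
    return LogisticModel(
        coefficients=beta,
        converged=converged,
        iterations=iterations,
        quasi_separated=bool(np.max(np.abs(beta)) > SEPARATION_CAP),
    )


def logistic_labels(model: LogisticModel, X: np.ndarray, features=None) -> np.ndarray:
    _, cols = _feature_indices(features)
    p = model.probabilities(np.asarray(X, float)[:, cols])
    return np.where(p > 0.5, FEMALE, MALE)


def _sex_accuracies(predicted: np.ndarray, sex: np.ndarray) -> tuple[float, float, float]:
    """(male %, female %, unweighted mean %) accuracy columns."""
    acc_m = 100.0 * float((predicted[sex == MALE] == MALE).mean())
    acc_f = 100.0 * float((predicted[sex == FEMALE] == FEMALE).mean())
    return acc_m, acc_f, 0.5 * (acc_m + acc_f)


def compare_models(
    dataset: MeasurementDataset,
    config: NetworkConfig | None = None,
    T: int = 4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-method male/female/mean test accuracies on one shared split.

    Rows: the boosted network on all six variables, the six univariate
    discriminants, the six-variable discriminant, and six-variable
    logistic regression. The mean column is the unweighted average of
    the per-sex accuracies.
    """
    config = config if config is not None else NetworkConfig(max_epochs=2000)
    if seed is not None:
        config = NetworkConfig(**{**config.to_dict(), "seed": seed})
    Xte, yte = dataset.subset_arrays("test")
    rows = []

    ensemble = train_adaboost(dataset, T=T, config=config)
    rows.append(("BPNN (6 variables)", *_sex_accuracies(ensemble_labels(ensemble, Xte), yte)))

    for name in FEATURES:
        model = fit_lda(dataset, features=(name,))
        predicted = lda_labels(model, Xte[:, [FEATURES.index(name)]])
        rows.append((f"Discriminant analysis ({name})", *_sex_accuracies(predicted, yte)))

    lda6 = fit_lda(dataset)
    rows.append((
        "Discriminant analysis (6 variables)",
        *_sex_accuracies(lda_labels(lda6, Xte), yte),
    ))
    logit = fit_logistic(dataset)
    rows.append((
        "Logistic regression (6 variables)",
        *_sex_accuracies(logistic_labels(logit, Xte), yte),
    ))
    return pd.DataFrame(rows, columns=["method", "male_acc_pct", "female_acc_pct", "mean_acc_pct"])
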