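"""The two identification models: fine KNN and regularized linear discriminant.

Both are small, fully specified, deterministic estimators:

* **KNN** — majority vote among the ``k`` nearest training samples under
  Euclidean distance (``k = 2`` is the "fine" setting used for within-day
  identification).  Vote ties are resolved by the nearer of the tied
  neighbours; exact distance ties by the smallest training-row index, which
  makes predictions independent of training-row order.
* **LDA** — Gaussian classes with a shared (pooled within-class) covariance
  estimated with divisor ``N - C`` and a small ridge ``gamma`` added to the
  diagonal for numerical stability.  Prediction maximises the linear
  discriminant ``delta_c(x) = x' S^-1 mu_c - 1/2 mu_c' S^-1 mu_c + log pi_c``
  with empirical class priors ``pi_c``.

No randomness lives here; stochasticity belongs to the validation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KNNConfig:
    k: int = 2
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class LDAConfig:
    #: ridge added to the pooled-covariance diagonal, as a fraction of the
    #: mean diagonal element; 0 disables regularization.
    gamma: float = 1e-6
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


ModelConfig = Union[KNNConfig, LDAConfig]


@dataclass
class FittedModel:
    """Frozen state of a fitted classifier; prediction is a pure function."""

    kind: str  # "knn" | "lda"
    config: ModelConfig
    classes: np.ndarray
    # knn state
    train_x: Optional[np.ndarray] = None
    train_y_idx: Optional[np.ndarray] = None
    # lda state
    means: Optional[np.ndarray] = None  # (C, d)
    precision: Optional[np.ndarray] = None  # Sigma^-1, (d, d)
    log_priors: Optional[np.ndarray] = None
    # standardization
    center: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        if self.train_x is not None:
            return self.train_x.shape[1]
        return self.means.shape[1]


def fit(features: np.ndarray, labels: np.ndarray, config: ModelConfig) -> FittedModel:
    """Fit a KNN or LDA model; deterministic in its inputs."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D (samples, d) array")
    if len(y) != x.shape[0]:
        raise ValueError("labels length must match feature rows")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    center = scale = None
    if config.standardize:
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        x = (x - center) / scale
    if isinstance(config, KNNConfig):
        if config.k >= x.shape[0]:
            raise ValueError(f"k={config.k} must be smaller than the training set ({x.shape[0]})")
        return FittedModel(kind="knn", config=config, classes=classes,
                           train_x=x, train_y_idx=y_idx, center=center, scale=scale)
    if isinstance(config, LDAConfig):
        return _fit_lda(x, y_idx, classes, config, center, scale)
    raise TypeError(f"unknown model config {type(config).__name__}")


def _fit_lda(x, y_idx, classes, config, center, scale) -> FittedModel:
    n, d = x.shape
    n_classes = len(classes)
    if n - n_classes <= 0:
        raise ValueError("LDA needs more samples than classes for a pooled covariance")
    means = np.stack([x[y_idx == c].mean(axis=0) for c in range(n_classes)])
    resid = x - means[y_idx]
    cov = resid.T @ resid / (n - n_classes)
    if config.gamma > 0:
        cov = cov + config.gamma * np.mean(np.diag(cov)) * np.eye(d)
    try:
        precision = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular after ridge; increase gamma"
        ) from exc
    counts = np.bincount(y_idx, minlength=n_classes)
    log_priors = np.log(counts / n)
    return FittedModel(kind="lda", config=config, classes=classes, means=means,
                       precision=precision, log_priors=log_priors,
                       center=center, scale=scale)


def predict(model: FittedModel, queries: np.ndarray) -> np.ndarray:
    """Predict class labels for each query row."""
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    if q.shape[1] != model.n_features:
        raise ValueError(
            f"query dimension {q.shape[1]} != model dimension {model.n_features}"
        )
    if model.center is not None:
        q = (q - model.center) / model.scale
    if model.kind == "knn":
        idx = _knn_predict_idx(model, q)
    else:
        idx = _lda_predict_idx(model, q)
    return model.classes[idx]


def _knn_predict_idx(model: FittedModel, q: np.ndarray) -> np.ndarray:
    k = model.config.k
    dist = cdist(q, model.train_x, metric="euclidean")
    out = np.empty(len(q), dtype=int)
    for i, row in enumerate(dist):
        # stable sort: equidistant neighbours ordered by training-row index
        order = np.argsort(row, kind="stable")[:k]
        votes = model.train_y_idx[order]
        counts = np.bincount(votes, minlength=len(model.classes))
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            # vote tie: the nearest neighbour belonging to a tied class wins
            # (for k=2 this is simply the nearer neighbour's label)
            for j in order:
                if model.train_y_idx[j] in tied:
                    out[i] = model.train_y_idx[j]
                    break
    return out


def _lda_predict_idx(model: FittedModel, q: np.ndarray) -> np.ndarray:
    a = model.precision @ model.means.T  # (d, C)
    scores = q @ a - 0.5 * np.einsum("cd,dc->c", model.means, a) + model.log_priors
    return np.argmax(scores, axis=1)
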