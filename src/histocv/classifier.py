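"""Reference classifiers with a uniform fit/predict contract.

Two deliberately simple models stand in for whatever classifier a real
study would train (a CNN, typically):

* ``nearest_centroid`` — stores per-class mean feature vectors and assigns
  the class of the closest centroid.  It averages away patient identity
  and is therefore only mildly leakage-sensitive.
* ``knn`` — memorises the training set and votes among the k nearest
  training patches.  With k=1 it is maximally leakage-sensitive: whenever
  a same-patient patch is available in the training set it will usually be
  the nearest neighbour, which is precisely the mechanism that inflates
  patch-level cross-validation.

Any object exposing the same ``fit(X, y)`` / ``predict(X)`` contract can be
substituted in the experiment drivers, so real models can be wired in.

Determinism: Euclidean distances, neighbour ties broken by smallest
training index (stable sort), label-vote and centroid-distance ties broken
toward the more severe class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .classes import CLASSES, CLASS_INDEX

KINDS = ("nearest_centroid", "knn")


@dataclass
class TrainedModel:
    kind: str
    classes: tuple[str, ...]  # in severity order
    state: dict = field(default_factory=dict)
    fingerprint: str = ""  # hash of the training data, for provenance
    n_features: int = 0

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _check_matrix(X, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if np.isnan(X).any():
        raise ValueError("NaN features are not allowed")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model ({n_features})"
        )
    return X


def _training_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(",".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def fit(kind: str, X, y, k_neighbors: int = 1) -> TrainedModel:
    """Train a model of ``kind`` on feature rows ``X`` with class labels ``y``."""
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    X = _check_matrix(X)
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    if len(y) == 0:
        raise ValueError("empty training set")
    present = sorted(set(y), key=lambda c: CLASS_INDEX[c])
    if len(present) == 0:
        raise ValueError("no classes present after filtering")

    model = TrainedModel(
        kind=kind,
        classes=tuple(present),
        n_features=X.shape[1],
        fingerprint=_training_fingerprint(X, y),
    )
    if kind == "nearest_centroid":
        centroids = np.stack([X[y == c].mean(axis=0) for c in present])
        model.state = {"centroids": centroids}
    else:
        if k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        codes = np.array([CLASS_INDEX[c] for c in y])
        model.state = {"X": X.copy(), "codes": codes, "k": int(k_neighbors)}
    return model


def predict(model: TrainedModel, X) -> np.ndarray:
    """Predicted class labels for each row of ``X``."""
    X = _check_matrix(X, model.n_features)
    if model.kind == "nearest_centroid":
        dist = cdist(X, model.state["centroids"])
        # ties toward the more severe class: scan argmin from the severe end
        idx = (dist.shape[1] - 1) - np.argmin(dist[:, ::-1], axis=1)
        return np.array([model.classes[i] for i in idx])

    k = model.state["k"]
    train_X = model.state["X"]
    train_codes = model.state["codes"]
    out = np.empty(len(X), dtype=np.int64)
    chunk = max(1, int(2_000_000 // max(1, len(train_X))))
    for start in range(0, len(X), chunk):
        block = X[start:start + chunk]
        dist = cdist(block, train_X)
        if k == 1:
            # stable tie-break: smallest training index among equidistant
            nearest = np.argmin(dist, axis=1)
            out[start:start + len(block)] = train_codes[nearest]
        else:
            order = np.argsort(dist, axis=1, kind="stable")[:, :k]
            for i, neighbors in enumerate(order):
                votes = np.bincount(train_codes[neighbors], minlength=len(CLASSES))
                top = votes.max()
                # label-vote ties toward the more severe class
                out[start + i] = np.nonzero(votes == top)[0][-1]
    return np.array([CLASSES[c] for c in out])
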