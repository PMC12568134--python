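"""The two fall detectors behind one contract: 1-NN and RBF-kernel SVM.

Both operate on z-scored feature vectors (standardization fitted on training
rows only; a zero-variance feature gets unit scale). The nearest-neighbor
classifier is evaluated directly on the standardized training matrix so that
distance and vote ties resolve deterministically to the smallest training
index. The SVM is scikit-learn's C-SVC with the RBF kernel and
``gamma = 1 / (n_features * Var(X))`` ("scale").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from fallwin.balance import LabeledFeatures
from fallwin.errors import UsageError

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of a detector.

    ``kind``: ``knn`` (k nearest neighbors, default k=1) or ``svm``
    (RBF kernel, C-SVC). ``gamma_mode='scale'`` sets
    gamma = 1 / (n_features * Var(X)) on the (standardized) training matrix.
    ``standardize`` toggles the z-score step; on by default because mean-g
    features and kurtosis live on very different scales and 1-NN distances
    are scale-sensitive.
    """

    kind: Literal["knn", "svm"] = "knn"
    k: int = 1
    C: float = 1.0
    gamma_mode: Literal["scale"] = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm"):
            raise UsageError(f"kind must be 'knn' or 'svm', got {self.kind!r}")
        if self.k < 1:
            raise UsageError(f"k must be >= 1, got {self.k}")
        if self.C <= 0:
            raise UsageError(f"C must be > 0, got {self.C}")


@dataclass
class TrainedDetector:
    """A fitted standardizer + classifier with its provenance fingerprint."""

    spec: ModelSpec
    scaler: StandardScaler | None
    classes: tuple
    fingerprint: dict = field(default_factory=dict)
    # knn state: standardized training matrix + labels; svm state: fitted SVC
    train_matrix: np.ndarray | None = None
    train_labels: np.ndarray | None = None
    svc: SVC | None = None

    @property
    def n_features(self) -> int:
        return int(self.fingerprint["n_features"])

    def save(self, path: str | Path) -> None:
        """Persist to a single versioned archive."""
        joblib.dump({"format_version": FORMAT_VERSION, "detector": self}, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedDetector":
        blob = joblib.load(path)
        if blob.get("format_version") != FORMAT_VERSION:
            raise UsageError(
                f"unsupported model archive version {blob.get('format_version')}"
            )
        return blob["detector"]


def _transform(det: TrainedDetector, rows: np.ndarray) -> np.ndarray:
    return det.scaler.transform(rows) if det.scaler is not None else rows


def fit(data: LabeledFeatures, spec: ModelSpec, seed: int = 0) -> TrainedDetector:
    """Fit a detector on labeled feature rows.

    The standardizer is computed on the training rows only; the model is
    fitted on the standardized rows. Deterministic for a given seed.
    """
    x, y = data.matrix, data.labels
    if np.isnan(x).any():
        bad = int(np.where(np.isnan(x).any(axis=0))[0][0])
        name = data.feature_names[bad] if data.feature_names else f"column {bad}"
        raise UsageError(f"NaN in feature {name!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise UsageError("training data must contain >= 2 classes")

    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(x)  # zero-variance columns get unit scale
        xs = scaler.transform(x)
    else:
        xs = np.asarray(x, dtype=float)

    det = TrainedDetector(
        spec=spec,
        scaler=scaler,
        classes=tuple(classes),
        fingerprint={"n_rows": x.shape[0], "n_features": x.shape[1], "seed": seed},
    )
    if spec.kind == "knn":
        if spec.k > x.shape[0]:
            raise UsageError(f"k={spec.k} exceeds {x.shape[0]} training rows")
        det.train_matrix = xs
        det.train_labels = np.asarray(y)
    else:
        det.svc = SVC(
            kernel="rbf", C=spec.C, gamma="scale", random_state=seed
        ).fit(xs, y)
    return det


def predict(model: TrainedDetector, rows) -> np.ndarray:
    """Predict one label per row; labels are those seen in training.

    The k-NN vote uses Euclidean distance on standardized features;
    distance ties and vote ties resolve to the smallest training index.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] == 0:
        return np.asarray([], dtype=object)
    if rows.shape[1] != model.n_features:
        raise UsageError(
            f"feature count mismatch: model expects {model.n_features}, "
            f"got {rows.shape[1]}"
        )
    xs = _transform(model, rows)
    if model.spec.kind == "svm":
        return model.svc.predict(xs)

    dist = cdist(xs, model.train_matrix)
    # stable sort: equal distances keep ascending training-index order
    order = np.argsort(dist, axis=1, kind="stable")[:, : model.spec.k]
    out = []
    for row_neighbors in order:
        votes: dict = {}
        for idx in row_neighbors:
            lab = model.train_labels[idx]
            if lab not in votes:
                votes[lab] = [0, idx]  # count, earliest index
            votes[lab][0] += 1
        out.append(max(votes.items(), key=lambda kv: (kv[1][0], -kv[1][1]))[0])
    return np.asarray(out)


def decision_scores(model: TrainedDetector, rows, positive) -> np.ndarray:
    """Scalar scores for attribution: higher means more ``positive``-like.

    k-NN reports the positive-class fraction among the k neighbors; the SVM
    reports its signed decision value, sign-flipped if needed so that
    ``positive`` is the high-score class.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    xs = _transform(model, rows)
    if model.spec.kind == "knn":
        dist = cdist(xs, model.train_matrix)
        order = np.argsort(dist, axis=1, kind="stable")[:, : model.spec.k]
        return np.mean(model.train_labels[order] == positive, axis=1)
    raw = model.svc.decision_function(xs)
    if raw.ndim != 1:
        raise UsageError("decision scores require a binary SVM")
    # sklearn's decision_function is positive toward classes_[1]
    return raw if model.svc.classes_[1] == positive else -raw
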