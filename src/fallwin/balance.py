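"""SMOTE minority oversampling, applied only inside training folds.

Synthetic minority rows are linear interpolations between a minority row and
one of its k nearest minority neighbors: ``p + lambda * (q - p)`` with
``lambda ~ U[0, 1]``. Balancing raises every class to the majority count;
original rows are never altered, and synthetic rows are tagged with a
sentinel subject id so downstream fold audits can prove they never leak
into a test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from fallwin.errors import UsageError

SYNTHETIC_SUBJECT = "__synthetic__"
DEFAULT_K = 5


@dataclass(frozen=True)
class LabeledFeatures:
    """An events x features matrix with per-event labels and subject ids."""

    matrix: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        subjects = np.asarray(self.subject_ids)
        if mat.ndim != 2:
            raise UsageError(f"matrix must be 2-D, got shape {mat.shape}")
        if not (mat.shape[0] == len(labels) == len(subjects)):
            raise UsageError(
                f"row counts disagree: matrix {mat.shape[0]}, labels "
                f"{len(labels)}, subjects {len(subjects)}"
            )
        if self.feature_names and len(self.feature_names) != mat.shape[1]:
            raise UsageError("feature_names length must match feature count")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", subjects)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices) -> "LabeledFeatures":
        idx = np.asarray(indices)
        return LabeledFeatures(
            self.matrix[idx], self.labels[idx], self.subject_ids[idx],
            self.feature_names,
        )


def smote_sample(
    minority: np.ndarray, k: int, n_new: int, seed: int
) -> np.ndarray:
    """Draw ``n_new`` synthetic rows from a minority-class matrix.

    Each row is ``p + lambda * (q - p)`` where ``p`` is a uniformly chosen
    minority row, ``q`` one of its ``k`` nearest minority neighbors under
    Euclidean distance (never ``p`` itself), and ``lambda ~ U[0, 1]``.
    Deterministic under a fixed seed. If the nearest neighbor coincides
    with ``p`` the synthetic point equals the parent, which is allowed.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise UsageError(
            f"SMOTE needs >= 2 minority rows, got shape {minority.shape}"
        )
    max_k = minority.shape[0] - 1
    if k > max_k:
        warnings.warn(
            f"SMOTE k={k} exceeds available neighbors ({max_k}); clamped",
            stacklevel=2,
        )
        k = max_k
    if k < 1:
        raise UsageError("SMOTE needs k >= 1")
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    if n_new < 0:
        raise UsageError("n_new must be >= 0")

    rng = np.random.default_rng(seed)
    # k+1 because each row's nearest neighbor is itself
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, neigh = nn.kneighbors(minority)
    neigh = neigh[:, 1:]  # drop self-match

    parents = rng.integers(0, minority.shape[0], size=n_new)
    picks = rng.integers(0, k, size=n_new)
    lams = rng.uniform(0.0, 1.0, size=n_new)
    p = minority[parents]
    q = minority[neigh[parents, picks]]
    return p + lams[:, None] * (q - p)


def balance_training_set(
    data: LabeledFeatures, k: int = DEFAULT_K, seed: int = 0
) -> LabeledFeatures:
    """Oversample every minority class up to the majority count.

    Original rows are preserved first, in their original order; synthetic
    rows follow, labeled with their class and ``subject_id`` set to a
    sentinel marker. An already balanced input is returned unchanged.
    """
    classes, counts = np.unique(data.labels, return_counts=True)
    if len(classes) < 2:
        raise UsageError("balancing needs >= 2 classes in the training set")
    target = int(counts.max())
    if np.all(counts == target):
        return data

    new_rows, new_labels = [], []
    for cls_i, (cls, count) in enumerate(zip(classes, counts)):
        deficit = target - int(count)
        if deficit == 0:
            continue
        rows = data.matrix[data.labels == cls]
        synth = smote_sample(rows, k=k, n_new=deficit, seed=seed + cls_i)
        new_rows.append(synth)
        new_labels.extend([cls] * deficit)

    matrix = np.vstack([data.matrix] + new_rows)
    labels = np.concatenate([data.labels, np.asarray(new_labels)])
    subjects = np.concatenate(
        [data.subject_ids, np.full(len(new_labels), SYNTHETIC_SUBJECT, dtype=object)]
    )
    return LabeledFeatures(matrix, labels, subjects, data.feature_names)
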