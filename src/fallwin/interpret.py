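"""Model-agnostic Shapley feature attribution by permutation sampling.

The value of a feature coalition S is the model score with features in S
taken from the explained instance and the rest from a background row,
averaged over the background. Attributions are estimated by sampling
feature permutations: walking a random permutation and switching features
from a sampled background row to the instance's values, each feature is
credited the score increment it causes; averaging over permutations yields
the Shapley values of this game. The estimator is exact (up to the
background average) when all permutations and background rows are
enumerated, and otherwise reports a Monte-Carlo standard error per feature.

Attributions satisfy efficiency — they sum to the instance score minus the
mean background score — within Monte-Carlo error, and a feature the model
ignores receives exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from fallwin.errors import UsageError


@dataclass(frozen=True)
class AttributionResult:
    """Shapley attributions for one explained instance.

    ``phi`` is in model-output units (e.g., k-NN positive-class vote
    fraction or SVM decision value); ``base_value`` is the mean model score
    over the background; ``mc_error`` is the per-feature Monte-Carlo
    standard error (zeros under full enumeration); ``efficiency_se`` is the
    standard error of the attribution total, against which the efficiency
    identity |sum(phi) - (score - base_value)| is judged.
    """

    phi: np.ndarray
    base_value: float
    score: float
    instance: np.ndarray
    mc_error: np.ndarray
    efficiency_se: float
    n_permutations: int
    seed: int
    feature_names: tuple[str, ...] = ()

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.phi.sum() - (self.score - self.base_value)))

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or tuple(
            f"f{j}" for j in range(len(self.phi))
        )
        return pd.DataFrame({
            "feature": list(names),
            "value": self.instance,
            "phi": self.phi,
            "mc_error": self.mc_error,
        })


def shapley_attributions(
    model_fn,
    instance,
    background,
    n_perm: int = 200,
    seed: int = 0,
    feature_names: tuple[str, ...] = (),
    enumerate_all: bool = False,
) -> AttributionResult:
    """Estimate Shapley attributions of ``model_fn`` at ``instance``.

    ``model_fn`` maps a 2-D (rows x features) array to a 1-D score array
    and must be deterministic. ``background`` supplies the off-coalition
    feature values; each sampled permutation pairs with one uniformly drawn
    background row. With ``enumerate_all=True`` every permutation is paired
    with every background row (exact; only feasible for few features).
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = len(instance)
    if background.shape[0] < 1:
        raise UsageError("background must be non-empty")
    if background.shape[1] != d:
        raise UsageError(
            f"background has {background.shape[1]} features, instance has {d}"
        )
    if not enumerate_all and n_perm < 1:
        raise UsageError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    if enumerate_all:
        if d > 8:
            raise UsageError("full enumeration is limited to <= 8 features")
        perms = [np.asarray(p) for p in iter_permutations(range(d))]
        pairs = [(p, b) for p in perms for b in range(background.shape[0])]
    else:
        pairs = [
            (rng.permutation(d), int(rng.integers(background.shape[0])))
            for _ in range(n_perm)
        ]

    base_value = float(np.mean(model_fn(background)))
    score = float(model_fn(instance[None, :])[0])

    increments = np.empty((len(pairs), d))
    totals = np.empty(len(pairs))
    for i, (perm, b_idx) in enumerate(pairs):
        # rows[k] has the first k features (in perm order) set to the instance
        rows = np.tile(background[b_idx], (d + 1, 1))
        for k, j in enumerate(perm):
            rows[k + 1 :, j] = instance[j]
        scores = np.asarray(model_fn(rows), dtype=float)
        increments[i, perm] = np.diff(scores)
        totals[i] = scores[-1] - scores[0]

    n = len(pairs)
    phi = increments.mean(axis=0)
    if enumerate_all:
        mc_error = np.zeros(d)
        eff_se = 0.0
    else:
        mc_error = increments.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else \
            np.full(d, np.inf)
        eff_se = float(totals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.inf
    return AttributionResult(
        phi=phi,
        base_value=base_value,
        score=score,
        instance=instance,
        mc_error=mc_error,
        efficiency_se=eff_se,
        n_permutations=n,
        seed=seed,
        feature_names=tuple(feature_names),
    )


def global_importance(attributions) -> pd.DataFrame:
    """Rank features by mean absolute attribution over many instances.

    Ties break toward the canonical feature order (the order features
    appear in each AttributionResult).
    """
    attributions = list(attributions)
    if not attributions:
        raise UsageError("global_importance needs at least one attribution")
    d = len(attributions[0].phi)
    names = attributions[0].feature_names or tuple(f"f{j}" for j in range(d))
    for a in attributions:
        if len(a.phi) != d:
            raise UsageError("attributions have inconsistent feature counts")
    mean_abs = np.mean([np.abs(a.phi) for a in attributions], axis=0)
    df = pd.DataFrame({"feature": list(names), "mean_abs_phi": mean_abs})
    # stable sort keeps canonical order among ties
    return df.sort_values(
        "mean_abs_phi", ascending=False, kind="stable"
    ).reset_index(drop=True)


def dependence_table(
    attributions, feature: str, color_feature: str | None = None
) -> pd.DataFrame:
    """Tidy table of (feature value, phi, optional coloring feature value)
    across instances — the tabular form of a dependence plot."""
    rows = []
    for i, a in enumerate(attributions):
        names = list(a.feature_names)
        if feature not in names:
            raise UsageError(f"unknown feature {feature!r}")
        j = names.index(feature)
        row = {"instance": i, "value": a.instance[j], "phi": a.phi[j]}
        if color_feature is not None:
            row["color_value"] = a.instance[names.index(color_feature)]
        rows.append(row)
    return pd.DataFrame(rows)
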