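"""The sub-window statistical feature bank.

Eight quantities are computed per sub-window: mean, median, population
standard deviation, skewness, non-excess kurtosis, maximum, minimum (each
per axis) and a single 3-axis slope — the Euclidean norm of the per-axis
(max - min) ranges. With m sub-windows the assembled vector has 22*m
entries; the default two-sub-window 3 s scheme yields the 44-dimensional
vector the detectors consume.

Moment conventions are the literal population forms: sd = sqrt(m2),
skew = m3 / sd^3, kurt = m4 / sd^4 with m_k the k-th central 1/n moment.
A constant sub-window (sd = 0) reports skew = kurt = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fallwin.errors import UsageError
from fallwin.windowing import Window, WindowScheme, subwindow_bounds

AXES = ("x", "y", "z")
# feature-major order inside one sub-window: stat varies slowest, axis fastest
STAT_PREFIXES = ("m", "me", "sd", "sk", "k", "max", "min")


@dataclass(frozen=True)
class AxisStats:
    """The seven per-axis statistics of one sub-window."""

    mean: float
    median: float
    sd: float
    skew: float
    kurt: float
    max: float
    min: float


@dataclass(frozen=True)
class FeatureVector:
    """A named 22*m feature vector for one event window."""

    values: np.ndarray
    names: tuple[str, ...]
    scheme: WindowScheme

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != len(self.names):
            raise UsageError("values and names must have equal length")
        if len(vals) != self.scheme.n_features:
            raise UsageError(
                f"expected {self.scheme.n_features} features for m={self.scheme.m}, "
                f"got {len(vals)}"
            )
        object.__setattr__(self, "values", vals)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def axis_stats(samples) -> AxisStats:
    """Compute the seven statistics of one axis of one sub-window.

    Requires at least two finite samples. Population (1/n) moments are used
    throughout, kurtosis is non-excess (a normal sample gives ~3), and a
    degenerate constant input reports skew = kurt = 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise UsageError(f"axis_stats needs >= 2 samples in one axis, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise UsageError("axis_stats input contains non-finite values")
    mu = float(np.mean(x))
    dev = x - mu
    var = float(np.mean(dev**2))
    sd = float(np.sqrt(var))
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(dev**3)) / sd**3
        kurt = float(np.mean(dev**4)) / sd**4
    return AxisStats(
        mean=mu,
        median=float(np.median(x)),
        sd=sd,
        skew=skew,
        kurt=kurt,
        max=float(np.max(x)),
        min=float(np.min(x)),
    )


def slope(subwindow) -> float:
    """3-axis slope: sqrt(sum over axes of (max - min)^2), in g."""
    arr = np.asarray(subwindow, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
        raise UsageError(f"slope needs a non-empty (n, 3) sub-window, got {arr.shape}")
    ranges = arr.max(axis=0) - arr.min(axis=0)
    return float(np.sqrt(np.sum(ranges**2)))


def feature_names(scheme: WindowScheme) -> tuple[str, ...]:
    """Canonical feature names in canonical order.

    Per sub-window s (1-based): means ``m_{axis}{s}``, medians ``me_``,
    standard deviations ``sd_``, skews ``sk_``, kurtoses ``k_``, maxima
    ``max_``, minima ``min_`` (axis order x, y, z), then ``SLOP{s}``.
    Sub-windows are concatenated in time order.
    """
    names: list[str] = []
    for s in range(1, scheme.m + 1):
        for prefix in STAT_PREFIXES:
            names.extend(f"{prefix}_{axis}{s}" for axis in AXES)
        names.append(f"SLOP{s}")
    return tuple(names)


def extract_features(window: Window, scheme: WindowScheme) -> FeatureVector:
    """Assemble the 22*m feature vector of one event window.

    Sub-windows are sliced per ``subwindow_bounds`` at the trace rate; each
    contributes 7 statistics x 3 axes plus one slope, in the canonical name
    order of :func:`feature_names`.
    """
    rate = window.source.rate
    expected = round(scheme.n_s * rate)
    if window.length_samples != expected:
        raise UsageError(
            f"window of {window.length_samples} samples does not match scheme "
            f"({scheme.n_s} s at {rate} Hz = {expected} samples)"
        )
    data = window.samples
    values: list[float] = []
    for start, end in subwindow_bounds(scheme, rate):
        sub = data[start:end]
        stats = [axis_stats(sub[:, j]) for j in range(3)]
        for prefix in STAT_PREFIXES:
            attr = {"m": "mean", "me": "median", "sd": "sd", "sk": "skew",
                    "k": "kurt", "max": "max", "min": "min"}[prefix]
            values.extend(getattr(st, attr) for st in stats)
        values.append(slope(sub))
    return FeatureVector(
        values=np.asarray(values), names=feature_names(scheme), scheme=scheme
    )


def feature_table(
    windows_with_meta, scheme: WindowScheme
) -> pd.DataFrame:
    """Build a feature table: one row per event, named columns, trailing
    ``label`` and ``subject_id`` columns.

    ``windows_with_meta`` yields (Window, label, subject_id) triples.
    """
    names = feature_names(scheme)
    rows, labels, subjects = [], [], []
    for window, label, subject in windows_with_meta:
        rows.append(extract_features(window, scheme).values)
        labels.append(label)
        subjects.append(subject)
    df = pd.DataFrame(np.asarray(rows), columns=list(names))
    df["label"] = labels
    df["subject_id"] = subjects
    return df
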