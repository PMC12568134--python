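"""Tri-axial accelerometer traces: data model, CSV I/O, resampling, clipping.

A trace is a uniformly sampled 3-axis acceleration signal in g. Sample ``i``
lives at time ``i / rate`` seconds, with ``t = 0`` at the first sample.
Annotations (ground-truth fall intervals) are kept in seconds so they survive
resampling unchanged. Units are g throughout; callers with m/s^2 data must
divide by 9.81 before constructing a trace.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from fallwin.errors import DataError, UsageError

POSITIONS = ("pocket", "lower_back", "thigh", "unknown")

Dialect = Literal["time_xyz", "xyz"]


@dataclass(frozen=True)
class FallAnnotation:
    """A ground-truth fall interval, in seconds from trace start."""

    start_s: float
    end_s: float
    label: str = "fall"

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise UsageError(
                f"annotation requires 0 <= start < end, got "
                f"[{self.start_s}, {self.end_s}]"
            )


@dataclass(frozen=True)
class TriaxialTrace:
    """A uniformly sampled 3-axis acceleration signal in g.

    Parameters
    ----------
    samples
        Array of shape (n, 3): columns are the x, y, z axes, values in g.
    rate
        Sampling rate in Hz (> 0).
    range_g
        Symmetric sensor range in g (samples must lie in [-range_g, range_g]).
    subject_id
        Opaque subject identifier.
    position
        Sensor placement, one of ``pocket``, ``lower_back``, ``thigh``,
        ``unknown``.
    annotations
        Ground-truth fall intervals, each within [0, duration].
    """

    samples: np.ndarray
    rate: float
    range_g: float = 2.0
    subject_id: str = "unknown"
    position: str = "unknown"
    annotations: tuple[FallAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise UsageError(f"samples must have shape (n>=1, 3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DataError("samples contain non-finite values")
        if self.rate <= 0:
            raise UsageError(f"rate must be > 0, got {self.rate}")
        if self.range_g <= 0:
            raise UsageError(f"range_g must be > 0, got {self.range_g}")
        if np.any(np.abs(arr) > self.range_g + 1e-12):
            raise DataError(
                f"samples exceed sensor range +-{self.range_g} g "
                f"(max |a| = {np.max(np.abs(arr)):.4g})"
            )
        if self.position not in POSITIONS:
            raise UsageError(f"position must be one of {POSITIONS}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "annotations", tuple(self.annotations))
        for ann in self.annotations:
            if ann.end_s > self.duration_s + 1e-9:
                raise UsageError(
                    f"annotation [{ann.start_s}, {ann.end_s}] exceeds trace "
                    f"duration {self.duration_s:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Duration from first to one period past the last sample."""
        return self.n_samples / self.rate

    def __len__(self) -> int:
        return self.n_samples


def read_trace(
    path: str | Path,
    rate_hint: float | None = None,
    dialect: Dialect = "time_xyz",
) -> TriaxialTrace:
    """Read a trace from CSV, with an optional ``<name>.meta.json`` sidecar.

    Dialect ``time_xyz`` expects a header ``t,x,y,z`` with a uniform,
    monotone time column (seconds); the rate is inferred from the spacing
    and the time column is discarded. Dialect ``xyz`` expects ``x,y,z``
    and requires ``rate_hint`` (or a sidecar carrying the rate).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    meta = _read_sidecar(path)

    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        expected = ["t", "x", "y", "z"] if dialect == "time_xyz" else ["x", "y", "z"]
        if [h.strip() for h in header] != expected:
            raise DataError(
                f"{path}: expected header {','.join(expected)!r}, got "
                f"{','.join(header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(expected):
                raise DataError(f"{path}: line {lineno}: expected "
                                f"{len(expected)} fields, got {len(cells)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise DataError(f"{path}: line {lineno}: non-numeric cell") from None
    if not rows:
        raise DataError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)

    if dialect == "time_xyz":
        t = data[:, 0]
        xyz = data[:, 1:]
        if len(t) < 2:
            if rate_hint is None and "rate" not in meta:
                raise UsageError("single-row time_xyz trace needs rate_hint")
            rate = rate_hint or meta["rate"]
        else:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise DataError(f"{path}: time column is not strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-6 * max(abs(dt[0]), 1e-12):
                raise DataError(f"{path}: time grid is not uniform")
            rate = 1.0 / float(dt[0])
    else:
        xyz = data
        rate = rate_hint if rate_hint is not None else meta.get("rate")
        if rate is None:
            raise UsageError("dialect 'xyz' requires rate_hint or a sidecar rate")

    annotations = tuple(
        FallAnnotation(a["start_s"], a["end_s"], a.get("label", "fall"))
        for a in meta.get("annotations", [])
    )
    return TriaxialTrace(
        samples=xyz,
        rate=float(meta.get("rate", rate)),
        range_g=float(meta.get("range_g", max(2.0, float(np.max(np.abs(xyz)))))),
        subject_id=str(meta.get("subject_id", "unknown")),
        position=str(meta.get("position", "unknown")),
        annotations=annotations,
    )


def write_trace(trace: TriaxialTrace, path: str | Path) -> None:
    """Write a trace as an ``x,y,z`` CSV plus a ``.meta.json`` sidecar.

    ``read_trace(write_trace(t))`` reproduces the samples to 1e-9 (full
    float precision is written) and the rate exactly (via the sidecar).
    """
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("x,y,z\n")
            for x, y, z in trace.samples:
                fh.write(f"{x:.17g},{y:.17g},{z:.17g}\n")
        meta = {
            "rate": trace.rate,
            "range_g": trace.range_g,
            "subject_id": trace.subject_id,
            "position": trace.position,
            "annotations": [
                {"start_s": a.start_s, "end_s": a.end_s, "label": a.label}
                for a in trace.annotations
            ],
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(meta, fh, indent=1)
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


def resample_trace(
    trace: TriaxialTrace,
    target_rate: float,
    method: Literal["decimate", "linear"] = "linear",
) -> TriaxialTrace:
    """Convert a trace to ``target_rate`` Hz.

    ``decimate`` keeps every (source/target)-th sample starting at index 0
    and requires an integer ratio (plain sample dropping, no anti-alias
    filter). ``linear`` evaluates per-axis piecewise-linear interpolants on
    the uniform target grid starting at t=0, within the source time span.
    Annotations are carried over unchanged (they are in seconds).
    """
    if target_rate <= 0:
        raise UsageError("target_rate must be > 0")
    if method == "decimate":
        ratio = trace.rate / target_rate
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise UsageError(
                f"decimation needs source rate an integer multiple of target "
                f"({trace.rate}/{target_rate} = {ratio:.4g}); use method='linear'"
            )
        step = int(round(ratio))
        new = trace.samples[::step]
    elif method == "linear":
        span = (trace.n_samples - 1) / trace.rate
        n_new = math.floor(span * target_rate) + 1
        t_new = np.arange(n_new) / target_rate
        if n_new < 1 or t_new[-1] > span + 1e-12:
            raise UsageError("target grid exceeds the source time span")
        t_old = np.arange(trace.n_samples) / trace.rate
        new = np.column_stack(
            [np.interp(t_new, t_old, trace.samples[:, j]) for j in range(3)]
        )
    else:
        raise UsageError(f"unknown resampling method {method!r}")
    return replace(trace, samples=new, rate=float(target_rate))


def clip_range(trace: TriaxialTrace, limit_g: float) -> TriaxialTrace:
    """Clamp every sample to [-limit_g, limit_g] and set range_g accordingly.

    Emulates sensor saturation (e.g., a +-2 g smartphone accelerometer).
    Idempotent; clipping at nested limits is order-insensitive.
    """
    if limit_g <= 0:
        raise UsageError("limit_g must be > 0")
    clipped = np.clip(trace.samples, -limit_g, limit_g)
    return replace(trace, samples=clipped, range_g=float(limit_g))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json") if path.suffix else Path(str(path) + ".meta.json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}
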