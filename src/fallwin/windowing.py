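"""Window/sub-window segmentation and sliding windows over long recordings.

The segmentation family is parameterized by (n, m, o): a window of ``n``
seconds split into ``m`` sub-windows whose pairwise overlap fraction is
``o``. The default (3, 2, 0.5) splits a 3 s event into two 2 s sub-windows
overlapping by 1 s — the first captures the onset of a fall, the second its
impact. Sample intervals are half-open and 0-based everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from fallwin.errors import UsageError
from fallwin.signal_core import TriaxialTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowScheme:
    """The (n, m, o) window/sub-window segmentation hypothesis.

    ``n_s``: window length in seconds; ``m``: sub-window count;
    ``o``: sub-window overlap fraction in [0, 1). Sub-window length is
    ``L = n / (m - (m-1)*o)`` seconds; for m=1 it equals n regardless of o.
    """

    n_s: float = 3.0
    m: int = 2
    o: float = 0.5

    def __post_init__(self) -> None:
        if self.n_s <= 0:
            raise UsageError(f"window length must be > 0 s, got {self.n_s}")
        if self.m < 1:
            raise UsageError(f"sub-window count must be >= 1, got {self.m}")
        if not (0.0 <= self.o < 1.0):
            raise UsageError(f"overlap must be in [0, 1), got {self.o}")

    @property
    def subwindow_s(self) -> float:
        if self.m == 1:
            return self.n_s
        return self.n_s / (self.m - (self.m - 1) * self.o)

    @property
    def n_features(self) -> int:
        """Feature vector length: 22 per sub-window (7 stats x 3 axes + slope)."""
        return 22 * self.m


@dataclass(frozen=True)
class Window:
    """A half-open sample interval [start, start+length) into a trace."""

    source: TriaxialTrace
    start_sample: int
    length_samples: int

    def __post_init__(self) -> None:
        if self.start_sample < 0 or self.length_samples < 1:
            raise UsageError("window needs start >= 0 and length >= 1")
        if self.start_sample + self.length_samples > len(self.source):
            raise UsageError(
                f"window [{self.start_sample}, "
                f"{self.start_sample + self.length_samples}) exceeds trace "
                f"length {len(self.source)}"
            )

    @property
    def samples(self):
        return self.source.samples[
            self.start_sample : self.start_sample + self.length_samples
        ]

    @property
    def end_time_s(self) -> float:
        """Time at which the last sample of the window is available."""
        return (self.start_sample + self.length_samples) / self.source.rate


@dataclass(frozen=True)
class StreamConfig:
    """Sliding-window configuration for streaming over continuous recordings.

    For window length W and hop H = W*(1 - overlap), the decision for window
    index t is available only at time t*H + W (no look-ahead); alarms are
    stamped at window ends.
    """

    window_s: float = 3.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise UsageError("window_s must be > 0")
        if not (0.0 <= self.overlap < 1.0):
            raise UsageError(f"overlap must be in [0, 1), got {self.overlap}")

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    def hop_samples(self, rate: float) -> int:
        hop = round(self.hop_s * rate)
        if hop < 1:
            raise UsageError(f"hop rounds to 0 samples at {rate} Hz")
        return hop

    def window_samples(self, rate: float) -> int:
        return round(self.window_s * rate)


def subwindow_bounds(scheme: WindowScheme, rate: float) -> list[tuple[int, int]]:
    """Sub-window sample bounds for a window of ``scheme`` at ``rate`` Hz.

    Returns ``m`` half-open (start, end) pairs. Sub-window length and hop are
    rounded to whole samples; the last sub-window is anchored to end exactly
    at ``n_s * rate`` so rounding error accumulates nowhere. For the default
    (3, 2, 0.5) scheme at 50 Hz this yields [(0, 100), (50, 150)].
    """
    n_samp = round(scheme.n_s * rate)
    if scheme.m == 1:
        return [(0, n_samp)]
    sub = round(scheme.subwindow_s * rate)
    hop = round((1.0 - scheme.o) * sub)
    if sub < 1 or hop < 1:
        raise UsageError(
            f"scheme {scheme} at {rate} Hz: sub-window ({sub}) or hop ({hop}) "
            f"rounds to < 1 sample"
        )
    bounds = [(i * hop, i * hop + sub) for i in range(scheme.m - 1)]
    bounds.append((n_samp - sub, n_samp))
    return bounds


def segment_event(trace: TriaxialTrace, scheme: WindowScheme) -> Window:
    """Anchor one event window of ``scheme.n_s`` seconds at sample 0.

    Single-event datasets carry one action per trace; the window covers the
    first ``n_s * rate`` samples. A trace longer by exactly one sample is
    truncated (tolerating the off-by-one sample count some archives use);
    anything else mismatched is an error.
    """
    needed = round(scheme.n_s * trace.rate)
    n = len(trace)
    if n < needed:
        raise UsageError(
            f"trace too short: need {needed} samples "
            f"({scheme.n_s} s at {trace.rate} Hz), got {n}"
        )
    if n > needed + 1:
        raise UsageError(
            f"trace has {n} samples but the event window needs {needed}; "
            f"only a single trailing extra sample is truncated"
        )
    return Window(source=trace, start_sample=0, length_samples=needed)


def slide_windows(trace: TriaxialTrace, cfg: StreamConfig) -> list[Window]:
    """All full windows of ``cfg`` over ``trace``, in time order.

    Window count is ``floor((N - W) / H) + 1`` for N trace samples, window
    W and hop H in samples. A trailing partial window is dropped, never
    padded. A trace shorter than one window yields an empty list.
    """
    w = cfg.window_samples(trace.rate)
    h = cfg.hop_samples(trace.rate)
    n = len(trace)
    if n < w:
        logger.info("trace of %d samples shorter than window (%d): no windows", n, w)
        return []
    count = (n - w) // h + 1
    return [Window(trace, i * h, w) for i in range(count)]
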