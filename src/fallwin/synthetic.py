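"""Synthetic tri-axial fall / ADL accelerometer signals.

Every generated signal is gravity-inclusive (a constant 1 g vector on a
random orientation), expressed in g, sampled at a configurable rate within
a symmetric sensor range. A fall follows the two-phase morphology observed
in real fall traces: a quiet baseline, a pre-impact oscillation of roughly
half a g while balance is lost, a brief free-fall dip in which the resultant
magnitude approaches zero, a sharp impact burst of one g and above, and
post-impact rest at a new orientation. ADL subtypes cover walking (~2 Hz
periodicity), sitting down (a single moderate spike — the designed hard
negative), jumping (repeated spikes), lying still, and slow posture
transitions.

Per-subject effects (multiplicative amplitude jitter plus a small additive
offset) give leave-one-subject-out evaluation a genuine domain gap.
All generators are bit-identical under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from fallwin.errors import UsageError
from fallwin.evaluate import ADL, FALL
from fallwin.signal_core import FallAnnotation, TriaxialTrace
from fallwin.windowing import WindowScheme

ADL_SUBTYPES = ("walk", "sit_down", "jump", "lie_still", "transition")

DEFAULT_ADL_MIX = {
    "walk": 0.35, "sit_down": 0.20, "jump": 0.15,
    "lie_still": 0.20, "transition": 0.10,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions.

    Amplitudes are in g: pre-impact oscillation ~0.5 g, impact burst 1.5 g
    (one g and above, saturating toward the 2 g sensor range), sit-down
    hard-negative spike 0.8 g. Fall duration is uniform on [1, 3] s so the
    whole event fits a 3 s window. ``subject_effect_sd`` controls both the
    multiplicative amplitude jitter (1 + N(0, sd)) and the additive
    per-subject offset (N(0, sd/10) g per axis, on the order of a real
    accelerometer's bias).
    """

    rate: float = 50.0
    range_g: float = 2.0
    n_subjects: int = 10
    falls_per_subject: int = 20
    adls_per_subject: int = 80
    adl_mix: dict = field(default_factory=lambda: dict(DEFAULT_ADL_MIX))
    pre_osc_amp_g: float = 0.5
    impact_amp_g: float = 1.5
    sit_spike_amp_g: float = 0.8
    fall_duration_s: tuple[float, float] = (1.0, 3.0)
    subject_effect_sd: float = 0.1
    noise_sd_g: float = 0.03
    seed: int = 0
    window_s: float = 3.0

    def __post_init__(self) -> None:
        if min(self.pre_osc_amp_g, self.impact_amp_g, self.sit_spike_amp_g) <= 0:
            raise UsageError("amplitudes must be > 0")
        lo, hi = self.fall_duration_s
        if not (0 < lo <= hi <= self.window_s):
            raise UsageError("fall duration range must fit inside the window")
        total = sum(self.adl_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise UsageError(f"adl_mix weights must sum to 1, got {total}")
        unknown = set(self.adl_mix) - set(ADL_SUBTYPES)
        if unknown:
            raise UsageError(f"unknown ADL subtypes: {sorted(unknown)}")


@dataclass(frozen=True)
class GeneratedDataset:
    """Events and/or recordings plus the provenance that regenerates them."""

    events: tuple[tuple[TriaxialTrace, str, str], ...]  # (trace, label, subject)
    recordings: tuple[TriaxialTrace, ...]
    config: SyntheticConfig
    seed: int

    def to_labeled_features(self, scheme: WindowScheme | None = None,
                            binary: bool = True):
        """Extract a LabeledFeatures table from the single-event traces.

        With ``binary=True`` every ADL subtype collapses to the ADL class.
        """
        from fallwin.balance import LabeledFeatures
        from fallwin.features import extract_features, feature_names
        from fallwin.windowing import segment_event

        scheme = scheme or WindowScheme()
        rows, labels, subjects = [], [], []
        for trace, label, subject in self.events:
            window = segment_event(trace, scheme)
            rows.append(extract_features(window, scheme).values)
            labels.append(FALL if label == FALL else (ADL if binary else label))
            subjects.append(subject)
        return LabeledFeatures(
            np.asarray(rows), np.asarray(labels), np.asarray(subjects, dtype=object),
            feature_names(scheme),
        )


# ---------------------------------------------------------------------------
# seeding helpers

def _subject_int(subject: str) -> int:
    return zlib.crc32(subject.encode()) & 0x7FFFFFFF


def _event_rng(seed: int, subject: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _subject_int(subject), salt])


def _subject_effects(cfg: SyntheticConfig, subject: str):
    """Per-subject amplitude scale and axis offset, fixed by cfg.seed."""
    rng = np.random.default_rng([cfg.seed, _subject_int(subject), 777])
    scale = max(0.3, 1.0 + cfg.subject_effect_sd * rng.standard_normal())
    offset = (cfg.subject_effect_sd / 10.0) * rng.standard_normal(3)
    return scale, offset


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _finish(cfg: SyntheticConfig, subject: str, signal: np.ndarray,
            rng: np.random.Generator,
            annotations: tuple[FallAnnotation, ...] = ()) -> TriaxialTrace:
    """Apply subject effects, sensor noise and range clipping."""
    scale, offset = _subject_effects(cfg, subject)
    out = scale * signal + offset
    out = out + cfg.noise_sd_g * rng.standard_normal(signal.shape)
    out = np.clip(out, -cfg.range_g, cfg.range_g)
    return TriaxialTrace(
        samples=out, rate=cfg.rate, range_g=cfg.range_g,
        subject_id=subject, position="pocket", annotations=annotations,
    )


# ---------------------------------------------------------------------------
# clean signal builders (no noise, no subject effects)

def _fall_signal(cfg: SyntheticConfig, rng: np.random.Generator,
                 u_start: np.ndarray | None = None):
    """Clean fall window signal.

    Returns (signal, fall_start_s, fall_end_s, end_orientation); passing
    ``u_start`` keeps gravity continuous when stitching long recordings.
    """
    n = round(cfg.window_s * cfg.rate)
    t = np.arange(n) / cfg.rate
    u_stand = _unit_vector(rng) if u_start is None else u_start
    u_lying = _unit_vector(rng)
    sig = np.outer(np.ones(n), u_stand)  # 1 g gravity baseline

    t_imp = rng.uniform(1.9, 2.5)
    d_hi = min(cfg.fall_duration_s[1], t_imp - 0.05)
    d = rng.uniform(min(cfg.fall_duration_s[0], d_hi), d_hi)
    fall_start = t_imp - d
    t_ff = 0.08  # free-fall dip just before impact
    imp_len = 0.45

    # phase 1: balance-loss oscillation whose amplitude grows toward impact
    osc_dir = _unit_vector(rng)
    f_osc = rng.uniform(3.0, 6.0)
    phase = rng.uniform(0, 2 * np.pi)
    # the instability transient is brief (<~1.2 s) however long the fall
    osc_start = max(fall_start, t_imp - t_ff - 1.2)
    osc_mask = (t >= osc_start) & (t < t_imp - t_ff)
    amp = cfg.pre_osc_amp_g * rng.uniform(0.8, 1.2)
    env = ((t[osc_mask] - osc_start) / max(t_imp - t_ff - osc_start, 1e-6)) ** 2
    sig[osc_mask] += (amp * env * np.sin(2 * np.pi * f_osc * t[osc_mask] + phase)
                      )[:, None] * osc_dir

    # free-fall dip: resultant magnitude ramps toward ~0 g
    ff_mask = (t >= t_imp - t_ff) & (t < t_imp)
    ramp = 1.0 - 0.95 * (t[ff_mask] - (t_imp - t_ff)) / t_ff
    sig[ff_mask] = ramp[:, None] * u_stand

    # impact: damped high-frequency burst of one g and above
    imp_dir = _unit_vector(rng)
    imp_amp = cfg.impact_amp_g * rng.uniform(1.15, 1.4)
    imp_mask = (t >= t_imp) & (t < t_imp + imp_len)
    ti = t[imp_mask] - t_imp
    burst = imp_amp * np.exp(-ti / 0.15) * np.cos(2 * np.pi * 9.0 * ti)
    sig[imp_mask] = u_lying + burst[:, None] * imp_dir

    # post-impact: body settles at the lying orientation with a bounce
    rest_mask = t >= t_imp + imp_len
    sig[rest_mask] = u_lying
    t_bounce = t_imp + imp_len
    bounce_mask = (t >= t_bounce) & (t < t_bounce + 0.3)
    tb = t[bounce_mask] - t_bounce
    bounce = 0.6 * imp_amp * np.exp(-tb / 0.12) * np.cos(2 * np.pi * 7.0 * tb)
    sig[bounce_mask] += bounce[:, None] * _unit_vector(rng)
    # the annotated event runs through impact and the settling bounce
    return sig, fall_start, min(t_bounce + 0.3, cfg.window_s), u_lying


def _spike(t: np.ndarray, t0: float, amp: float, direction: np.ndarray,
           decay: float = 0.08, freq: float = 7.0) -> np.ndarray:
    mask = t >= t0
    out = np.zeros((len(t), 3))
    ti = t[mask] - t0
    out[mask] = (amp * np.exp(-ti / decay) * np.cos(2 * np.pi * freq * ti)
                 )[:, None] * direction
    return out


def _adl_signal(cfg: SyntheticConfig, subtype: str, rng: np.random.Generator,
                u_start: np.ndarray | None = None):
    """Clean ADL window signal; returns (signal, end_orientation).

    Oscillatory components taper to zero at the window edges so that
    consecutive stitched segments stay continuous.
    """
    n = round(cfg.window_s * cfg.rate)
    t = np.arange(n) / cfg.rate
    u = _unit_vector(rng) if u_start is None else u_start
    sig = np.outer(np.ones(n), u)
    u_end = u
    taper = np.minimum.reduce([t / 0.2, np.ones(n), (cfg.window_s - t) / 0.2])

    if subtype == "lie_still":
        pass
    elif subtype == "walk":
        f = rng.uniform(1.8, 2.2)
        amp = rng.uniform(0.25, 0.40)
        step_dir = _unit_vector(rng)
        phase = rng.uniform(0, 2 * np.pi)
        wave = amp * np.sin(2 * np.pi * f * t + phase)
        wave += 0.25 * amp * np.sin(2 * np.pi * 2 * f * t + phase)
        sig += (wave * taper)[:, None] * step_dir
    elif subtype == "sit_down":
        t0 = rng.uniform(0.8, 2.2)
        amp = cfg.sit_spike_amp_g * rng.uniform(0.6, 1.0)
        sig += _spike(t, t0, amp, _unit_vector(rng))
        settle = np.clip((t - t0) / 0.4, 0, 1)
        u2 = _unit_vector(rng)
        sig += 0.15 * settle[:, None] * (u2 - u)
        u_end = sig[-1] / np.linalg.norm(sig[-1])
    elif subtype == "jump":
        n_spikes = rng.integers(2, 5)
        times = np.sort(rng.uniform(0.2, 2.55, size=n_spikes))
        for t0 in times:
            amp = rng.uniform(0.5, 0.9)
            sig += _spike(t, float(t0), amp, _unit_vector(rng), decay=0.06)
    elif subtype == "transition":
        u2 = _unit_vector(rng)
        frac = 0.5 * (1 - np.cos(np.pi * t / cfg.window_s))  # smooth 0 -> 1
        sig = (1 - frac)[:, None] * np.outer(np.ones(n), u) + frac[:, None] * u2
        u_end = u2
    else:
        raise UsageError(f"unknown ADL subtype {subtype!r}")
    return sig, u_end


# ---------------------------------------------------------------------------
# public generators

def gen_fall_window(cfg: SyntheticConfig, subject: str, seed: int) -> TriaxialTrace:
    """One 3 s fall window for ``subject``; label FALL."""
    rng = _event_rng(seed, subject, salt=1)
    sig, start, end, _ = _fall_signal(cfg, rng)
    return _finish(cfg, subject, sig, rng,
                   annotations=(FallAnnotation(start, end, "fall"),))


def gen_adl_window(cfg: SyntheticConfig, subtype: str, subject: str,
                   seed: int) -> TriaxialTrace:
    """One 3 s ADL window of the given subtype for ``subject``."""
    if subtype not in ADL_SUBTYPES:
        raise UsageError(
            f"unknown ADL subtype {subtype!r}; choose from {ADL_SUBTYPES}"
        )
    rng = _event_rng(seed, subject, salt=2)
    sig, _ = _adl_signal(cfg, subtype, rng)
    return _finish(cfg, subject, sig, rng)


def subject_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"S{i:02d}" for i in range(1, cfg.n_subjects + 1)]


def gen_event_dataset(cfg: SyntheticConfig) -> GeneratedDataset:
    """A single-event dataset: per-subject fall/ADL counts as configured.

    Class imbalance is achieved purely by the configured counts. The
    dataset regenerates bit-identically from (cfg, cfg.seed).
    """
    events: list[tuple[TriaxialTrace, str, str]] = []
    subtypes = list(cfg.adl_mix.keys())
    weights = np.asarray([cfg.adl_mix[s] for s in subtypes], dtype=float)
    for subject in subject_ids(cfg):
        mix_rng = _event_rng(cfg.seed, subject, salt=3)
        for j in range(cfg.falls_per_subject):
            seed = int(mix_rng.integers(0, 2**31 - 1))
            events.append((gen_fall_window(cfg, subject, seed), FALL, subject))
        for j in range(cfg.adls_per_subject):
            seed = int(mix_rng.integers(0, 2**31 - 1))
            subtype = subtypes[int(mix_rng.choice(len(subtypes), p=weights))]
            events.append(
                (gen_adl_window(cfg, subtype, subject, seed), subtype, subject)
            )
    return GeneratedDataset(
        events=tuple(events), recordings=(), config=cfg, seed=cfg.seed
    )


def gen_continuous_recording(
    cfg: SyntheticConfig,
    duration_s: float,
    n_falls: int,
    seed: int,
    subject: str = "S01",
) -> TriaxialTrace:
    """A long annotated recording: ADL background with falls inserted.

    The recording is stitched from 3 s ADL-subtype blocks drawn per
    ``cfg.adl_mix``; ``n_falls`` blocks are replaced by fall signals at
    random non-overlapping positions, each annotated with the true fall
    interval [start, end] in seconds from recording start.
    """
    block = cfg.window_s
    n_blocks = int(duration_s // block)
    if n_falls > n_blocks:
        raise UsageError(
            f"cannot pack {n_falls} falls into {n_blocks} blocks of {block} s"
        )
    rng = _event_rng(seed, subject, salt=4)
    fall_blocks = set(
        int(b) for b in rng.choice(n_blocks, size=n_falls, replace=False)
    )
    subtypes = list(cfg.adl_mix.keys())
    weights = np.asarray([cfg.adl_mix[s] for s in subtypes], dtype=float)

    pieces: list[np.ndarray] = []
    annotations: list[FallAnnotation] = []
    u = _unit_vector(rng)  # gravity orientation threads through all blocks
    for b in range(n_blocks):
        if b in fall_blocks:
            sig, start, end, u = _fall_signal(cfg, rng, u_start=u)
            annotations.append(
                FallAnnotation(b * block + start, b * block + end, "fall")
            )
        else:
            subtype = subtypes[int(rng.choice(len(subtypes), p=weights))]
            sig, u = _adl_signal(cfg, subtype, rng, u_start=u)
        pieces.append(sig)
    remainder = round((duration_s - n_blocks * block) * cfg.rate)
    if remainder > 0:
        pieces.append(np.outer(np.ones(remainder), u))
    signal = np.vstack(pieces)
    return _finish(cfg, subject, signal, rng, annotations=tuple(annotations))
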