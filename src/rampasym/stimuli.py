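"""Intensity-modulated stimulus battery and envelope rendering.

The stimulus set used throughout the package consists, per sound quality
(broadband white noise or an 8 kHz harmonic complex), of 23 intensity
modulations: seven 250 ms constant sounds (50, 55, 60, 65, 70, 80 and
85 dB SPL) and up/down intensity ramps spanning 50-85 and 60-85 dB SPL at
four durations (0.1, 0.25, 1 and 2 s).  Envelopes are rendered as dB-SPL
time series on the imaging frame grid; ramps are linear in dB.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Quality",
    "RampKind",
    "StimulusSpec",
    "StimulusEnvelope",
    "CONSTANT_LEVELS",
    "RAMP_DURATIONS",
    "RAMP_RANGES",
    "build_stimulus_set",
    "render_envelope",
    "render_battery",
    "time_reverse",
    "battery_to_tsv",
    "battery_from_tsv",
]

#: Levels (dB SPL) of the seven 250 ms constant sounds.
CONSTANT_LEVELS = (50.0, 55.0, 60.0, 65.0, 70.0, 80.0, 85.0)
#: Ramp durations in seconds.
RAMP_DURATIONS = (0.1, 0.25, 1.0, 2.0)
#: (low, high) dB SPL spans of the ramps.
RAMP_RANGES = ((50.0, 85.0), (60.0, 85.0))
#: Duration of the constant sounds, seconds.
CONSTANT_DURATION = 0.25


class Quality(str, enum.Enum):
    """Spectral content of the sound carrier."""

    WHITE_NOISE = "white_noise"
    HARMONIC_8K = "harmonic_8k"


class RampKind(str, enum.Enum):
    CONSTANT = "constant"
    UP_RAMP = "up_ramp"
    DOWN_RAMP = "down_ramp"


class InvalidSpecError(ValueError):
    """Raised for stimulus specifications violating their invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """One intensity modulation: constant sound or linear-in-dB ramp.

    Parameters
    ----------
    quality : Quality
        Carrier spectral content.
    kind : RampKind
        Constant, up-ramp (intensity increases) or down-ramp.
    level_start, level_end : float
        dB SPL at stimulus onset / offset.
    duration : float
        Stimulus duration, seconds.
    """

    quality: Quality
    kind: RampKind
    level_start: float
    level_end: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidSpecError(f"duration must be positive, got {self.duration}")
        if self.kind == RampKind.CONSTANT and self.level_start != self.level_end:
            raise InvalidSpecError("constant stimulus requires level_start == level_end")
        if self.kind == RampKind.UP_RAMP and not self.level_end > self.level_start:
            raise InvalidSpecError("up_ramp requires level_end > level_start")
        if self.kind == RampKind.DOWN_RAMP and not self.level_end < self.level_start:
            raise InvalidSpecError("down_ramp requires level_end < level_start")

    @property
    def label(self) -> str:
        if self.kind == RampKind.CONSTANT:
            return f"{self.quality.value}:const_{self.level_start:g}dB_{self.duration:g}s"
        arrow = "up" if self.kind == RampKind.UP_RAMP else "down"
        lo, hi = sorted((self.level_start, self.level_end))
        return f"{self.quality.value}:{arrow}_{lo:g}-{hi:g}dB_{self.duration:g}s"

    def reversed(self) -> "StimulusSpec":
        """The time-reversed specification (up-ramp <-> down-ramp)."""
        if self.kind == RampKind.CONSTANT:
            return self
        kind = RampKind.DOWN_RAMP if self.kind == RampKind.UP_RAMP else RampKind.UP_RAMP
        return replace(self, kind=kind, level_start=self.level_end, level_end=self.level_start)


@dataclass
class StimulusEnvelope:
    """A dB-SPL envelope rendered on a regular frame grid.

    ``values[onset_index:offset_index]`` holds the stimulus; frames outside
    that window sit at ``silence_floor``.
    """

    values: np.ndarray
    rate: float
    onset_index: int
    offset_index: int
    silence_floor: float
    spec: StimulusSpec | None = None

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


def build_stimulus_set(quality: Quality | str) -> list[StimulusSpec]:
    """Build the 23-stimulus battery for one sound quality.

    Returns the seven constant sounds followed by the sixteen ramps
    (two dB ranges x four durations x two directions).
    """
    quality = Quality(quality)
    specs = [
        StimulusSpec(quality, RampKind.CONSTANT, lev, lev, CONSTANT_DURATION)
        for lev in CONSTANT_LEVELS
    ]
    for lo, hi in RAMP_RANGES:
        for dur in RAMP_DURATIONS:
            specs.append(StimulusSpec(quality, RampKind.UP_RAMP, lo, hi, dur))
            specs.append(StimulusSpec(quality, RampKind.DOWN_RAMP, hi, lo, dur))
    return specs


def render_envelope(
    spec: StimulusSpec,
    rate: float,
    pre_pad: float = 0.0,
    post_pad: float = 0.0,
    silence_floor: float = 0.0,
) -> StimulusEnvelope:
    """Discretize a stimulus spec to a dB-SPL envelope at ``rate`` Hz.

    The stimulus occupies ``round(duration * rate)`` frames whose values
    interpolate linearly in dB between ``level_start`` and ``level_end``
    (both endpoints included).  Onset falls on a frame boundary.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_stim = int(round(spec.duration * rate))
    if n_stim < 2:
        raise ValueError("duration * rate must be at least 2 frames")
    n_pre = int(round(pre_pad * rate))
    n_post = int(round(post_pad * rate))
    values = np.full(n_pre + n_stim + n_post, silence_floor, dtype=float)
    values[n_pre : n_pre + n_stim] = np.linspace(spec.level_start, spec.level_end, n_stim)
    return StimulusEnvelope(
        values=values,
        rate=rate,
        onset_index=n_pre,
        offset_index=n_pre + n_stim,
        silence_floor=silence_floor,
        spec=spec,
    )


def render_battery(
    specs: list[StimulusSpec],
    rate: float,
    pre_pad: float = 0.5,
    total_duration: float | None = None,
    silence_floor: float = 0.0,
) -> list[StimulusEnvelope]:
    """Render a battery on a common frame grid of equal length.

    ``total_duration`` (default: pre_pad + longest stimulus + 2 s) fixes the
    envelope length so batteries stack into rectangular tensors; the
    post-stimulus pad absorbs the difference in stimulus durations.
    """
    if total_duration is None:
        total_duration = pre_pad + max(s.duration for s in specs) + 2.0
    out = []
    for spec in specs:
        post = total_duration - pre_pad - spec.duration
        if post < 0:
            raise ValueError(f"total_duration too short for {spec.label}")
        env = render_envelope(spec, rate, pre_pad, post, silence_floor)
        # equalize rounding jitter so all envelopes share one grid
        n_target = int(round(total_duration * rate))
        if env.n_frames > n_target:
            env.values = env.values[:n_target]
        elif env.n_frames < n_target:
            env.values = np.concatenate(
                [env.values, np.full(n_target - env.n_frames, silence_floor)]
            )
        env.offset_index = min(env.offset_index, n_target)
        out.append(env)
    return out


def time_reverse(env: StimulusEnvelope) -> StimulusEnvelope:
    """Reverse the envelope about its stimulus-window midpoint.

    Frames inside ``[onset_index, offset_index)`` are reversed in place;
    the silent pads are untouched, so reversal is an involution and
    preserves the multiset of envelope values.
    """
    values = env.values.copy()
    values[env.onset_index : env.offset_index] = values[
        env.onset_index : env.offset_index
    ][::-1]
    spec = env.spec.reversed() if env.spec is not None else None
    return StimulusEnvelope(
        values=values,
        rate=env.rate,
        onset_index=env.onset_index,
        offset_index=env.offset_index,
        silence_floor=env.silence_floor,
        spec=spec,
    )


def battery_to_tsv(specs: list[StimulusSpec], path: str | Path) -> None:
    """Write one row per stimulus spec to a TSV table."""
    rows = [
        {
            "quality": s.quality.value,
            "kind": s.kind.value,
            "level_start": s.level_start,
            "level_end": s.level_end,
            "duration": s.duration,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def battery_from_tsv(path: str | Path) -> list[StimulusSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        StimulusSpec(
            Quality(r.quality),
            RampKind(r.kind),
            float(r.level_start),
            float(r.level_end),
            float(r.duration),
        )
        for r in df.itertuples()
    ]
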