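"""Tinnitus-avatar synthesis and stepped cross-fade morphing.

The avatar is a pure tone (bandwidth 0) or band-limited noise centred
geometrically on the matched pitch.  Morph schedules describe the
avatar's share of total *intensity* (power) over the duration of a sound
file; rendering therefore mixes the two equal-RMS stems with amplitude
weights ``sqrt(r)`` and ``sqrt(1 - r)`` so that the short-time power
ratio of the stems' contributions tracks the scheduled ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: Allowed avatar bandwidths, in octaves.
BANDWIDTH_LADDER = (0.0, 1 / 24, 1 / 12, 1 / 6, 1 / 3, 1 / 2, 1.0, 2.0, 3.0, 4.0)

PITCH_MIN = 250.0
PITCH_MAX = 16000.0


@dataclass(frozen=True)
class AvatarSpec:
    """Psychoacoustic parameters of the synthesized tinnitus avatar."""

    pitch: float  # Hz
    bandwidth: float = 0.0  # octaves, from BANDWIDTH_LADDER
    level: float = 0.1  # target RMS (per channel)
    balance: float = 0.0  # stereo pan in [-1, 1]

    def __post_init__(self) -> None:
        if not PITCH_MIN <= self.pitch <= PITCH_MAX:
            raise ValueError(
                f"pitch must be within {PITCH_MIN:g}-{PITCH_MAX:g} Hz, got {self.pitch:g}"
            )
        if not any(np.isclose(self.bandwidth, b) for b in BANDWIDTH_LADDER):
            raise ValueError(
                f"bandwidth {self.bandwidth!r} not on the ladder {BANDWIDTH_LADDER}"
            )
        if self.level <= 0:
            raise ValueError("level must be positive")
        if not -1.0 <= self.balance <= 1.0:
            raise ValueError("balance must lie in [-1, 1]")


def synthesize_avatar(
    spec: AvatarSpec, rate: float, duration: float, seed: int = 0
) -> np.ndarray:
    """Render the avatar as a stereo ``(2, n)`` waveform.

    Bandwidth 0 gives a pure sinusoid at the pitch; a positive bandwidth
    ``b`` gives noise band-limited to ``[pitch * 2**(-b/2), pitch * 2**(b/2)]``
    (-3 dB edges), whose geometric centre is the pitch.  Per-channel RMS
    equals ``spec.level`` (within 1 %); stereo balance uses constant-power
    panning.
    """
    n = int(round(rate * duration))
    t = np.arange(n) / rate
    if spec.bandwidth == 0:
        mono = np.sqrt(2.0) * np.sin(2 * np.pi * spec.pitch * t)
    else:
        lo = spec.pitch * 2.0 ** (-spec.bandwidth / 2)
        hi = spec.pitch * 2.0 ** (spec.bandwidth / 2)
        nyq = rate / 2.0
        if hi >= nyq:
            warnings.warn(
                f"upper band edge {hi:.0f} Hz clipped at Nyquist ({nyq:.0f} Hz)",
                stacklevel=2,
            )
            hi = 0.999 * nyq
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        mono = sps.sosfilt(sos, noise)
        mono = mono / np.sqrt(np.mean(mono**2))
    mono = spec.level * mono / np.sqrt(np.mean(mono**2))
    # Constant-power pan: gains sum to unit power, sqrt(2) restores
    # per-channel RMS at centre balance.
    gl = np.sqrt((1.0 - spec.balance) / 2.0) * np.sqrt(2.0)
    gr = np.sqrt((1.0 + spec.balance) / 2.0) * np.sqrt(2.0)
    return np.vstack([gl * mono, gr * mono])


@dataclass(frozen=True)
class MorphSegment:
    start: float
    end: float
    ratio_start: float
    ratio_end: float
    interpolation: str = "linear"  # "constant" | "linear"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        for r in (self.ratio_start, self.ratio_end):
            if not 0.0 <= r <= 1.0:
                raise ValueError("ratios must lie in [0, 1]")
        if self.interpolation not in ("constant", "linear"):
            raise ValueError("interpolation must be 'constant' or 'linear'")
        if self.interpolation == "constant" and self.ratio_start != self.ratio_end:
            raise ValueError("constant segment must have equal start/end ratios")


@dataclass(frozen=True)
class MorphSchedule:
    """Piecewise avatar-intensity-ratio function over a file's duration."""

    duration: float
    segments: tuple[MorphSegment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        t = 0.0
        for seg in self.segments:
            if not np.isclose(seg.start, t):
                raise ValueError("segments must tile the duration without gaps/overlap")
            t = seg.end
        if not np.isclose(t, self.duration):
            raise ValueError("segments must end exactly at the schedule duration")

    def ratio(self, t) -> np.ndarray:
        """Avatar power ratio at time(s) ``t``; right-continuous at boundaries."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any((t < 0) | (t > self.duration)):
            raise ValueError("time outside schedule duration")
        starts = np.array([s.start for s in self.segments])
        idx = np.minimum(
            np.searchsorted(starts, t, side="right") - 1, len(self.segments) - 1
        )
        out = np.empty_like(t)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if not m.any():
                continue
            if seg.interpolation == "constant":
                out[m] = seg.ratio_start
            else:
                f = (t[m] - seg.start) / (seg.end - seg.start)
                out[m] = seg.ratio_start + f * (seg.ratio_end - seg.ratio_start)
        return out if out.size > 1 else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "duration": self.duration,
                "segments": [
                    [s.start, s.end, s.ratio_start, s.ratio_end, s.interpolation]
                    for s in self.segments
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MorphSchedule":
        obj = json.loads(text)
        return cls(
            obj["duration"],
            tuple(MorphSegment(*seg) for seg in obj["segments"]),
        )


def acute_schedule() -> MorphSchedule:
    """The 1-hour acute morph: 90 % avatar share for the first 10 min,
    a steady linear decrease over the middle 40 min, and 10 % for the
    last 10 min (50/50 at the midpoint, minutes 25-35)."""
    return MorphSchedule(
        3600.0,
        (
            MorphSegment(0.0, 600.0, 0.9, 0.9, "constant"),
            MorphSegment(600.0, 3000.0, 0.9, 0.1, "linear"),
            MorphSegment(3000.0, 3600.0, 0.1, 0.1, "constant"),
        ),
    )


def chronic_schedules() -> list[MorphSchedule]:
    """The four 1-hour chronic versions: 100 % constant, 100 -> 50 %,
    50 -> 10 %, and 10 -> 0 % avatar share."""
    ladder = [(1.0, 1.0, "constant"), (1.0, 0.5, "linear"), (0.5, 0.1, "linear"), (0.1, 0.0, "linear")]
    return [
        MorphSchedule(3600.0, (MorphSegment(0.0, 3600.0, r0, r1, kind),))
        for r0, r1, kind in ladder
    ]


def render_morph(
    avatar: np.ndarray,
    environment: np.ndarray,
    schedule: MorphSchedule,
    rate: float,
) -> np.ndarray:
    """Cross-fade two equal-RMS stems following the intensity schedule.

    ``output(t) = sqrt(r(t)) * avatar(t) + sqrt(1 - r(t)) * environment(t)``
    so the power ratio of the contributions equals ``r(t)``.
    """
    avatar = np.atleast_2d(np.asarray(avatar, dtype=float))
    environment = np.atleast_2d(np.asarray(environment, dtype=float))
    if avatar.shape != environment.shape:
        raise ValueError(
            f"stem shapes differ: {avatar.shape} vs {environment.shape}"
        )
    n = avatar.shape[1]
    expected = int(round(schedule.duration * rate))
    if n != expected:
        raise ValueError(
            f"stems have {n} samples but schedule expects {expected} at {rate:g} Hz"
        )
    t = np.arange(n) / rate
    r = schedule.ratio(t)
    return np.sqrt(r) * avatar + np.sqrt(1.0 - r) * environment


def band_power_share(
    output: np.ndarray,
    rate: float,
    band_a: tuple[float, float],
    band_b: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Fraction of band-limited power in ``band_a`` relative to both bands.

    This is the round-trip measurement used to validate intensity
    tracking: render with stems occupying the disjoint bands ``band_a``
    (avatar) and ``band_b`` (environment), then read the avatar's power
    share straight from the output spectrum over the given time window.
    """
    x = np.atleast_2d(np.asarray(output, dtype=float))
    if window is not None:
        i0, i1 = (int(round(w * rate)) for w in window)
        x = x[:, i0:i1]
    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / rate)

    def power(band):
        m = (freqs >= band[0]) & (freqs <= band[1])
        return spec[:, m].sum()

    pa, pb = power(band_a), power(band_b)
    return float(pa / (pa + pb))
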