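"""Synthetic EEG generation with planted lagged couplings.

Recordings are seeded Gaussian noise (optionally 1/f-shaped) on which a
set of directed, lagged, linear couplings is planted: each edge
``(source -> target, lag L, gain g)`` adds ``g * x_source[n - L]`` to
``x_target[n]``.  Downstream network-inference stages are tested by
checking that the changes they report cluster around the planted edges.

The study-shaped fixture reproduces the six-condition schedule
(Pre, Sound1..3, Post, Post3Month) with a laterality layout that moves
from left-hemisphere couplings (Sound1) through bilateral (Sound2/3) to
right-hemisphere couplings (Post, Post3Month).  All six recordings of a
fixture share one noise background, so differences between conditions
are attributable purely to the planted couplings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage, make_default_montage
from .recording import EEGRecording

#: The fixed six-level condition schedule, in presentation order.
CONDITIONS = ("Pre", "Sound1", "Sound2", "Sound3", "Post", "Post3Month")

#: Default acquisition profile of the emulated study setup.
ACQUISITION_RATE = 8192.0
ANALYSIS_RATE = 256.0


@dataclass(frozen=True)
class CouplingEdge:
    source: str
    target: str
    lag: int
    gain: float

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if self.source == self.target:
            raise ValueError(f"self-edge on channel {self.source!r}")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted lagged couplings plus the noise model for one recording."""

    edges: tuple[CouplingEdge, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0
    pink: bool = False  # 1/f-shaped noise instead of white

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ConditionProfile:
    condition: str
    coupling: CouplingSpec
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, pink: bool) -> np.ndarray:
    x = rng.normal(0.0, sd, size=shape)
    if not pink:
        return x
    # Shape the spectrum by 1/sqrt(f), then rescale to the requested sd.
    spec = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(shape[1])
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= weights
    x = np.fft.irfft(spec, n=shape[1], axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def simulate_recording(
    profile: ConditionProfile,
    montage: Montage | None = None,
    rate: float = ANALYSIS_RATE,
) -> EEGRecording:
    """Generate one seeded recording with the profile's planted couplings.

    Identical ``(profile, montage, rate)`` always yields a bit-identical
    matrix.  Couplings are applied sequentially in edge order, so chained
    edges compose.
    """
    if rate not in (ACQUISITION_RATE, ANALYSIS_RATE):
        raise ValueError(f"rate must be {ACQUISITION_RATE} or {ANALYSIS_RATE} Hz")
    montage = montage if montage is not None else make_default_montage()
    coupling = profile.coupling
    for e in coupling.edges:
        for ch in (e.source, e.target):
            if ch not in montage:
                raise ValueError(f"coupling references unknown channel {ch!r}")

    n_samples = int(round(profile.duration * rate))
    rng = np.random.default_rng(coupling.seed)
    data = _noise(rng, (len(montage), n_samples), coupling.noise_sd, coupling.pink)
    for e in coupling.edges:
        s, t = montage.index(e.source), montage.index(e.target)
        data[t, e.lag:] += e.gain * data[s, : n_samples - e.lag]
    return EEGRecording(data, rate, montage.labels, condition=profile.condition)


# Planted layouts per condition.  Edges stay inside one hemisphere zone
# each so that zone-level recovery scoring is well defined: Sound1 left,
# Sound2/Sound3 bilateral, Post and Post3Month right.
_LEFT_EDGES = (("P5", "P3", 4), ("FC5", "FC3", 3), ("PO7", "PO3", 5), ("F5", "F3", 3))
_RIGHT_EDGES = (("P6", "P4", 4), ("FC6", "FC4", 3), ("PO8", "PO4", 5), ("F6", "F4", 3))

_CONDITION_LAYOUT: dict[str, tuple[tuple[str, str, int], ...]] = {
    "Pre": (),
    "Sound1": _LEFT_EDGES,
    "Sound2": (_LEFT_EDGES[0], _RIGHT_EDGES[0]),
    "Sound3": (_LEFT_EDGES[0], _LEFT_EDGES[2], _RIGHT_EDGES[0], _RIGHT_EDGES[2]),
    "Post": _RIGHT_EDGES,
    "Post3Month": _RIGHT_EDGES,
}


@dataclass(eq=False)
class StudyFixture:
    """Six condition recordings plus the planted ground truth."""

    recordings: list[EEGRecording]
    planted: dict[str, tuple[CouplingEdge, ...]]
    seed: int
    noise_sd: float
    gain: float

    def recording(self, condition: str) -> EEGRecording:
        for rec in self.recordings:
            if rec.condition == condition:
                return rec
        raise KeyError(f"no recording for condition {condition!r}")

    def metadata(self) -> dict:
        """JSON-serializable planted-layout description."""
        return {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "gain": self.gain,
            "conditions": list(CONDITIONS),
            "planted": {
                cond: [
                    {"source": e.source, "target": e.target, "lag": e.lag, "gain": e.gain}
                    for e in edges
                ]
                for cond, edges in self.planted.items()
            },
        }


def make_study_fixture(
    seed: int,
    montage: Montage | None = None,
    duration: float = 60.0,
    rate: float = ANALYSIS_RATE,
    gain: float = 0.9,
    noise_sd: float = 0.1,
) -> StudyFixture:
    """Build the six-condition desk-scale fixture.

    All conditions share one seeded noise background (same ``seed``); only
    the planted coupling layout differs, following the left -> bilateral
    -> right progression.  ``duration`` defaults to 60 s per condition
    (desk scale); pass 600 for study-length segments.
    """
    montage = montage if montage is not None else make_default_montage()
    recordings = []
    planted: dict[str, tuple[CouplingEdge, ...]] = {}
    for cond in CONDITIONS:
        edges = tuple(
            CouplingEdge(src, tgt, lag, gain) for src, tgt, lag in _CONDITION_LAYOUT[cond]
        )
        planted[cond] = edges
        profile = ConditionProfile(
            condition=cond,
            coupling=CouplingSpec(edges=edges, noise_sd=noise_sd, seed=seed),
            duration=duration,
        )
        recordings.append(simulate_recording(profile, montage, rate))
    return StudyFixture(recordings, planted, seed, noise_sd, gain)
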