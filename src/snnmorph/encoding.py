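"""Step Forward (SF) ternary spike encoding.

The encoder keeps, per channel, a fixed amplitude threshold and a moving
baseline.  At each sample an upward excursion of at least one threshold
above the baseline emits a positive spike and raises the baseline by one
threshold; a downward excursion emits a negative spike and lowers it;
otherwise no spike is emitted and the baseline is unchanged.  The
baseline moves at most one threshold per sample, so when the per-sample
signal increments are bounded by the threshold the decoded baseline
trajectory tracks the signal within one threshold everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .recording import EEGRecording

Thresholds = Union[float, np.ndarray]


@dataclass(eq=False)
class EncoderParams:
    """Configuration of the SF encoder.

    ``sf_threshold`` may be a scalar (shared by all channels) or a
    per-channel array.  ``baseline_init`` selects the initial baseline:
    the channel's first sample (default) or its mean.
    """

    sf_threshold: Optional[Thresholds] = None
    baseline_init: str = "first"
    optimize: bool = False
    candidate_grid: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.baseline_init not in ("first", "mean"):
            raise ValueError("baseline_init must be 'first' or 'mean'")
        if self.sf_threshold is not None:
            thr = np.atleast_1d(np.asarray(self.sf_threshold, dtype=float))
            if np.any(thr <= 0):
                raise ValueError("sf_threshold must be positive")
        if self.optimize and self.candidate_grid is not None and len(self.candidate_grid) == 0:
            raise ValueError("candidate_grid must be non-empty when optimizing")


@dataclass(eq=False)
class SpikeRaster:
    """Ternary spike trains plus the encoder state that produced them."""

    spikes: np.ndarray  # (channels, samples) int8 in {-1, 0, +1}
    rate: float
    thresholds: np.ndarray  # per-channel SF threshold
    baselines: np.ndarray  # per-channel initial baseline
    labels: tuple[str, ...]
    params: EncoderParams

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.int8)
        if not np.isin(self.spikes, (-1, 0, 1)).all():
            raise ValueError("spikes must be ternary {-1, 0, +1}")

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.spikes.shape[1]

    def to_triplets(self) -> np.ndarray:
        """Sparse ``(channel, sample, sign)`` representation."""
        ch, sm = np.nonzero(self.spikes)
        return np.column_stack([ch, sm, self.spikes[ch, sm]]).astype(np.int64)


@njit(cache=True)
def _sf_encode_kernel(x, thr, b0):  # pragma: no cover - exercised via sf_encode
    n_ch, n_s = x.shape
    out = np.zeros((n_ch, n_s), dtype=np.int8)
    for c in range(n_ch):
        b = b0[c]
        t = thr[c]
        for n in range(n_s):
            d = x[c, n] - b
            if d >= t:
                out[c, n] = 1
                b += t
            elif -d >= t:
                out[c, n] = -1
                b -= t
    return out


def _resolve_thresholds(recording: EEGRecording, params: EncoderParams) -> np.ndarray:
    if params.sf_threshold is None:
        raise ValueError("sf_threshold is unset; provide one or use optimize_threshold")
    thr = np.asarray(params.sf_threshold, dtype=float)
    if thr.ndim == 0:
        thr = np.full(recording.n_channels, float(thr))
    if thr.shape != (recording.n_channels,):
        raise ValueError(
            f"threshold array has shape {thr.shape}, expected ({recording.n_channels},)"
        )
    return thr


def _initial_baselines(recording: EEGRecording, rule: str) -> np.ndarray:
    if rule == "first":
        return recording.data[:, 0].astype(float)
    return recording.data.mean(axis=1)


def sf_encode(recording: EEGRecording, params: EncoderParams) -> SpikeRaster:
    """Encode a recording into ternary spike trains with the SF rule."""
    if not np.isfinite(recording.data).all():
        ch, sm = np.argwhere(~np.isfinite(recording.data))[0]
        raise ValueError(
            f"non-finite sample in channel {recording.labels[ch]!r} at index {sm}"
        )
    if params.optimize:
        params = optimize_threshold(recording, params.candidate_grid, params.baseline_init)
    thr = _resolve_thresholds(recording, params)
    b0 = _initial_baselines(recording, params.baseline_init)
    spikes = _sf_encode_kernel(recording.data, thr, b0)
    return SpikeRaster(spikes, recording.rate, thr, b0, recording.labels, params)


def sf_decode(raster: SpikeRaster) -> np.ndarray:
    """Reconstruct the per-channel baseline trajectory B(n).

    ``B(n) = B0 + SFthr * cumsum(spikes)[n]`` — the inverse of the SF
    moving-baseline rule.
    """
    steps = raster.spikes.astype(np.int64).cumsum(axis=1)
    return raster.baselines[:, None] + raster.thresholds[:, None] * steps


def optimize_threshold(
    recording: EEGRecording,
    grid: Optional[Sequence[float]] = None,
    baseline_init: str = "first",
) -> EncoderParams:
    """Select, per channel, the grid threshold minimising encode/decode RMSE.

    With ``grid=None`` each channel scans 21 log-spaced candidates over
    ``[0.01, 1] x`` its own standard deviation.  Ties break towards the
    smaller threshold.
    """
    if grid is not None:
        candidates = np.asarray(list(grid), dtype=float)
        if candidates.size == 0:
            raise ValueError("threshold grid must be non-empty")
        if candidates.size < 2:
            raise ValueError("threshold grid needs at least 2 candidates")
        if np.any(candidates <= 0):
            raise ValueError("threshold candidates must be positive")
        per_channel = np.tile(candidates, (recording.n_channels, 1))
    else:
        multipliers = np.logspace(np.log10(0.01), 0.0, 21)
        sds = recording.data.std(axis=1)
        sds = np.where(sds > 0, sds, 1.0)
        per_channel = sds[:, None] * multipliers[None, :]

    # Sort candidates ascending so that argmin's first-hit tie-break
    # lands on the smaller threshold.
    per_channel = np.sort(per_channel, axis=1)
    b0 = _initial_baselines(recording, baseline_init)
    n_grid = per_channel.shape[1]
    rmse = np.empty((recording.n_channels, n_grid))
    for g in range(n_grid):
        thr = per_channel[:, g].copy()
        spikes = _sf_encode_kernel(recording.data, thr, b0)
        recon = b0[:, None] + thr[:, None] * spikes.astype(np.int64).cumsum(axis=1)
        rmse[:, g] = np.sqrt(np.mean((recording.data - recon) ** 2, axis=1))
    best = np.argmin(rmse, axis=1)
    chosen = per_channel[np.arange(recording.n_channels), best]
    return EncoderParams(sf_threshold=chosen, baseline_init=baseline_init)
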