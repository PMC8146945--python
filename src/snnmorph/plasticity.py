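"""Spike-timing-dependent plasticity training of the reservoir.

Nearest-spike STDP interleaved with the LIF dynamics: at each
postsynaptic firing every incoming connection is potentiated by
``a_plus * exp(-(t_post - t_pre)/tau_plus)`` for the source's most
recent strictly-prior spike, and at each presynaptic firing every
outgoing connection is depressed by ``a_minus * exp(-(t_pre - t_post)/tau_minus)``
for the target's most recent strictly-prior spike.  Updates act on
connection magnitudes (inhibitory connections mirror the rule) and are
clipped to ``[0, w_max]``; learning never creates a connection absent
from the initial sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import lif_stdp_kernel
from .encoding import EncoderParams, SpikeRaster, optimize_threshold, sf_encode
from .recording import EEGRecording
from .reservoir import ReservoirModel, SpikeActivity, _injection_vector


@dataclass(frozen=True)
class STDPParams:
    # Default learning rate is deliberately small: with symmetric rates
    # around 0.01 the weights drift to the bounds during a 60 s segment
    # and condition differences wash out.
    a_plus: float = 0.002
    a_minus: float = 0.002
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    w_min: float = -1.0
    w_max: float = 1.0
    passes: int = 1

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP amplitudes must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.w_min > 0 or self.w_max <= 0:
            raise ValueError("weight bounds must straddle zero (w_min <= 0 < w_max)")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


@dataclass(eq=False)
class TrainedModel:
    """A reservoir after STDP training on one condition's spike stream."""

    model: ReservoirModel  # post-training weights
    trained_on: str
    activity: SpikeActivity
    params: STDPParams
    initial_weights: np.ndarray  # pre-training weights, same sparsity

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights


def stdp_train(
    model: ReservoirModel,
    raster: SpikeRaster,
    params: STDPParams | None = None,
    condition: str = "",
) -> TrainedModel:
    """Train a copy of ``model`` on a spike raster; deterministic."""
    params = params or STDPParams()
    inj = _injection_vector(model, raster)
    out_indptr, out_idx, in_indptr, in_idx = model.adjacency_csr()
    sign = np.where(model.grid.excitatory, 1.0, -1.0)
    trained = model.copy()
    W = trained.weights

    all_t, all_i = [], []
    total_steps = 0
    for _ in range(params.passes):
        ft, fi, _ = lif_stdp_kernel(
            W,
            out_indptr,
            out_idx,
            in_indptr,
            in_idx,
            sign,
            inj,
            raster.spikes,
            np.zeros(model.n_neurons),
            float(np.exp(-1.0 / model.lif.tau_m)),
            model.lif.v_thr,
            model.lif.v_reset,
            int(model.lif.refractory),
            model.lif.k_in,
            True,
            params.a_plus,
            params.a_minus,
            params.tau_plus,
            params.tau_minus,
            params.w_max,
            False,
        )
        all_t.append(ft + total_steps)
        all_i.append(fi)
        total_steps += raster.n_samples
    activity = SpikeActivity(np.concatenate(all_t), np.concatenate(all_i), total_steps)
    return TrainedModel(
        model=trained,
        trained_on=condition,
        activity=activity,
        params=params,
        initial_weights=model.weights.copy(),
    )


def train_condition_models(
    recordings: list[EEGRecording],
    base: ReservoirModel,
    enc: EncoderParams,
    params: STDPParams | None = None,
) -> dict[str, TrainedModel]:
    """Train one model per condition from identical copies of ``base``.

    All recordings must share montage labels and sampling rate so that
    differences between the trained models are attributable to the data.
    When ``enc.optimize`` is set, thresholds are optimised once on the
    first recording and shared by every condition, keeping the encoding
    comparable across conditions.
    """
    params = params or STDPParams()
    if not recordings:
        raise ValueError("no recordings given")
    labels0, rate0 = recordings[0].labels, recordings[0].rate
    for rec in recordings[1:]:
        if rec.labels != labels0:
            raise ValueError("recordings have mixed montages")
        if rec.rate != rate0:
            raise ValueError("recordings have mixed sampling rates")

    if enc.optimize:
        enc = optimize_threshold(recordings[0], enc.candidate_grid, enc.baseline_init)

    out: dict[str, TrainedModel] = {}
    for rec in recordings:
        cond = rec.condition or f"recording{len(out)}"
        if cond in out:
            raise ValueError(f"duplicate condition tag {cond!r}")
        raster = sf_encode(rec, enc)
        out[cond] = stdp_train(base, raster, params, condition=cond)
    return out
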