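"""Numba core: discrete-time LIF dynamics with optional interleaved STDP.

One simulation step corresponds to one input sample.  Update order per
step ``t``:

1. leak: ``v <- v * exp(-1/tau_m)`` plus recurrent input from spikes at
   ``t - 1``;
2. input injection: an input spike of sign ``s`` adds ``s * k_in * v_thr``
   to its mapped neuron;
3. threshold detection (respecting refractoriness);
4. nearest-spike STDP updates computed from last-spike times strictly
   earlier than ``t`` (weights change before propagation);
5. reset, refractory bookkeeping, last-spike update, and propagation of
   the new spikes into the next step's recurrent input.

Weight updates act on connection *magnitudes*; the sign of a connection
is fixed by its source neuron's excitatory/inhibitory type.  Magnitudes
are clipped to ``[0, w_cap]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lif_stdp_kernel(
    W,  # (N, N) float64, modified in place when plastic
    out_indptr,
    out_idx,  # CSR adjacency over outgoing connections
    in_indptr,
    in_idx,  # CSR adjacency over incoming connections
    sign,  # (N,) float64, +1 excitatory / -1 inhibitory source
    inj,  # (C,) int64, input neuron per raster channel
    raster,  # (C, T) int8
    v0,  # (N,) float64 initial potentials
    decay,
    v_thr,
    v_reset,
    refractory,
    k_in,
    plastic,
    a_plus,
    a_minus,
    tau_plus,
    tau_minus,
    w_cap,
    record,
):  # pragma: no cover - exercised through reservoir/plasticity wrappers
    N = W.shape[0]
    C, T = raster.shape
    NEVER = np.int64(-(10**9))

    v = v0.copy()
    rec_in = np.zeros(N)
    last = np.full(N, NEVER)
    refr_until = np.zeros(N, dtype=np.int64)
    buf = np.empty(N, dtype=np.int64)

    cap = 1024
    fired_t = np.empty(cap, dtype=np.int64)
    fired_i = np.empty(cap, dtype=np.int64)
    count = 0

    if record:
        pot = np.zeros((T, N))
    else:
        pot = np.zeros((1, 1))

    for t in range(T):
        for j in range(N):
            v[j] = v[j] * decay + rec_in[j]
            rec_in[j] = 0.0
        for c in range(C):
            s = raster[c, t]
            if s != 0:
                v[inj[c]] += s * k_in * v_thr

        nf = 0
        for j in range(N):
            if v[j] >= v_thr and t >= refr_until[j]:
                buf[nf] = j
                nf += 1

        if plastic and nf > 0:
            for b in range(nf):
                f = buf[b]
                # Potentiate incoming connections whose source spiked before t.
                for p in range(in_indptr[f], in_indptr[f + 1]):
                    i = in_idx[p]
                    if last[i] != NEVER and last[i] < t:
                        dw = a_plus * np.exp(-(t - last[i]) / tau_plus)
                        m = abs(W[i, f]) + dw
                        if m > w_cap:
                            m = w_cap
                        W[i, f] = m if sign[i] > 0 else -m
                # Depress outgoing connections whose target spiked before t.
                for p in range(out_indptr[f], out_indptr[f + 1]):
                    j2 = out_idx[p]
                    if last[j2] != NEVER and last[j2] < t:
                        dw = a_minus * np.exp(-(t - last[j2]) / tau_minus)
                        m = abs(W[f, j2]) - dw
                        if m < 0.0:
                            m = 0.0
                        W[f, j2] = m if sign[f] > 0 else -m

        for b in range(nf):
            f = buf[b]
            v[f] = v_reset
            refr_until[f] = t + refractory
            last[f] = t
            for p in range(out_indptr[f], out_indptr[f + 1]):
                rec_in[out_idx[p]] += W[f, out_idx[p]]
            if count == cap:
                cap *= 2
                new_t = np.empty(cap, dtype=np.int64)
                new_i = np.empty(cap, dtype=np.int64)
                new_t[:count] = fired_t
                new_i[:count] = fired_i
                fired_t = new_t
                fired_i = new_i
            fired_t[count] = t
            fired_i[count] = f
            count += 1

        if record:
            for j in range(N):
                pot[t, j] = v[j]

    return fired_t[:count], fired_i[:count], pot
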