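"""Numba-compiled inner loop of the clock-driven LIF simulation.

The kernel advances the whole network by a block of time steps.  Between
events the membrane potential is propagated by the exact exponential solution
of the membrane equation toward its bias-shifted steady state; delta-pulse
synaptic input and external Poisson events are applied at the end of each
step.  Spikes in transit live in a ring buffer of per-target accumulated
currents, giving an exact transmission delay of ``delay_steps`` steps.

External Poisson counts are obtained by inverse-CDF table lookup: the
caller supplies one raw 32-bit variate per neuron and step (drawn in bulk
from a seeded NumPy generator, which keeps every source of randomness in one
stream) and the kernel indexes a precomputed count table with its top bits.
The rate is homogeneous, so a single table serves the whole population; the
table resolves the distribution to one part in 2^20 per count class.

Excitatory neuron indices are ``0 .. n_e-1``; inhibitory follow.  Calcium is
tracked for excitatory neurons only: per step it decays by a precomputed
factor, then increments by ``beta_ca`` for each spike emitted in the step.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_chunk(
    n_steps,
    V,             # float64[n] membrane potentials, mV (updated in place)
    refr,          # int64[n] remaining refractory steps
    C,             # float64[n_e] calcium traces
    pending,       # float64[delay_steps + 1, n] ring buffer of in-transit PSPs
    slot0,         # int: current ring slot
    decay,         # exp(-dt / tau_m)
    bias,          # float64[n] steady-state potential per neuron (v_0 + dV), mV
    v_reset,
    v_th,
    ref_steps,     # int: refractory period in steps
    threshold_on,  # bool: False disables spiking (free membrane potential)
    j_ext,
    pois_lut,      # uint8[2**bits] inverse-CDF table of per-step counts
    lut_shift,     # int: 32 - bits; raw variates are shifted down by this
    randoms,       # uint32[n_steps, n] raw variates driving the external input
    s_indptr,      # static out-edge CSR over all neurons
    s_idx,
    s_w,
    A,             # int32[n_e, n_e] E->E synapse counts, A[post, pre]
    j_e,
    n_e,
    ca_decay,      # exp(-dt / tau_ca)
    beta_ca,
    counts,        # int64[n] spike counts, accumulated in place
    rec_t,         # float64[cap] spike time record (ms)
    rec_id,        # int64[cap] spike neuron record
    rec_n0,        # int: records already present
    record_spikes,
    t0,            # ms, time at chunk start
    dt,
    rec_v,         # float64[n_steps] voltage trace of neuron 0
    record_v,
):
    n = V.shape[0]
    n_slots = pending.shape[0]
    delay_steps = n_slots - 1
    slot = slot0
    nrec = rec_n0
    for step in range(n_steps):
        for i in range(n_e):
            C[i] *= ca_decay
        dep_slot = slot + delay_steps
        if dep_slot >= n_slots:
            dep_slot -= n_slots
        for i in range(n):
            if refr[i] > 0:
                # clamped at reset; synaptic and external input is discarded
                refr[i] -= 1
                V[i] = v_reset
                pending[slot, i] = 0.0
                continue
            k = pois_lut[randoms[step, i] >> lut_shift]
            V[i] = bias[i] + (V[i] - bias[i]) * decay + pending[slot, i] + j_ext * k
            pending[slot, i] = 0.0
            if threshold_on and V[i] >= v_th:
                V[i] = v_reset
                refr[i] = ref_steps
                counts[i] += 1
                if i < n_e:
                    C[i] += beta_ca
                if record_spikes and nrec < rec_t.shape[0]:
                    rec_t[nrec] = t0 + (step + 1) * dt
                    rec_id[nrec] = i
                    nrec += 1
                for e in range(s_indptr[i], s_indptr[i + 1]):
                    pending[dep_slot, s_idx[e]] += s_w[e]
                if i < n_e:
                    for tgt in range(n_e):
                        a = A[tgt, i]
                        if a > 0:
                            pending[dep_slot, tgt] += j_e * a
        if record_v:
            rec_v[step] = V[0]
        slot += 1
        if slot == n_slots:
            slot = 0
    return slot, nrec
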