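"""Numba inner loop for the stochastic network integrator.

One fixed-step RK4 step advances (V, m, h, n) of every neuron.  The
channel noise of each gate is a single standard-normal draw per step,
scaled by sqrt(2 D / dt) and added as a constant forcing to the gating
derivative at all four stages; D is recomputed at each stage from the
stage voltage (the intensities are voltage dependent) while the draw z
is frozen, which preserves the per-step white-noise variance contract.
Gap-junction currents are re-evaluated from the stage voltages; the
synaptic open fractions s are held constant within a step and advanced
by exact exponential decay plus unit spike jumps at the step boundary.

The scalar rate functions here mirror ``hh_neuron.rate_constants``; a
unit test pins the two implementations against each other.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# coupling mode codes
MODE_NONE = 0
MODE_GAP = 1
MODE_CHEM = 2


@njit(cache=True, inline="always")
def _rates(v):
    u = (25.0 - v) * 0.1
    if abs(u) < 1e-7:
        am = 1.0 - 0.5 * u + u * u / 12.0
    else:
        am = u / math.expm1(u)
    bm = 4.0 * math.exp(-v / 18.0)
    ah = 0.07 * math.exp(-v / 20.0)
    bh = 1.0 / (math.exp((30.0 - v) * 0.1) + 1.0)
    w = (10.0 - v) * 0.1
    if abs(w) < 1e-7:
        an = 0.1 * (1.0 - 0.5 * w + w * w / 12.0)
    else:
        an = 0.1 * w / math.expm1(w)
    bn = 0.125 * math.exp(-v / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True, fastmath=True)
def run_chunk(
    V, m, h, n, s, above,           # state arrays, length N (above: uint8)
    indptr, indices,                # CSR adjacency
    mode, g, E_rev, tau_syn,        # coupling
    inv_NNa, inv_NK,                # reciprocal channel counts (0 => no noise)
    dt, n_steps,
    noise, has_noise,               # float32 (n_steps, N, 3) when has_noise
    threshold,
    record_from,                    # step index (within chunk) from which to record spikes
    t0,                             # absolute time (ms) at chunk start
    spike_i, spike_t,               # preallocated output buffers
    traces, trace_every, trace_phase,  # traces: (n_samples, N) float32 or (0,0)
    trace_start,                    # first already-filled row count in traces
):
    """Advance ``n_steps`` steps in place; returns (n_spikes, n_traces, ok)."""
    N = V.size
    inv2dt = 2.0 / dt
    dec = math.exp(-dt / tau_syn)
    gNa = 120.0
    gK = 36.0
    gL = 0.3
    ENa = 115.0
    EK = -12.0
    EL = 10.6
    I0 = 6.8

    kV = np.empty((4, N))
    km = np.empty((4, N))
    kh = np.empty((4, N))
    kn = np.empty((4, N))
    Vs = np.empty(N)
    ms = np.empty(N)
    hs = np.empty(N)
    ns = np.empty(N)
    S = np.zeros(N)
    Isyn = np.zeros(N)

    n_spikes = 0
    n_traces = 0
    cap = spike_i.size
    record_traces = traces.shape[0] > 0

    for step in range(n_steps):
        if mode == MODE_CHEM and g > 0.0:
            for i in range(N):
                acc = 0.0
                for jj in range(indptr[i], indptr[i + 1]):
                    acc += s[indices[jj]]
                S[i] = acc

        for stage in range(4):
            if stage == 0:
                for i in range(N):
                    Vs[i] = V[i]
                    ms[i] = m[i]
                    hs[i] = h[i]
                    ns[i] = n[i]
            else:
                c = 0.5 * dt if stage < 3 else dt
                p = stage - 1
                for i in range(N):
                    Vs[i] = V[i] + c * kV[p, i]
                    ms[i] = m[i] + c * km[p, i]
                    hs[i] = h[i] + c * kh[p, i]
                    ns[i] = n[i] + c * kn[p, i]

            if mode == MODE_GAP and g > 0.0:
                for i in range(N):
                    acc = 0.0
                    deg = indptr[i + 1] - indptr[i]
                    for jj in range(indptr[i], indptr[i + 1]):
                        acc += Vs[indices[jj]]
                    Isyn[i] = g * (acc - deg * Vs[i])
            elif mode == MODE_CHEM and g > 0.0:
                for i in range(N):
                    Isyn[i] = g * S[i] * (E_rev - Vs[i])

            for i in range(N):
                v = Vs[i]
                am, bm, ah, bh, an, bn = _rates(v)
                xm = 0.0
                xh = 0.0
                xn = 0.0
                if has_noise:
                    Dm = am * bm / (am + bm) * inv_NNa
                    Dh = ah * bh / (ah + bh) * inv_NNa
                    Dn = an * bn / (an + bn) * inv_NK
                    xm = noise[step, i, 0] * math.sqrt(Dm * inv2dt)
                    xh = noise[step, i, 1] * math.sqrt(Dh * inv2dt)
                    xn = noise[step, i, 2] * math.sqrt(Dn * inv2dt)
                mm = ms[i]
                hh = hs[i]
                nn = ns[i]
                km[stage, i] = am * (1.0 - mm) - bm * mm + xm
                kh[stage, i] = ah * (1.0 - hh) - bh * hh + xh
                kn[stage, i] = an * (1.0 - nn) - bn * nn + xn
                m3 = mm * mm * mm
                n2 = nn * nn
                kV[stage, i] = (
                    -gNa * m3 * hh * (v - ENa)
                    - gK * n2 * n2 * (v - EK)
                    - gL * (v - EL)
                    + I0
                    + Isyn[i]
                )

        t_new = t0 + (step + 1) * dt
        for i in range(N):
            V[i] += dt / 6.0 * (kV[0, i] + 2.0 * kV[1, i] + 2.0 * kV[2, i] + kV[3, i])
            m[i] += dt / 6.0 * (km[0, i] + 2.0 * km[1, i] + 2.0 * km[2, i] + km[3, i])
            h[i] += dt / 6.0 * (kh[0, i] + 2.0 * kh[1, i] + 2.0 * kh[2, i] + kh[3, i])
            n[i] += dt / 6.0 * (kn[0, i] + 2.0 * kn[1, i] + 2.0 * kn[2, i] + kn[3, i])
            if m[i] < 0.0:
                m[i] = 0.0
            elif m[i] > 1.0:
                m[i] = 1.0
            if h[i] < 0.0:
                h[i] = 0.0
            elif h[i] > 1.0:
                h[i] = 1.0
            if n[i] < 0.0:
                n[i] = 0.0
            elif n[i] > 1.0:
                n[i] = 1.0
            if not math.isfinite(V[i]):
                return n_spikes, n_traces, False

            fired = False
            if V[i] >= threshold:
                if above[i] == 0:
                    fired = True
                    above[i] = 1
            else:
                above[i] = 0

            s[i] *= dec
            if fired:
                s[i] += 1.0
                if step >= record_from:
                    if n_spikes >= cap:
                        return n_spikes, n_traces, False
                    spike_i[n_spikes] = i
                    spike_t[n_spikes] = t_new
                    n_spikes += 1

        if record_traces and (step + trace_phase + 1) % trace_every == 0:
            row = trace_start + n_traces
            if row < traces.shape[0]:
                for i in range(N):
                    traces[row, i] = V[i]
                n_traces += 1

    return n_spikes, n_traces, True
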