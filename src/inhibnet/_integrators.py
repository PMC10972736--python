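"""Numba-compiled fixed-step integrators.

All kernels use explicit Euler (Euler--Maruyama when noise is present) at a
fixed step ``dt`` in ms.  Synaptic coupling is realized as a pair of linear
filter states (rise and decay exponentials) per network or per neuron, driven
through a spike-count ring buffer that implements the kernel latency; this is
exactly equivalent to convolving the binned spike train with the sampled
biexponential kernel (asserted in the test suite).

The homogeneous-network kernel exploits all-to-all coupling: the shared filter
is advanced once per step, so the cost per step is O(N).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# spike-count buffers grow by this expected ceiling (spikes per neuron per ms)
_MAX_RATE_PER_MS = 0.5


@njit(cache=True)
def izh_spike_times_from_state(v0, u0, I, a, b, c, d, Cm, vpeak, dt, n_steps):
    """Deterministic Izhikevich run; returns (spike_times, v_final, u_final)."""
    cap = int(n_steps * dt * _MAX_RATE_PER_MS) + 16
    times = np.empty(cap, dtype=np.float64)
    n = 0
    v = v0
    u = u0
    for k in range(n_steps):
        dv = (0.04 * v * v + 5.0 * v + 140.0 - u + I) / Cm
        du = a * (b * v - u)
        v += dt * dv
        u += dt * du
        if v >= vpeak:
            if n < cap:
                times[n] = (k + 1) * dt
                n += 1
            v = c
            u += d
    return times[:n], v, u


@njit(cache=True)
def _via_rates(V, theta, s1, s2, k1, k2, idx):
    x = theta[idx] - V
    if abs(x) < 1e-8:
        alpha = k1[idx] * (s1[idx] - 0.5 * x)
    else:
        alpha = k1[idx] * x / (np.expm1(x / s1[idx]))
    beta = k2[idx] * np.exp(V / s2[idx])
    return alpha, beta


@njit(cache=True)
def _via_step(V, m, h, n_, a_, I, Cm, gNa, gKv7, gKv3, gL, ENa, EK, EL,
              theta, s1, s2, k1, k2, dt):
    INa = gNa * m * m * m * h * (ENa - V)
    IK7 = gKv7 * a_ * a_ * a_ * a_ * (EK - V)
    IK3 = gKv3 * n_ * n_ * n_ * n_ * (EK - V)
    IL = gL * (EL - V)
    dV = (INa + IK7 + IK3 + IL + I) / Cm
    am, bm = _via_rates(V, theta, s1, s2, k1, k2, 0)
    ah, bh = _via_rates(V, theta, s1, s2, k1, k2, 1)
    an, bn = _via_rates(V, theta, s1, s2, k1, k2, 2)
    aa, ba = _via_rates(V, theta, s1, s2, k1, k2, 3)
    m2 = min(1.0, max(0.0, m + dt * (am * (1.0 - m) - bm * m)))
    # h: |alpha| de-inactivates (its k1-form rate is negative for all V),
    # beta inactivates -- see models.via_deriv
    h2 = min(1.0, max(0.0, h + dt * (abs(ah) * (1.0 - h) - bh * h)))
    n2 = min(1.0, max(0.0, n_ + dt * (an * (1.0 - n_) - bn * n_)))
    a2 = min(1.0, max(0.0, a_ + dt * (aa * (1.0 - a_) - ba * a_)))
    return V + dt * dV, m2, h2, n2, a2


@njit(cache=True)
def via_spike_times_from_state(v0, m0, h0, n0, a0, I, Cm, gNa, gKv7, gKv3, gL,
                               ENa, EK, EL, theta, s1, s2, k1, k2, dt, n_steps):
    """Deterministic Via-model run; spikes are upward crossings of 0 mV."""
    cap = int(n_steps * dt * _MAX_RATE_PER_MS) + 16
    times = np.empty(cap, dtype=np.float64)
    cnt = 0
    V, m, h, n_, a_ = v0, m0, h0, n0, a0
    above = V >= 0.0
    for k in range(n_steps):
        V, m, h, n_, a_ = _via_step(V, m, h, n_, a_, I, Cm, gNa, gKv7, gKv3, gL,
                                    ENa, EK, EL, theta, s1, s2, k1, k2, dt)
        if V >= 0.0 and not above:
            if cnt < cap:
                times[cnt] = (k + 1) * dt
                cnt += 1
            above = True
        elif V < 0.0:
            above = False
    return times[:cnt]


@njit(cache=True)
def izh_network(v, u, a, b, c, d, Cm, vpeak, Iext, sigma, coupling, conductance,
                esyn, amp, decR, decD, n_delay, dt, n_steps, rec_stride, seed):
    """Homogeneous all-to-all Izhikevich network, shared synaptic filter.

    ``coupling`` is J/N.  In current mode (``conductance`` False) the recurrent
    input is -coupling * s(t) (inhibitory, charge-normalized kernel); in
    conductance mode it is coupling * s(t) * (esyn_i - v_i) with the
    peak-normalized kernel (``amp`` carries the normalization).  Noise is an
    independent Gaussian increment of sd sigma*sqrt(dt)/Cm per neuron per step.

    Returns (spike_idx, spike_t, v_rec, irec_rec, srec) where v_rec samples all
    membrane potentials every ``rec_stride`` steps, irec_rec is the
    population-mean recurrent current at those times and srec the shared
    filter output s(t).
    """
    np.random.seed(seed)
    N = v.shape[0]
    cap = int(N * n_steps * dt * _MAX_RATE_PER_MS) + 1024
    spike_idx = np.empty(cap, dtype=np.int32)
    spike_t = np.empty(cap, dtype=np.float64)
    nsp = 0
    ring = np.zeros(n_delay, dtype=np.float64)
    xR = 0.0
    xD = 0.0
    n_rec = n_steps // rec_stride
    v_rec = np.empty((n_rec, N), dtype=np.float64)
    irec_rec = np.empty(n_rec, dtype=np.float64)
    srec = np.empty(n_rec, dtype=np.float64)
    sq = np.sqrt(dt)
    irec = 0
    for k in range(n_steps):
        slot = k % n_delay
        arr = ring[slot]
        if arr > 0.0:
            xR += arr * amp
            xD += arr * amp
        s = xD - xR
        imean = 0.0
        count = 0.0
        for i in range(N):
            vi = v[i]
            if conductance:
                isyn = coupling * s * (esyn[i] - vi)
            else:
                isyn = -coupling * s
            imean += isyn
            dv = (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + Iext + isyn) / Cm
            vi = vi + dt * dv + (sigma / Cm) * sq * np.random.normal(0.0, 1.0)
            u[i] += dt * a * (b * v[i] - u[i])
            if vi >= vpeak:
                if nsp < cap:
                    spike_idx[nsp] = i
                    spike_t[nsp] = (k + 1) * dt
                    nsp += 1
                vi = c
                u[i] += d
                count += 1.0
            if not np.isfinite(vi):
                raise ValueError("non-finite membrane potential during network run")
            v[i] = vi
        xR *= decR
        xD *= decD
        ring[slot] = count
        if (k + 1) % rec_stride == 0 and irec < n_rec:
            for i in range(N):
                v_rec[irec, i] = v[i]
            irec_rec[irec] = imean / N
            srec[irec] = s
            irec += 1
    return spike_idx[:nsp], spike_t[:nsp], v_rec, irec_rec, srec


@njit(cache=True)
def via_network(v, m, h, n_, a_, Cm, gNa, gKv7, gKv3, gL, ENa, EK, EL,
                theta, s1, s2, k1, k2, Iext, sigma, coupling, esyn,
                amp, decR, decD, n_delay, dt, n_steps, rec_stride, seed):
    """Homogeneous all-to-all Via network with conductance-based synapses.

    ``coupling`` = J/N in nS, ``esyn`` per-neuron reversal (mV); currents in pA.
    Same shared-filter scheme as ``izh_network``; the kernel is peak-normalized
    via ``amp``.
    """
    np.random.seed(seed)
    N = v.shape[0]
    cap = int(N * n_steps * dt * _MAX_RATE_PER_MS) + 1024
    spike_idx = np.empty(cap, dtype=np.int32)
    spike_t = np.empty(cap, dtype=np.float64)
    nsp = 0
    ring = np.zeros(n_delay, dtype=np.float64)
    xR = 0.0
    xD = 0.0
    n_rec = n_steps // rec_stride
    v_rec = np.empty((n_rec, N), dtype=np.float64)
    irec_rec = np.empty(n_rec, dtype=np.float64)
    srec = np.empty(n_rec, dtype=np.float64)
    above = np.zeros(N, dtype=np.bool_)
    for i in range(N):
        above[i] = v[i] >= 0.0
    sq = np.sqrt(dt)
    irec = 0
    for k in range(n_steps):
        slot = k % n_delay
        arr = ring[slot]
        if arr > 0.0:
            xR += arr * amp
            xD += arr * amp
        s = xD - xR
        imean = 0.0
        count = 0.0
        for i in range(N):
            isyn = coupling * s * (esyn[i] - v[i])
            imean += isyn
            V2, m2, h2, n2, a2 = _via_step(
                v[i], m[i], h[i], n_[i], a_[i], Iext + isyn, Cm, gNa, gKv7,
                gKv3, gL, ENa, EK, EL, theta, s1, s2, k1, k2, dt)
            V2 += (sigma / Cm) * sq * np.random.normal(0.0, 1.0)
            if V2 >= 0.0 and not above[i]:
                if nsp < cap:
                    spike_idx[nsp] = i
                    spike_t[nsp] = (k + 1) * dt
                    nsp += 1
                above[i] = True
                count += 1.0
            elif V2 < 0.0:
                above[i] = False
            if not np.isfinite(V2):
                raise ValueError("non-finite membrane potential during network run")
            v[i] = V2
            m[i], h[i], n_[i], a_[i] = m2, h2, n2, a2
        xR *= decR
        xD *= decD
        ring[slot] = count
        if (k + 1) % rec_stride == 0 and irec < n_rec:
            for i in range(N):
                v_rec[irec, i] = v[i]
            irec_rec[irec] = imean / N
            srec[irec] = s
            irec += 1
    return spike_idx[:nsp], spike_t[:nsp], v_rec, irec_rec, srec


@njit(cache=True)
def via_network_sparse(v, m, h, n_, a_, Cm_i, gNa_i, gKv7_i, gKv3_i, gL_i,
                       EL_i, ENa, EK, theta, s1, s2, k1, k2,
                       edge_ptr, edge_post, edge_w, edge_we, edge_delay,
                       Iext, sigma, amp, decR, decD, max_delay, dt, n_steps, seed):
    """Spatially embedded heterogeneous Via network with per-synapse weights,
    delays and reversal potentials.

    Per neuron two filter pairs are kept: one driven by the synaptic
    conductance g (nS) and one by g*E_syn, so the total synaptic current is
    I_i = B_i - G_i * V_i, which supports an arbitrary per-synapse reversal
    without one filter per synapse.  ``edge_w`` carries the conductance and
    ``edge_we`` = conductance * E_syn; ``amp`` is the peak normalization.
    """
    np.random.seed(seed)
    N = v.shape[0]
    cap = int(N * n_steps * dt * _MAX_RATE_PER_MS) + 1024
    spike_idx = np.empty(cap, dtype=np.int32)
    spike_t = np.empty(cap, dtype=np.float64)
    nsp = 0
    bufg = np.zeros((max_delay, N), dtype=np.float64)
    bufb = np.zeros((max_delay, N), dtype=np.float64)
    gR = np.zeros(N, dtype=np.float64)
    gD = np.zeros(N, dtype=np.float64)
    bR = np.zeros(N, dtype=np.float64)
    bD = np.zeros(N, dtype=np.float64)
    above = np.zeros(N, dtype=np.bool_)
    for i in range(N):
        above[i] = v[i] >= 0.0
    sq = np.sqrt(dt)
    for k in range(n_steps):
        slot = k % max_delay
        for i in range(N):
            ag = bufg[slot, i]
            if ag != 0.0:
                gR[i] += ag * amp
                gD[i] += ag * amp
                ab = bufb[slot, i]
                bR[i] += ab * amp
                bD[i] += ab * amp
                bufg[slot, i] = 0.0
                bufb[slot, i] = 0.0
        for i in range(N):
            G = gD[i] - gR[i]
            B = bD[i] - bR[i]
            isyn = B - G * v[i]
            V2, m2, h2, n2, a2 = _via_step(
                v[i], m[i], h[i], n_[i], a_[i], Iext + isyn, Cm_i[i], gNa_i[i],
                gKv7_i[i], gKv3_i[i], gL_i[i], ENa, EK, EL_i[i],
                theta, s1, s2, k1, k2, dt)
            V2 += (sigma / Cm_i[i]) * sq * np.random.normal(0.0, 1.0)
            if V2 >= 0.0 and not above[i]:
                if nsp < cap:
                    spike_idx[nsp] = i
                    spike_t[nsp] = (k + 1) * dt
                    nsp += 1
                above[i] = True
                for e in range(edge_ptr[i], edge_ptr[i + 1]):
                    tgt = edge_post[e]
                    dslot = (k + edge_delay[e]) % max_delay
                    bufg[dslot, tgt] += edge_w[e]
                    bufb[dslot, tgt] += edge_we[e]
            elif V2 < 0.0:
                above[i] = False
            if not np.isfinite(V2):
                raise ValueError("non-finite membrane potential during network run")
            v[i] = V2
            m[i], h[i], n_[i], a_[i] = m2, h2, n2, a2
        for i in range(N):
            gR[i] *= decR
            gD[i] *= decD
            bR[i] *= decR
            bD[i] *= decD
    return spike_idx[:nsp], spike_t[:nsp]


@njit(cache=True)
def izh_psth_realizations(a, b, c, d, Cm, vpeak, Iext, sigma, amp, f_hz,
                          v0_lo, v0_hi, dt, n_transient, n_steps, bin_steps,
                          n_real, seed):
    """Trial-averaged spike counts of a noisy Izhikevich neuron under
    sinusoidal drive ``amp * sin(2 pi f t)``.

    The drive phase is referenced to the start of the measurement window
    (t = 0 after the transient).  Returns spike counts per 1 ms bin summed
    over realizations; divide by (n_real * bin width) for the rate.
    """
    np.random.seed(seed)
    n_bins = n_steps // bin_steps
    counts = np.zeros(n_bins, dtype=np.float64)
    w = 2.0 * np.pi * f_hz / 1000.0  # rad per ms
    sq = np.sqrt(dt)
    for r in range(n_real):
        v = v0_lo + (v0_hi - v0_lo) * np.random.random()
        u = b * v
        for k in range(n_transient):
            t = (k - n_transient) * dt
            I = Iext + amp * np.sin(w * t)
            dv = (0.04 * v * v + 5.0 * v + 140.0 - u + I) / Cm
            v2 = v + dt * dv + (sigma / Cm) * sq * np.random.normal(0.0, 1.0)
            u += dt * a * (b * v - u)
            if v2 >= vpeak:
                v2 = c
                u += d
            v = v2
        for k in range(n_steps):
            t = k * dt
            I = Iext + amp * np.sin(w * t)
            dv = (0.04 * v * v + 5.0 * v + 140.0 - u + I) / Cm
            v2 = v + dt * dv + (sigma / Cm) * sq * np.random.normal(0.0, 1.0)
            u += dt * a * (b * v - u)
            if v2 >= vpeak:
                v2 = c
                u += d
                bi = k // bin_steps
                if bi < n_bins:
                    counts[bi] += 1.0
            v = v2
    return counts
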