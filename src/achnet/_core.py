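"""Compiled integration kernels.

The network integrator advances all neurons with classical RK4 at a fixed
step, holding the drive, noise and synaptic currents constant across the
four substages of each step.  Synaptic conductances use the exact recursive
form of the double-exponential kernel (two decaying traces per presynaptic
neuron, incremented at spikes), and the STDP pairing sums use an exact
recursive form of the 40 ms-windowed exponential trace, so no kernel
truncation error is introduced beyond the hard pairing window itself.

The pure-Python operations in :mod:`achnet.neuron` and
:mod:`achnet.synapse` implement the same definitions independently and act
as oracles for these kernels in the test suite.
"""

import math

import numpy as np
from numba import njit

__all__ = ["simulate_single", "simulate_network"]


@njit(cache=True, inline="always")
def _sig(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


@njit(cache=True, inline="always")
def _deriv(V, h, n, z, C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz, I_ext):
    m_inf = _sig((V + 30.0) / 9.5)
    h_inf = _sig(-(V + 53.0) / 7.0)
    tau_h = 0.37 + 2.78 * _sig(-(V + 40.5) / 6.0)
    n_inf = _sig((V + 30.0) / 10.0)
    tau_n = 0.37 + 1.85 * _sig(-(V + 27.0) / 15.0)
    z_inf = _sig((V + 39.0) / 5.0)
    I_ion = (gNa * m_inf * m_inf * m_inf * h * (V - ENa)
             + gKdr * n * n * n * n * (V - EK)
             + gKs * z * (V - EK)
             + gL * (V - EL))
    dV = (-I_ion + I_ext) / C
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / tau_n
    dz = (z_inf - z) / tauz
    return dV, dh, dn, dz


@njit(cache=True, inline="always")
def _rk4(V, h, n, z, C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz, I_ext, dt):
    k1V, k1h, k1n, k1z = _deriv(V, h, n, z, C, gNa, gKdr, gKs, gL,
                                ENa, EK, EL, tauz, I_ext)
    k2V, k2h, k2n, k2z = _deriv(V + 0.5 * dt * k1V, h + 0.5 * dt * k1h,
                                n + 0.5 * dt * k1n, z + 0.5 * dt * k1z,
                                C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz, I_ext)
    k3V, k3h, k3n, k3z = _deriv(V + 0.5 * dt * k2V, h + 0.5 * dt * k2h,
                                n + 0.5 * dt * k2n, z + 0.5 * dt * k2z,
                                C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz, I_ext)
    k4V, k4h, k4n, k4z = _deriv(V + dt * k3V, h + dt * k3h,
                                n + dt * k3n, z + dt * k3z,
                                C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz, I_ext)
    Vn = V + dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
    hn = h + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
    nn = n + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
    zn = z + dt / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
    if hn < 0.0:
        hn = 0.0
    elif hn > 1.0:
        hn = 1.0
    if nn < 0.0:
        nn = 0.0
    elif nn > 1.0:
        nn = 1.0
    if zn < 0.0:
        zn = 0.0
    elif zn > 1.0:
        zn = 1.0
    return Vn, hn, nn, zn


@njit(cache=True)
def simulate_single(params, I_drive, n_steps, dt, V0,
                    noise_amp, noise_p, pulse_steps, seed,
                    pert_time, pert_weight,
                    tau_d=0.5, tau_r=0.2):
    """Isolated neuron; returns the voltage trace at samples 0..n_steps.

    Optionally injects pulse noise and/or one excitatory synaptic-kernel
    conductance pulse at ``pert_time`` (ms; negative disables).
    """
    C, gNa, gKdr, gKs, gL, ENa, EK, EL, tauz = params
    np.random.seed(seed)
    V = V0
    h = 1.0
    n = 0.0
    z = 0.0
    out = np.empty(n_steps + 1)
    out[0] = V
    counter = 0
    for t in range(n_steps):
        I_ext = I_drive
        if noise_p > 0.0:
            if np.random.random() < noise_p:
                counter = pulse_steps
            if counter > 0:
                I_ext += noise_amp
                counter -= 1
        if pert_time >= 0.0:
            el = t * dt - pert_time
            if 0.0 <= el < 20.0 * tau_d:
                kern = math.exp(-el / tau_d) - math.exp(-el / tau_r)
                I_ext -= pert_weight * kern * (V - 0.0)
        V, h, n, z = _rk4(V, h, n, z, C, gNa, gKdr, gKs, gL,
                          ENa, EK, EL, tauz, I_ext, dt)
        out[t + 1] = V
    return out


@njit(cache=True)
def simulate_network(params, dt, n_steps, t_offset,
                     indptr, indices, w,
                     col_indptr, col_indices, col_to_data,
                     is_inh, E_syn_exc, E_syn_inh, tau_d, tau_r,
                     seg_ends, seg_gks, seg_drive, seg_plastic,
                     noise_amp, noise_p, pulse_steps,
                     A_L, tau_stdp, w_max, window_steps, plastic,
                     V, h, n, z, a, b,
                     seed, max_spikes):
    """Advance the whole network ``n_steps`` steps in place.

    Connectivity is CSR over postsynaptic rows (``w`` holds the mutable
    weights); ``col_*`` give the matching CSC view for presynaptic-side
    STDP updates.  ``seg_*`` define a piecewise schedule of (g_Ks, I_drive,
    plasticity-enabled) segments by end step.

    Returns (spike_counts, spike_times, lfp, err_step); ``err_step`` is -1
    on success or the step at which a non-finite voltage appeared.  State
    arrays (V, h, n, z and the synaptic traces a, b) are updated in place
    so runs can be chained.
    """
    N = V.shape[0]
    C, gNa, gKdr, gKs0, gL, ENa, EK, EL, tauz = params
    np.random.seed(seed)

    ed = math.exp(-dt / tau_d)
    er = math.exp(-dt / tau_r)
    etau = math.exp(-dt / tau_stdp)
    expired = math.exp(-(window_steps + 1) * dt / tau_stdp)

    counts = np.zeros(N, dtype=np.int64)
    times = np.zeros((N, max_spikes))
    lfp = np.zeros(n_steps)
    counter = np.zeros(N, dtype=np.int64)
    spiked = np.zeros(N, dtype=np.uint8)
    r = np.zeros(N)
    hist = np.zeros((N, window_steps + 1), dtype=np.uint8)
    I_ext = np.zeros(N)
    s = np.zeros(N)

    seg = 0
    for t in range(n_steps):
        while t >= seg_ends[seg]:
            seg += 1
        gKs = seg_gks[seg]
        I_drive = seg_drive[seg]
        plast_on = seg_plastic[seg] and A_L > 0.0

        for j in range(N):
            s[j] = a[j] - b[j]
        for i in range(N):
            I = I_drive
            if noise_p > 0.0:
                if np.random.random() < noise_p:
                    counter[i] = pulse_steps
                if counter[i] > 0:
                    I += noise_amp
                    counter[i] -= 1
            Isyn = 0.0
            Vi = V[i]
            for p in range(indptr[i], indptr[i + 1]):
                wv = w[p]
                if wv > 0.0:
                    j = indices[p]
                    if is_inh[j]:
                        Isyn += wv * s[j] * (Vi - E_syn_inh)
                    else:
                        Isyn += wv * s[j] * (Vi - E_syn_exc)
            I_ext[i] = I - Isyn

        lfpsum = 0.0
        any_spike = False
        for i in range(N):
            Vold = V[i]
            Vn, hn, nn, zn = _rk4(Vold, h[i], n[i], z[i], C, gNa, gKdr, gKs,
                                  gL, ENa, EK, EL, tauz, I_ext[i], dt)
            if not math.isfinite(Vn):
                return counts, times, lfp, t
            V[i] = Vn
            h[i] = hn
            n[i] = nn
            z[i] = zn
            if Vold <= 0.0 and Vn > 0.0:
                spiked[i] = 1
                any_spike = True
                if counts[i] < max_spikes:
                    times[i, counts[i]] = t_offset + (t + 1) * dt
                    counts[i] += 1
            else:
                spiked[i] = 0
            if not is_inh[i]:
                lfpsum += Vn
        lfp[t] = lfpsum

        if plast_on and any_spike:
            for i in range(N):
                if spiked[i] == 0:
                    continue
                # potentiation: presynaptic spikes preceding this postsynaptic one
                for p in range(indptr[i], indptr[i + 1]):
                    if plastic[p]:
                        rj = r[indices[p]]
                        if rj > 0.0:
                            wn = w[p] + A_L * rj
                            w[p] = w_max if wn > w_max else wn
                # depression: postsynaptic spikes preceding this presynaptic one
                for p in range(col_indptr[i], col_indptr[i + 1]):
                    q = col_to_data[p]
                    if plastic[q]:
                        ri = r[col_indices[p]]
                        if ri > 0.0:
                            wn = w[q] - A_L * ri
                            w[q] = 0.0 if wn < 0.0 else wn

        # advance synaptic traces and the windowed STDP pairing trace
        slot_new = t % (window_steps + 1)
        slot_exp = (t + 1) % (window_steps + 1)
        for i in range(N):
            a[i] = a[i] * ed + spiked[i]
            b[i] = b[i] * er + spiked[i]
            r[i] = etau * (r[i] + spiked[i]) - hist[i, slot_exp] * expired
            if r[i] < 0.0:
                r[i] = 0.0
            hist[i, slot_new] = spiked[i]

    return counts, times, lfp, -1
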