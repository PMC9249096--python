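"""Synaptic currents and spike-timing-dependent plasticity.

The synaptic kernel is a double exponential, rising with ``tau_r`` and
decaying with ``tau_d``; a presynaptic spike of neuron ``j`` at ``t_jk``
contributes ``w_ij * (exp(-(t-t_jk)/tau_d) - exp(-(t-t_jk)/tau_r)) *
(V_i - E_syn)`` to the current received by postsynaptic neuron ``i``.

Plasticity is a fully asymmetric pairwise STDP rule: every (pre, post)
spike pair with time difference ``dt_pair = t_post - t_pre`` within the
40 ms pairing window contributes ``+A_L * exp(-|dt_pair|/tau_STDP)`` if the
presynaptic spike came first, the exact negative mirror otherwise.
Weights are hard-bounded in ``[0, w_max]`` and synapses absent at
initialization are never created.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "PlasticityParams",
    "synaptic_kernel",
    "synaptic_current",
    "stdp_pair_delta",
    "stdp_update",
]


@dataclass(frozen=True)
class SynapseParams:
    tau_d: float = 0.5          # decay constant, ms
    tau_r: float = 0.2          # rise constant, ms
    E_syn_exc: float = 0.0      # mV
    E_syn_inh: float = -75.0    # mV
    kernel_cutoff: float = 5.0  # ms; kernel treated as zero beyond this

    def __post_init__(self) -> None:
        if not self.tau_d > self.tau_r > 0:
            raise ValueError("need tau_d > tau_r > 0")
        if self.kernel_cutoff < 5.0 * self.tau_d:
            raise ValueError("kernel_cutoff must be at least 5*tau_d")


@dataclass(frozen=True)
class PlasticityParams:
    """STDP parameters.

    The default amplitude ``A_L = 0.002 mS/cm**2`` is 5% of the initial
    weight per pairing; over a few seconds of activity this produces the
    region-dependent reorganization the simulator is built to study.  A
    tenfold smaller amplitude (0.0002) is a documented alternative
    calibration and yields proportionally weaker reorganization.
    """

    A_L: float = 0.002          # maximal weight change per pairing, mS/cm^2
    tau_STDP: float = 10.0      # pairing decay constant, ms
    w_max: float = 0.08         # upper weight bound (2 * w0), mS/cm^2
    pairing_window: float = 40.0  # ms
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.A_L < 0:
            raise ValueError("A_L must be non-negative")
        if self.tau_STDP <= 0:
            raise ValueError("tau_STDP must be positive")
        if self.w_max < 0:
            raise ValueError("w_max must be non-negative")


def synaptic_kernel(elapsed, params: SynapseParams = SynapseParams()):
    """Unit-weight double-exponential kernel at ``elapsed`` ms after a
    spike (zero before the spike and beyond the cutoff)."""
    el = np.asarray(elapsed, dtype=float)
    k = np.exp(-el / params.tau_d) - np.exp(-el / params.tau_r)
    return np.where((el >= 0) & (el <= params.kernel_cutoff), k, 0.0)


def synaptic_current(weights: np.ndarray, spike_history, V: np.ndarray,
                     t: float, params: SynapseParams = SynapseParams(),
                     is_inhibitory: np.ndarray | None = None) -> np.ndarray:
    """Total synaptic current received by each neuron at time ``t``.

    ``spike_history`` holds, per neuron, the (sorted) spike times at or
    before ``t``; contributions older than the kernel cutoff are dropped.
    This is the direct event-sum evaluation — the network integrator uses
    an algebraically equivalent recursive form.
    """
    n = weights.shape[0]
    V = np.asarray(V, dtype=float)
    if is_inhibitory is None:
        is_inhibitory = np.zeros(n, dtype=bool)
    E_syn = np.where(is_inhibitory, params.E_syn_inh, params.E_syn_exc)
    drive = np.zeros(n)  # summed kernel per presynaptic neuron
    for j in range(n):
        times = np.asarray(spike_history[j], dtype=float)
        if times.size:
            el = t - times
            drive[j] = synaptic_kernel(
                el[(el >= 0) & (el <= params.kernel_cutoff)], params).sum()
    I = np.zeros(n)
    for i in range(n):
        pre = np.flatnonzero(weights[i])
        if pre.size:
            I[i] = np.sum(weights[i, pre] * drive[pre] * (V[i] - E_syn[pre]))
    return I


def stdp_pair_delta(dt_pair, params: PlasticityParams = PlasticityParams()):
    """Weight change for a single pre/post pairing with
    ``dt_pair = t_post - t_pre`` (ms).  Antisymmetric; zero at
    ``dt_pair = 0`` and beyond the pairing window."""
    d = np.asarray(dt_pair, dtype=float)
    mag = params.A_L * np.exp(-np.abs(d) / params.tau_STDP)
    out = np.where(d > 0, mag, -mag)
    out = np.where((d == 0) | (np.abs(d) > params.pairing_window), 0.0, out)
    return out


def stdp_update(weights: np.ndarray, spike_trains,
                params: PlasticityParams = PlasticityParams(),
                plastic_mask: np.ndarray | None = None) -> np.ndarray:
    """Apply the all-to-all pairing rule over complete spike trains.

    For every existing synapse j -> i, sums the pairwise contributions of
    all (pre, post) spike pairs within the pairing window, then clips to
    ``[0, w_max]``.  Zero-weight (nonexistent) synapses are never created.

    This whole-train form is the reference implementation used to validate
    the event-by-event updates of the network integrator; it coincides with
    them only when no weight reaches a bound mid-run (clipping at bounds is
    path-dependent).
    """
    if not params.enabled or params.A_L == 0:
        return weights.copy()
    W = weights.copy()
    n = W.shape[0]
    if plastic_mask is None:
        plastic_mask = weights > 0
    for i in range(n):
        post = np.asarray(spike_trains[i], dtype=float)
        for j in np.flatnonzero(plastic_mask[i]):
            if i == j:
                continue
            pre = np.asarray(spike_trains[j], dtype=float)
            if post.size == 0 or pre.size == 0:
                continue
            d = post[:, None] - pre[None, :]
            W[i, j] = np.clip(W[i, j] + stdp_pair_delta(d, params).sum(),
                              0.0, params.w_max)
    return W
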