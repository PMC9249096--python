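"""Spike-train and weight-matrix analysis.

Implements the synchrony and directionality statistics used throughout:

* **Mean phase coherence (MPC)** — resultant length of the circular
  distribution of one train's spike phases within another train's
  interspike intervals; 1 = perfect phase locking.
* **Zero-lag cross-correlation (CC)** — normalized inner product of
  mean-subtracted, Gaussian-smoothed (sigma = 1 ms) spike trains; the
  "synchrony" measure.
* **AMD / AMD-Z / asymmetry** — average distance from each spike of one
  train to the most recent preceding spike of the other, Z-scored against
  an analytic uniform-placement null built from the reference train's
  interspike intervals; the asymmetry Z_ij - Z_ji quantifies which train
  reliably leads (|Z| > 2 is flagged significant).
* **Region-resolved synaptic change** — the summed weight change in each
  of the four hub-defined regions, normalized by (number of synapses in
  the region) * w0.
* **LFP spectrum** — FFT of the z-scored sum of excitatory membrane
  voltages.

Network-level averages are taken over ordered pairs i != j for which the
statistic is defined, and by convention are evaluated on the second half
of the recording window to discard the initial transient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpikeData",
    "PairwiseMatrix",
    "mean_phase_coherence",
    "mpc_matrix",
    "network_mpc",
    "cross_correlation",
    "cc_matrix",
    "network_cc",
    "amd",
    "amd_zscore",
    "region_delta",
    "firing_frequency",
    "lfp_spectrum",
    "AMD_SIGNIFICANCE_Z",
]

AMD_SIGNIFICANCE_Z = 2.0  # |Z| beyond which temporal locking is significant


@dataclass
class SpikeData:
    """Per-neuron sorted spike-time lists over a recording window (ms)."""

    trains: list
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for k, t in enumerate(self.trains):
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"train {k} is not strictly increasing")
            if t.size and (t[0] < self.t_start or t[-1] > self.t_end):
                raise ValueError(f"train {k} has spikes outside the window")

    @property
    def n(self) -> int:
        return len(self.trains)

    @classmethod
    def from_buffers(cls, counts: np.ndarray, times: np.ndarray,
                     t_start: float, t_end: float) -> "SpikeData":
        return cls([times[i, : counts[i]].copy() for i in range(len(counts))],
                   t_start, t_end)

    def restrict(self, t0: float, t1: float) -> "SpikeData":
        return SpikeData([t[(t >= t0) & (t <= t1)] for t in self.trains],
                         t0, t1)

    def second_half(self) -> "SpikeData":
        mid = 0.5 * (self.t_start + self.t_end)
        return self.restrict(mid, self.t_end)

    def _flat(self):
        offsets = np.zeros(self.n + 1, dtype=np.int64)
        for i, t in enumerate(self.trains):
            offsets[i + 1] = offsets[i] + t.size
        flat = np.concatenate(self.trains) if offsets[-1] else np.empty(0)
        return flat, offsets


@dataclass
class PairwiseMatrix:
    values: np.ndarray
    kind: str
    mask: np.ndarray  # True where the pair statistic is defined

    def defined_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# mean phase coherence

@njit(cache=True)
def _mpc_pair(ti, tj):
    """(resultant length, n_phases) of j's spikes in i's intervals."""
    if ti.size < 2:
        return 0.0, 0
    cs = 0.0
    sn = 0.0
    count = 0
    for t in tj:
        k = np.searchsorted(ti, t, side="right") - 1
        if k < 0 or k >= ti.size - 1:
            continue
        phi = 2.0 * np.pi * (t - ti[k]) / (ti[k + 1] - ti[k])
        cs += np.cos(phi)
        sn += np.sin(phi)
        count += 1
    if count == 0:
        return 0.0, 0
    return np.sqrt(cs * cs + sn * sn) / count, count


@njit(cache=True)
def _mpc_matrix(flat, offsets, n):
    vals = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        ti = flat[offsets[i]:offsets[i + 1]]
        if ti.size < 2:
            continue
        for j in range(n):
            tj = flat[offsets[j]:offsets[j + 1]]
            v, cnt = _mpc_pair(ti, tj)
            if cnt > 0:
                vals[i, j] = v
                mask[i, j] = 1
    return vals, mask


def mean_phase_coherence(train_i, train_j) -> float:
    """Pairwise MPC sigma_ij: phase locking of j's spikes within i's
    interspike intervals.  Returns NaN when undefined (i has fewer than
    two spikes, or no spike of j falls inside i's span)."""
    ti = np.asarray(train_i, dtype=float)
    tj = np.asarray(train_j, dtype=float)
    v, cnt = _mpc_pair(ti, tj)
    return float(v) if cnt else float("nan")


def mpc_matrix(spike_data: SpikeData) -> PairwiseMatrix:
    flat, offsets = spike_data._flat()
    vals, mask = _mpc_matrix(flat, offsets, spike_data.n)
    return PairwiseMatrix(vals, "mpc", mask.astype(bool))


def _block_average(mat: PairwiseMatrix, hub_mask: np.ndarray) -> dict:
    """Network mean over ordered pairs i != j plus hub-block breakdown."""
    n = mat.values.shape[0]
    off = ~np.eye(n, dtype=bool)
    defined = mat.mask & off
    if not np.any(defined):
        raise ValueError("insufficient spiking: no defined pairs")
    out = {"network": float(mat.values[defined].mean())}
    hh = defined & np.outer(hub_mask, hub_mask)
    nn = defined & np.outer(~hub_mask, ~hub_mask)
    out["hub"] = float(mat.values[hh].mean()) if np.any(hh) else float("nan")
    out["nonhub"] = float(mat.values[nn].mean()) if np.any(nn) else float("nan")
    out["hub_minus_nonhub"] = out["hub"] - out["nonhub"]
    out["n_pairs"] = int(defined.sum())
    return out


def network_mpc(spike_data: SpikeData, hub=None,
                use_second_half: bool = True) -> dict:
    """Network-average MPC with hub / non-hub block averages."""
    data = spike_data.second_half() if use_second_half else spike_data
    hub_mask = np.zeros(data.n, dtype=bool)
    if hub is not None:
        hub_mask[np.asarray(hub, dtype=int)] = True
    return _block_average(mpc_matrix(data), hub_mask)


# ---------------------------------------------------------------------------
# zero-lag cross-correlation

def _smoothed_traces(spike_data: SpikeData, sigma: float, dt: float):
    n_bins = int(round((spike_data.t_end - spike_data.t_start) / dt))
    S = np.zeros((spike_data.n, n_bins))
    for i, t in enumerate(spike_data.trains):
        idx = np.clip(((t - spike_data.t_start) / dt).astype(int), 0,
                      n_bins - 1)
        np.add.at(S[i], idx, 1.0)
    S = gaussian_filter1d(S, sigma / dt, axis=1, mode="constant",
                          truncate=5.0)
    S -= S.mean(axis=1, keepdims=True)
    return S


def cc_matrix(spike_data: SpikeData, sigma: float = 1.0,
              dt: float = 0.1) -> PairwiseMatrix:
    S = _smoothed_traces(spike_data, sigma, dt)
    norms = np.linalg.norm(S, axis=1)
    ok = norms > 0
    C = np.zeros((spike_data.n, spike_data.n))
    if np.any(ok):
        G = S[ok] @ S[ok].T
        denom = np.outer(norms[ok], norms[ok])
        C[np.ix_(ok, ok)] = G / denom
    np.clip(C, -1.0, 1.0, out=C)
    return PairwiseMatrix(C, "cc", np.outer(ok, ok))


def cross_correlation(train_i, train_j, t_start: float, t_end: float,
                      sigma: float = 1.0, dt: float = 0.1) -> float:
    """Pairwise zero-lag CC of two trains over [t_start, t_end]; NaN when
    either smoothed trace has zero variance."""
    data = SpikeData([np.asarray(train_i, float), np.asarray(train_j, float)],
                     t_start, t_end)
    m = cc_matrix(data, sigma, dt)
    return float(m.values[0, 1]) if m.mask[0, 1] else float("nan")


def network_cc(spike_data: SpikeData, hub=None, sigma: float = 1.0,
               dt: float = 0.1, use_second_half: bool = True) -> dict:
    data = spike_data.second_half() if use_second_half else spike_data
    hub_mask = np.zeros(data.n, dtype=bool)
    if hub is not None:
        hub_mask[np.asarray(hub, dtype=int)] = True
    return _block_average(cc_matrix(data, sigma, dt), hub_mask)


# ---------------------------------------------------------------------------
# average minimal (preceding) distance and its Z-score

@njit(cache=True)
def _amd_pair(ti, tj):
    """Mean distance from spikes of i to the most recent spike of j at or
    before them; spikes of i before j's first spike are dropped."""
    total = 0.0
    count = 0
    for t in ti:
        k = np.searchsorted(tj, t, side="right") - 1
        if k < 0:
            continue
        total += t - tj[k]
        count += 1
    if count == 0:
        return -1.0, 0
    return total / count, count


def amd(train_i, train_j) -> float:
    """Pairwise AMD (ms): average distance from each spike of i to the most
    recent preceding spike of j.  NaN when no spike of i has a
    predecessor in j."""
    v, cnt = _amd_pair(np.asarray(train_i, float), np.asarray(train_j, float))
    return float(v) if cnt else float("nan")


def _null_moments(ref_train: np.ndarray):
    """Mean and SD of the preceding distance under uniform placement
    against ``ref_train``'s interval structure (first and second moments
    of the interval-length-biased uniform distance)."""
    L = np.diff(ref_train)
    T = L.sum()
    if L.size == 0 or T <= 0:
        return float("nan"), float("nan")
    mu1 = np.sum(L ** 2) / (2.0 * T)
    mu2 = np.sum(L ** 3) / (3.0 * T)
    var = mu2 - mu1 ** 2
    return float(mu1), float(np.sqrt(var)) if var > 0 else 0.0


def amd_zscore(spike_data: SpikeData,
               use_second_half: bool = True) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """AMD Z-score matrix and the exactly antisymmetric asymmetry matrix
    Z_ij - Z_ji.

    Z_ij = (AMD_ij - mu) / sigma with mu, sigma the analytic null moments
    of the reference (preceding) train j.  Z_ij < -2 flags significant
    temporal locking of i just after j.
    """
    data = spike_data.second_half() if use_second_half else spike_data
    n = data.n
    Z = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    mu = np.empty(n)
    sd = np.empty(n)
    for j in range(n):
        mu[j], sd[j] = _null_moments(data.trains[j])
    for i in range(n):
        ti = data.trains[i]
        if ti.size == 0:
            continue
        for j in range(n):
            if i == j:
                continue
            tj = data.trains[j]
            if tj.size < 2 or not np.isfinite(mu[j]) or sd[j] == 0:
                continue
            v, cnt = _amd_pair(ti, tj)
            if cnt == 0:
                continue
            Z[i, j] = (v - mu[j]) / sd[j]
            mask[i, j] = True
    both = mask & mask.T
    asym = np.where(both, np.nan_to_num(Z) - np.nan_to_num(Z).T, np.nan)
    return (PairwiseMatrix(Z, "amd_z", mask),
            PairwiseMatrix(asym, "asymmetry", both))


# ---------------------------------------------------------------------------
# weights, rates, spectra

REGIONS = ("hub_hub", "hub_to_nonhub", "nonhub_to_hub", "nonhub_nonhub")


def region_delta(weights_before: np.ndarray, weights_after: np.ndarray,
                 hub, w0: float) -> dict:
    """Normalized synaptic-weight change in the four hub-defined regions.

    For region R: sum of (w_after - w_before) over synapses in R, divided
    by (synapse count in R) * w0.  Synapses are classified by the hub
    membership of their presynaptic (column) and postsynaptic (row)
    neurons.  Regions with no synapses are reported as NaN.
    """
    Wb = np.asarray(weights_before, float)
    Wa = np.asarray(weights_after, float)
    if Wb.shape != Wa.shape:
        raise ValueError("weight matrices differ in shape")
    exists = Wb > 0
    if np.any((Wa > 0) & ~exists):
        raise ValueError("weight matrices differ in sparsity pattern")
    n = Wb.shape[0]
    hub_mask = np.zeros(n, dtype=bool)
    hub_mask[np.asarray(hub, dtype=int)] = True
    post_hub = hub_mask[:, None]
    pre_hub = hub_mask[None, :]
    regions = {
        "hub_hub": pre_hub & post_hub,
        "hub_to_nonhub": pre_hub & ~post_hub,
        "nonhub_to_hub": ~pre_hub & post_hub,
        "nonhub_nonhub": ~pre_hub & ~post_hub,
    }
    out = {}
    for name, sel in regions.items():
        m = sel & exists
        A = int(m.sum())
        out[name] = float((Wa[m] - Wb[m]).sum() / (A * w0)) if A else float("nan")
        out[f"n_{name}"] = A
    return out


def firing_frequency(spike_data: SpikeData,
                     window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-neuron firing rate (Hz): spike count in the window divided by
    the window length."""
    t0, t1 = window if window is not None else (spike_data.t_start,
                                                spike_data.t_end)
    if t1 <= t0:
        raise ValueError("empty window")
    dur_s = (t1 - t0) / 1000.0
    return np.array([np.count_nonzero((t >= t0) & (t <= t1)) / dur_s
                     for t in spike_data.trains])


def lfp_spectrum(traces: np.ndarray, dt: float,
                 band: tuple[float, float] = (1.0, 100.0)):
    """One-sided power spectrum of the z-scored population voltage.

    ``traces`` is either a (n_neurons, n_samples) stack of excitatory
    voltage traces (summed internally) or an already-summed 1-D signal.
    Returns (freqs_Hz, power, dominant_freq_Hz) where the dominant
    frequency is the power argmax within ``band``.
    """
    traces = np.asarray(traces, dtype=float)
    sig = traces.sum(axis=0) if traces.ndim == 2 else traces
    sd = sig.std()
    sig = (sig - sig.mean()) / sd if sd > 0 else sig - sig.mean()
    n = sig.size
    power = np.abs(np.fft.rfft(sig)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("band outside spectral range")
    dom = float(freqs[in_band][np.argmax(power[in_band])])
    return freqs, power, dom
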