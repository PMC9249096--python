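"""Full network simulations and the study protocols built on them.

``run_simulation`` assembles a topology, selects the per-g_Ks subthreshold
drive, and integrates the coupled membrane equations with RK4 at
dt = 0.1 ms, with pulse noise, double-exponential synapses and (optionally)
STDP.  The protocol functions reproduce the standard experiments:
g_Ks / g_syn / noise sweeps, the excitatory-vs-mixed (E-I) comparison, hub
removal, STDP reorganization, and the 9-s wake-sleep-wake frequency
experiment.

Each protocol runs ``n_trials`` independent repetitions, every trial with a
freshly grown connectivity matrix and fresh initial conditions, and reports
trial means with standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import _core, measures
from .network import NetworkConfig, NetworkTopology, build_network, remove_hub
from .neuron import NeuronParams, StimulusConfig, select_drive
from .synapse import PlasticityParams, SynapseParams

__all__ = [
    "SimulationConfig",
    "Segment",
    "SimResult",
    "ExperimentResult",
    "run_simulation",
    "gks_sweep",
    "robustness_sweeps",
    "ei_comparison",
    "hub_removal_experiment",
    "stdp_reorganization",
    "wake_sleep_wake",
    "DRIVE_GRID",
]

# 0.01 uA/cm^2 grid over which the just-subthreshold drive is resolved
# (spans negative currents: the Type I rheobase sits slightly below zero)
DRIVE_GRID = np.arange(-1.0, 3.0005, 0.01)

P_IN_PRESETS = {
    "strong_hub_out": 0.1,
    "moderate_hub_out": 0.3,
    "balanced": 0.5,
    "moderate_hub_in": 0.7,
    "strong_hub_in": 0.9,
}


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise simulation schedule."""

    duration: float          # ms
    g_Ks: float              # mS/cm^2
    stdp: bool = False


@dataclass
class SimulationConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    # plasticity is off in the standard runs; protocols enable it explicitly
    plasticity: PlasticityParams = field(
        default_factory=lambda: PlasticityParams(enabled=False))
    neuron: NeuronParams = field(default_factory=NeuronParams)
    g_Ks: float = 0.0
    g_syn: float | None = None      # overrides network.w0_exc when set
    duration: float = 2000.0        # ms
    n_trials: int = 10
    record_voltage: bool = False
    auto_drive: bool = True         # select I_drive per g_Ks when True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 1000.0:
            raise ValueError("duration must be >= 1000 ms (second-half analysis)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def effective_network(self) -> NetworkConfig:
        if self.g_syn is None:
            return self.network
        return replace(self.network, w0_exc=self.g_syn)


@dataclass
class SimResult:
    spikes: measures.SpikeData
    topology: NetworkTopology
    w_before: np.ndarray
    w_after: np.ndarray
    lfp: np.ndarray           # summed excitatory voltage per step
    dt: float
    drives: list              # I_drive per segment
    seed: int


@dataclass
class ExperimentResult:
    """Per-trial measure summaries plus across-trial mean and SE."""

    trials: pd.DataFrame
    group_keys: list

    @property
    def summary(self) -> pd.DataFrame:
        num = self.trials.drop(columns=["trial"])
        g = num.groupby(self.group_keys)
        return g.agg(["mean", "sem"])


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31 - 1)


def _csr_views(W: np.ndarray):
    """CSR + matching CSC views of the weight matrix, with the CSC-to-CSR
    data-position map (sparsity pattern is fixed for a whole run)."""
    C = sparse.csr_matrix(W)
    C.sort_indices()
    nnz = C.nnz
    tag = sparse.csr_matrix((np.arange(nnz, dtype=np.int64), C.indices.copy(),
                             C.indptr.copy()), shape=C.shape)
    T = tag.tocsc()
    T.sort_indices()
    return (C.indptr.astype(np.int64), C.indices.astype(np.int64),
            C.data.astype(np.float64).copy(),
            T.indptr.astype(np.int64), T.indices.astype(np.int64),
            T.data.astype(np.int64))


def _drive_for(params: NeuronParams, g_Ks: float) -> float:
    return select_drive(params.with_gks(g_Ks), DRIVE_GRID)


def run_simulation(config: SimulationConfig,
                   schedule: list[Segment] | None = None,
                   topology: NetworkTopology | None = None) -> SimResult:
    """Build (or reuse) a topology and integrate the network.

    The default schedule is a single segment of ``config.duration`` at
    ``config.g_Ks`` with plasticity per ``config.plasticity.enabled``.
    A fixed config + seed yields bit-identical outputs.
    """
    topo_seed, init_seed, noise_seed = (int(s) for s in
                                        _spawn_seeds(config.seed, 3))
    if topology is None:
        netcfg = replace(config.effective_network(), seed=topo_seed)
        topology = build_network(netcfg)
    if schedule is None:
        schedule = [Segment(config.duration, config.g_Ks,
                            config.plasticity.enabled)]

    dt = config.stimulus.dt
    n = topology.n
    w_before = topology.weights.copy()
    indptr, indices, wdata, col_indptr, col_indices, col_to_data = \
        _csr_views(topology.weights)
    # plastic synapses: excitatory presynaptic onto excitatory postsynaptic
    inh = topology.is_inhibitory
    plastic = np.zeros(wdata.size, dtype=bool)
    for i in range(n):
        if not inh[i]:
            sl = slice(indptr[i], indptr[i + 1])
            plastic[sl] = ~inh[indices[sl]]

    seg_steps = [int(round(s.duration / dt)) for s in schedule]
    n_steps = int(sum(seg_steps))
    seg_ends = np.cumsum(seg_steps).astype(np.int64)
    seg_gks = np.array([s.g_Ks for s in schedule])
    if config.auto_drive:
        drives = [_drive_for(config.neuron, s.g_Ks) for s in schedule]
    else:
        drives = [config.stimulus.I_drive for _ in schedule]
    seg_drive = np.array(drives)
    seg_plastic = np.array([s.stdp for s in schedule])

    rng = np.random.default_rng(init_seed)
    V = rng.uniform(-70.0, 0.0, size=n)
    h = np.ones(n)
    nn = np.zeros(n)
    z = np.zeros(n)
    a = np.zeros(n)
    b = np.zeros(n)

    pl = config.plasticity
    st = config.stimulus
    sy = config.synapse
    window_steps = int(round(pl.pairing_window / dt))
    pulse_steps = int(round(st.noise_duration / dt))
    max_spikes = int(n_steps * dt) + 8  # one spike per ms is ample headroom

    counts, times, lfp, err = _core.simulate_network(
        config.neuron.as_tuple(), dt, n_steps, 0.0,
        indptr, indices, wdata, col_indptr, col_indices, col_to_data,
        inh, sy.E_syn_exc, sy.E_syn_inh, sy.tau_d, sy.tau_r,
        seg_ends, seg_gks, seg_drive, seg_plastic,
        st.noise_amplitude, st.noise_prob_per_step, pulse_steps,
        pl.A_L, pl.tau_STDP, pl.w_max, window_steps, plastic,
        V, h, nn, z, a, b, noise_seed, max_spikes)
    if err >= 0:
        raise FloatingPointError(
            f"non-finite state at step {err} (t = {err * dt:.1f} ms); "
            f"config seed {config.seed}")

    w_after = np.zeros_like(w_before)
    for i in range(n):
        sl = slice(indptr[i], indptr[i + 1])
        w_after[i, indices[sl]] = wdata[sl]
    spikes = measures.SpikeData.from_buffers(counts, times, 0.0, n_steps * dt)
    return SimResult(spikes, topology, w_before, w_after, lfp, dt,
                     drives, config.seed)


def _trial_configs(base: SimulationConfig, n_trials: int):
    for trial, s in enumerate(_spawn_seeds(base.seed, n_trials)):
        yield trial, replace(base, seed=int(s))


def _coherence_row(res: SimResult) -> dict:
    exc = res.topology.excitatory
    data = measures.SpikeData([res.spikes.trains[i] for i in exc],
                              res.spikes.t_start, res.spikes.t_end)
    hub_local = np.searchsorted(exc, res.topology.hub)
    mpc = measures.network_mpc(data, hub_local)
    cc = measures.network_cc(data, hub_local)
    freq = measures.firing_frequency(
        res.spikes, (res.spikes.t_end / 2, res.spikes.t_end))[exc]
    return {
        "mpc": mpc["network"], "mpc_hub": mpc["hub"],
        "mpc_nonhub": mpc["nonhub"], "mpc_diff": mpc["hub_minus_nonhub"],
        "cc": cc["network"], "cc_hub": cc["hub"],
        "cc_nonhub": cc["nonhub"], "cc_diff": cc["hub_minus_nonhub"],
        "rate_mean": float(freq.mean()), "rate_sd": float(freq.std()),
    }


def gks_sweep(base_config: SimulationConfig, gks_list, pin_list=None
              ) -> ExperimentResult:
    """Network MPC/CC (with hub-block differences) over a grid of g_Ks and
    hub-orientation values, ``n_trials`` independent runs per cell."""
    if pin_list is None:
        pin_list = [base_config.network.p_in]
    rows = []
    for p_in in pin_list:
        for g in gks_list:
            cfg0 = replace(base_config,
                           network=replace(base_config.network, p_in=p_in),
                           g_Ks=g)
            for trial, cfg in _trial_configs(cfg0, base_config.n_trials):
                row = {"p_in": p_in, "g_Ks": g, "trial": trial}
                row.update(_coherence_row(run_simulation(cfg)))
                rows.append(row)
    return ExperimentResult(pd.DataFrame(rows), ["p_in", "g_Ks"])


def robustness_sweeps(base_config: SimulationConfig, gsyn_list, noise_list,
                      gks_list=(0.0, 1.5), noise_prob: float = 0.001
                      ) -> dict[str, ExperimentResult]:
    """Coupling-strength and noise-amplitude robustness grids.

    The noise variants use sparse strong pulses: the listed amplitudes at
    an initiation probability of 0.1% per step.
    """
    rows_g = []
    for g_syn in gsyn_list:
        for g in gks_list:
            cfg0 = replace(base_config, g_syn=g_syn, g_Ks=g)
            for trial, cfg in _trial_configs(cfg0, base_config.n_trials):
                row = {"g_syn": g_syn, "g_Ks": g, "trial": trial}
                row.update(_coherence_row(run_simulation(cfg)))
                rows_g.append(row)
    rows_n = []
    for amp in noise_list:
        stim = replace(base_config.stimulus, noise_amplitude=amp,
                       noise_prob_per_step=noise_prob)
        for g in gks_list:
            cfg0 = replace(base_config, stimulus=stim, g_Ks=g)
            for trial, cfg in _trial_configs(cfg0, base_config.n_trials):
                row = {"noise_amplitude": amp, "g_Ks": g, "trial": trial}
                row.update(_coherence_row(run_simulation(cfg)))
                rows_n.append(row)
    return {"gsyn": ExperimentResult(pd.DataFrame(rows_g), ["g_syn", "g_Ks"]),
            "noise": ExperimentResult(pd.DataFrame(rows_n),
                                      ["noise_amplitude", "g_Ks"])}


def ei_comparison(base_config: SimulationConfig, inhibitory_fractions,
                  gks_list=(0.0, 0.5, 1.0, 1.5)) -> ExperimentResult:
    """Excitatory-only versus mixed E-I networks.

    Reports E-minus-E-I differences of the hub and non-hub block MPC and
    CC, computed over excitatory cells only (inhibitory cells have no
    scale-free rank).
    """
    rows = []
    for frac in inhibitory_fractions:
        for g in gks_list:
            cfg_e0 = replace(base_config, g_Ks=g)
            for trial, cfg_e in _trial_configs(cfg_e0, base_config.n_trials):
                cfg_ei = replace(
                    cfg_e, network=replace(cfg_e.network,
                                           inhibitory_fraction=frac))
                r_e = _coherence_row(run_simulation(cfg_e))
                r_ei = _coherence_row(run_simulation(cfg_ei))
                rows.append({
                    "inhibitory_fraction": frac, "g_Ks": g, "trial": trial,
                    "d_mpc_hub": r_e["mpc_hub"] - r_ei["mpc_hub"],
                    "d_mpc_nonhub": r_e["mpc_nonhub"] - r_ei["mpc_nonhub"],
                    "d_cc_hub": r_e["cc_hub"] - r_ei["cc_hub"],
                    "d_cc_nonhub": r_e["cc_nonhub"] - r_ei["cc_nonhub"],
                })
    return ExperimentResult(pd.DataFrame(rows), ["inhibitory_fraction", "g_Ks"])


def hub_removal_experiment(base_config: SimulationConfig,
                           segment: float = 2000.0) -> ExperimentResult:
    """Run 2 s intact, silence every synapse touching the hub, run 2 s
    more, and compare non-hub MPC/CC between the second halves of the two
    segments (pre minus post)."""
    rows = []
    for trial, cfg in _trial_configs(base_config, base_config.n_trials):
        netcfg = replace(cfg.effective_network(),
                         seed=int(_spawn_seeds(cfg.seed, 3)[0]))
        topo = build_network(netcfg)
        res1 = run_simulation(replace(cfg, duration=segment), topology=topo)
        topo_cut = remove_hub(topo)
        res2 = run_simulation(
            replace(cfg, duration=segment,
                    seed=int(_spawn_seeds(cfg.seed, 4)[3])),
            topology=topo_cut)
        nonhub = np.setdiff1d(topo.excitatory, topo.hub)

        def _nonhub_measures(res):
            data = measures.SpikeData(
                [res.spikes.trains[i] for i in nonhub],
                res.spikes.t_start, res.spikes.t_end)
            m = measures.network_mpc(data)
            c = measures.network_cc(data)
            return m["network"], c["network"]

        mpc1, cc1 = _nonhub_measures(res1)
        mpc2, cc2 = _nonhub_measures(res2)
        rows.append({"g_Ks": cfg.g_Ks, "trial": trial,
                     "mpc_pre": mpc1, "mpc_post": mpc2,
                     "cc_pre": cc1, "cc_post": cc2,
                     "d_mpc": mpc1 - mpc2, "d_cc": cc1 - cc2})
    return ExperimentResult(pd.DataFrame(rows), ["g_Ks"])


def stdp_reorganization(base_config: SimulationConfig, gks_list,
                        pin_list=None, duration: float = 3000.0
                        ) -> ExperimentResult:
    """Region-resolved normalized synaptic change after ``duration`` ms of
    activity with STDP enabled."""
    if pin_list is None:
        pin_list = [base_config.network.p_in]
    rows = []
    for p_in in pin_list:
        for g in gks_list:
            cfg0 = replace(base_config,
                           network=replace(base_config.network, p_in=p_in),
                           g_Ks=g, duration=duration,
                           plasticity=replace(base_config.plasticity,
                                              enabled=True))
            for trial, cfg in _trial_configs(cfg0, base_config.n_trials):
                res = run_simulation(cfg)
                delta = measures.region_delta(
                    res.w_before, res.w_after, res.topology.hub,
                    res.topology.w0_exc)
                row = {"p_in": p_in, "g_Ks": g, "trial": trial}
                row.update({k: v for k, v in delta.items()
                            if not k.startswith("n_")})
                rows.append(row)
    return ExperimentResult(pd.DataFrame(rows), ["p_in", "g_Ks"])


@dataclass
class WakeSleepResult:
    trials: pd.DataFrame          # per-trial slope, R^2
    points: pd.DataFrame          # per-trial per-neuron (f_pre, df)
    slope_mean: float             # mean of per-trial slopes
    slope_sem: float
    r2_mean: float                # mean of per-trial R^2
    slope: float = float("nan")   # OLS on trial-averaged per-neuron points
    r2: float = float("nan")


def wake_sleep_wake(base_config: SimulationConfig,
                    wake_gks: float = 0.0, sleep_gks: float = 1.5,
                    segment: float = 3000.0) -> WakeSleepResult:
    """The 9-s wake-sleep-wake protocol.

    Three equal segments: high ACh (g_Ks = 0, weights frozen), low ACh
    (g_Ks = 1.5, STDP active), high ACh again (weights frozen).  Firing
    frequency is measured over the latter 2 s of each wake segment and the
    per-neuron change df = f_post - f_pre is regressed on f_pre by OLS.

    The headline ``slope``/``r2`` come from the fit to trial-averaged
    per-neuron points (neuron index is comparable across trials because
    the growth process ties index to degree); per-trial fits and their
    across-trial mean are reported alongside.
    """
    schedule = [Segment(segment, wake_gks, False),
                Segment(segment, sleep_gks, True),
                Segment(segment, wake_gks, False)]
    rows, pts = [], []
    for trial, cfg in _trial_configs(base_config, base_config.n_trials):
        res = run_simulation(cfg, schedule=schedule)
        f_pre = measures.firing_frequency(res.spikes,
                                          (segment - 2000.0, segment))
        f_post = measures.firing_frequency(
            res.spikes, (3 * segment - 2000.0, 3 * segment))
        df = f_post - f_pre
        fit = stats.linregress(f_pre, df)
        rows.append({"trial": trial, "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "r2": float(fit.rvalue ** 2),
                     "mean_df": float(df.mean())})
        for i in range(len(f_pre)):
            pts.append({"trial": trial, "neuron": i,
                        "f_pre": float(f_pre[i]), "df": float(df[i])})
    tdf = pd.DataFrame(rows)
    pdf = pd.DataFrame(pts)
    avg = pdf.groupby("neuron")[["f_pre", "df"]].mean()
    pooled = stats.linregress(avg["f_pre"], avg["df"])
    return WakeSleepResult(
        trials=tdf, points=pdf,
        slope_mean=float(tdf["slope"].mean()),
        slope_sem=float(tdf["slope"].sem()),
        r2_mean=float(tdf["r2"].mean()),
        slope=float(pooled.slope), r2=float(pooled.rvalue ** 2))
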