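"""Single-cell biophysical model and its characterization.

The neuron is a Hodgkin-Huxley-type point model with a transient sodium
current, a delayed-rectifier potassium current, a leak current, and a slow,
low-threshold, non-inactivating M-type potassium current gated by ``z``.
The maximal M-conductance ``g_Ks`` is the model's proxy for (inverse)
acetylcholine level: ``g_Ks = 0`` corresponds to high ACh (waking cortex,
Type I excitability), ``g_Ks = 1.5 mS/cm**2`` to low ACh (slow-wave sleep,
Type II excitability).

Units follow the usual conductance-based conventions: mV, ms, mS/cm**2,
uA/cm**2, uF/cm**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import _core

__all__ = [
    "NeuronParams",
    "NeuronStateArray",
    "StimulusConfig",
    "gating_functions",
    "membrane_derivatives",
    "rk4_step",
    "generate_noise",
    "detect_spikes",
    "simulate_single_neuron",
    "f_i_curve",
    "select_drive",
    "compute_prc",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters.  Defaults are the values used throughout."""

    C: float = 1.0          # membrane capacitance, uF/cm^2
    g_Na: float = 24.0      # sodium conductance, mS/cm^2
    g_Kdr: float = 3.0      # delayed-rectifier conductance, mS/cm^2
    g_Ks: float = 0.0       # M-current conductance, mS/cm^2 (0 = high ACh)
    g_L: float = 0.02       # leak conductance, mS/cm^2
    E_Na: float = 55.0      # mV
    E_K: float = -90.0      # mV
    E_L: float = -60.0      # mV
    tau_z: float = 75.0     # M-current gate time constant, ms

    def __post_init__(self) -> None:
        for name in ("C", "g_Na", "g_Kdr", "g_Ks", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("reversal potentials must satisfy E_K < E_L < E_Na")

    def with_gks(self, g_Ks: float) -> "NeuronParams":
        return replace(self, g_Ks=g_Ks)

    def as_tuple(self) -> tuple:
        """Flat parameter tuple consumed by the compiled kernels."""
        return (self.C, self.g_Na, self.g_Kdr, self.g_Ks, self.g_L,
                self.E_Na, self.E_K, self.E_L, self.tau_z)


@dataclass
class NeuronStateArray:
    """Per-neuron dynamical state (V, h, n, z)."""

    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    z: np.ndarray

    @classmethod
    def initial(cls, n_neurons: int, rng: np.random.Generator | None = None,
                V: float | None = None) -> "NeuronStateArray":
        """Standard initial condition: V ~ Uniform[-70, 0] mV (or fixed),
        h = 1 and all other gates 0."""
        if V is not None:
            V0 = np.full(n_neurons, float(V))
        else:
            if rng is None:
                raise ValueError("need an rng for random initial voltages")
            V0 = rng.uniform(-70.0, 0.0, size=n_neurons)
        return cls(V=V0, h=np.ones(n_neurons), n=np.zeros(n_neurons),
                   z=np.zeros(n_neurons))

    def copy(self) -> "NeuronStateArray":
        return NeuronStateArray(self.V.copy(), self.h.copy(),
                                self.n.copy(), self.z.copy())


@dataclass(frozen=True)
class StimulusConfig:
    """Constant drive plus the random pulse-noise process.

    The noise is a train of square current pulses: at every integration step
    each neuron independently initiates a pulse with probability
    ``noise_prob_per_step``; a pulse holds ``noise_amplitude`` for
    ``noise_duration`` ms, and a new initiation during an active pulse
    restarts its clock (amplitudes do not stack).  At the default 2% per
    0.1 ms step this yields ~200 initiation events per second per neuron.
    """

    I_drive: float = 0.0            # uA/cm^2
    noise_amplitude: float = 0.7    # uA/cm^2
    noise_duration: float = 2.0     # ms
    noise_prob_per_step: float = 0.02
    dt: float = 0.1                 # ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.noise_prob_per_step <= 1.0:
            raise ValueError("noise_prob_per_step must be in [0, 1]")


def gating_functions(V):
    """Steady-state activations and time constants at voltage ``V`` (mV).

    Returns a dict with ``m_inf, h_inf, tau_h, n_inf, tau_n, z_inf``.
    All sigmoids lie in (0, 1) and the time constants are positive; the
    evaluation is overflow-safe at extreme voltages.
    """
    V = np.asarray(V, dtype=float)
    return {
        "m_inf": expit((V + 30.0) / 9.5),
        "h_inf": expit(-(V + 53.0) / 7.0),
        "tau_h": 0.37 + 2.78 * expit(-(V + 40.5) / 6.0),
        "n_inf": expit((V + 30.0) / 10.0),
        "tau_n": 0.37 + 1.85 * expit(-(V + 27.0) / 15.0),
        "z_inf": expit((V + 39.0) / 5.0),
    }


def membrane_derivatives(state: NeuronStateArray, params: NeuronParams,
                         I_drive=0.0, I_noise=0.0, I_syn=0.0):
    """Right-hand side of the membrane equations.

    ``I_syn`` enters with a minus sign (it is a current *received through
    synapses*, positive values hyperpolarize).  Returns (dV, dh, dn, dz)
    in units per ms.
    """
    V, h, n, z = state.V, state.h, state.n, state.z
    if np.any(~np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise FloatingPointError(f"non-finite voltage at neuron {bad}")
    g = gating_functions(V)
    I_ion = (params.g_Na * g["m_inf"] ** 3 * h * (V - params.E_Na)
             + params.g_Kdr * n ** 4 * (V - params.E_K)
             + params.g_Ks * z * (V - params.E_K)
             + params.g_L * (V - params.E_L))
    dV = (-I_ion + I_drive + I_noise - I_syn) / params.C
    dh = (g["h_inf"] - h) / g["tau_h"]
    dn = (g["n_inf"] - n) / g["tau_n"]
    dz = (g["z_inf"] - z) / params.tau_z
    return dV, dh, dn, dz


def rk4_step(state: NeuronStateArray, params: NeuronParams, dt: float,
             I_drive=0.0, I_noise=0.0, I_syn=0.0) -> NeuronStateArray:
    """One classical Runge-Kutta 4 step of the full state.

    External currents are held constant across the four substages (they are
    defined per integration step).  Gates are clipped to [0, 1] afterwards
    to guard against O(dt^4) overshoot.
    """

    def f(s):
        return membrane_derivatives(s, params, I_drive, I_noise, I_syn)

    def shift(s, k, a):
        return NeuronStateArray(s.V + a * k[0], s.h + a * k[1],
                                s.n + a * k[2], s.z + a * k[3])

    k1 = f(state)
    k2 = f(shift(state, k1, dt / 2))
    k3 = f(shift(state, k2, dt / 2))
    k4 = f(shift(state, k3, dt))
    out = NeuronStateArray(
        state.V + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        state.h + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        state.n + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        state.z + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
    )
    np.clip(out.h, 0.0, 1.0, out=out.h)
    np.clip(out.n, 0.0, 1.0, out=out.n)
    np.clip(out.z, 0.0, 1.0, out=out.z)
    return out


def generate_noise(n_neurons: int, n_steps: int, config: StimulusConfig,
                   seed: int | np.random.Generator,
                   return_initiations: bool = False):
    """Dense (n_neurons, n_steps) array of the pulse-noise current.

    With ``return_initiations`` also returns the boolean initiation-event
    array (a pulse initiated during an active pulse restarts the clock, so
    initiations are not recoverable from the merged current trace).
    """
    if config.noise_duration < config.dt:
        raise ValueError("noise_duration must be at least one step")
    rng = np.random.default_rng(seed)
    p = config.noise_prob_per_step
    starts = rng.random((n_neurons, n_steps)) < p
    pulse_steps = int(round(config.noise_duration / config.dt))
    active = np.zeros((n_neurons, n_steps), dtype=bool)
    for k in range(pulse_steps):
        active[:, k:] |= starts[:, : n_steps - k] if k else starts
    current = np.where(active, config.noise_amplitude, 0.0)
    return (current, starts) if return_initiations else current


def detect_spikes(V_trace: np.ndarray, dt: float, t_offset: float = 0.0) -> np.ndarray:
    """Spike times (ms) of the upward crossings of 0 mV.

    A spike is registered at sample ``k`` whenever ``V[k-1] <= 0 < V[k]``;
    a trace that starts above threshold and never re-crosses produces no
    spike, and supra-threshold plateaus count once.
    """
    V = np.asarray(V_trace, dtype=float)
    idx = np.flatnonzero((V[:-1] <= 0.0) & (V[1:] > 0.0)) + 1
    return t_offset + idx * dt


def simulate_single_neuron(params: NeuronParams, I_drive: float,
                           duration: float, dt: float = 0.1,
                           V0: float = -70.0,
                           noise: StimulusConfig | None = None,
                           seed: int = 0,
                           pert_time: float = -1.0,
                           pert_weight: float = 0.0) -> np.ndarray:
    """Integrate one isolated neuron and return its voltage trace.

    ``pert_time``/``pert_weight`` optionally inject a single excitatory
    synaptic-kernel conductance pulse (the probe used for phase-response
    curves).  Returns V at samples 0..n_steps.
    """
    n_steps = int(round(duration / dt))
    amp, p, pulse = 0.0, 0.0, 1
    if noise is not None:
        amp = noise.noise_amplitude
        p = noise.noise_prob_per_step
        pulse = int(round(noise.noise_duration / noise.dt))
    return _core.simulate_single(params.as_tuple(), I_drive, n_steps, dt, V0,
                                 amp, p, pulse, int(seed),
                                 float(pert_time), float(pert_weight))


def f_i_curve(params: NeuronParams, currents: Sequence[float],
              duration: float = 2000.0, dt: float = 0.1) -> np.ndarray:
    """Firing rate versus applied current for an isolated, noiseless neuron.

    Each current is applied from rest for ``duration`` ms; the first half is
    discarded as transient and the steady-state rate (spikes/s) is measured
    over the second half.  Returns an (len(currents), 2) array of
    (I, rate_Hz).

    With g_Ks = 0 the onset is Type I: the rate rises continuously from
    0 Hz above rheobase.  With g_Ks = 1.5 the onset is Type II: the rate
    jumps discontinuously at rheobase.
    """
    currents = np.asarray(list(currents), dtype=float)
    if currents.size == 0:
        raise ValueError("current grid is empty")
    out = np.empty((currents.size, 2))
    half = duration / 2.0
    for k, I in enumerate(currents):
        V = simulate_single_neuron(params, I, duration, dt)
        t = detect_spikes(V, dt)
        rate = np.count_nonzero(t >= half) / (half / 1000.0)
        out[k] = (I, rate)
    return out


_drive_cache: dict[tuple, float] = {}


def select_drive(params: NeuronParams, currents: Sequence[float],
                 duration: float = 2000.0, dt: float = 0.1) -> float:
    """Largest grid current that produces no spike over ``duration`` ms.

    This is the "highest applied subthreshold current" used as the constant
    drive in network simulations.  Sub/supra-threshold is judged on the
    steady state (the second half of the run, as in the f-I curve), so an
    onset transient from the resting initial condition does not count as
    firing.  The grid is scanned from the top, which realizes the
    definition exactly even if firing were non-monotone in I; the result is
    cached per parameter set.
    """
    grid = np.asarray(list(currents), dtype=float)
    if grid.size == 0:
        raise ValueError("current grid is empty")
    key = (params.as_tuple(), round(float(grid[0]), 12),
           round(float(grid[-1]), 12), grid.size, duration, dt)
    if key in _drive_cache:
        return _drive_cache[key]

    def fires(I: float) -> bool:
        V = simulate_single_neuron(params, I, duration, dt)
        t = detect_spikes(V, dt)
        return np.count_nonzero(t >= duration / 2.0) > 0

    result = None
    for I in grid[::-1]:
        if not fires(I):
            result = float(I)
            break
    if result is None:
        raise ValueError("grid below rheobase exhausted")
    _drive_cache[key] = result
    return result


def _find_periodic_drive(params: NeuronParams, dt: float,
                         target_hz: float = 7.5) -> tuple[float, float]:
    """Smallest 0.01-grid current giving regular firing at or above
    ``target_hz``; returns (I, period_ms).

    Targeting the middle of the 5-10 Hz band keeps the Type II operating
    point safely away from the bistable region just above its rheobase,
    where a synaptic perturbation can terminate the oscillation.
    """
    for I in np.arange(-0.5, 5.0, 0.01):
        V = simulate_single_neuron(params, I, 3000.0, dt)
        t = detect_spikes(V, dt)
        t = t[t >= 1000.0]
        if t.size < 4:
            continue
        isi = np.diff(t)
        rate = 1000.0 / isi.mean()
        if rate < target_hz:
            continue
        if np.std(isi) / np.mean(isi) > 1e-3:
            continue
        return float(I), float(isi.mean())
    raise ValueError("no periodic firing found at the target rate")


def compute_prc(params: NeuronParams, I_suprathreshold: float | None = None,
                perturbation_weight: float = 0.04, n_phases: int = 50,
                dt: float = 0.1) -> np.ndarray:
    """Phase response curve of the periodically firing neuron.

    A brief excitatory synaptic-kernel pulse (conductance
    ``perturbation_weight`` mS/cm^2, E_syn = 0 mV) is delivered at each of
    ``n_phases`` equally spaced phases of the unperturbed period T0, and the
    normalized shift (T0 - T_perturbed)/T0 of the next spike is reported
    (positive = phase advance).

    Type I neurons (g_Ks = 0) have a strictly positive PRC; Type II neurons
    (g_Ks = 1.5) are biphasic, with delays at early phases.
    """
    if I_suprathreshold is None:
        I_suprathreshold, _ = _find_periodic_drive(params, dt)
    V = simulate_single_neuron(params, I_suprathreshold, 3000.0, dt)
    spikes = detect_spikes(V, dt)
    late = spikes[spikes >= 1000.0]
    if late.size < 4:
        raise ValueError("neuron is not firing periodically under this drive")
    isi = np.diff(late)
    if np.std(isi) / np.mean(isi) > 1e-3:
        raise ValueError("neuron is not firing periodically under this drive")
    T0 = float(np.mean(isi))
    t_ref = float(late[0])

    phases = (np.arange(n_phases) + 0.5) / n_phases
    out = np.empty((n_phases, 2))
    for k, phi in enumerate(phases):
        t_pert = t_ref + phi * T0
        Vp = simulate_single_neuron(params, I_suprathreshold,
                                    t_ref + 4.0 * T0, dt,
                                    pert_time=t_pert,
                                    pert_weight=perturbation_weight)
        sp = detect_spikes(Vp, dt)
        nxt = sp[sp > t_ref + 0.5 * dt]
        if nxt.size == 0:
            raise ValueError("perturbed run lost its spiking")
        T_pert = float(nxt[0]) - t_ref
        out[k] = (phi, (T0 - T_pert) / T0)
    return out
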