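"""Membrane model, integrator, noise, spike detection, f-I and drive."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from achnet import _core
from achnet.neuron import (NeuronParams, NeuronStateArray, StimulusConfig,
                           detect_spikes, f_i_curve, gating_functions,
                           generate_noise, membrane_derivatives, rk4_step,
                           select_drive, simulate_single_neuron, compute_prc)

DT = 0.1


class TestGating:
    def test_sigmoid_midpoints(self):
        g = gating_functions(-30.0)
        assert g["m_inf"] == pytest.approx(0.5)
        assert g["n_inf"] == pytest.approx(0.5)
        assert gating_functions(-39.0)["z_inf"] == pytest.approx(0.5)
        assert gating_functions(-53.0)["h_inf"] == pytest.approx(0.5)

    def test_time_constant_midpoints(self):
        assert gating_functions(-40.5)["tau_h"] == pytest.approx(0.37 + 2.78 / 2)
        assert gating_functions(-27.0)["tau_n"] == pytest.approx(0.37 + 1.85 / 2)

    def test_z_closed_form(self):
        assert gating_functions(-14.0)["z_inf"] == pytest.approx(
            1.0 / (1.0 + math.exp(-5.0)), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-500.0, max_value=500.0))
    def test_bounded_and_overflow_safe(self, V):
        g = gating_functions(V)
        for k in ("m_inf", "h_inf", "n_inf", "z_inf"):
            assert 0.0 <= g[k] <= 1.0
        assert g["tau_h"] > 0 and g["tau_n"] > 0
        assert all(np.isfinite(v) for v in g.values())


class TestDerivatives:
    def test_pure_capacitor(self):
        p = NeuronParams(g_Na=0, g_Kdr=0, g_Ks=0, g_L=0)
        s = NeuronStateArray(np.array([-50.0]), np.array([0.5]),
                            np.array([0.5]), np.array([0.5]))
        dV, _, _, _ = membrane_derivatives(s, p, I_drive=1.0)
        assert dV[0] == pytest.approx(1.0)

    def test_leak_only_at_potassium_reversal(self):
        p = NeuronParams()
        s = NeuronStateArray(np.array([-90.0]), np.array([0.0]),
                            np.array([0.0]), np.array([0.0]))
        dV, _, _, _ = membrane_derivatives(s, p)
        assert dV[0] == pytest.approx(-0.02 * (-90.0 + 60.0))  # = +0.6 mV/ms

    def test_steady_state_is_fixed_point(self):
        # solve dV/dt = 0 with gates at steady state, subthreshold drive
        from scipy.optimize import brentq
        p = NeuronParams(g_Ks=1.5)

        def f(V):
            g = gating_functions(V)
            s = NeuronStateArray(np.array([V]), np.array([g["h_inf"]]),
                                np.array([g["n_inf"]]), np.array([g["z_inf"]]))
            return membrane_derivatives(s, p, I_drive=0.5)[0][0]

        V0 = brentq(f, -80.0, -40.0)
        g = gating_functions(V0)
        s = NeuronStateArray(np.array([V0]), np.array([g["h_inf"]]),
                            np.array([g["n_inf"]]), np.array([g["z_inf"]]))
        derivs = membrane_derivatives(s, p, I_drive=0.5)
        assert all(abs(d[0]) < 1e-9 for d in derivs)

    def test_nan_state_raises(self):
        s = NeuronStateArray(np.array([np.nan]), np.array([1.0]),
                            np.array([0.0]), np.array([0.0]))
        with pytest.raises(FloatingPointError):
            membrane_derivatives(s, NeuronParams())


class TestRK4:
    def test_linear_drift_exact(self):
        p = NeuronParams(g_Na=0, g_Kdr=0, g_Ks=0, g_L=0)
        s = NeuronStateArray(np.array([-60.0]), np.array([0.5]),
                            np.array([0.5]), np.array([0.5]))
        out = rk4_step(s, p, DT, I_drive=2.0)
        assert out.V[0] == pytest.approx(-60.0 + 2.0 * DT, abs=1e-14)

    def test_leak_decay_matches_closed_form(self):
        p = NeuronParams(g_Na=0, g_Kdr=0, g_Ks=0)
        s = NeuronStateArray(np.array([0.0]), np.array([1.0]),
                            np.array([0.0]), np.array([0.0]))
        tau = p.C / p.g_L
        for k in range(2000):
            s = rk4_step(s, p, DT)
        expected = p.E_L + 60.0 * math.exp(-2000 * DT / tau)
        assert s.V[0] == pytest.approx(expected, rel=1e-8)

    def test_vectorized_matches_scalar_kernel(self, rng):
        p = NeuronParams(g_Ks=1.0)
        n = 5
        s = NeuronStateArray(rng.uniform(-70, -50, n), rng.random(n),
                            rng.random(n) * 0.3, rng.random(n) * 0.2)
        V, h, nn, z = (s.V.copy(), s.h.copy(), s.n.copy(), s.z.copy())
        for _ in range(1000):
            s = rk4_step(s, p, DT, I_drive=0.3)
            for i in range(n):
                V[i], h[i], nn[i], z[i] = _core._rk4(
                    V[i], h[i], nn[i], z[i], *p.as_tuple(), 0.3, DT)
        assert np.abs(s.V - V).max() < 1e-12
        assert np.abs(s.h - h).max() < 1e-12

    def test_gate_bounds_preserved(self):
        p = NeuronParams(g_Ks=1.5)
        V = simulate_single_neuron(p, 2.0, 1000.0, DT,
                                   noise=StimulusConfig(noise_amplitude=4.0,
                                                        noise_prob_per_step=0.01),
                                   seed=3)
        assert V.min() > -110.0 and V.max() < 75.0

    def test_step_halving_shifts_early_spikes_less_than_dt(self):
        p = NeuronParams(g_Ks=1.5)
        s1 = detect_spikes(simulate_single_neuron(p, 1.3, 2000.0, 0.1), 0.1)
        s2 = detect_spikes(simulate_single_neuron(p, 1.3, 2000.0, 0.05), 0.05)
        assert len(s1) == len(s2)
        # early spike times agree to within the coarse-grid quantization
        assert np.abs(s1[:5] - s2[:5]).max() <= 0.2
        # accumulated period error stays below 1e-4 relative
        T1 = np.diff(s1).mean()
        T2 = np.diff(s2).mean()
        assert abs(T1 - T2) / T2 < 1e-4


class TestNoise:
    def test_zero_probability_silent(self):
        cfg = StimulusConfig(noise_prob_per_step=0.0)
        assert not generate_noise(3, 100, cfg, 0).any()

    def test_always_on_is_constant(self):
        cfg = StimulusConfig(noise_prob_per_step=1.0)
        cur = generate_noise(2, 50, cfg, 1)
        assert np.all(cur == cfg.noise_amplitude)

    def test_initiation_rate_calibration_short(self):
        cfg = StimulusConfig()
        n_steps = 100_000  # 10 s
        _, starts = generate_noise(1, n_steps, cfg, 7, return_initiations=True)
        rate = starts.sum() / (n_steps * cfg.dt / 1000.0)
        se = math.sqrt(n_steps * 0.02 * 0.98) / (n_steps * cfg.dt / 1000.0)
        assert abs(rate - 200.0) < 3 * se

    def test_pulse_duration(self):
        cfg = StimulusConfig(noise_prob_per_step=0.001)
        cur, starts = generate_noise(1, 50_000, cfg, 11,
                                     return_initiations=True)
        # isolated initiations yield exactly 20 active steps
        on = np.flatnonzero(np.diff((cur[0] > 0).astype(int)) == 1) + 1
        offs = np.flatnonzero(np.diff((cur[0] > 0).astype(int)) == -1) + 1
        lengths = offs - on[: offs.size]
        iso = lengths[lengths == 20]
        assert iso.size > 0  # most pulses are isolated at this rate


class TestDetectSpikes:
    def test_sine_crossings(self):
        t = np.arange(0, 1000.0, DT)
        V = 10 * np.sin(2 * np.pi * 10 * t / 1000.0)  # 10 Hz
        sp = detect_spikes(V, DT)
        assert sp.size == 10
        expected = np.arange(10) * 100.0
        assert np.abs(sp - expected).max() <= DT + 1e-9

    def test_no_crossing_cases(self):
        assert detect_spikes(np.full(100, -50.0), DT).size == 0
        assert detect_spikes(np.full(100, +10.0), DT).size == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(min_value=-40, max_value=40), min_size=2,
                    max_size=60))
    def test_one_spike_per_upward_crossing(self, vals):
        V = np.asarray(vals)
        sp = detect_spikes(V, DT)
        manual = sum(1 for k in range(1, len(V))
                     if V[k - 1] <= 0.0 < V[k])
        assert sp.size == manual


class TestExcitabilityClasses:
    def test_type_one_continuous_onset(self):
        p = NeuronParams(g_Ks=0.0)
        fi = f_i_curve(p, np.arange(-0.16, -0.05, 0.01))
        nz = fi[fi[:, 1] > 0]
        assert nz.size and nz[0, 1] < 5.0  # approaches 0 Hz continuously

    def test_type_two_discontinuous_onset_and_flatness(self):
        lo = f_i_curve(NeuronParams(g_Ks=1.5), np.arange(1.0, 1.61, 0.05))
        nz = lo[lo[:, 1] > 0]
        assert nz[0, 1] >= 5.0  # finite jump at rheobase
        # flat f-I: one full extra uA/cm^2 less than doubles the rate
        hi = f_i_curve(NeuronParams(g_Ks=1.5), [nz[0, 0] + 1.0])
        assert hi[0, 1] < 2 * nz[0, 1]

    def test_rheobase_increases_with_gks(self):
        grid = np.arange(-0.5, 2.5, 0.05)
        d0 = select_drive(NeuronParams(g_Ks=0.0), grid)
        d15 = select_drive(NeuronParams(g_Ks=1.5), grid)
        assert d15 > d0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            f_i_curve(NeuronParams(), [])
        with pytest.raises(ValueError):
            select_drive(NeuronParams(), [])


class TestSelectDrive:
    def test_zero_grid_subthreshold_at_high_gks(self):
        assert select_drive(NeuronParams(g_Ks=1.5), [0.0]) == 0.0

    def test_all_suprathreshold_raises(self):
        with pytest.raises(ValueError, match="rheobase"):
            select_drive(NeuronParams(g_Ks=0.0), [0.5, 1.0])

    def test_below_smallest_spiking_current(self):
        grid = np.arange(0.5, 2.0, 0.05)
        p = NeuronParams(g_Ks=1.5)
        d = select_drive(p, grid)
        rates = f_i_curve(p, grid)
        spiking = rates[rates[:, 1] > 0][:, 0]
        assert d < spiking.min()

    def test_refinement_consistency(self):
        p = NeuronParams(g_Ks=1.5)
        coarse = select_drive(p, np.arange(0.8, 1.6, 0.04))
        fine = select_drive(p, np.arange(0.8, 1.6, 0.02))
        assert abs(fine - coarse) < 0.04 + 1e-12


class TestPRC:
    def test_zero_perturbation_zero_shift(self):
        prc = compute_prc(NeuronParams(g_Ks=0.0), perturbation_weight=0.0,
                          n_phases=4)
        assert np.abs(prc[:, 1]).max() < 1e-12
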