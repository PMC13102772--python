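"""Hodgkin-Huxley cable dynamics: rates, drive, integration, wrapping."""

import numpy as np
import pytest

from tiesim.cable import (
    SimConfig,
    activating_drive,
    gate_rates,
    simulate_axon,
    wrap_drive,
)
from tiesim.field import AxonPotentialSeries
from tiesim.metrics import count_aps, detect_aps


def bump_drive(positions, config, windows_ms, amp_mv=50.0, width_nodes=1.5,
               center=25, dt=None):
    """Synthetic focal extracellular pulse(s): negative V_e well centred
    on one node, switched on during the given windows."""
    dt = dt or config.dt
    n_w = round(config.t_window / dt)
    times = np.arange(n_w) * dt
    n = positions.shape[0]
    prof = amp_mv * np.exp(-0.5 * ((np.arange(n) - center) / width_nodes) ** 2)
    ve = np.zeros((n, n_w))
    for t_on, t_off in windows_ms:
        mask = (times >= t_on * 1e-3) & (times < t_off * 1e-3)
        ve[:, mask] = -prof[:, None]
    return AxonPotentialSeries(0, positions, times, ve)


class TestGateRates:
    def test_singularity_limits(self):
        a_m = gate_rates(-40.0)[0]
        assert a_m == pytest.approx(1.0, rel=1e-6)
        a_n = gate_rates(-55.0)[4]
        assert a_n == pytest.approx(0.1, rel=1e-6)
        # continuity across the singular voltage
        assert gate_rates(-40.0 + 1e-5)[0] == pytest.approx(a_m, rel=1e-4)
        assert gate_rates(-40.0 - 1e-5)[0] == pytest.approx(a_m, rel=1e-4)

    def test_steady_state_activation_at_rest(self):
        a_m, b_m, *_ = gate_rates(-65.0)
        assert a_m / (a_m + b_m) == pytest.approx(0.053, abs=0.002)

    def test_depolarized_asymptotes(self):
        a_m, b_m, a_h, b_h, _, _ = gate_rates(120.0)
        assert a_m / (a_m + b_m) > 0.999  # m_inf -> 1
        assert a_h / (a_h + b_h) < 0.001  # h_inf -> 0


class TestActivatingDrive:
    def test_linear_field_no_drive_interior(self):
        ve = np.linspace(0.0, 5.0, 11)
        d2 = activating_drive(ve, 0.1)
        assert np.allclose(d2[1:-1], 0.0, atol=1e-9)

    def test_quadratic_field_exact(self):
        x = np.arange(11) * 0.1
        d2 = activating_drive(x ** 2, 0.1)
        assert np.allclose(d2[1:-1], 2.0, atol=1e-9)

    def test_point_source_peak_at_closest_node(self):
        # surface point source above node 20 of a straight axon
        x = np.arange(51) * 0.1
        r = np.sqrt((x - x[20]) ** 2 + 0.5 ** 2)  # 0.5 mm standoff
        d2 = activating_drive(1.0 / r, 0.1)
        assert np.argmax(np.abs(d2[1:-1])) + 1 == 20

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            activating_drive(np.array([1.0, 2.0]), 0.1)


class TestWrapDrive:
    def test_constant_window_stays_constant(self, sim_config,
                                            straight_axon_positions):
        n_w = sim_config.n_window
        ve = np.full((51, n_w), 3.5)
        drv = AxonPotentialSeries(0, straight_axon_positions,
                                  sim_config.times_window(), ve)
        out = wrap_drive(drv, sim_config)
        assert np.all(out.ve == 3.5)
        assert out.ve.shape[1] == 2 * sim_config.n_guard + n_w + 1

    def test_periodic_window_wraps_to_time_shift(self, sim_config,
                                                 straight_axon_positions):
        # a sinusoid with integer cycles in T_w wraps into the same
        # sinusoid evaluated at t - T_guard, phase-continuous at seams
        t_w = sim_config.times_window()
        f = 1000.0
        ve = np.tile(np.sin(2 * np.pi * f * t_w), (51, 1))
        drv = AxonPotentialSeries(0, straight_axon_positions, t_w, ve)
        out = wrap_drive(drv, sim_config)
        expect = np.sin(2 * np.pi * f * (out.times - sim_config.t_guard))
        assert np.allclose(out.ve[0], expect, atol=1e-9)

    def test_two_tone_seam_continuity(self, sim_config,
                                      straight_axon_positions):
        t_w = sim_config.times_window()
        ve = np.tile(np.sin(2 * np.pi * 1000 * t_w)
                     + np.sin(2 * np.pi * 1030 * t_w), (51, 1))
        drv = AxonPotentialSeries(0, straight_axon_positions, t_w, ve)
        out = wrap_drive(drv, sim_config)
        ng = sim_config.n_guard
        for seam in (ng, ng + sim_config.n_window):
            jump = abs(out.ve[0, seam] - out.ve[0, seam - 1])
            interior = np.abs(np.diff(out.ve[0, ng:ng + 100])).max()
            assert jump <= interior * 1.5

    def test_non_periodic_window_falls_back_with_warning(
            self, sim_config, straight_axon_positions):
        t_w = sim_config.times_window()
        ve = np.tile(np.linspace(0, 10, t_w.size), (51, 1))  # ramp
        drv = AxonPotentialSeries(0, straight_axon_positions, t_w, ve)
        with pytest.warns(UserWarning, match="not periodic"):
            out = wrap_drive(drv, sim_config)
        assert np.all(out.ve[:, :sim_config.n_guard] == 0.0)


class TestSimulateAxon:
    def test_resting_stability(self, sim_config, cable_params,
                               straight_axon_positions):
        ve = np.zeros((51, sim_config.n_window))
        drv = wrap_drive(AxonPotentialSeries(0, straight_axon_positions,
                                             sim_config.times_window(), ve),
                         sim_config)
        tr = simulate_axon(drv, cable_params, sim_config)
        after_guard = tr.vm[:, sim_config.n_guard:]
        assert np.abs(after_guard - cable_params.v_rest).max() < 1.0
        assert count_aps(tr, sim_config) == 0
        assert tr.vm.min() > -120 and tr.vm.max() < 80

    def test_propagation_away_from_focus(self, sim_config, cable_params,
                                         straight_axon_positions):
        drv = wrap_drive(bump_drive(straight_axon_positions, sim_config,
                                    [(40, 45)]), sim_config)
        tr = simulate_axon(drv, cable_params, sim_config)
        # first -20 mV crossing occurs later at nodes farther from the
        # initiation focus (node 25): finite positive conduction speed.
        # (the window mask skips the equilibration transient in the
        # temporal pre-guard)
        t_first = []
        for node in range(25, 46, 5):
            idx = np.where((tr.vm[node] >= sim_config.v_thr)
                           & (tr.times >= 30.0))[0]
            assert idx.size, f"node {node} never crossed threshold"
            t_first.append(tr.times[idx[0]])
        assert all(b > a for a, b in zip(t_first, t_first[1:]))

    def test_ap_shape_overshoot_and_ahp(self, sim_config, cable_params,
                                        straight_axon_positions):
        drv = wrap_drive(bump_drive(straight_axon_positions, sim_config,
                                    [(40, 45)]), sim_config)
        tr = simulate_axon(drv, cable_params, sim_config)
        v40 = tr.vm[40]  # node away from the focus, inside the window
        peak = int(np.argmax(v40))
        assert v40[peak] > 0.0  # overshoot
        assert v40[peak:peak + 1500].min() < cable_params.v_rest - 1.0  # AHP

    def test_refractoriness(self, sim_config, cable_params,
                            straight_axon_positions):
        close = wrap_drive(bump_drive(straight_axon_positions, sim_config,
                                      [(40, 42), (44, 46)]), sim_config)
        apart = wrap_drive(bump_drive(straight_axon_positions, sim_config,
                                      [(40, 42), (72, 74)]), sim_config)
        n_close = count_aps(simulate_axon(close, cable_params, sim_config),
                            sim_config)
        n_apart = count_aps(simulate_axon(apart, cable_params, sim_config),
                            sim_config)
        assert n_apart == 2
        assert n_close < n_apart

    def test_time_step_convergence(self, cable_params,
                                   straight_axon_positions):
        counts, times = [], []
        for dt in (10e-6, 5e-6):
            cfg = SimConfig(dt=dt)
            drv = wrap_drive(bump_drive(straight_axon_positions, cfg,
                                        [(40, 45)], dt=dt), cfg)
            tr = simulate_axon(drv, cable_params, cfg)
            ev = [e for e in detect_aps(tr, cfg) if e.counted]
            counts.append(len(ev))
            times.append(sorted(e.initiation_time for e in ev))
        assert counts[0] == counts[1]
        assert np.allclose(times[0], times[1], atol=0.1)  # ms

    def test_wrong_length_drive_rejected(self, sim_config, cable_params,
                                         straight_axon_positions):
        ve = np.zeros((51, 100))
        drv = AxonPotentialSeries(0, straight_axon_positions,
                                  np.arange(100) * sim_config.dt, ve)
        with pytest.raises(ValueError):
            simulate_axon(drv, cable_params, sim_config)

    def test_membrane_lowpass_attenuates_high_carriers(
            self, sim_config, cable_params, straight_axon_positions):
        # fixed-amplitude unmodulated sinusoidal drive: AP count is
        # non-increasing in carrier frequency over 1-4 kHz
        t_w = sim_config.times_window()
        n = straight_axon_positions.shape[0]
        prof = np.exp(-0.5 * ((np.arange(n) - 25) / 1.5) ** 2)
        counts = []
        for fc in (1000.0, 2000.0, 3000.0, 4000.0):
            ve = -80.0 * prof[:, None] * np.sin(2 * np.pi * fc * t_w)[None, :]
            drv = wrap_drive(
                AxonPotentialSeries(0, straight_axon_positions, t_w, ve),
                sim_config)
            tr = simulate_axon(drv, cable_params, sim_config)
            counts.append(count_aps(tr, sim_config))
        assert counts[0] > 0
        assert all(a >= b for a, b in zip(counts, counts[1:]))
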