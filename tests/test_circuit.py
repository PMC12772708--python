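"""Circuit data model and time-domain solver."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemocal.circuit import (Component, DivergenceError, InputError,
                             InvalidParameterError, Netlist, NotApplicableError,
                             SolverSettings, StructuralError, Waveform,
                             assemble_system, cycle_metrics, simulate,
                             total_stressed_volume)
from hemocal.model import build_stage_netlist
from hemocal.units import MMHG

from conftest import constant_inflow, pulsatile_inflow, windkessel_netlist


class TestValidation:
    def test_zero_valued_element_rejected(self):
        with pytest.raises(InvalidParameterError):
            Component("resistor", "R", "a", "b", value=0.0)

    def test_self_loop_rejected(self):
        with pytest.raises(InvalidParameterError):
            Component("capacitor", "C", "a", "a", value=1.0)

    def test_disconnected_netlist_is_structural_error(self):
        net = Netlist(components=[
            Component("resistor", "R1", "a", "ground", value=1.0),
            Component("resistor", "R2", "x", "y", value=1.0),
        ])
        with pytest.raises(StructuralError, match="disconnected"):
            assemble_system(net, SolverSettings())

    def test_unresolvable_controller_rejected(self):
        net = Netlist(components=[
            Component("controlled_resistor", "V", "a", "ground",
                      params={"r_on": 1e-3, "r_off": 1e3,
                              "rs_controller": "ghost"}),
        ])
        with pytest.raises(StructuralError, match="ghost"):
            net.validate()

    def test_solver_settings_invariants(self):
        with pytest.raises(InvalidParameterError):
            SolverSettings(time_step=0.9, heart_period=0.8)
        with pytest.raises(InvalidParameterError):
            SolverSettings(periodicity_tolerance=0.0)


class TestAssembly:
    def test_windkessel_state_dimension_is_one(self):
        sys_ = assemble_system(windkessel_netlist(inflow=constant_inflow()),
                               SolverSettings())
        assert sys_.state_dim == 1

    def test_state_dimension_counts_storage_elements(self, moderate_patient):
        net = build_stage_netlist(moderate_patient.model, stage=3)
        n_c = sum(1 for c in net.components if c.kind == "capacitor")
        n_l = sum(1 for c in net.components if c.kind == "inductor")
        n_ch = sum(1 for c in net.components if c.kind == "elastance_chamber")
        sys_ = assemble_system(net, moderate_patient.model.solver_settings())
        assert sys_.state_dim == n_c + n_l + n_ch


class TestCycleMetrics:
    def test_constant_waveform(self):
        t = np.linspace(0, 0.8, 101)
        m = cycle_metrics(Waveform(t, np.full_like(t, 50.0)))
        assert m["P_mean"] == pytest.approx(50.0)
        assert m["P_pulse"] == pytest.approx(0.0)

    def test_sinusoid_closed_form(self):
        t = np.linspace(0, 1.0, 4001)
        wf = Waveform(t, 100 + 20 * np.sin(2 * np.pi * t))
        m = cycle_metrics(wf)
        assert m["P_sys"] == pytest.approx(120, abs=1e-4)
        assert m["P_dia"] == pytest.approx(80, abs=1e-4)
        assert m["P_pulse"] == pytest.approx(40, abs=2e-4)
        assert m["P_mean"] == pytest.approx(100, abs=1e-6)

    def test_against_direct_quadrature(self, moderate_patient):
        wf = moderate_patient.simulation.node_pressure_waveforms["MPA"]
        m = cycle_metrics(wf)
        period = wf.times[-1] - wf.times[0]
        assert m["P_mean"] == pytest.approx(
            float(np.trapezoid(wf.values, wf.times)) / period, rel=1e-12)
        assert m["P_sys"] == float(np.max(wf.values))
        assert m["P_dia"] == float(np.min(wf.values))

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(InputError):
            cycle_metrics(Waveform(t, np.ones_like(t)))


class TestWindkesselSteadyState:
    def test_constant_inflow_matches_algebraic_solution(self):
        rp, rd, c, pd, q = 0.02, 0.10, 8.0, 5.0, 60000.0
        net = windkessel_netlist(rp, rd, c, pd, constant_inflow(q))
        res = simulate(net, SolverSettings(heart_period=0.8))
        expected = (q * (rp + rd) + pd * MMHG) / MMHG
        got = res.final_cycle_metrics["inlet"]["P_mean"]
        assert abs(got - expected) / expected < 0.005

    def test_doubling_compliance_reduces_pulse_pressure(self):
        inflow = pulsatile_inflow()
        pulses = []
        for c in (8.0, 16.0):
            net = windkessel_netlist(c=c, inflow=inflow)
            res = simulate(net, SolverSettings(heart_period=0.8))
            pulses.append(res.final_cycle_metrics["inlet"]["P_pulse"])
        assert pulses[1] < pulses[0]


class TestClosedLoop:
    def test_pressure_ordering_at_every_site(self, moderate_patient):
        for site, m in moderate_patient.simulation.final_cycle_metrics.items():
            if "P_mean" in m:
                assert m["P_sys"] >= m["P_mean"] >= m["P_dia"], site

    def test_periodicity_metric_non_increasing_at_convergence(
            self, moderate_patient):
        hist = moderate_patient.simulation.periodicity_history
        assert moderate_patient.simulation.periodicity_achieved
        tail = hist[-3:]
        for a, b in zip(tail, tail[1:]):
            assert b <= a * 1.05

    def test_volume_conservation_within_tenth_percent(self, moderate_patient):
        net = build_stage_netlist(moderate_patient.model, stage=3)
        vol = total_stressed_volume(moderate_patient.simulation, net)
        assert np.max(np.abs(vol - vol.mean())) / vol.mean() < 1e-3

    def test_open_loop_volume_not_applicable(self):
        net = windkessel_netlist(inflow=constant_inflow())
        res = simulate(net, SolverSettings(heart_period=0.8))
        with pytest.raises(NotApplicableError):
            total_stressed_volume(res, net)

    def test_grid_refinement_and_conservation(self, moderate_patient):
        """Halving the step changes mean pressures by <0.2% and does not
        worsen volume conservation."""
        model = moderate_patient.model
        results = {}
        for dt in (1.0e-4, 5.0e-5):
            net = build_stage_netlist(model, stage=3)
            res = simulate(net, model.solver_settings(
                time_step=dt, max_cycles=3, periodicity_tolerance=1e-12))
            vol = total_stressed_volume(res, net)
            results[dt] = (res.final_cycle_metrics,
                           np.max(np.abs(vol - vol.mean())) / vol.mean())
        coarse, fine = results[1.0e-4], results[5.0e-5]
        for site in ("MPA", "AAo"):
            a, b = coarse[0][site]["P_mean"], fine[0][site]["P_mean"]
            assert abs(a - b) / abs(b) < 0.002, site
        # deviation must not grow beyond round-off on refinement
        assert fine[1] <= max(coarse[1] * 1.5, 1e-9)
        assert fine[1] < 1e-3

    def test_divergence_reports_offending_node(self):
        # drive the pressure past float range so the state goes non-finite
        t = np.linspace(0, 0.8, 9)
        inflow = Waveform(t, np.full_like(t, 1e308), "flow")
        net = windkessel_netlist(rp=100.0, rd=100.0, c=1e-12, inflow=inflow)
        with pytest.raises(DivergenceError, match="node"):
            simulate(net, SolverSettings(heart_period=0.8))


class TestIndependentIntegrator:
    """Cross-check the production stepper against an independently written
    ODE model of a single-ventricle circuit, integrated with SciPy."""

    def test_single_ventricle_against_scipy_radau(self):
        from scipy.integrate import solve_ivp
        from hemocal.units import MMHG_PER_ML, ML

        period = 0.8
        emax, emin = 2.0 * MMHG_PER_ML, 0.08 * MMHG_PER_ML
        v0 = 5.0 * ML
        sysfrac = 0.34
        rs_coef = 4.0e-7
        l_in, l_out = 7.0e-6, 7.0e-6
        r_in_on, r_out_on = 4.0e-4, 6.0e-4
        off = 1.0e6
        c_root, r_load = 3.0, 0.10
        p_src, p_dist = 9.0 * MMHG, 5.0 * MMHG
        width = 1.0 * MMHG

        def elast(t):
            tau = (t / period) % 1.0
            if tau < sysfrac:
                act = 0.5 * (1 - np.cos(2 * np.pi * tau / sysfrac))
            else:
                act = 0.0
            return emin + (emax - emin) * act

        def sigmoid(x):
            return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))

        def rhs(t, y):
            v, qi, qo, pc = y
            e = elast(t)
            pv = e * (v - v0)
            g_in = (1 / r_in_on - 1 / (r_in_on * off)) * sigmoid(
                (p_src - pv) / (0.1 * MMHG)) + 1 / (r_in_on * off)
            # inflow branch: diode + inductor in series, lumped resistance
            dqi = (p_src - pv - qi / g_in) / l_in
            rs = rs_coef * max(pv, 0.0)
            r_on_eff = r_out_on + rs
            g_out = (1 / r_on_eff - 1 / (r_out_on * off)) * sigmoid(
                (pv - pc) / width) + 1 / (r_out_on * off)
            dqo = (pv - pc - qo / g_out) / l_out
            dv = qi - qo
            dpc = (qo - (pc - p_dist) / r_load) / c_root
            return [dv, dqi, dqo, dpc]

        y0 = [v0 + 8 * MMHG / emin, 0.0, 0.0, 60.0 * MMHG]
        n_cycles = 6
        sol = solve_ivp(rhs, (0, n_cycles * period), y0, method="Radau",
                        max_step=1e-3, rtol=1e-7, atol=1e-6)
        tt = np.linspace((n_cycles - 1) * period, n_cycles * period, 400)
        from scipy.interpolate import interp1d
        pc_last = interp1d(sol.t, sol.y[3])(tt) / MMHG

        # same circuit through the production netlist/stepper
        from hemocal.circuit import Component, Netlist, SolverSettings, simulate
        net = Netlist(
            components=[
                Component("diode", "Dv1", "src", "m_in",
                          params={"r_on": r_in_on, "r_off": r_in_on * off}),
                Component("inductor", "Lv1", "m_in", "V", value=l_in),
                Component("elastance_chamber", "ventricle", "V", "ground",
                          params={"e_max": emax, "e_min": emin, "v0": v0,
                                  "systolic_fraction": sysfrac}),
                Component("controlled_resistor", "Rv2", "V", "m_out",
                          params={"r_on": r_out_on,
                                  "r_off": r_out_on * off,
                                  "transition_width_mmhg": 1.0,
                                  "rs_controller": "ventricle",
                                  "rs_coefficient": rs_coef}),
                Component("inductor", "Lv2", "m_out", "root", value=l_out),
                Component("capacitor", "Croot", "root", "ground", value=c_root),
                Component("resistor", "Rload", "root", "dist", value=r_load),
            ],
            fixed_pressures={"src": p_src / MMHG, "dist": p_dist / MMHG},
            initial_pressures={"V": 8.0, "root": 60.0},
            monitor_pressure={"root": "root"},
        )
        res = simulate(net, SolverSettings(
            time_step=1e-4, heart_period=period, max_cycles=n_cycles,
            periodicity_tolerance=1e-12))
        ours = res.final_cycle_metrics["root"]

        ref = {"P_mean": float(np.trapezoid(pc_last, tt) / period),
               "P_sys": float(pc_last.max()), "P_dia": float(pc_last.min())}
        for key, val in ref.items():
            assert ours[key] == pytest.approx(val, rel=0.02), key


@settings(max_examples=30, deadline=None, derandomize=True)
@given(offset=st.floats(10, 200), amp=st.floats(0.1, 50),
       phase=st.floats(0, 2 * np.pi))
def test_cycle_metrics_sinusoid_property(offset, amp, phase):
    """Mean/extrema of sampled sinusoids match the closed form."""
    t = np.linspace(0, 1.0, 2001)
    m = cycle_metrics(Waveform(t, offset + amp * np.sin(2 * np.pi * t + phase)))
    assert m["P_mean"] == pytest.approx(offset, abs=max(1e-6, amp * 2e-3))
    assert m["P_sys"] == pytest.approx(offset + amp, rel=1e-3, abs=1e-3)
    assert m["P_dia"] == pytest.approx(offset - amp, rel=1e-3, abs=1e-3)
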