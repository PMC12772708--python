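"""Fixed-point update rules and the staged calibration."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemocal.calibration import (CalibrationConfig,
                                 WindkesselParams, distribute_outlet_params,
                                 initial_model_from_targets, percent_error,
                                 run_stage, update_initial_pressures,
                                 update_total_compliance,
                                 update_total_resistance)
from hemocal.circuit import InputError, SolverSettings, simulate
from hemocal.metrics import UndefinedBaselineError
from hemocal.units import MMHG

from conftest import pulsatile_inflow, windkessel_netlist


class TestPercentError:
    def test_direct_arithmetic(self):
        assert percent_error(100.0, 90.0) == pytest.approx(10.0)
        assert percent_error(59.4, 55.0) == pytest.approx(7.4074, abs=1e-3)

    def test_identity_is_zero(self):
        assert percent_error(42.0, 42.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedBaselineError):
            percent_error(0.0, 1.0)


class TestResistanceUpdate:
    def test_fixed_point(self):
        assert update_total_resistance(1.3, 100.0, 100.0, 10.0) == 1.3

    def test_direct_arithmetic(self):
        assert update_total_resistance(1.0, 100.0, 90.0, 10.0) == \
            pytest.approx(2.0)

    def test_converges_to_algebraic_fixed_point_in_two_iterations(self):
        """Against P_mean = R_T·Q + Pd the update lands on the closed-form
        solution immediately (the map is exact for a linear plant)."""
        q, pd_ = 10.0, 7.0
        target = 120.0
        r = 0.5
        for _ in range(2):
            p_sim = r * q + pd_
            r = update_total_resistance(r, target, p_sim, q)
        assert r == pytest.approx((target - pd_) / q, rel=1e-12)

    def test_nonpositive_result_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            r = update_total_resistance(0.1, 1.0, 1e9, 1.0)
        assert r > 0


class TestComplianceUpdate:
    def test_fixed_point(self):
        assert update_total_compliance(5.0, 30.0, 30.0) == pytest.approx(5.0)

    def test_ratio(self):
        assert update_total_compliance(5.0, 30.0, 60.0) == pytest.approx(10.0)

    def test_nonpositive_pulse_rejected(self):
        with pytest.raises(InputError):
            update_total_compliance(5.0, 0.0, 30.0)

    def test_simulation_in_the_loop_convergence(self):
        """Iterating C_T against a simulated Windkessel drives the pulse
        pressure to the target within 2% in at most 15 iterations."""
        inflow = pulsatile_inflow()
        target_pulse = 25.0  # mmHg
        c = 3.0
        settings_ = SolverSettings(heart_period=0.8, max_cycles=12)
        pulse = None
        for it in range(15):
            res = simulate(windkessel_netlist(c=c, inflow=inflow), settings_)
            pulse = res.final_cycle_metrics["inlet"]["P_pulse"]
            if abs(pulse - target_pulse) / target_pulse < 0.02:
                break
            c = update_total_compliance(c, target_pulse * MMHG, pulse * MMHG)
        assert abs(pulse - target_pulse) / target_pulse < 0.02
        assert it < 15


class TestOutletDistribution:
    def test_proportional_scaling_preserves_ratios(self):
        outlets = {"a": WindkesselParams(1.0, 3.0, 2.0),
                   "b": WindkesselParams(3.0, 9.0, 6.0)}
        scaled = distribute_outlet_params(outlets, 2.0, 1.0, 1.0, 1.0)
        assert scaled["a"].rp == pytest.approx(2.0)
        assert scaled["b"].rp == pytest.approx(6.0)
        assert scaled["b"].rp / scaled["a"].rp == pytest.approx(3.0)
        assert scaled["b"].c / scaled["a"].c == pytest.approx(3.0)

    def test_unchanged_totals_are_identity(self):
        outlets = {"a": WindkesselParams(1.0, 3.0, 2.0)}
        scaled = distribute_outlet_params(outlets, 1.0, 1.0, 5.0, 5.0)
        assert scaled["a"].c == 2.0
        assert scaled["a"].rd == 3.0

    def test_parallel_sum_tracks_total(self):
        outlets = {"a": WindkesselParams(1.0, 3.0, 2.0),
                   "b": WindkesselParams(2.0, 6.0, 1.0)}
        def par(o):
            return 1.0 / sum(1.0 / wk.total_resistance for wk in o.values())
        r0 = par(outlets)
        scaled = distribute_outlet_params(outlets, 1.7 * r0, r0, 1.0, 1.0)
        assert par(scaled) == pytest.approx(1.7 * r0)


class TestInitialPressureUpdate:
    def test_both_ratios_one_is_identity(self):
        p = {"a": 10.0, "b": 20.0}
        assert update_initial_pressures(p, 5.0, 5.0, 80.0, 80.0) == p

    def test_opposing_ratios_cancel(self):
        p = update_initial_pressures({"a": 10.0}, 1.2, 1.0, 0.8, 1.0)
        assert p["a"] == pytest.approx(10.0)

    def test_arithmetic_mean_of_ratios(self):
        p = update_initial_pressures({"a": 10.0, "b": 4.0}, 2.0, 1.0, 1.0, 1.0)
        assert p["a"] == pytest.approx(15.0)
        assert p["b"] == pytest.approx(6.0)

    def test_zero_simulated_mean_rejected(self):
        with pytest.raises(InputError):
            update_initial_pressures({"a": 1.0}, 1.0, 0.0, 1.0, 1.0)


class TestStages:
    def test_stage1_recovers_total_resistance(self, moderate_patient):
        """Open-loop calibration against targets generated by a known
        circuit recovers the pulmonary resistance total within 2% and
        drives all gated errors below 10%."""
        from hemocal.metrics import pulmonary_rc_split
        model = initial_model_from_targets(moderate_patient.targets,
                                           moderate_patient.geometry)
        config = CalibrationConfig(max_iterations={1: 15, 2: 10, 3: 20})
        state = run_stage(1, model, moderate_patient.targets, config)
        assert state.converged
        assert max(state.errors.values()) < 10.0
        split = pulmonary_rc_split(model)
        truth = moderate_patient.truth_summary["R_total_pulmonary"]
        assert abs(split["R_total"] - truth) / truth < 0.02

    def test_forced_non_convergence_reports_history(self, moderate_patient):
        model = initial_model_from_targets(moderate_patient.targets,
                                           moderate_patient.geometry)
        config = CalibrationConfig(convergence_threshold=1e-9,
                                   max_iterations={1: 2, 2: 2, 3: 2})
        state = run_stage(1, model, moderate_patient.targets, config)
        assert not state.converged
        assert len(state.history) == 2
        assert state.worst_metric is not None

    def test_stage_iterations_are_deterministic(self, moderate_patient):
        """Two identical stage-1 runs produce identical error histories."""
        histories = []
        for _ in range(2):
            model = initial_model_from_targets(moderate_patient.targets,
                                               moderate_patient.geometry)
            config = CalibrationConfig(max_iterations={1: 2, 2: 2, 3: 2},
                                       convergence_threshold=1e-9)
            state = run_stage(1, model, moderate_patient.targets, config)
            histories.append([h["errors"] for h in state.history])
        assert histories[0] == histories[1]


class TestOptimizerReport:
    def test_full_pipeline_converges(self, calibrated):
        _, report = calibrated
        assert report["converged"]
        assert report["max_error_percent"] < 10.0
        for stage in ("1", "2", "3"):
            assert report["stages"][stage]["converged"], stage

    def test_parameter_count_in_reported_range(self, calibrated):
        _, report = calibrated
        assert 30 <= report["parameter_count"] <= 60

    def test_monotone_error_tail(self, calibrated):
        """Max percent error is non-increasing over the final iterations of
        the converged closed-loop stage (under-relaxation active)."""
        _, report = calibrated
        hist = report["stages"]["3"]["history"]
        maxima = [max(h["errors"].values()) for h in hist][-3:]
        for a, b in zip(maxima, maxima[1:]):
            assert b <= a * 1.10

    def test_noise_robust_convergence(self, moderate_patient):
        """Stage-3 convergence below the 10% gate survives 5% multiplicative
        measurement noise on the targets."""
        from hemocal.synth import add_measurement_noise
        noised = add_measurement_noise(moderate_patient.targets, 0.05, 7)
        model = initial_model_from_targets(noised, moderate_patient.geometry)
        from hemocal.calibration import run_optimizer
        report = run_optimizer(model, noised)
        assert report["stages"]["3"]["converged"]
        assert max(report["stages"]["3"]["final_errors"].values()) < 10.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(r=st.floats(1e-3, 10), p=st.floats(1, 1e4), q=st.floats(1, 1e5),
       c=st.floats(1e-3, 100), pulse=st.floats(0.1, 1e3))
def test_updates_are_stationary_at_the_fixed_point(r, p, q, c, pulse):
    """If simulated metrics equal the targets, no update changes anything."""
    assert update_total_resistance(r, p, p, q) == r
    assert update_total_compliance(c, pulse, pulse) == c
    outlets = {"j": WindkesselParams(r, 2 * r, c)}
    scaled = distribute_outlet_params(outlets, r, r, c, c)
    assert scaled["j"].rp == outlets["j"].rp
    assert update_initial_pressures({"n": p}, q, q, p, p) == {"n": p}
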