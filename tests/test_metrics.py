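"""Derived hemodynamic metrics: stiffness, PWV, R/C split, comparisons."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemocal.circuit import Waveform
from hemocal.metrics import (DegenerateDeformationError, PhaseOrderError,
                             StiffnessInput, UndefinedBaselineError,
                             derived_metrics, foot_to_foot_pwv,
                             linearized_stiffness, longitudinal_report,
                             moens_korteweg_pwv, percent_change,
                             pulmonary_rc_split, radius_from_area)


class TestLinearizedStiffness:
    def test_worked_arithmetic(self):
        # Ri=10, Ro=11.5, ΔR=1, ΔP=1 → 1.5·1·100·11.5 / (32.25·1)
        e = linearized_stiffness(StiffnessInput(
            p_sys=2.0, p_dia=1.0, r_sys=11.0, r_dia=10.0))
        assert e == pytest.approx(1725.0 / 32.25, rel=1e-12)

    def test_homogeneity_in_pulse_pressure(self):
        base = StiffnessInput(p_sys=2.0, p_dia=1.0, r_sys=11.0, r_dia=10.0)
        double = StiffnessInput(p_sys=3.0, p_dia=1.0, r_sys=11.0, r_dia=10.0)
        assert linearized_stiffness(double) == \
            pytest.approx(2 * linearized_stiffness(base))

    def test_inverse_in_radial_deformation(self):
        base = StiffnessInput(p_sys=2.0, p_dia=1.0, r_sys=11.0, r_dia=10.0)
        half = StiffnessInput(p_sys=2.0, p_dia=1.0, r_sys=10.5, r_dia=10.0)
        assert linearized_stiffness(half) == \
            pytest.approx(2 * linearized_stiffness(base))

    def test_degenerate_deformation_rejected(self):
        with pytest.raises(DegenerateDeformationError):
            StiffnessInput(p_sys=2.0, p_dia=1.0, r_sys=10.0, r_dia=10.0)

    def test_roundtrip_through_generator_geometry(self, moderate_patient):
        """Re-estimating stiffness from the exported geometry table and the
        target pressures reproduces the ground-truth segment stiffness."""
        geo = moderate_patient.geometry
        targets = moderate_patient.targets
        rows = geo[geo["site"].isin(["MPA", "AAo", "DTA", "LPA", "RPA"])]
        for _, row in rows.iterrows():
            tm = targets.sites[row["site"]]
            e = linearized_stiffness(StiffnessInput(
                p_sys=tm["P_sys"] * 133.322, p_dia=tm["P_dia"] * 133.322,
                r_sys=row["R_sys_mm"], r_dia=row["R_dia_mm"]))
            assert e == pytest.approx(row["stiffness_true"], rel=1e-9)


class TestMoensKorteweg:
    def test_direct_formula(self):
        assert moens_korteweg_pwv(9e4, 1.5, 10.0, 1.06e-3) == \
            pytest.approx(np.sqrt(9e4 * 1.5 / (2 * 1.06e-3 * 10.0)))

    def test_sqrt_scaling_in_stiffness(self):
        assert moens_korteweg_pwv(4e5, 1.5, 10.0, 1.06e-3) == \
            pytest.approx(2 * moens_korteweg_pwv(1e5, 1.5, 10.0, 1.06e-3))

    def test_vanishing_wall_limit(self):
        assert moens_korteweg_pwv(1e5, 0.0, 10.0, 1.06e-3) == 0.0

    def test_radius_from_area_circular(self):
        assert radius_from_area(np.pi * 49.0) == pytest.approx(7.0)


class TestFootToFoot:
    def _wave(self, period=0.8, shift=0.0):
        t = np.linspace(0, period, 2001)
        v = 40 + 20 * np.exp(-0.5 * (((t - 0.15 - shift) % period) / 0.03) ** 2)
        return Waveform(t, v, "pressure")

    def test_constructed_shift(self):
        pwv = foot_to_foot_pwv(self._wave(), self._wave(shift=0.010), 100.0)
        assert pwv == pytest.approx(10000.0, rel=0.02)

    def test_zero_delay_is_phase_order_error(self):
        with pytest.raises(PhaseOrderError):
            foot_to_foot_pwv(self._wave(), self._wave(), 100.0)

    def test_periodic_wrap(self):
        """A negative raw delay wraps by one period."""
        a, b = self._wave(shift=0.010), self._wave()
        pwv = foot_to_foot_pwv(a, b, 100.0)
        assert pwv == pytest.approx(100.0 / (0.8 - 0.010), rel=0.05)


class TestRcSplit:
    def test_fraction_arithmetic(self, moderate_patient):
        split = pulmonary_rc_split(moderate_patient.model)
        assert split["C_central_fraction"] + \
            split["C_peripheral_fraction"] == pytest.approx(1.0)
        assert split["R_central_fraction"] + \
            split["R_peripheral_fraction"] == pytest.approx(1.0)
        assert all(v > 0 for v in split.values())

    def test_ohmic_identity_on_simulation(self, moderate_patient):
        """Component-wise total pulmonary resistance agrees with
        (mean MPA pressure − venous reference)/mean flow on the simulated
        waveforms within 5%."""
        split = pulmonary_rc_split(moderate_patient.model)
        m = moderate_patient.simulation.final_cycle_metrics["MPA"]
        pcwp = moderate_patient.targets.extras["PCWP"]
        r_ohm = (m["P_mean"] - pcwp) * 133.322 / m["Q_mean"]
        # subtract the small venous-pathway resistance included in the path
        r_ohm -= moderate_patient.model.pulmonary_venous.total_resistance
        assert split["R_total"] == pytest.approx(r_ohm, rel=0.05)


class TestPercentChange:
    @pytest.mark.parametrize("baseline, followup, expected", [
        (59.4, 113.3, 90.7),
        (8.45, 6.54, -22.6),
        (42.0, 42.0, 0.0),
    ])
    def test_examples(self, baseline, followup, expected):
        assert round(percent_change(baseline, followup), 1) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedBaselineError):
            percent_change(0.0, 5.0)


class TestLongitudinalReport:
    def test_stiffness_percent_changes(self):
        rep = longitudinal_report({"MPA_stiffness": 134683.6},
                                  {"MPA_stiffness": 430298.3})
        assert rep.loc[0, "percent_change"] == pytest.approx(219.5)
        rep = longitudinal_report({"MPA_stiffness": 190034.9},
                                  {"MPA_stiffness": 98286.2})
        assert rep.loc[0, "percent_change"] == pytest.approx(-48.3)

    def test_identical_timepoints_all_zero(self):
        vals = {"a": 1.0, "b": 2.5}
        rep = longitudinal_report(vals, dict(vals))
        assert (rep["percent_change"] == 0).all()

    def test_mismatched_keys_listed_not_fatal(self):
        rep = longitudinal_report({"a": 1.0, "only_base": 2.0}, {"a": 1.5})
        row = rep[rep["metric"] == "only_base"].iloc[0]
        assert row["followup"] is None or np.isnan(row["followup"])
        assert row["percent_change"] is None or np.isnan(row["percent_change"])

    def test_derived_metrics_cover_required_set(self, moderate_patient):
        vals = derived_metrics(moderate_patient.model,
                               moderate_patient.simulation)
        for site in ("AAo", "DTA", "MPA", "LPA", "RPA"):
            assert f"stiffness_{site}" in vals
        for pair in ("MPA-LPA", "MPA-RPA", "AAo-DTA"):
            assert f"pwv_mk_{pair}" in vals
        assert "pulmonary_R_total" in vals and "pulmonary_C_total" in vals


@settings(max_examples=60, deadline=None, derandomize=True)
@given(base=st.floats(0.01, 1e6), pct=st.floats(-99.0, 500.0))
def test_percent_change_roundtrip_property(base, pct):
    assert percent_change(base, base * (1 + pct / 100.0)) == \
        pytest.approx(pct, abs=1e-8)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(ri=st.floats(1.0, 20.0), dr=st.floats(1e-3, 2.0),
       dp=st.floats(0.1, 1e4), k=st.floats(1.1, 20.0))
def test_stiffness_homogeneity_property(ri, dr, dp, k):
    def e(dp_, dr_):
        return linearized_stiffness(StiffnessInput(
            p_sys=1.0 + dp_, p_dia=1.0, r_sys=ri + dr_, r_dia=ri))
    assert e(k * dp, dr) == pytest.approx(k * e(dp, dr), rel=1e-9)
    assert e(dp, k * dr) == pytest.approx(e(dp, dr) / k, rel=1e-9)
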