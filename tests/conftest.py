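"""Shared fixtures.

The expensive artifacts — a simulated virtual patient and its full staged
calibration — are session-scoped and shared across test modules; everything
else is generated per test.
"""
from __future__ import annotations

import numpy as np
import pytest

from hemocal.calibration import (CalibrationConfig, initial_model_from_targets,
                                 run_optimizer)
from hemocal.circuit import Component, Netlist, Waveform
from hemocal.synth import generate_patient

PATIENT_SEED = 7


@pytest.fixture(scope="session")
def moderate_patient():
    """Moderate-severity virtual patient with its converged truth simulation."""
    return generate_patient(PATIENT_SEED, "moderate")


@pytest.fixture(scope="session")
def normal_patient():
    return generate_patient(PATIENT_SEED, "normal")


@pytest.fixture(scope="session")
def severe_patient():
    return generate_patient(PATIENT_SEED, "severe")


@pytest.fixture(scope="session")
def calibrated(moderate_patient):
    """Default-threshold staged calibration of the moderate patient."""
    model = initial_model_from_targets(moderate_patient.targets,
                                       moderate_patient.geometry)
    report = run_optimizer(model, moderate_patient.targets)
    return model, report


@pytest.fixture(scope="session")
def calibrated_tight(moderate_patient):
    """Tight-gate calibration used for parameter-identifiability checks."""
    model = initial_model_from_targets(moderate_patient.targets,
                                       moderate_patient.geometry)
    config = CalibrationConfig(convergence_threshold=1.5,
                               max_iterations={1: 12, 2: 12, 3: 60})
    report = run_optimizer(model, moderate_patient.targets, config)
    return model, report


def windkessel_netlist(rp=0.02, rd=0.10, c=8.0, pd_mmhg=5.0,
                       inflow: Waveform | None = None) -> Netlist:
    """Three-element Windkessel driven by an imposed inflow at node 'a'."""
    net = Netlist(
        components=[
            Component("resistor", "Rp", "a", "m", value=rp),
            Component("capacitor", "C", "m", "ground", value=c),
            Component("resistor", "Rd", "m", "ref", value=rd),
        ],
        fixed_pressures={"ref": pd_mmhg},
        monitor_pressure={"inlet": "a"},
    )
    if inflow is not None:
        net.imposed_flows = {"a": inflow}
    return net


def constant_inflow(q=60000.0, period=0.8) -> Waveform:
    t = np.linspace(0.0, period, 9)
    return Waveform(t, np.full_like(t, q), "flow")


def pulsatile_inflow(q_mean=60000.0, period=0.8, pulse_fraction=0.9):
    t = np.linspace(0.0, period, 801)
    v = q_mean * (1.0 + pulse_fraction * np.sin(2 * np.pi * t / period))
    return Waveform(t, v, "flow")
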