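"""0D lumped-parameter heart: elastance chambers, valves and root capacitors.

Each side of the heart is the chain

    atrium → inflow valve (diode Dv1 + inductor Lv1) → ventricle
           → outflow valve (controlled resistor Rv2 + inductor Lv2)
           → arterial root capacitor CR

The ventricle is a time-varying elastance chamber P = E(t)·(V − V0) with a
dynamic source resistance Rs(t) proportional to the instantaneous isovolumic
pressure, Rs(t) = rs_coefficient · E(t)·(V − V0); Rs sits in series with the
outflow valve (nothing else attaches between chamber and valve, so the two
resistances merge into the valve's on-resistance).  Atria default to
constant-elastance chambers (no atrial kick).

Default valve resistances/inertances are this package's own choices from
common 0D heart-model practice; no published values are attached to them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .activation import activation_value
from .circuit import Component, InvalidParameterError
from .units import MMHG_PER_ML, ML, ML_PER_MMHG

__all__ = ["ChamberParams", "ValveParams", "HeartParams", "elastance_at",
           "chamber_pressure", "build_heart_netlist"]


@dataclass
class ChamberParams:
    """Elastance-chamber parameters (internal g–mm–s units).

    ``e_max``/``e_min`` in g/(mm⁴·s²) (= 0.133322 × mmHg/mL), ``v0`` in mm³.
    ``onset_fraction`` places the start of activation within the period;
    ``systolic_fraction`` is the active fraction of the period.
    ``rs_coefficient`` (s/mm³) scales the source resistance; 0 disables it.
    """

    e_max: float
    e_min: float
    v0: float
    onset_fraction: float = 0.0
    systolic_fraction: float = 0.3
    rs_coefficient: float = 0.0
    law: str = "cosine"

    def __post_init__(self):
        if not self.e_max >= self.e_min > 0:
            raise InvalidParameterError("need e_max >= e_min > 0")
        if self.v0 < 0:
            raise InvalidParameterError("v0 must be >= 0")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise InvalidParameterError("systolic_fraction must be in (0, 1)")
        if self.rs_coefficient < 0:
            raise InvalidParameterError("rs_coefficient must be >= 0")

    def as_chamber_params(self) -> dict:
        return {"e_max": self.e_max, "e_min": self.e_min, "v0": self.v0,
                "onset_fraction": self.onset_fraction,
                "systolic_fraction": self.systolic_fraction, "law": self.law}


@dataclass
class ValveParams:
    """Inflow (diode + inductor) and outflow (controlled resistor + inductor)
    valve parameters, internal units."""

    l_inflow: float = 7.0e-6        # g/mm⁴
    r_inflow_on: float = 4.0e-4     # g/(mm⁴·s)
    r_inflow_off_factor: float = 1.0e8
    l_outflow: float = 7.0e-6
    r_outflow_on: float = 6.0e-4
    r_outflow_off_factor: float = 1.0e8
    transition_width_mmhg: float = 1.0

    def __post_init__(self):
        if self.l_inflow <= 0 or self.l_outflow <= 0:
            raise InvalidParameterError("valve inductances must be positive")
        if self.r_inflow_on <= 0 or self.r_outflow_on <= 0:
            raise InvalidParameterError("valve on-resistances must be positive")
        if self.r_inflow_off_factor <= 1 or self.r_outflow_off_factor <= 1:
            raise InvalidParameterError("off-resistance must exceed on-resistance")


def _default_lv() -> ChamberParams:
    return ChamberParams(e_max=2.2 * MMHG_PER_ML, e_min=0.09 * MMHG_PER_ML,
                         v0=5.0 * ML, systolic_fraction=0.34,
                         rs_coefficient=4.0e-7)


def _default_rv() -> ChamberParams:
    return ChamberParams(e_max=0.55 * MMHG_PER_ML, e_min=0.06 * MMHG_PER_ML,
                         v0=8.0 * ML, systolic_fraction=0.34,
                         rs_coefficient=4.0e-7)


def _default_la() -> ChamberParams:
    return ChamberParams(e_max=0.25 * MMHG_PER_ML, e_min=0.25 * MMHG_PER_ML,
                         v0=4.0 * ML)


def _default_ra() -> ChamberParams:
    return ChamberParams(e_max=0.20 * MMHG_PER_ML, e_min=0.20 * MMHG_PER_ML,
                         v0=4.0 * ML)


@dataclass
class HeartParams:
    """Four-chamber heart with valves and arterial root capacitors."""

    lv: ChamberParams = field(default_factory=_default_lv)
    rv: ChamberParams = field(default_factory=_default_rv)
    la: ChamberParams = field(default_factory=_default_la)
    ra: ChamberParams = field(default_factory=_default_ra)
    left_valves: ValveParams = field(default_factory=ValveParams)
    right_valves: ValveParams = field(default_factory=ValveParams)
    cr_aortic: float = 0.30 * ML_PER_MMHG      # 0.30 mL/mmHg
    cr_pulmonary: float = 0.45 * ML_PER_MMHG   # 0.45 mL/mmHg
    heart_rate: float = 90.0   # beats/min

    def __post_init__(self):
        if self.cr_aortic <= 0 or self.cr_pulmonary <= 0:
            raise InvalidParameterError("root capacitances must be positive")
        if self.heart_rate <= 0:
            raise InvalidParameterError("heart rate must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


def elastance_at(t: float, chamber: ChamberParams, period: float) -> float:
    """Periodic time-varying elastance E(t), internal units."""
    if period <= 0:
        raise InvalidParameterError("period must be positive")
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    act = activation_value(t, period, chamber.onset_fraction,
                           chamber.systolic_fraction, chamber.law)
    return chamber.e_min + (chamber.e_max - chamber.e_min) * act


def chamber_pressure(v: float, q_out: float, t: float,
                     chamber: ChamberParams, period: float) -> float:
    """Chamber pressure P = E(t)·(V − V0) − Rs(t)·Q_out (internal units).

    Rs(t) = rs_coefficient × max(E(t)·(V − V0), 0): the source resistance is
    proportional to the instantaneous isovolumic pressure, so ejection
    pressure falls below the isovolumic value in proportion to outflow.
    """
    e = elastance_at(t, chamber, period)
    p_iso = e * (v - chamber.v0)
    rs = chamber.rs_coefficient * max(p_iso, 0.0)
    return p_iso - rs * q_out


def _side_components(prefix: str, atrium_node: str, ventricle_node: str,
                     root_node: str, atrium: ChamberParams,
                     ventricle: ChamberParams, valves: ValveParams,
                     cr: float) -> list[Component]:
    mid_in = f"{prefix}_inflow_mid"
    mid_out = f"{prefix}_outflow_mid"
    comps = [
        Component("elastance_chamber", f"{prefix}_atrium", atrium_node,
                  "ground", params=atrium.as_chamber_params()),
        Component("diode", f"{prefix}_inflow_valve", atrium_node, mid_in,
                  params={"r_on": valves.r_inflow_on,
                          "r_off": valves.r_inflow_on * valves.r_inflow_off_factor}),
        Component("inductor", f"{prefix}_inflow_L", mid_in, ventricle_node,
                  value=valves.l_inflow),
        Component("elastance_chamber", f"{prefix}_ventricle", ventricle_node,
                  "ground", params=ventricle.as_chamber_params()),
        Component("controlled_resistor", f"{prefix}_outflow_valve",
                  ventricle_node, mid_out,
                  params={"r_on": valves.r_outflow_on,
                          "r_off": valves.r_outflow_on * valves.r_outflow_off_factor,
                          "transition_width_mmhg": valves.transition_width_mmhg,
                          "rs_controller": f"{prefix}_ventricle",
                          "rs_coefficient": ventricle.rs_coefficient}),
        Component("inductor", f"{prefix}_outflow_L", mid_out, root_node,
                  value=valves.l_outflow),
        Component("capacitor", f"{prefix}_root_C", root_node, "ground",
                  value=cr),
    ]
    return comps


def build_heart_netlist(params: HeartParams) -> list[Component]:
    """Netlist fragment for the four-chamber heart.

    Exposes nodes ``LA``, ``LV``, ``Ao_root`` (left) and ``RA``, ``RV``,
    ``PA_root`` (right) for embedding in a larger circuit; component names
    are deterministic (``left_*`` / ``right_*``).
    """
    comps = _side_components("left", "LA", "LV", "Ao_root",
                             params.la, params.lv, params.left_valves,
                             params.cr_aortic)
    comps += _side_components("right", "RA", "RV", "PA_root",
                              params.ra, params.rv, params.right_valves,
                              params.cr_pulmonary)
    return comps
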