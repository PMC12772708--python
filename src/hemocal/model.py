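"""Whole-patient circulation model and stage-wise netlist assembly.

A :class:`PatientModel` bundles the 0D heart, the reduced-order systemic and
pulmonary arterial trees, three-element Windkessel outlets, venous return
pathways and nodal initial pressures.  The three calibration stages use
progressively more complete circuits:

Stage 1
    Open-loop arterial trees driven by prescribed inlet flow waveforms at
    the aortic and pulmonary roots; Windkessel outlets drain to fixed
    distal reference pressures.
Stage 2
    The 0D heart replaces the imposed flows; atria fill from fixed preload
    reservoirs through a small filling resistance; outlets still drain to
    fixed references.
Stage 3
    Fully closed loop: arterial outlets feed venous Windkessel pathways
    that return to the atria.  No boundary pressures or flows remain, so
    total stressed volume is set by the initial nodal pressures.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .circuit import (BloodProperties, Component, InvalidParameterError,
                      Netlist, SolverSettings, Waveform)
from .heart import HeartParams, build_heart_netlist
from .vessels import ArterialTree, build_tree_netlist

__all__ = ["WindkesselParams", "PatientModel", "build_stage_netlist",
           "MONITORED_PRESSURE_SITES", "MONITORED_FLOW_SITES"]

MONITORED_PRESSURE_SITES = ("MPA", "LPA", "RPA", "AAo", "DTA")
MONITORED_FLOW_SITES = ("MPA", "LPA", "RPA", "AAo", "DTA")

_FILL_RESISTANCE = 2.0e-3  # g/(mm⁴·s), preload-to-atrium filling (stage 2)


@dataclass
class WindkesselParams:
    """Three-element Windkessel: proximal/distal resistance and compliance."""

    rp: float   # g/(mm⁴·s)
    rd: float
    c: float    # mm⁴·s²/g

    def __post_init__(self):
        if min(self.rp, self.rd, self.c) <= 0:
            raise InvalidParameterError("Windkessel parameters must be positive")

    @property
    def total_resistance(self) -> float:
        return self.rp + self.rd

    def scaled(self, r_factor: float = 1.0, c_factor: float = 1.0) -> "WindkesselParams":
        return WindkesselParams(self.rp * r_factor, self.rd * r_factor,
                                self.c * c_factor)


@dataclass
class PatientModel:
    heart: HeartParams
    pulmonary_tree: ArterialTree
    systemic_tree: ArterialTree
    pulmonary_outlets: dict[str, WindkesselParams]
    systemic_outlets: dict[str, WindkesselParams]
    pulmonary_venous: WindkesselParams
    systemic_venous: WindkesselParams
    initial_pressures: dict[str, float] = field(default_factory=dict)  # mmHg
    preload_pressures: dict[str, float] = field(
        default_factory=lambda: {"left": 9.0, "right": 5.0})  # mmHg, stage 2
    distal_reference: dict[str, float] = field(
        default_factory=lambda: {"pulmonary": 8.0, "systemic": 4.0})  # mmHg
    blood: BloodProperties = field(default_factory=BloodProperties)
    time_step: float = 1.0e-4
    max_cycles: int = 20
    periodicity_tolerance: float = 1.0e-3

    def solver_settings(self, **overrides) -> SolverSettings:
        kw = dict(time_step=self.time_step,
                  heart_period=self.heart.period,
                  max_cycles=self.max_cycles,
                  periodicity_tolerance=self.periodicity_tolerance)
        kw.update(overrides)
        return SolverSettings(**kw)

    def copy(self) -> "PatientModel":
        return copy.deepcopy(self)

    def parameter_count(self) -> int:
        """Number of parameters exposed to the automated calibration.

        Counts the three Windkessel elements per arterial outlet and venous
        pathway, the two ventricular peak elastances, the preload source
        pressures and the initial pressures of the key storage nodes
        (chambers, arterial roots, Windkessel and venous capacitor nodes)
        whose levels the fixed-point updates tune.
        """
        n = 3 * (len(self.pulmonary_outlets) + len(self.systemic_outlets))
        n += 3 * 2                      # venous pathways
        n += 2                          # ventricular peak elastances
        n += len(self.preload_pressures)
        key_nodes = {"LA", "LV", "RA", "RV", "Ao_root", "PA_root",
                     "pul_ven_sum", "sys_ven_sum",
                     "pul_wk_venous", "sys_wk_venous"}
        key_nodes |= {f"pul_wk_{name}" for name in self.pulmonary_outlets}
        key_nodes |= {f"sys_wk_{name}" for name in self.systemic_outlets}
        n += sum(1 for k in self.initial_pressures if k in key_nodes)
        return n


def _mid_node(tree: ArterialTree, name: str, prefix: str) -> str:
    seg = tree.by_name[name]
    n = seg.sections
    if n == 1:
        return f"{prefix}{name}_out"
    k = max(n // 2 - 1, 0)
    return f"{prefix}{name}_s{k}"


def _monitors(model: PatientModel) -> tuple[dict[str, str], dict[str, str]]:
    mp, mf = {}, {}
    for tree, prefix in ((model.pulmonary_tree, "pul_"),
                         (model.systemic_tree, "sys_")):
        for seg in tree.segments:
            if seg.site in MONITORED_PRESSURE_SITES:
                mp[seg.site] = _mid_node(tree, seg.name, prefix)
                mf[seg.site] = f"{prefix}{seg.name}_L0"
    return mp, mf


def _windkessel_components(name: str, wk: WindkesselParams, outlet_node: str,
                           tail_node: str, prefix: str) -> list[Component]:
    mid = f"{prefix}wk_{name}"
    return [
        Component("resistor", f"{prefix}wk_{name}_Rp", outlet_node, mid,
                  value=wk.rp),
        Component("capacitor", f"{prefix}wk_{name}_C", mid, "ground",
                  value=wk.c),
        Component("resistor", f"{prefix}wk_{name}_Rd", mid, tail_node,
                  value=wk.rd),
    ]


def build_stage_netlist(model: PatientModel, stage: int,
                        inlet_flows: dict[str, Waveform] | None = None) -> Netlist:
    """Assemble the stage-1/2/3 netlist for a patient model.

    ``inlet_flows`` maps ``"AAo"``/``"MPA"`` to periodic flow waveforms
    (mm³/s) and is required for stage 1.
    """
    if stage not in (1, 2, 3):
        raise InvalidParameterError("stage must be 1, 2 or 3")
    comps: list[Component] = []
    fixed: dict[str, float] = {}
    imposed: dict[str, Waveform] = {}

    comps += build_tree_netlist(model.pulmonary_tree, model.blood,
                                "PA_root", prefix="pul_")
    comps += build_tree_netlist(model.systemic_tree, model.blood,
                                "Ao_root", prefix="sys_")

    tails = {}
    for side, prefix in (("pulmonary", "pul_"), ("systemic", "sys_")):
        if stage == 3:
            tails[side] = f"{prefix}ven_sum"
        else:
            tails[side] = f"{prefix}distal_ref"
            fixed[tails[side]] = model.distal_reference[side]
    for name, wk in model.pulmonary_outlets.items():
        comps += _windkessel_components(
            name, wk, f"pul_{name}_out", tails["pulmonary"], "pul_")
    for name, wk in model.systemic_outlets.items():
        comps += _windkessel_components(
            name, wk, f"sys_{name}_out", tails["systemic"], "sys_")

    if stage == 1:
        if not inlet_flows or not {"AAo", "MPA"} <= set(inlet_flows):
            raise InvalidParameterError(
                "stage 1 requires inlet flow waveforms for AAo and MPA")
        imposed["Ao_root"] = inlet_flows["AAo"]
        imposed["PA_root"] = inlet_flows["MPA"]
    else:
        comps += build_heart_netlist(model.heart)
        if stage == 2:
            for side, atrium in (("left", "LA"), ("right", "RA")):
                src = f"{side}_preload_src"
                fixed[src] = model.preload_pressures[side]
                comps.append(Component("resistor", f"{side}_fill_R", src,
                                       atrium, value=_FILL_RESISTANCE))
        else:
            comps += _windkessel_components(
                "venous", model.pulmonary_venous, "pul_ven_sum", "LA", "pul_")
            comps += _windkessel_components(
                "venous", model.systemic_venous, "sys_ven_sum", "RA", "sys_")

    netlist = Netlist(components=comps, fixed_pressures=fixed,
                      imposed_flows=imposed)
    mp, mf = _monitors(model)
    netlist.monitor_pressure = mp
    netlist.monitor_flow = mf
    netlist.initial_pressures = _expand_initial_pressures(model, netlist, stage)
    netlist.validate()
    return netlist


def _expand_initial_pressures(model: PatientModel, netlist: Netlist,
                              stage: int) -> dict[str, float]:
    """Fill every node's initial pressure from the model's key-node map.

    Unlisted tree and valve nodes inherit the pressure of their side's root
    (arterial) or neighbouring chamber so the startup transient stays short;
    only the key-node map itself is exposed to calibration.
    """
    ics = dict(model.initial_pressures)
    pa = ics.get("PA_root", 20.0)
    ao = ics.get("Ao_root", 80.0)
    out: dict[str, float] = {}
    for node in netlist.nodes:
        if node in ics:
            out[node] = ics[node]
        elif node in netlist.fixed_pressures or node == netlist.ground:
            continue
        elif node.startswith("pul_ven"):
            out[node] = ics.get("LA", 8.0)
        elif node.startswith("sys_ven"):
            out[node] = ics.get("RA", 4.0)
        elif node.startswith("pul_wk_"):
            out[node] = 0.8 * pa
        elif node.startswith("sys_wk_"):
            out[node] = 0.8 * ao
        elif node.startswith("pul_"):
            out[node] = pa
        elif node.startswith("sys_"):
            out[node] = ao
        elif node == "left_inflow_mid":
            out[node] = ics.get("LA", 8.0)
        elif node == "right_inflow_mid":
            out[node] = ics.get("RA", 4.0)
        elif node == "left_outflow_mid":
            out[node] = ao
        elif node == "right_outflow_mid":
            out[node] = pa
        else:
            out[node] = 0.0
    return out
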