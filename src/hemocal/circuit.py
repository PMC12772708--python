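"""Lumped-parameter hydraulic circuit model and fixed-step time-domain solver.

The circuit is the hydraulic analog of an electrical network: pressure plays
the role of voltage, volumetric flow the role of current.  Supported element
kinds are resistors, capacitors (vascular compliance), inductors (blood
inertance), diodes (ideal valves with a large off-resistance), controlled
resistors (smoothly switched valve resistances, optionally with a
flow-dependent ventricular source resistance folded in series) and
time-varying elastance chambers (P = E(t)·(V − V0) against ground).

Internally everything is in g–mm–s units (see :mod:`hemocal.units`): the
netlist stores initial/fixed pressures in mmHg for convenience and converts
at assembly time.

The solver is a semi-implicit fixed-step scheme: backward-Euler companion
models for every storage element assembled by modified nodal analysis, with
an inner switching iteration for diode states and smoothly controlled valve
resistances.  Backward Euler is L-stable, which keeps the stiff on/off valve
transitions well behaved at the default 0.1 ms step.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .activation import activation_value
from .units import MMHG

__all__ = [
    "BloodProperties", "SolverSettings", "Component", "Netlist", "Waveform",
    "SimulationResult", "assemble_system", "simulate", "cycle_metrics",
    "total_stressed_volume", "CircuitError", "StructuralError",
    "InvalidParameterError", "DivergenceError", "NotApplicableError",
    "InputError",
]


class CircuitError(Exception):
    """Base class for circuit-level failures."""


class StructuralError(CircuitError):
    """Netlist topology is unusable (disconnected graph, dangling refs)."""


class InvalidParameterError(CircuitError):
    """An element has a zero/negative/non-finite parameter."""


class DivergenceError(CircuitError):
    """The time integration produced non-finite values."""


class NotApplicableError(CircuitError):
    """The requested analysis does not apply to this netlist."""


class InputError(CircuitError):
    """Malformed waveform or argument."""


COMPONENT_KINDS = (
    "resistor", "capacitor", "inductor", "diode", "controlled_resistor",
    "elastance_chamber",
)

_DEFAULT_DIODE_OFF_FACTOR = 1.0e6


@dataclass
class BloodProperties:
    """Blood density and dynamic viscosity in g–mm–s units."""

    density: float = 1.06e-3        # g/mm³
    dynamic_viscosity: float = 4.0e-3  # g/(mm·s)

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidParameterError("blood density and viscosity must be positive")


@dataclass
class SolverSettings:
    """Fixed-step solver configuration.

    ``time_step`` is nudged to the nearest exact divisor of ``heart_period``
    at assembly so every cycle covers an integer number of steps.
    """

    time_step: float = 1.0e-4          # s
    heart_period: float = 0.8          # s
    max_cycles: int = 20
    periodicity_tolerance: float = 1.0e-3  # relative L-infinity, cycle to cycle

    def __post_init__(self):
        if self.time_step <= 0:
            raise InvalidParameterError("time_step must be positive")
        if self.heart_period <= 0 or self.time_step >= self.heart_period:
            raise InvalidParameterError("need 0 < time_step < heart_period")
        if self.periodicity_tolerance <= 0:
            raise InvalidParameterError("periodicity_tolerance must be positive")
        if self.max_cycles < 1:
            raise InvalidParameterError("max_cycles must be >= 1")

    @property
    def steps_per_cycle(self) -> int:
        return max(2, int(round(self.heart_period / self.time_step)))

    @property
    def effective_time_step(self) -> float:
        return self.heart_period / self.steps_per_cycle


@dataclass
class Waveform:
    """Uniformly sampled signal over (at convergence) exactly one period."""

    times: np.ndarray
    values: np.ndarray
    quantity_kind: str = "pressure"   # "pressure" | "flow" | "volume"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InputError("waveform needs at least two samples")
        if self.values.shape != self.times.shape:
            raise InputError("times and values must have matching shapes")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("waveform times must be strictly increasing")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of the waveform."""
        tt = (np.asarray(t, dtype=float) - self.times[0]) % self.period + self.times[0]
        return np.interp(tt, self.times, self.values)


@dataclass
class Component:
    """A single circuit element between two named nodes.

    ``value`` is the primary parameter in internal units (resistance,
    compliance or inertance); kinds with richer parameterization (diode,
    controlled resistor, elastance chamber) use ``params``:

    diode
        ``r_on``, ``r_off`` (defaults ``r_off = 1e6·r_on``); conducts a→b
        when the pressure drop a→b is positive.
    controlled_resistor
        ``r_on``, ``r_off``, ``transition_width_mmhg`` (smooth logistic
        switch on its own pressure drop); optional ``rs_controller``
        (name of an elastance chamber) and ``rs_coefficient`` add a series
        source resistance Rs(t) = coeff · E(t)·(V − V0).
    elastance_chamber
        ``e_max``, ``e_min``, ``v0``, ``onset_fraction``,
        ``systolic_fraction``, ``law``; must connect node_a to ground.
    """

    kind: str
    name: str
    node_a: str
    node_b: str
    value: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in COMPONENT_KINDS:
            raise InvalidParameterError(f"unknown component kind {self.kind!r}")
        if self.node_a == self.node_b:
            raise InvalidParameterError(f"{self.name}: node_a == node_b")
        if self.kind in ("resistor", "capacitor", "inductor"):
            if self.value is None or not math.isfinite(self.value) or self.value <= 0:
                raise InvalidParameterError(
                    f"{self.name}: {self.kind} needs a positive finite value")
        if self.kind == "diode":
            r_on = self.params.get("r_on", 1.0e-3)
            r_off = self.params.get("r_off", r_on * _DEFAULT_DIODE_OFF_FACTOR)
            if r_on <= 0 or r_off <= r_on:
                raise InvalidParameterError(f"{self.name}: need 0 < r_on < r_off")
            self.params.setdefault("r_on", r_on)
            self.params.setdefault("r_off", r_off)
        if self.kind == "controlled_resistor":
            r_on = self.params.get("r_on")
            r_off = self.params.get("r_off")
            if r_on is None or r_off is None or r_on <= 0 or r_off <= r_on:
                raise InvalidParameterError(f"{self.name}: need 0 < r_on < r_off")
            self.params.setdefault("transition_width_mmhg", 1.0)
        if self.kind == "elastance_chamber":
            p = self.params
            for key in ("e_max", "e_min", "v0"):
                if key not in p:
                    raise InvalidParameterError(f"{self.name}: chamber needs {key!r}")
            if not p["e_max"] >= p["e_min"] > 0:
                raise InvalidParameterError(f"{self.name}: need e_max >= e_min > 0")
            if p["v0"] < 0:
                raise InvalidParameterError(f"{self.name}: v0 must be >= 0")
            p.setdefault("onset_fraction", 0.0)
            p.setdefault("systolic_fraction", 0.3)
            p.setdefault("law", "cosine")


@dataclass
class Netlist:
    """A complete circuit: components, boundary data and monitoring maps.

    ``initial_pressures`` and ``fixed_pressures`` are in mmHg.  Nodes in
    ``fixed_pressures`` are Dirichlet boundary nodes (open-loop distal
    references, preload reservoirs); ``ground`` is always fixed at 0.
    ``imposed_flows`` inject a periodic flow waveform (mm³/s) at a node.
    ``monitor_pressure`` maps site labels to node names, ``monitor_flow``
    maps site labels to component names whose branch flow is recorded.
    """

    components: list[Component]
    initial_pressures: dict[str, float] = field(default_factory=dict)
    imposed_flows: dict[str, Waveform] = field(default_factory=dict)
    fixed_pressures: dict[str, float] = field(default_factory=dict)
    ground: str = "ground"
    monitor_pressure: dict[str, str] = field(default_factory=dict)
    monitor_flow: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.components:
            seen.setdefault(c.node_a)
            seen.setdefault(c.node_b)
        return list(seen)

    @property
    def is_closed_loop(self) -> bool:
        return not self.imposed_flows and not self.fixed_pressures

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise StructuralError(f"no component named {name!r}")

    def validate(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise StructuralError(f"duplicate component names: {dup}")
        nodes = self.nodes
        if not nodes:
            raise StructuralError("empty netlist")
        # connectivity (union-find over component edges)
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for c in self.components:
            parent[find(c.node_a)] = find(c.node_b)
        roots = {find(n) for n in nodes}
        if len(roots) > 1:
            raise StructuralError(f"netlist graph is disconnected ({len(roots)} parts)")
        chamber_names = {c.name for c in self.components
                         if c.kind == "elastance_chamber"}
        for c in self.components:
            if c.kind == "elastance_chamber" and c.node_b != self.ground:
                raise StructuralError(f"{c.name}: chambers must reference ground")
            ref = c.params.get("rs_controller")
            if ref is not None and ref not in chamber_names:
                raise StructuralError(f"{c.name}: unresolvable controller {ref!r}")
        for node, p in {**self.initial_pressures, **self.fixed_pressures}.items():
            if not math.isfinite(p) or p < 0:
                raise StructuralError(f"pressure at {node!r} must be finite and >= 0")
        for site, node in self.monitor_pressure.items():
            if node not in parent:
                raise StructuralError(f"monitor site {site!r}: unknown node {node!r}")
        for site, name in self.monitor_flow.items():
            self.component(name)


@dataclass
class SimulationResult:
    """Final-cycle waveforms and per-site summary metrics."""

    times: np.ndarray
    node_pressure_waveforms: dict[str, Waveform]
    branch_flow_waveforms: dict[str, Waveform]
    cycles_run: int
    periodicity_achieved: bool
    periodicity_history: list[float]
    final_cycle_metrics: dict[str, dict[str, float]]
    # full final-cycle traces for conservation / PV-loop analyses
    node_index: dict[str, int] = field(default_factory=dict)
    pressure_trace: np.ndarray | None = None      # (n_nodes, K+1), internal units
    chamber_names: list[str] = field(default_factory=list)
    chamber_volume_trace: np.ndarray | None = None  # (n_chambers, K+1), mm³
    inductor_names: list[str] = field(default_factory=list)
    inductor_flow_trace: np.ndarray | None = None   # (n_inductors, K+1), mm³/s

    def chamber_volume(self, name: str) -> np.ndarray:
        return self.chamber_volume_trace[self.chamber_names.index(name)]

    def node_pressure(self, node: str) -> np.ndarray:
        return self.pressure_trace[self.node_index[node]]


def cycle_metrics(waveform: Waveform) -> dict[str, float]:
    """Summary metrics of a single-period waveform.

    Pressure: time-averaged mean (trapezoidal), systolic max, diastolic min
    and pulse pressure.  Flow: time-averaged mean and stroke volume
    (integral over the period).  Plateau extrema resolve to the first time
    index attaining them (np.argmax/argmin convention).
    """
    t, v = waveform.times, waveform.values
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise InputError("cycle_metrics requires a uniform time grid")
    period = t[-1] - t[0]
    mean = float(np.trapezoid(v, t) / period)
    if waveform.quantity_kind == "flow":
        return {
            "Q_mean": mean,
            "stroke_volume": float(np.trapezoid(v, t)),
        }
    vmax = float(v[np.argmax(v)])
    vmin = float(v[np.argmin(v)])
    return {
        "P_mean": mean,
        "P_sys": vmax,
        "P_dia": vmin,
        "P_pulse": vmax - vmin,
    }


class AssembledSystem:
    """Netlist compiled into index maps and stamp arrays for time stepping.

    The dynamical state consists of one entry per capacitor (its pressure
    drop), per elastance chamber (its volume) and per inductor (its flow);
    ``state_index`` maps ``(kind, name)`` to the position in that vector and
    ``state_dim`` is its length.  ``derivative(t, y)`` evaluates the
    continuous-time right-hand side (used for cross-checking against
    general-purpose ODE integrators); the production stepper uses implicit
    backward-Euler companion models instead.
    """

    def __init__(self, netlist: Netlist, settings: SolverSettings):
        netlist.validate()
        self.netlist = netlist
        self.settings = settings
        self.dt = settings.effective_time_step
        self.period = settings.heart_period

        nodes = netlist.nodes
        if netlist.ground not in nodes:
            raise StructuralError(f"ground node {netlist.ground!r} not in netlist")
        self.node_names = nodes
        self.nidx = {n: i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)

        fixed = {self.nidx[netlist.ground]: 0.0}
        for node, p in netlist.fixed_pressures.items():
            if node not in self.nidx:
                raise StructuralError(f"fixed-pressure node {node!r} not in netlist")
            fixed[self.nidx[node]] = p * MMHG
        self.fixed = fixed
        self.free_idx = np.array(
            [i for i in range(self.n_nodes) if i not in fixed], dtype=int)
        self.red = -np.ones(self.n_nodes, dtype=int)
        for r, i in enumerate(self.free_idx):
            self.red[i] = r
        self.n_free = len(self.free_idx)

        # element groups
        res, cap, ind, dio, vres, ch = [], [], [], [], [], []
        for c in netlist.components:
            {"resistor": res, "capacitor": cap, "inductor": ind,
             "diode": dio, "controlled_resistor": vres,
             "elastance_chamber": ch}[c.kind].append(c)
        self.res, self.cap, self.ind = res, cap, ind
        self.dio, self.vres, self.ch = dio, vres, ch

        def pairs(group):
            a = np.array([self.nidx[c.node_a] for c in group], dtype=int)
            b = np.array([self.nidx[c.node_b] for c in group], dtype=int)
            return a, b

        self.res_a, self.res_b = pairs(res)
        self.res_g = np.array([1.0 / c.value for c in res])
        self.cap_a, self.cap_b = pairs(cap)
        self.cap_c = np.array([c.value for c in cap])
        self.cap_g = self.cap_c / self.dt
        self.ind_a, self.ind_b = pairs(ind)
        self.ind_l = np.array([c.value for c in ind])
        self.ind_g = self.dt / self.ind_l
        self.dio_a, self.dio_b = pairs(dio)
        self.dio_gon = np.array([1.0 / c.params["r_on"] for c in dio])
        self.dio_goff = np.array([1.0 / c.params["r_off"] for c in dio])
        self.vres_a, self.vres_b = pairs(vres)
        self.ch_a, _ = pairs(ch)
        self.ch_v0 = np.array([c.params["v0"] for c in ch])
        self.ch_names = [c.name for c in ch]
        self._ch_by_name = {c.name: k for k, c in enumerate(ch)}
        self.ind_names = [c.name for c in ind]

        self.state_index: dict[tuple[str, str], int] = {}
        pos = 0
        for c in cap:
            self.state_index[("capacitor", c.name)] = pos
            pos += 1
        for c in ch:
            self.state_index[("elastance_chamber", c.name)] = pos
            pos += 1
        for c in ind:
            self.state_index[("inductor", c.name)] = pos
            pos += 1
        self.state_dim = pos

        # per-cycle precomputations: chamber elastance arrays, imposed flows
        K = settings.steps_per_cycle
        self.K = K
        tgrid = self.dt * np.arange(K + 1)
        self.tgrid = tgrid
        self.ch_E = np.empty((len(ch), K + 1))
        for k, c in enumerate(ch):
            p = c.params
            act = activation_value(tgrid, self.period, p["onset_fraction"],
                                   p["systolic_fraction"], p.get("law", "cosine"))
            self.ch_E[k] = p["e_min"] + (p["e_max"] - p["e_min"]) * act
        self.imposed_idx = []
        self.imposed_q = []
        for node, wf in netlist.imposed_flows.items():
            self.imposed_idx.append(self.nidx[node])
            self.imposed_q.append(wf.sample(tgrid))

        # controlled resistors: controller linkage
        self.vres_gon = np.array([1.0 / c.params["r_on"] for c in vres])
        self.vres_goff = np.array([1.0 / c.params["r_off"] for c in vres])
        self.vres_w = np.array(
            [c.params["transition_width_mmhg"] * MMHG for c in vres])
        self.vres_rs_coef = np.array(
            [c.params.get("rs_coefficient", 0.0) for c in vres])
        self.vres_rs_ch = np.array(
            [self._ch_by_name.get(c.params.get("rs_controller"), -1)
             for c in vres], dtype=int)
        self.vres_ron = np.array([c.params["r_on"] for c in vres])
        self.vres_roff = np.array([c.params["r_off"] for c in vres])

        self._build_stepper_arrays(netlist)

    def _build_stepper_arrays(self, netlist: Netlist) -> None:
        """Precompute the backward-Euler stepping structures.

        Series resistor–inductor pairs joined by an internal degree-2 node
        (the transmission-line sections) are merged into single companion
        branches, shrinking the nodal system; every inductor becomes an
        RL branch (R = 0 when nothing merges).  Time-varying elements
        (chambers, diodes, controlled resistors) get precomputed flat stamp
        indices so per-step assembly is a handful of vectorized adds.
        """
        dt = self.dt
        usage: dict[int, list[Component]] = {}
        for c in netlist.components:
            usage.setdefault(self.nidx[c.node_a], []).append(c)
            usage.setdefault(self.nidx[c.node_b], []).append(c)
        protected = set(self.fixed) | {self.nidx[n] for n in
                                       netlist.imposed_flows}
        protected |= {self.nidx[n] for n in netlist.monitor_pressure.values()}

        res_by_id = {id(c): k for k, c in enumerate(self.res)}
        consumed_res: dict[int, int] = {}  # id(resistor) -> res group idx
        rl_rows = []  # (a, b, g, alpha)
        self.rl_names: list[str] = []
        merged_mid: set[int] = set()
        for k, c in enumerate(self.ind):
            ia, ib = int(self.ind_a[k]), int(self.ind_b[k])
            L = self.ind_l[k]
            partner = None
            for mid, mid_is_b in ((ia, False), (ib, True)):
                if mid in protected or mid in merged_mid:
                    continue
                comps = usage[mid]
                if len(comps) != 2:
                    continue
                other = comps[0] if comps[1] is c else comps[1]
                if other.kind != "resistor" or id(other) in consumed_res:
                    continue
                partner = (mid, other, mid_is_b)
                break
            if partner is None:
                a, b, r = ia, ib, 0.0
            else:
                mid, other, mid_is_b = partner
                r = float(other.value)
                consumed_res[id(other)] = res_by_id[id(other)]
                merged_mid.add(mid)
                r_outer = (self.nidx[other.node_a]
                           if self.nidx[other.node_b] == mid
                           else self.nidx[other.node_b])
                # branch runs a -> (resistor/inductor chain) -> b with the
                # inductor's own orientation, so branch flow == inductor flow
                a, b = (ia, r_outer) if mid_is_b else (r_outer, ib)
            g = dt / (L + r * dt)
            alpha = L / (L + r * dt)
            rl_rows.append((a, b, g, alpha))
            self.rl_names.append(c.name)
        self.rl_a = np.array([r[0] for r in rl_rows], dtype=int)
        self.rl_b = np.array([r[1] for r in rl_rows], dtype=int)
        self.rl_g = np.array([r[2] for r in rl_rows])
        self.rl_alpha = np.array([r[3] for r in rl_rows])
        self._consumed_res_idx = set(consumed_res.values())
        self._res_flow_idx = {c.name: k for k, c in enumerate(self.res)
                              if k not in self._consumed_res_idx}

        # merged internal nodes leave the nodal system entirely
        if merged_mid:
            self.free_idx = np.array(
                [i for i in range(self.n_nodes)
                 if i not in self.fixed and i not in merged_mid], dtype=int)
            self.red = -np.ones(self.n_nodes, dtype=int)
            for rr, i in enumerate(self.free_idx):
                self.red[i] = rr
            self.n_free = len(self.free_idx)
        self.merged_mid = merged_mid

        G0 = np.zeros((self.n_free, self.n_free))
        b0 = np.zeros(self.n_free)
        for k, c in enumerate(self.res):
            if k not in self._consumed_res_idx:
                self._stamp(G0, b0, int(self.res_a[k]), int(self.res_b[k]),
                            float(self.res_g[k]))
        for k in range(len(self.cap)):
            self._stamp(G0, b0, int(self.cap_a[k]), int(self.cap_b[k]),
                        float(self.cap_g[k]))
        for k in range(len(self.rl_a)):
            self._stamp(G0, b0, int(self.rl_a[k]), int(self.rl_b[k]),
                        float(self.rl_g[k]))
        self.G0, self.b0 = G0, b0

        # flat stamp indices for time-varying conductances
        pos, elem, sgn = [], [], []
        bpos, belem, bpfix = [], [], []
        nf = self.n_free

        def add_var(eidx, ia, ib):
            ra, rb = self.red[ia], self.red[ib]
            if ra >= 0:
                pos.append(ra * nf + ra); elem.append(eidx); sgn.append(1.0)
                if rb < 0:
                    bpos.append(ra); belem.append(eidx)
                    bpfix.append(self.fixed[ib])
            if rb >= 0:
                pos.append(rb * nf + rb); elem.append(eidx); sgn.append(1.0)
                if ra < 0:
                    bpos.append(rb); belem.append(eidx)
                    bpfix.append(self.fixed[ia])
            if ra >= 0 and rb >= 0:
                pos.append(ra * nf + rb); elem.append(eidx); sgn.append(-1.0)
                pos.append(rb * nf + ra); elem.append(eidx); sgn.append(-1.0)

        gidx = self.nidx[netlist.ground]
        n_ch, n_dio = len(self.ch), len(self.dio)
        for k in range(n_ch):
            add_var(k, int(self.ch_a[k]), gidx)
        for k in range(n_dio):
            add_var(n_ch + k, int(self.dio_a[k]), int(self.dio_b[k]))
        for k in range(len(self.vres)):
            add_var(n_ch + n_dio + k, int(self.vres_a[k]), int(self.vres_b[k]))
        self.var_pos = np.array(pos, dtype=int)
        self.var_elem = np.array(elem, dtype=int)
        self.var_sgn = np.array(sgn)
        self.var_bpos = np.array(bpos, dtype=int)
        self.var_belem = np.array(belem, dtype=int)
        self.var_bpfix = np.array(bpfix)
        self.ch_red = self.red[self.ch_a] if n_ch else np.empty(0, dtype=int)

    # -- stamping helpers -------------------------------------------------
    def _stamp(self, G, b, a: int, bn: int, g: float, J: float = 0.0):
        """Stamp a branch a→b with conductance g and source flow J (a→b)."""
        ra, rb = self.red[a], self.red[bn]
        if ra >= 0:
            G[ra, ra] += g
            b[ra] += J
            if rb < 0:
                b[ra] += g * self.fixed[bn]
        if rb >= 0:
            G[rb, rb] += g
            b[rb] -= J
            if ra < 0:
                b[rb] += g * self.fixed[a]
        if ra >= 0 and rb >= 0:
            G[ra, rb] -= g
            G[rb, ra] -= g

    # -- continuous-time view (for external ODE cross-checks) -------------
    def derivative(self, t: float, y: np.ndarray) -> np.ndarray:
        """Right-hand side dy/dt of the ODE view of the circuit.

        State layout per ``state_index``.  Requires every capacitor and
        chamber to reference ground (true for all models built here); diode
        and valve conductances use the same smooth logistic law as the
        stepper so the vector field is continuous.
        """
        y = np.asarray(y, dtype=float)
        p = np.zeros(self.n_nodes)
        for i, pv in self.fixed.items():
            p[i] = pv
        ncap, nch = len(self.cap), len(self.ch)
        storage_nodes = set()
        for k, c in enumerate(self.cap):
            if c.node_b != self.netlist.ground:
                raise NotApplicableError("ODE view needs grounded capacitors")
            p[self.cap_a[k]] = y[k]
            storage_nodes.add(int(self.cap_a[k]))
        E_now = np.empty(nch)
        for k, c in enumerate(self.ch):
            pr = c.params
            act = activation_value(t, self.period, pr["onset_fraction"],
                                   pr["systolic_fraction"], pr.get("law", "cosine"))
            E_now[k] = pr["e_min"] + (pr["e_max"] - pr["e_min"]) * act
            p[self.ch_a[k]] = E_now[k] * (y[ncap + k] - self.ch_v0[k])
            storage_nodes.add(int(self.ch_a[k]))
        iL = y[ncap + nch:]

        # algebraic nodes: neither fixed, nor holding a grounded storage element
        alg = [i for i in range(self.n_nodes)
               if i not in self.fixed and i not in storage_nodes]
        aidx = {n: i for i, n in enumerate(alg)}
        G = np.zeros((len(alg), len(alg)))
        rhs = np.zeros(len(alg))

        def add_branch(a, b, g):
            for (x, yn, sgn) in ((a, b, 1.0), (b, a, 1.0)):
                if x in aidx:
                    G[aidx[x], aidx[x]] += g
                    if yn in aidx:
                        G[aidx[x], aidx[yn]] -= g
                    else:
                        rhs[aidx[x]] += g * p[yn]

        def add_inj(node, q):
            if node in aidx:
                rhs[aidx[node]] += q

        for k in range(len(self.res)):
            add_branch(int(self.res_a[k]), int(self.res_b[k]), self.res_g[k])
        gdio = self._smooth_g(p[self.dio_a] - p[self.dio_b],
                              self.dio_gon, self.dio_goff,
                              np.full(len(self.dio), 0.1 * MMHG))
        for k in range(len(self.dio)):
            add_branch(int(self.dio_a[k]), int(self.dio_b[k]), gdio[k])
        gv = self._vres_g(p[self.vres_a] - p[self.vres_b], E_now,
                          y[ncap:ncap + nch] if nch else np.empty(0))
        for k in range(len(self.vres)):
            add_branch(int(self.vres_a[k]), int(self.vres_b[k]), gv[k])
        for k in range(len(self.ind)):
            add_inj(int(self.ind_a[k]), -iL[k])
            add_inj(int(self.ind_b[k]), iL[k])
        for node, wf in self.netlist.imposed_flows.items():
            add_inj(self.nidx[node], wf.sample(t))
        if alg:
            p_alg = np.linalg.solve(G, rhs)
            for n, i in aidx.items():
                p[n] = p_alg[i]

        # net inflow into each storage node
        inflow = np.zeros(self.n_nodes)
        for arr_a, arr_b, g in ((self.res_a, self.res_b, self.res_g),):
            flow = g * (p[arr_a] - p[arr_b])
            np.add.at(inflow, arr_a, -flow)
            np.add.at(inflow, arr_b, flow)
        if len(self.dio):
            flow = gdio * (p[self.dio_a] - p[self.dio_b])
            np.add.at(inflow, self.dio_a, -flow)
            np.add.at(inflow, self.dio_b, flow)
        if len(self.vres):
            flow = gv * (p[self.vres_a] - p[self.vres_b])
            np.add.at(inflow, self.vres_a, -flow)
            np.add.at(inflow, self.vres_b, flow)
        if len(self.ind):
            np.add.at(inflow, self.ind_a, -iL)
            np.add.at(inflow, self.ind_b, iL)
        for node, wf in self.netlist.imposed_flows.items():
            inflow[self.nidx[node]] += wf.sample(t)

        dy = np.empty_like(y)
        for k in range(ncap):
            dy[k] = inflow[self.cap_a[k]] / self.cap_c[k]
        for k in range(nch):
            dy[ncap + k] = inflow[self.ch_a[k]]
        dy[ncap + nch:] = (p[self.ind_a] - p[self.ind_b]) / self.ind_l
        return dy

    @staticmethod
    def _smooth_g(dp, g_on, g_off, width):
        x = np.clip(dp / width, -40.0, 40.0)
        s = 1.0 / (1.0 + np.exp(-x))
        return g_off + (g_on - g_off) * s

    def _vres_g(self, dp, E_now, Vch):
        """Controlled-resistor conductance incl. series source resistance."""
        r_on = self.vres_ron.copy()
        has_rs = self.vres_rs_ch >= 0
        if np.any(has_rs):
            idx = self.vres_rs_ch[has_rs]
            piso = np.maximum(E_now[idx] * (Vch[idx] - self.ch_v0[idx]), 0.0)
            r_on[has_rs] += self.vres_rs_coef[has_rs] * piso
        g_on = 1.0 / r_on
        return self._smooth_g(dp, g_on, self.vres_goff, self.vres_w)


def assemble_system(netlist: Netlist, settings: SolverSettings) -> AssembledSystem:
    """Compile a netlist into an assembled dynamical system."""
    return AssembledSystem(netlist, settings)


def simulate(netlist: Netlist, settings: SolverSettings) -> SimulationResult:
    """Integrate the circuit to cycle-to-cycle periodicity.

    Runs fixed-step backward Euler for up to ``settings.max_cycles`` heart
    periods, comparing every monitored waveform with the previous cycle;
    stops once the maximum relative L∞ change drops below
    ``settings.periodicity_tolerance``.  Returns the final cycle.
    """
    from scipy.linalg import lapack

    sys_ = assemble_system(netlist, settings)
    dt, K = sys_.dt, sys_.K
    N = sys_.n_nodes
    free_idx = sys_.free_idx

    p = np.zeros(N)
    for node, pv in netlist.initial_pressures.items():
        if node in sys_.nidx:
            p[sys_.nidx[node]] = pv * MMHG
    for i, pv in sys_.fixed.items():
        p[i] = pv
    irl = np.zeros(len(sys_.rl_a))
    Vch = np.empty(len(sys_.ch))
    for k in range(len(sys_.ch)):
        Vch[k] = sys_.ch_v0[k] + max(p[sys_.ch_a[k]], 0.0) / sys_.ch_E[k, 0]
    dio_on = np.zeros(len(sys_.dio), dtype=bool)

    mon_p_nodes = {site: sys_.nidx[node]
                   for site, node in netlist.monitor_pressure.items()}
    mon_f: dict[str, tuple[str, int]] = {}
    for site, cname in netlist.monitor_flow.items():
        comp = netlist.component(cname)
        if comp.kind == "inductor":
            mon_f[site] = ("inductor", sys_.rl_names.index(cname))
        elif comp.kind == "resistor" and cname in sys_._res_flow_idx:
            mon_f[site] = ("resistor", sys_._res_flow_idx[cname])
        else:
            raise StructuralError(
                f"monitor_flow {site!r}: only inductor or unmerged resistor "
                f"branches supported")

    prev_mon: dict[str, np.ndarray] | None = None
    periodicity_history: list[float] = []
    periodic = False

    p_trace = np.empty((N, K + 1))
    irl_trace = np.empty((len(sys_.rl_a), K + 1))
    V_trace = np.empty((len(sys_.ch), K + 1))

    n_ch, n_dio, n_vres = len(sys_.ch), len(sys_.dio), len(sys_.vres)
    g_all = np.empty(n_ch + n_dio + n_vres)
    has_cap = len(sys_.cap) > 0
    has_rl = len(sys_.rl_a) > 0
    Gflat_template = sys_.G0.reshape(-1)

    cycles = 0
    for cycle in range(settings.max_cycles):
        cycles = cycle + 1
        p_trace[:, 0] = p
        irl_trace[:, 0] = irl
        V_trace[:, 0] = Vch
        for k in range(K):
            kk = k + 1
            E_next = sys_.ch_E[:, kk]
            if n_ch:
                g_all[:n_ch] = 1.0 / (E_next * dt)
                J_ch = (Vch - sys_.ch_v0) / dt

            b_full = np.zeros(N)
            if has_cap:
                Jc = sys_.cap_g * (p[sys_.cap_a] - p[sys_.cap_b])
                np.add.at(b_full, sys_.cap_a, Jc)
                np.add.at(b_full, sys_.cap_b, -Jc)
            if has_rl:
                Jrl = sys_.rl_alpha * irl
                np.add.at(b_full, sys_.rl_a, -Jrl)
                np.add.at(b_full, sys_.rl_b, Jrl)
            for node_i, qarr in zip(sys_.imposed_idx, sys_.imposed_q):
                b_full[node_i] += qarr[kk]
            b_base = sys_.b0 + b_full[free_idx]
            if n_ch:
                np.add.at(b_base, sys_.ch_red, J_ch)

            if n_vres:
                dp_v = p[sys_.vres_a] - p[sys_.vres_b]
                g_v = sys_._vres_g(dp_v, E_next, Vch)
            p_new = p
            for it in range(6):
                if n_dio:
                    g_all[n_ch:n_ch + n_dio] = np.where(
                        dio_on, sys_.dio_gon, sys_.dio_goff)
                if n_vres:
                    g_all[n_ch + n_dio:] = g_v
                G = Gflat_template.copy()
                np.add.at(G, sys_.var_pos,
                          g_all[sys_.var_elem] * sys_.var_sgn)
                b = b_base.copy()
                if sys_.var_bpos.size:
                    np.add.at(b, sys_.var_bpos,
                              g_all[sys_.var_belem] * sys_.var_bpfix)
                _, _, x, info = lapack.dgesv(
                    G.reshape(sys_.n_free, sys_.n_free), b,
                    overwrite_a=1, overwrite_b=1)
                if info != 0 or not np.isfinite(x).all():
                    bad = sys_.node_names[free_idx[
                        int(np.argmax(~np.isfinite(x)))]] if info == 0 else "?"
                    raise DivergenceError(
                        f"linear solve failed near node {bad!r} "
                        f"(t={cycle * settings.heart_period + kk * dt:.4f}s)")
                p_new = p.copy()
                p_new[free_idx] = x
                done = True
                if n_dio:
                    new_on = (p_new[sys_.dio_a] - p_new[sys_.dio_b]) > 0.0
                    if not np.array_equal(new_on, dio_on):
                        dio_on = new_on
                        done = False
                if n_vres and done:
                    dp_now = p_new[sys_.vres_a] - p_new[sys_.vres_b]
                    g_now = sys_._vres_g(dp_now, E_next, Vch)
                    if np.any(np.abs(g_now - g_v) > 0.5 * np.abs(g_v)):
                        g_v = g_now
                        done = False
                if done:
                    break
            p = p_new
            if has_rl:
                irl = sys_.rl_g * (p[sys_.rl_a] - p[sys_.rl_b]) \
                    + sys_.rl_alpha * irl
            if n_ch:
                Vch = sys_.ch_v0 + p[sys_.ch_a] / E_next
            p_trace[:, kk] = p
            irl_trace[:, kk] = irl
            V_trace[:, kk] = Vch

        mon_now: dict[str, np.ndarray] = {
            f"P:{site}": p_trace[i].copy() for site, i in mon_p_nodes.items()}
        for site, (kind, idx) in mon_f.items():
            if kind == "inductor":
                mon_now[f"Q:{site}"] = irl_trace[idx].copy()
            else:
                a, b_ = int(sys_.res_a[idx]), int(sys_.res_b[idx])
                mon_now[f"Q:{site}"] = sys_.res_g[idx] * (
                    p_trace[a] - p_trace[b_])
        if not mon_now:
            mon_now = {"P:_all": p_trace.max(axis=0)}
        if prev_mon is not None:
            rel = 0.0
            for key, arr in mon_now.items():
                scale = max(float(np.max(np.abs(prev_mon[key]))), 1e-9)
                rel = max(rel, float(np.max(np.abs(arr - prev_mon[key]))) / scale)
            periodicity_history.append(rel)
            if rel <= settings.periodicity_tolerance:
                periodic = True
                break
        prev_mon = mon_now

    times = sys_.tgrid
    node_wf, flow_wf, metrics = {}, {}, {}
    for site, i in mon_p_nodes.items():
        wf = Waveform(times, p_trace[i] / MMHG, "pressure")
        node_wf[site] = wf
        m = cycle_metrics(Waveform(times, p_trace[i], "pressure"))
        metrics.setdefault(site, {}).update(
            {k: v / MMHG for k, v in m.items()})
    for site, (kind, idx) in mon_f.items():
        if kind == "inductor":
            q = irl_trace[idx]
        else:
            a, b_ = int(sys_.res_a[idx]), int(sys_.res_b[idx])
            q = sys_.res_g[idx] * (p_trace[a] - p_trace[b_])
        wf = Waveform(times, q, "flow")
        flow_wf[site] = wf
        metrics.setdefault(site, {}).update(cycle_metrics(wf))

    return SimulationResult(
        times=times,
        node_pressure_waveforms=node_wf,
        branch_flow_waveforms=flow_wf,
        cycles_run=cycles,
        periodicity_achieved=periodic,
        periodicity_history=periodicity_history,
        final_cycle_metrics=metrics,
        node_index=dict(sys_.nidx),
        pressure_trace=p_trace,
        chamber_names=list(sys_.ch_names),
        chamber_volume_trace=V_trace,
        inductor_names=list(sys_.rl_names),
        inductor_flow_trace=irl_trace,
    )


def total_stressed_volume(result: SimulationResult, netlist: Netlist) -> np.ndarray:
    """Total stressed volume (mm³) over the final cycle of a closed loop.

    Sums capacitor stored volumes C·ΔP and chamber volumes above their
    unstressed volume.  In a closed loop this trace is conserved by the
    integrator up to linear-solve round-off; raises
    :class:`NotApplicableError` for open-loop netlists (imposed flows or
    fixed boundary pressures exchange volume with the exterior).
    """
    if not netlist.is_closed_loop:
        raise NotApplicableError("stressed-volume conservation needs a closed loop")
    if result.pressure_trace is None:
        raise InputError("result carries no full pressure trace")
    vol = np.zeros(result.pressure_trace.shape[1])
    for c in netlist.components:
        ia, ib = result.node_index[c.node_a], result.node_index[c.node_b]
        if c.kind == "capacitor":
            vol += c.value * (result.pressure_trace[ia] - result.pressure_trace[ib])
        elif c.kind == "elastance_chamber":
            vol += result.chamber_volume(c.name) - c.params["v0"]
    return vol
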