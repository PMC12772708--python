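"""Reduced-order arterial network: RLC transmission-line segments.

The large systemic and pulmonary arteries are represented as a rooted tree
of thin-walled elastic tube segments, each lumped into one or more RLC
L-sections (series resistance + inertance, shunt compliance at the distal
node).  Per segment of length l, diastolic inner radius Ri, wall thickness h
and effective Young's modulus E (with blood density ρ, viscosity μ):

    R = 8 μ l / (π Ri⁴)          (Poiseuille)
    L = ρ l / (π Ri²)            (blood inertance)
    C = 3 π Ri³ l / (2 E h)      (thin-wall linear-elastic tube)

The compliance uses the Poisson-ratio-free 3/2-factor convention consistent
with the linearized-stiffness estimator in :mod:`hemocal.metrics`.  The
number of L-sections per segment trades wave-propagation fidelity for speed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .circuit import (BloodProperties, Component, InputError,
                      InvalidParameterError, StructuralError)

__all__ = ["VesselSegment", "ArterialTree", "segment_rlc",
           "build_tree_netlist", "interpolate_stiffness"]

MEASUREMENT_SITES = ("AAo", "DTA", "MPA", "LPA", "RPA")


@dataclass
class VesselSegment:
    """One vessel of the reduced-order tree.

    ``site`` is a measurement-site label (AAo/DTA/MPA/LPA/RPA) or
    ``"branch"`` for unmeasured side branches.  Geometry in mm, stiffness in
    internal pressure units (g/(mm·s²) = Pa).
    """

    name: str
    site: str
    inner_radius: float      # mm (diastolic)
    wall_thickness: float    # mm
    length: float            # mm
    stiffness: float         # g/(mm·s²)
    parent: str | None = None
    sections: int = 5

    def __post_init__(self):
        if min(self.inner_radius, self.wall_thickness, self.length,
               self.stiffness) <= 0:
            raise InvalidParameterError(
                f"{self.name}: geometry and stiffness must be positive")
        if self.sections < 1:
            raise InvalidParameterError(f"{self.name}: sections must be >= 1")


@dataclass
class ArterialTree:
    """Rooted tree of vessel segments; leaves are Windkessel outlets."""

    segments: list[VesselSegment]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate segment names")
        byname = self.by_name
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise StructuralError(f"tree must have exactly one root, got {len(roots)}")
        for s in self.segments:
            if s.parent is not None and s.parent not in byname:
                raise StructuralError(f"{s.name}: unknown parent {s.parent!r}")
        # reject cycles / unreachable segments
        for s in self.segments:
            seen = set()
            cur = s
            while cur.parent is not None:
                if cur.name in seen:
                    raise StructuralError("cycle in segment parents")
                seen.add(cur.name)
                cur = byname[cur.parent]

    @property
    def by_name(self) -> dict[str, VesselSegment]:
        return {s.name: s for s in self.segments}

    @property
    def root(self) -> VesselSegment:
        return next(s for s in self.segments if s.parent is None)

    @property
    def children(self) -> dict[str, list[VesselSegment]]:
        ch: dict[str, list[VesselSegment]] = {s.name: [] for s in self.segments}
        for s in self.segments:
            if s.parent is not None:
                ch[s.parent].append(s)
        return ch

    @property
    def outlets(self) -> list[str]:
        ch = self.children
        return [s.name for s in self.segments if not ch[s.name]]

    def centerline_positions(self) -> dict[str, float]:
        """Distance (mm) from the tree root to each segment's midpoint."""
        byname = self.by_name
        pos: dict[str, float] = {}

        def inlet_distance(seg: VesselSegment) -> float:
            if seg.parent is None:
                return 0.0
            par = byname[seg.parent]
            return inlet_distance(par) + par.length

        for s in self.segments:
            pos[s.name] = inlet_distance(s) + 0.5 * s.length
        return pos

    def path_to_root(self, name: str) -> list[str]:
        byname = self.by_name
        path = [name]
        while byname[path[-1]].parent is not None:
            path.append(byname[path[-1]].parent)
        return path

    def total_compliance(self, blood: BloodProperties | None = None) -> float:
        blood = blood or BloodProperties()
        return sum(segment_rlc(s, blood)[2] for s in self.segments)

    def equivalent_resistance(self, blood: BloodProperties | None = None) -> float:
        """Series/parallel-combined resistance from root inlet to all outlets."""
        blood = blood or BloodProperties()
        ch = self.children

        def req(seg: VesselSegment) -> float:
            r = segment_rlc(seg, blood)[0]
            kids = ch[seg.name]
            if not kids:
                return r
            inv = sum(1.0 / req(k) for k in kids)
            return r + 1.0 / inv

        return req(self.root)

    def scaled_stiffness(self, factor: float) -> "ArterialTree":
        return ArterialTree([replace(s, stiffness=s.stiffness * factor)
                             for s in self.segments])


def segment_rlc(seg: VesselSegment, blood: BloodProperties) -> tuple[float, float, float]:
    """Lumped (R, L, C) of one segment, internal units."""
    ri, l = seg.inner_radius, seg.length
    r = 8.0 * blood.dynamic_viscosity * l / (math.pi * ri ** 4)
    ind = blood.density * l / (math.pi * ri ** 2)
    c = 3.0 * math.pi * ri ** 3 * l / (2.0 * seg.stiffness * seg.wall_thickness)
    return r, ind, c


def build_tree_netlist(tree: ArterialTree, blood: BloodProperties,
                       inlet_node: str, prefix: str = "") -> list[Component]:
    """Netlist fragment for the tree: per section, series R then L then a
    shunt C to ground at the distal node.

    Node naming: segment ``X`` spans ``{prefix}X_in`` (= parent's outlet or
    ``inlet_node`` at the root) through ``{prefix}X_s{k}`` section nodes to
    ``{prefix}X_out``.  Leaf outlet nodes are ``{prefix}X_out``.
    """
    outlets = tree.outlets
    if len(set(outlets)) != len(outlets):
        raise StructuralError("duplicate outlet labels")
    comps: list[Component] = []
    for seg in tree.segments:
        r, ind, c = segment_rlc(seg, blood)
        n = seg.sections
        upstream = inlet_node if seg.parent is None else f"{prefix}{seg.parent}_out"
        for k in range(n):
            distal = (f"{prefix}{seg.name}_out" if k == n - 1
                      else f"{prefix}{seg.name}_s{k}")
            mid = f"{prefix}{seg.name}_m{k}"
            comps.append(Component("resistor", f"{prefix}{seg.name}_R{k}",
                                   upstream, mid, value=r / n))
            comps.append(Component("inductor", f"{prefix}{seg.name}_L{k}",
                                   mid, distal, value=ind / n))
            comps.append(Component("capacitor", f"{prefix}{seg.name}_C{k}",
                                   distal, "ground", value=c / n))
            upstream = distal
    return comps


def interpolate_stiffness(site_values: dict[str, float],
                          tree: ArterialTree) -> dict[str, float]:
    """Assign per-segment stiffness from site-wise measurements.

    Segments whose ``site`` is measured take that value.  Segments lying on
    a root-path between two measured segments are linearly interpolated in
    centerline position; segments beyond the measured range, and unmeasured
    branches, take the nearest measured segment's value (nearest in
    centerline distance).
    """
    if not site_values:
        raise InputError("site_values must not be empty")
    pos = tree.centerline_positions()
    byname = tree.by_name
    measured: dict[str, float] = {}
    for s in tree.segments:
        if s.site in site_values:
            measured[s.name] = float(site_values[s.site])
    if not measured:
        raise InputError("no tree segment matches a measured site")

    children = tree.children

    def measured_descendants(name: str) -> list[str]:
        out = []
        stack = [k.name for k in children[name]]
        while stack:
            n = stack.pop()
            if n in measured:
                out.append(n)
            else:
                stack.extend(k.name for k in children[n])
        return out

    result: dict[str, float] = {}
    for s in tree.segments:
        if s.name in measured:
            result[s.name] = measured[s.name]
            continue
        anc = None
        for n in tree.path_to_root(s.name)[1:]:
            if n in measured:
                anc = n
                break
        desc = measured_descendants(s.name)
        if anc is not None and desc:
            d = min(desc, key=lambda n: pos[n])
            x0, x1 = pos[anc], pos[d]
            w = 0.0 if x1 == x0 else (pos[s.name] - x0) / (x1 - x0)
            w = min(max(w, 0.0), 1.0)
            result[s.name] = (1 - w) * measured[anc] + w * measured[d]
        else:
            nearest = min(measured, key=lambda n: abs(pos[n] - pos[s.name]))
            result[s.name] = measured[nearest]
    return result
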