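"""Model- and clinically-derived hemodynamic metrics.

Covers the seven model-derived quantities the pipeline reports: linearized
arterial stiffness at the five measurement sites (AAo, DTA, MPA, LPA, RPA),
the three pulse wave velocities (MPA→LPA, MPA→RPA, AAo→DTA) and the
central/peripheral distribution of pulmonary resistance and compliance —
plus longitudinal baseline-vs-follow-up comparison tables.

Linearized stiffness of a thin-walled vessel from pressure and lumen
deformation:

    E = 1.5 · ΔP · Ri² · Ro / ((Ro² − Ri²) · ΔR)

with Ri the diastolic luminal radius, Ro = Ri·(1 + h/Ri) the outer radius
(default wall-thickness-to-radius ratio 15 %), ΔP the pulse pressure and
ΔR the systolic-minus-diastolic radius change.  E carries the pressure
units of ΔP.  Two PWV estimators are provided: Moens–Korteweg from wall
properties, and foot-to-foot transit time on simulated waveforms
(intersecting-tangent foot detection).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import InputError, InvalidParameterError, Waveform

__all__ = ["StiffnessInput", "linearized_stiffness", "moens_korteweg_pwv",
           "foot_to_foot_pwv", "pulmonary_rc_split", "percent_change",
           "longitudinal_report", "derived_metrics", "DegenerateDeformationError",
           "PhaseOrderError", "UndefinedBaselineError",
           "linearized_stiffness_delta_r", "radius_from_area"]

DEFAULT_THICKNESS_RATIO = 0.15


class DegenerateDeformationError(ValueError):
    """ΔR ≤ 0: stiffness is undefined/infinite."""


class PhaseOrderError(ValueError):
    """Non-positive wave transit time between two sites."""


class UndefinedBaselineError(ZeroDivisionError):
    """Percent change/error against a zero baseline."""


@dataclass
class StiffnessInput:
    """Site-wise pressure and lumen-radius pair for stiffness estimation.

    Pressures in any consistent unit (E inherits it), radii in mm.
    """

    p_sys: float
    p_dia: float
    r_sys: float
    r_dia: float
    thickness_ratio: float = DEFAULT_THICKNESS_RATIO

    def __post_init__(self):
        if not self.p_sys > self.p_dia:
            raise InvalidParameterError("need P_sys > P_dia")
        if not self.r_sys > self.r_dia > 0:
            raise DegenerateDeformationError("need R_sys > R_dia > 0")
        if self.thickness_ratio <= 0:
            raise InvalidParameterError("thickness_ratio must be positive")


def linearized_stiffness(inp: StiffnessInput) -> float:
    """Effective wall stiffness E from systolic/diastolic pressure and radius."""
    ri = inp.r_dia
    ro = ri * (1.0 + inp.thickness_ratio)
    dp = inp.p_sys - inp.p_dia
    dr = inp.r_sys - inp.r_dia
    if dr <= 0:
        raise DegenerateDeformationError("ΔR must be positive")
    return 1.5 * dp * ri ** 2 * ro / ((ro ** 2 - ri ** 2) * dr)


def linearized_stiffness_delta_r(dp: float, ri: float, ro: float,
                                 stiffness: float) -> float:
    """Invert the stiffness relation for ΔR (used by the data generator)."""
    return 1.5 * dp * ri ** 2 * ro / ((ro ** 2 - ri ** 2) * stiffness)


def radius_from_area(area: float) -> float:
    """Circular-lumen radius from a PC-MRI cross-sectional area."""
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    return math.sqrt(area / math.pi)


def moens_korteweg_pwv(stiffness: float, h: float, ri: float,
                       density: float) -> float:
    """Moens–Korteweg pulse wave velocity sqrt(E·h / (2·ρ·Ri)), mm/s."""
    if min(stiffness, h, ri, density) < 0 or min(stiffness, ri, density) == 0:
        raise InvalidParameterError("stiffness, Ri, density must be positive")
    return math.sqrt(stiffness * h / (2.0 * density * ri))


def _wave_foot(wf: Waveform) -> float:
    """Foot time by the intersecting-tangent method.

    The tangent at the steepest upslope is intersected with the horizontal
    through the waveform minimum; the crossing time is the foot.
    """
    t, v = wf.times, wf.values
    dv = np.gradient(v, t)
    k = int(np.argmax(dv))
    slope = dv[k]
    if slope <= 0:
        raise PhaseOrderError("waveform has no rising edge")
    vmin = float(np.min(v))
    return float(t[k] - (v[k] - vmin) / slope)


def foot_to_foot_pwv(wave_a: Waveform, wave_b: Waveform,
                     path_length: float) -> float:
    """PWV from the transit time between wave feet at two sites (mm/s).

    Transit times are wrapped into the (0, period) interval; identical
    (zero-delay) waveforms raise :class:`PhaseOrderError`.
    """
    if path_length <= 0:
        raise InvalidParameterError("path_length must be positive")
    if abs(wave_a.period - wave_b.period) > 1e-9 * wave_a.period:
        raise InputError("waveforms must share the same period")
    period = wave_a.period
    dt = _wave_foot(wave_b) - _wave_foot(wave_a)
    tol = 1e-9 * period
    if abs(dt) <= tol:
        raise PhaseOrderError("zero transit time between sites")
    if dt < 0:
        dt += period
    return path_length / dt


def percent_change(baseline: float, follow_up: float) -> float:
    """Signed longitudinal change, 100·(follow-up − baseline)/baseline."""
    if baseline == 0:
        raise UndefinedBaselineError("baseline value is zero")
    return 100.0 * (follow_up - baseline) / baseline


def pulmonary_rc_split(model) -> dict[str, float]:
    """Central vs peripheral pulmonary resistance and compliance.

    Central: the arterial-tree segments (series/parallel-combined R along
    the flow paths, summed compliances).  Peripheral: the Windkessel
    outlets (parallel combination of Rp+Rd, summed compliances).
    Returns totals and the central/peripheral fraction per quantity.
    """
    from .model import PatientModel
    if not isinstance(model, PatientModel):
        raise InvalidParameterError("expected a PatientModel")
    if not model.pulmonary_outlets:
        raise InvalidParameterError("model has no pulmonary outlets")
    tree = model.pulmonary_tree
    r_central = tree.equivalent_resistance(model.blood)
    c_central = tree.total_compliance(model.blood)
    r_periph = 1.0 / sum(1.0 / wk.total_resistance
                         for wk in model.pulmonary_outlets.values())
    c_periph = sum(wk.c for wk in model.pulmonary_outlets.values())
    r_total = r_central + r_periph
    c_total = c_central + c_periph
    return {
        "R_total": r_total, "C_total": c_total,
        "R_central": r_central, "R_peripheral": r_periph,
        "C_central": c_central, "C_peripheral": c_periph,
        "R_central_fraction": r_central / r_total,
        "R_peripheral_fraction": r_periph / r_total,
        "C_central_fraction": c_central / c_total,
        "C_peripheral_fraction": c_periph / c_total,
    }


def derived_metrics(model, result=None) -> dict[str, float]:
    """The model-derived metric set for one timepoint.

    Stiffness (internal pressure units) at the five sites from the tree's
    calibrated segment stiffness; Moens–Korteweg PWV along MPA→LPA,
    MPA→RPA and AAo→DTA paths (path-averaged wall properties); pulmonary
    R/C totals and central/peripheral fractions.  If a simulation result is
    supplied, foot-to-foot PWVs from the monitored pressure waveforms are
    added where both site waveforms exist.
    """
    out: dict[str, float] = {}
    trees = {"pulmonary": model.pulmonary_tree, "systemic": model.systemic_tree}
    site_seg = {}
    for tree in trees.values():
        for seg in tree.segments:
            if seg.site in ("AAo", "DTA", "MPA", "LPA", "RPA"):
                site_seg[seg.site] = seg
    for site, seg in site_seg.items():
        out[f"stiffness_{site}"] = seg.stiffness

    rho = model.blood.density
    for label, (a, b, tree) in {
            "MPA-LPA": ("MPA", "LPA", trees["pulmonary"]),
            "MPA-RPA": ("MPA", "RPA", trees["pulmonary"]),
            "AAo-DTA": ("AAo", "DTA", trees["systemic"])}.items():
        sa, sb = site_seg[a], site_seg[b]
        pwv = 0.5 * (
            moens_korteweg_pwv(sa.stiffness, sa.wall_thickness,
                               sa.inner_radius, rho)
            + moens_korteweg_pwv(sb.stiffness, sb.wall_thickness,
                                 sb.inner_radius, rho))
        out[f"pwv_mk_{label}"] = pwv
        if result is not None:
            wfs = result.node_pressure_waveforms
            if a in wfs and b in wfs:
                path = 0.5 * (sa.length + sb.length)
                try:
                    out[f"pwv_ftf_{label}"] = foot_to_foot_pwv(
                        wfs[a], wfs[b], path)
                except (PhaseOrderError, InputError):
                    pass
    out.update({f"pulmonary_{k}": v for k, v in pulmonary_rc_split(model).items()})
    if result is not None:
        m = result.final_cycle_metrics
        if "MPA" in m:
            out["mPAP"] = m["MPA"].get("P_mean", float("nan"))
            out["MPA_pulse_pressure"] = m["MPA"].get("P_pulse",
                                                     m["MPA"].get("P_sys", 0)
                                                     - m["MPA"].get("P_dia", 0))
    return out


def longitudinal_report(metrics_baseline: dict[str, float],
                        metrics_followup: dict[str, float]) -> pd.DataFrame:
    """Baseline / follow-up / percent-change table.

    Keys present in only one timepoint are listed with a missing percent
    change rather than raising.  Percent changes are rounded to 1 decimal
    place in the rendered table (raw values kept in ``percent_change_raw``).
    """
    keys = sorted(set(metrics_baseline) | set(metrics_followup))
    rows = []
    for k in keys:
        b = metrics_baseline.get(k)
        f = metrics_followup.get(k)
        pc = None
        if b is not None and f is not None and b != 0:
            pc = percent_change(b, f)
        rows.append({"metric": k, "baseline": b, "followup": f,
                     "percent_change_raw": pc,
                     "percent_change": None if pc is None else round(pc, 1)})
    return pd.DataFrame(rows)
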