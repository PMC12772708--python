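"""Virtual-patient generator: ground-truth circulation models with
clinical-style hemodynamic target tables.

Each virtual patient is a fully specified closed-loop circulation
(:class:`~hemocal.model.PatientModel`) whose converged simulation supplies
the "measured" pressures, flows and vessel deformations a real study would
obtain from catheterization and PC-MRI.  Because the ground truth is known,
every stage of the calibration pipeline can be scored against it.

Severity profiles span pediatric pulmonary arterial hypertension from
near-normal (mean pulmonary artery pressure ≈ 20 mmHg) to severe
(> 80 mmHg) by scaling pulmonary vascular resistance, arterial stiffness
(with peripheral compliance scaling inversely) and right-ventricular
contractility — the canonical PAH triad of raised resistance, stiffened
arteries and a pressure-overloaded but initially compensating right heart.
Longitudinal pairs re-simulate the same anatomy with stiffness/resistance/
compliance scaled by a progression spec, mimicking worsening or improving
disease over a follow-up interval.

Geometry defaults (MPA radius 8–14 mm, heart rate 70–110 bpm, body surface
area 0.9–1.9 m²) are this package's documented pediatric-plausible choices.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ClinicalTargets
from .circuit import CircuitError, SimulationResult, simulate
from .heart import ChamberParams, HeartParams, ValveParams
from .metrics import linearized_stiffness_delta_r
from .model import PatientModel, WindkesselParams, build_stage_netlist
from .units import L_PER_MIN, MMHG_PER_ML, ML, ML_PER_MMHG

__all__ = ["SeverityProfile", "ProgressionSpec", "VirtualPatient",
           "PROFILES", "generate_patient", "add_measurement_noise",
           "generate_longitudinal_pair", "export_cohort", "ClinicalTargets"]


@dataclass
class SeverityProfile:
    """Disease-severity scaling applied to the normal baseline circulation."""

    label: str
    mpap_band: tuple[float, float]        # mmHg, expected mean PAP range
    resistance_multiplier: float
    stiffness_multiplier: float
    contractility_multiplier: float

    def __post_init__(self):
        if min(self.resistance_multiplier, self.stiffness_multiplier,
               self.contractility_multiplier) <= 0:
            raise ValueError("profile multipliers must be positive")


PROFILES: dict[str, SeverityProfile] = {
    "normal": SeverityProfile("normal", (14.0, 30.0), 1.0, 1.0, 1.0),
    "moderate": SeverityProfile("moderate", (33.0, 65.0), 3.2, 2.2, 2.6),
    "severe": SeverityProfile("severe", (70.0, 115.0), 7.0, 3.6, 4.8),
}


@dataclass
class ProgressionSpec:
    """Longitudinal change imposed on a baseline virtual patient."""

    direction: str                     # "worsening" | "improving"
    stiffness_factor: float = 3.0
    resistance_factor: float = 1.3
    compliance_factor: float = 0.75
    contractility_factor: float = 1.3
    interval_years: float = 2.0

    def __post_init__(self):
        if self.direction not in ("worsening", "improving"):
            raise ValueError("direction must be 'worsening' or 'improving'")
        if min(self.stiffness_factor, self.resistance_factor,
               self.compliance_factor, self.contractility_factor) <= 0:
            raise ValueError("progression factors must be positive")


def improving_spec() -> ProgressionSpec:
    return ProgressionSpec("improving", stiffness_factor=0.5,
                           resistance_factor=0.6, compliance_factor=1.5,
                           contractility_factor=0.85)


@dataclass
class VirtualPatient:
    """Ground-truth model plus the clinical-style targets generated from it."""

    seed: int
    profile: str
    model: PatientModel                 # ground truth
    targets: ClinicalTargets            # clean
    geometry: pd.DataFrame              # per-site radii/lengths (mm)
    demographics: dict[str, float]
    truth_summary: dict[str, float]     # simulated ground-truth metrics
    simulation: SimulationResult | None = None


# ---------------------------------------------------------------------------
# baseline anatomy and physiology

_SITE_SEGMENTS_PULMONARY = [
    # name, site, parent, radius-scale vs MPA, length (mm), sections
    ("MPA", "MPA", None, 1.00, 45.0, 5),
    ("LPA", "LPA", "MPA", 0.70, 32.0, 5),
    ("RPA", "RPA", "MPA", 0.72, 36.0, 5),
    ("LPA_b1", "branch", "LPA", 0.48, 25.0, 2),
    ("LPA_b2", "branch", "LPA", 0.45, 25.0, 2),
    ("RPA_b1", "branch", "RPA", 0.50, 25.0, 2),
    ("RPA_b2", "branch", "RPA", 0.46, 25.0, 2),
]

_SITE_SEGMENTS_SYSTEMIC = [
    ("AAo", "AAo", None, 1.00, 55.0, 5),
    ("ARCH", "branch", "AAo", 0.45, 30.0, 2),
    ("DTA", "DTA", "AAo", 0.80, 110.0, 5),
]

_THICKNESS_RATIO = 0.15


def _build_tree(defs, r_root: float, stiffness: dict[str, float]):
    from .vessels import ArterialTree, VesselSegment
    segs = []
    for name, site, parent, rscale, length, sections in defs:
        ri = r_root * rscale
        segs.append(VesselSegment(
            name=name, site=site, inner_radius=ri,
            wall_thickness=_THICKNESS_RATIO * ri, length=length,
            stiffness=stiffness[name], parent=parent, sections=sections))
    return ArterialTree(segs)


def _murray_weights(tree, outlet_names):
    r3 = {n: tree.by_name[n].inner_radius ** 3 for n in outlet_names}
    total = sum(r3.values())
    return {n: v / total for n, v in r3.items()}


def generate_patient(seed: int, profile: SeverityProfile | str = "normal",
                     max_retries: int = 4) -> VirtualPatient:
    """Sample a virtual patient and generate its clinical target table.

    Deterministic per ``(seed, profile)``.  If a sampled parameter set fails
    to simulate (divergence), the anatomy is resampled with a shifted seed up
    to ``max_retries`` times.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    last_err: Exception | None = None
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng((seed + 7919 * attempt) % (2 ** 31))
        try:
            return _generate_once(rng, seed, profile)
        except CircuitError as err:   # pragma: no cover - defensive retry
            last_err = err
    raise CircuitError(
        f"could not generate a stable patient for seed {seed}: {last_err}")


def _generate_once(rng: np.random.Generator, seed: int,
                   profile: SeverityProfile) -> VirtualPatient:
    bsa = float(rng.uniform(0.9, 1.9))
    age = float(np.clip(rng.normal(15.0, 4.4), 6.0, 21.0))
    heart_rate = float(rng.uniform(70.0, 110.0))
    cardiac_output = 3.8 * bsa * L_PER_MIN        # mm³/s, CI 3.8 L/min/m²
    q = cardiac_output

    r_mpa = float(np.clip(9.0 + 3.5 * (bsa - 0.9) + rng.normal(0.0, 0.4),
                          8.0, 14.0))
    r_aao = r_mpa * float(rng.uniform(0.95, 1.05))

    # wall stiffness: normal pulmonary ~ 9e4, systemic ~ 2.4e5 g/(mm·s²)
    e_pul = 9.0e4 * profile.stiffness_multiplier * float(rng.uniform(0.9, 1.1))
    e_sys = 2.4e5 * float(rng.uniform(0.9, 1.1))
    stiff_pul = {name: e_pul * (1.25 if site == "branch" else 1.0)
                 for name, site, *_ in _SITE_SEGMENTS_PULMONARY}
    stiff_sys = {name: e_sys * (1.25 if site == "branch" else 1.0)
                 for name, site, *_ in _SITE_SEGMENTS_SYSTEMIC}
    pul_tree = _build_tree(_SITE_SEGMENTS_PULMONARY, r_mpa, stiff_pul)
    sys_tree = _build_tree(_SITE_SEGMENTS_SYSTEMIC, r_aao, stiff_sys)

    # total resistances from target pressure drops at this cardiac output
    lap, rap = 8.0, 4.0
    mpap_base = float(rng.uniform(17.0, 21.0))
    map_sys = float(rng.uniform(75.0, 90.0))
    r_t_pul = (mpap_base - lap) * 133.322 / q * profile.resistance_multiplier
    r_t_sys = (map_sys - rap) * 133.322 / q

    c_pul_periph = 24.0 / profile.stiffness_multiplier * float(rng.uniform(0.9, 1.1))
    c_sys_periph = 14.0 * float(rng.uniform(0.9, 1.1))

    def outlets_for(tree, r_total, c_total, rp_fraction):
        names = tree.outlets
        w = _murray_weights(tree, names)
        r_tree = tree.equivalent_resistance()
        r_periph = max(r_total - r_tree, 0.3 * r_total)
        out = {}
        for n in names:
            r_j = r_periph / w[n]
            out[n] = WindkesselParams(rp=rp_fraction * r_j,
                                      rd=(1 - rp_fraction) * r_j,
                                      c=w[n] * c_total)
        return out

    pulmonary_outlets = outlets_for(pul_tree, r_t_pul, c_pul_periph, 0.15)
    systemic_outlets = outlets_for(sys_tree, r_t_sys, c_sys_periph, 0.15)

    pulmonary_venous = WindkesselParams(rp=0.15 * 8.0e-4, rd=0.85 * 8.0e-4,
                                       c=15.0)
    systemic_venous = WindkesselParams(rp=0.15 * 3.0e-3, rd=0.85 * 3.0e-3,
                                       c=60.0)

    heart = HeartParams(
        lv=ChamberParams(
            e_max=1.9 * MMHG_PER_ML * float(rng.uniform(0.9, 1.1)) / bsa * 1.3,
            e_min=0.09 * MMHG_PER_ML, v0=5.0 * ML, systolic_fraction=0.34,
            rs_coefficient=4.0e-7),
        rv=ChamberParams(
            e_max=0.55 * MMHG_PER_ML * profile.contractility_multiplier
            * float(rng.uniform(0.9, 1.1)) / bsa * 1.3,
            e_min=0.06 * MMHG_PER_ML, v0=8.0 * ML, systolic_fraction=0.34,
            rs_coefficient=4.0e-7),
        la=ChamberParams(e_max=0.25 * MMHG_PER_ML, e_min=0.25 * MMHG_PER_ML,
                         v0=4.0 * ML),
        ra=ChamberParams(e_max=0.20 * MMHG_PER_ML, e_min=0.20 * MMHG_PER_ML,
                         v0=4.0 * ML),
        left_valves=ValveParams(), right_valves=ValveParams(),
        heart_rate=heart_rate,
    )

    mpap_guess = mpap_base * profile.resistance_multiplier * 0.85 + lap
    ics = {
        "LA": lap, "RA": rap, "LV": 10.0, "RV": 6.0,
        "Ao_root": map_sys, "PA_root": mpap_guess,
    }
    model = PatientModel(
        heart=heart, pulmonary_tree=pul_tree, systemic_tree=sys_tree,
        pulmonary_outlets=pulmonary_outlets, systemic_outlets=systemic_outlets,
        pulmonary_venous=pulmonary_venous, systemic_venous=systemic_venous,
        initial_pressures=ics,
        preload_pressures={"left": lap + 1.0, "right": rap + 1.0},
        distal_reference={"pulmonary": lap, "systemic": rap},
    )

    _tune_fill_volume(model, target_q=q)
    patient = _simulate_and_package(model, seed, profile.label)
    patient.demographics = {"age_years": age, "bsa_m2": bsa,
                            "heart_rate_bpm": heart_rate}
    return patient


def _tune_fill_volume(model: PatientModel, target_q: float,
                      tolerance: float = 0.04, max_iter: int = 5) -> None:
    """Scale the initial (filling) pressures until cardiac output matches.

    In the closed loop the initial nodal pressures fix the total stressed
    blood volume, which in turn sets preload and output via the
    Frank–Starling behaviour of the elastance ventricles.  A damped
    fixed-point on the fill level emulates how a real circulation's volume
    is regulated to its operating point; this runs at generation time only,
    on the ground-truth model.
    """
    for _ in range(max_iter):
        netlist = build_stage_netlist(model, stage=3)
        result = simulate(netlist, model.solver_settings(
            max_cycles=8, periodicity_tolerance=2e-3))
        q_sim = result.final_cycle_metrics["MPA"]["Q_mean"]
        if abs(q_sim / target_q - 1.0) < tolerance:
            break
        factor = (target_q / q_sim) ** 0.7
        model.initial_pressures = {k: v * factor
                                   for k, v in model.initial_pressures.items()}
        model.preload_pressures = {k: v * factor
                                   for k, v in model.preload_pressures.items()}


def _simulate_and_package(model: PatientModel, seed: int,
                          label: str) -> VirtualPatient:
    netlist = build_stage_netlist(model, stage=3)
    result = simulate(netlist, model.solver_settings())
    targets = targets_from_simulation(result, model)
    geometry = geometry_table(model, result)
    truth = truth_summary(model, result)
    return VirtualPatient(seed=seed, profile=label, model=model,
                          targets=targets, geometry=geometry,
                          demographics={}, truth_summary=truth,
                          simulation=result)


def targets_from_simulation(result: SimulationResult,
                            model: PatientModel) -> ClinicalTargets:
    sites = {}
    for site, m in result.final_cycle_metrics.items():
        sites[site] = dict(m)
        if {"P_sys", "P_dia"} <= set(m):
            sites[site]["P_pulse"] = m["P_sys"] - m["P_dia"]
    sv = None
    if "MPA" in result.branch_flow_waveforms:
        sv = sites["MPA"].get("stroke_volume")
    inlet = {k: result.branch_flow_waveforms[k]
             for k in ("AAo", "MPA") if k in result.branch_flow_waveforms}
    # catheter-style filling pressures: mean LA (wedge surrogate) and RA
    extras = {}
    tt = result.times
    for node, key in (("LA", "PCWP"), ("RA", "RAP")):
        if node in result.node_index:
            tr = result.pressure_trace[result.node_index[node]]
            extras[key] = float(np.trapezoid(tr, tt) / (tt[-1] - tt[0]) / 133.322)
    # MRI-style ventricular volumes (mm³) pin contractility during calibration
    for ch, key in (("left_ventricle", "LV"), ("right_ventricle", "RV")):
        if ch in result.chamber_names:
            v = result.chamber_volume(ch)
            extras[f"{key}_EDV"] = float(v.max())
            extras[f"{key}_ESV"] = float(v.min())
    t = ClinicalTargets(sites=sites, heart_rate=model.heart.heart_rate,
                        stroke_volume=sv, inlet_flows=inlet, extras=extras)
    t.validate()
    return t


def geometry_table(model: PatientModel, result: SimulationResult) -> pd.DataFrame:
    """Site geometry as PC-MRI would report it: diastolic and systolic radii.

    The systolic radius is obtained by inverting the linearized-stiffness
    relation with the segment's true stiffness and the simulated site pulse
    pressure, so re-estimating stiffness from this table round-trips.
    """
    rows = []
    for tree, side in ((model.pulmonary_tree, "pulmonary"),
                       (model.systemic_tree, "systemic")):
        for seg in tree.segments:
            row = {"site": seg.site if seg.site != "branch" else seg.name,
                   "segment": seg.name, "side": side,
                   "parent": seg.parent, "sections": seg.sections,
                   "R_dia_mm": seg.inner_radius,
                   "length_mm": seg.length,
                   "thickness_ratio": seg.wall_thickness / seg.inner_radius,
                   "stiffness_true": seg.stiffness}
            m = result.final_cycle_metrics.get(seg.site, {})
            if {"P_sys", "P_dia"} <= set(m):
                dp = (m["P_sys"] - m["P_dia"]) * 133.322
                dr = linearized_stiffness_delta_r(
                    dp, seg.inner_radius,
                    seg.inner_radius + seg.wall_thickness, seg.stiffness)
                row["R_sys_mm"] = seg.inner_radius + dr
                row["P_sys_mmhg"] = m["P_sys"]
                row["P_dia_mmhg"] = m["P_dia"]
            rows.append(row)
    return pd.DataFrame(rows)


def truth_summary(model: PatientModel, result: SimulationResult) -> dict[str, float]:
    from .metrics import pulmonary_rc_split
    split = pulmonary_rc_split(model)
    m = result.final_cycle_metrics
    out = {
        "R_total_pulmonary": split["R_total"],
        "C_total_pulmonary": split["C_total"],
        "R_total_systemic": (
            model.systemic_tree.equivalent_resistance(model.blood)
            + 1.0 / sum(1.0 / wk.total_resistance
                        for wk in model.systemic_outlets.values())),
        "mPAP": m["MPA"]["P_mean"],
        "MAP": m["AAo"]["P_mean"],
        "CO_lmin": m["MPA"]["Q_mean"] / L_PER_MIN,
    }
    return out


def add_measurement_noise(targets: ClinicalTargets, noise_sd_fraction: float,
                          seed: int) -> ClinicalTargets:
    """Multiplicative Gaussian noise per metric, reproducible per seed.

    Systolic/diastolic pressures are re-ordered if noise inverts them and
    pulse pressure is recomputed so the noised table stays internally
    consistent.
    """
    if not 0.0 <= noise_sd_fraction < 0.5:
        raise ValueError("noise_sd_fraction must be in [0, 0.5)")
    noised = copy.deepcopy(targets)
    if noise_sd_fraction == 0.0:
        noised.noise_spec = {"sd_fraction": 0.0, "seed": seed}
        return noised
    rng = np.random.default_rng(seed % (2 ** 31))
    for site in sorted(noised.sites):
        m = noised.sites[site]
        for key in sorted(m):
            if key == "P_pulse":
                continue
            m[key] = m[key] * float(1.0 + noise_sd_fraction * rng.standard_normal())
        if {"P_sys", "P_dia"} <= set(m):
            lo, hi = sorted((m["P_dia"], m["P_sys"]))
            m["P_dia"], m["P_sys"] = lo, hi
            m["P_mean"] = float(np.clip(m.get("P_mean", 0.5 * (lo + hi)),
                                        lo, hi))
            m["P_pulse"] = hi - lo
    noised.noise_spec = {"sd_fraction": noise_sd_fraction, "seed": seed}
    return noised


def generate_longitudinal_pair(seed: int,
                               profile: SeverityProfile | str = "moderate",
                               spec: ProgressionSpec | None = None
                               ) -> tuple[VirtualPatient, VirtualPatient]:
    """Baseline patient plus a follow-up with imposed disease progression.

    Follow-up ground truth = baseline ground truth with arterial stiffness,
    peripheral resistance and peripheral compliance scaled by the spec
    (worsening also raises right-ventricular contractility, the compensating
    response that maintains output against a higher load).
    """
    spec = spec or ProgressionSpec("worsening")
    baseline = generate_patient(seed, profile)
    fu_model = baseline.model.copy()
    fu_model.pulmonary_tree = fu_model.pulmonary_tree.scaled_stiffness(
        spec.stiffness_factor)
    fu_model.pulmonary_outlets = {
        n: wk.scaled(spec.resistance_factor, spec.compliance_factor)
        for n, wk in fu_model.pulmonary_outlets.items()}
    rv = fu_model.heart.rv
    fu_model.heart.rv = ChamberParams(
        e_max=rv.e_max * spec.contractility_factor, e_min=rv.e_min,
        v0=rv.v0, onset_fraction=rv.onset_fraction,
        systolic_fraction=rv.systolic_fraction,
        rs_coefficient=rv.rs_coefficient, law=rv.law)
    fu_model.initial_pressures = dict(fu_model.initial_pressures)
    fu_model.initial_pressures["PA_root"] *= spec.resistance_factor
    follow_up = _simulate_and_package(fu_model, seed, baseline.profile)
    follow_up.demographics = dict(baseline.demographics)

    mpap_b = baseline.truth_summary["mPAP"]
    mpap_f = follow_up.truth_summary["mPAP"]
    identity = all(f == 1.0 for f in (spec.stiffness_factor,
                                      spec.resistance_factor,
                                      spec.compliance_factor,
                                      spec.contractility_factor))
    ok = identity or (mpap_f > mpap_b if spec.direction == "worsening"
                      else mpap_f < mpap_b)
    if not ok:
        raise CircuitError(
            f"progression direction not realized (mPAP {mpap_b:.1f} -> "
            f"{mpap_f:.1f} for {spec.direction})")
    return baseline, follow_up


def export_cohort(patients: list[VirtualPatient], directory) -> dict:
    """Write per-patient model/targets/geometry files plus a manifest."""
    from . import io as hio
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": "1", "patients": []}
    for i, p in enumerate(patients):
        tag = f"patient{i + 1:02d}_{p.profile}_seed{p.seed}"
        files = {
            "model": directory / f"{tag}_model.json",
            "targets": directory / f"{tag}_targets.json",
            "geometry": directory / f"{tag}_geometry.csv",
        }
        hio.write_model(p.model, files["model"])
        hio.write_targets(p.targets, files["targets"])
        p.geometry.to_csv(files["geometry"], index=False)
        entry = {"tag": tag, "seed": p.seed, "profile": p.profile,
                 "files": {}}
        for kind, path in files.items():
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            entry["files"][kind] = {"path": path.name, "sha256": digest}
        manifest["patients"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
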