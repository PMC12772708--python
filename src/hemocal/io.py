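"""Readers and writers for the on-disk formats.

No domain-standard format exists for 0D hemodynamic netlists, so the
schemas are defined (and versioned) here:

* patient models and calibration reports — JSON;
* clinical target tables — JSON (with optional inlet flow waveforms,
  stored downsampled) or long-format CSV (site, metric, value, units);
* waveforms — two-column CSV (``time_s``, value) with a comment header
  naming site, quantity and units.

Readers unit-normalize on the way in (pressures mmHg, flows mm³/s) and
preserve unknown metrics as pass-through clinical values.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ClinicalTargets, WindkesselParams
from .circuit import Waveform
from .heart import ChamberParams, HeartParams, ValveParams
from .model import PatientModel
from .vessels import ArterialTree, VesselSegment

__all__ = ["read_targets", "write_targets", "read_model", "write_model",
           "write_report", "read_report", "waveform_to_csv",
           "waveform_from_csv", "SchemaError"]

SCHEMA_VERSION = "1"

_PRESSURE_METRICS = {"P_mean", "P_sys", "P_dia", "P_pulse"}
_FLOW_METRICS = {"Q_mean"}


class SchemaError(ValueError):
    """A file does not match its declared schema."""


# ---------------------------------------------------------------------------
# waveforms

def waveform_to_csv(wf: Waveform, path, site: str = "",
                    units: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# site={site} quantity={wf.quantity_kind} units={units}\n")
        fh.write("time_s,value\n")
        for t, v in zip(wf.times, wf.values):
            fh.write(f"{t:.6g},{v:.10g}\n")


def waveform_from_csv(path) -> Waveform:
    path = Path(path)
    quantity = "pressure"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("quantity="):
                    quantity = token.split("=", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if not {"time_s", "value"} <= set(df.columns):
        raise SchemaError(f"{path}: waveform CSV needs time_s,value columns")
    return Waveform(df["time_s"].to_numpy(), df["value"].to_numpy(), quantity)


def _waveform_to_obj(wf: Waveform, n_points: int = 256) -> dict:
    t = np.linspace(wf.times[0], wf.times[-1], n_points)
    return {"times": np.round(t, 9).tolist(),
            "values": np.round(wf.sample(t), 6).tolist(),
            "quantity_kind": wf.quantity_kind}


def _waveform_from_obj(obj: dict) -> Waveform:
    return Waveform(np.asarray(obj["times"]), np.asarray(obj["values"]),
                    obj.get("quantity_kind", "flow"))


# ---------------------------------------------------------------------------
# clinical targets

def write_targets(targets: ClinicalTargets, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for site, metrics in targets.sites.items():
            for metric, value in metrics.items():
                units = "mmHg" if metric in _PRESSURE_METRICS else (
                    "mm3/s" if metric in _FLOW_METRICS else "mm3")
                rows.append({"site": site, "metric": metric,
                             "value": value, "units": units})
        rows.append({"site": "global", "metric": "heart_rate",
                     "value": targets.heart_rate, "units": "bpm"})
        for key, value in targets.extras.items():
            rows.append({"site": "global", "metric": key, "value": value,
                         "units": ""})
        pd.DataFrame(rows).to_csv(path, index=False)
        return
    obj = {
        "schema_version": SCHEMA_VERSION,
        "sites": targets.sites,
        "heart_rate": targets.heart_rate,
        "stroke_volume": targets.stroke_volume,
        "extras": targets.extras,
        "noise_spec": targets.noise_spec,
        "inlet_flows": {k: _waveform_to_obj(wf)
                        for k, wf in targets.inlet_flows.items()},
    }
    path.write_text(json.dumps(obj, indent=1))


def read_targets(path) -> ClinicalTargets:
    """Load a target table (JSON or long-format CSV), validating invariants.

    Raises :class:`SchemaError` naming the offending field for structural
    problems; a pulse pressure inconsistent with P_sys − P_dia by more than
    1 mmHg produces a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"site", "metric", "value"} <= set(df.columns):
            raise SchemaError(f"{path}: need columns site, metric, value")
        sites: dict[str, dict[str, float]] = {}
        hr, extras = None, {}
        for i, row in df.iterrows():
            if row["site"] == "global":
                if row["metric"] == "heart_rate":
                    hr = float(row["value"])
                else:
                    extras[row["metric"]] = float(row["value"])
            else:
                sites.setdefault(row["site"], {})[row["metric"]] = \
                    float(row["value"])
        if hr is None:
            raise SchemaError(f"{path}: missing global heart_rate row")
        targets = ClinicalTargets(sites=sites, heart_rate=hr, extras=extras)
    else:
        obj = json.loads(path.read_text())
        for fieldname in ("sites", "heart_rate"):
            if fieldname not in obj:
                raise SchemaError(f"{path}: missing field {fieldname!r}")
        targets = ClinicalTargets(
            sites={s: {m: float(v) for m, v in d.items()}
                   for s, d in obj["sites"].items()},
            heart_rate=float(obj["heart_rate"]),
            stroke_volume=obj.get("stroke_volume"),
            extras=obj.get("extras") or {},
            noise_spec=obj.get("noise_spec"),
            inlet_flows={k: _waveform_from_obj(w)
                         for k, w in (obj.get("inlet_flows") or {}).items()},
        )
    for site, m in targets.sites.items():
        if {"P_sys", "P_dia"} <= set(m) and m["P_dia"] > m["P_sys"]:
            raise SchemaError(f"{path}: {site}: P_dia exceeds P_sys")
        pulse = m.get("P_pulse")
        if pulse is not None and {"P_sys", "P_dia"} <= set(m) and \
                abs(pulse - (m["P_sys"] - m["P_dia"])) > 1.0:
            warnings.warn(f"{site}: P_pulse differs from P_sys - P_dia by "
                          f"more than 1 mmHg", stacklevel=2)
    targets.validate()
    return targets


# ---------------------------------------------------------------------------
# patient models

def _segment_obj(seg: VesselSegment) -> dict:
    return {"name": seg.name, "site": seg.site,
            "inner_radius": seg.inner_radius,
            "wall_thickness": seg.wall_thickness, "length": seg.length,
            "stiffness": seg.stiffness, "parent": seg.parent,
            "sections": seg.sections}


def _tree_obj(tree: ArterialTree) -> list[dict]:
    return [_segment_obj(s) for s in tree.segments]


def _tree_from_obj(obj) -> ArterialTree:
    return ArterialTree([VesselSegment(**d) for d in obj])


def write_model(model: PatientModel, path) -> None:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "heart": asdict(model.heart),
        "pulmonary_tree": _tree_obj(model.pulmonary_tree),
        "systemic_tree": _tree_obj(model.systemic_tree),
        "pulmonary_outlets": {k: asdict(v)
                              for k, v in model.pulmonary_outlets.items()},
        "systemic_outlets": {k: asdict(v)
                             for k, v in model.systemic_outlets.items()},
        "pulmonary_venous": asdict(model.pulmonary_venous),
        "systemic_venous": asdict(model.systemic_venous),
        "initial_pressures": model.initial_pressures,
        "preload_pressures": model.preload_pressures,
        "distal_reference": model.distal_reference,
        "blood": asdict(model.blood),
        "time_step": model.time_step,
        "max_cycles": model.max_cycles,
        "periodicity_tolerance": model.periodicity_tolerance,
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def _heart_from_obj(obj: dict) -> HeartParams:
    def ch(d):
        return ChamberParams(**d)

    return HeartParams(
        lv=ch(obj["lv"]), rv=ch(obj["rv"]), la=ch(obj["la"]), ra=ch(obj["ra"]),
        left_valves=ValveParams(**obj["left_valves"]),
        right_valves=ValveParams(**obj["right_valves"]),
        cr_aortic=obj["cr_aortic"], cr_pulmonary=obj["cr_pulmonary"],
        heart_rate=obj["heart_rate"])


def read_model(path) -> PatientModel:
    path = Path(path)
    obj = json.loads(path.read_text())
    for fieldname in ("heart", "pulmonary_tree", "systemic_tree",
                      "pulmonary_outlets", "systemic_outlets"):
        if fieldname not in obj:
            raise SchemaError(f"{path}: missing field {fieldname!r}")
    from .circuit import BloodProperties
    return PatientModel(
        heart=_heart_from_obj(obj["heart"]),
        pulmonary_tree=_tree_from_obj(obj["pulmonary_tree"]),
        systemic_tree=_tree_from_obj(obj["systemic_tree"]),
        pulmonary_outlets={k: WindkesselParams(**v)
                           for k, v in obj["pulmonary_outlets"].items()},
        systemic_outlets={k: WindkesselParams(**v)
                          for k, v in obj["systemic_outlets"].items()},
        pulmonary_venous=WindkesselParams(**obj["pulmonary_venous"]),
        systemic_venous=WindkesselParams(**obj["systemic_venous"]),
        initial_pressures=obj.get("initial_pressures", {}),
        preload_pressures=obj.get("preload_pressures",
                                  {"left": 9.0, "right": 5.0}),
        distal_reference=obj.get("distal_reference",
                                 {"pulmonary": 8.0, "systemic": 4.0}),
        blood=BloodProperties(**obj.get("blood", {})),
        time_step=obj.get("time_step", 1.0e-4),
        max_cycles=obj.get("max_cycles", 20),
        periodicity_tolerance=obj.get("periodicity_tolerance", 1.0e-3),
    )


# ---------------------------------------------------------------------------
# reports

def write_report(report: dict, path) -> None:
    report = dict(report)
    report.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def read_report(path) -> dict:
    obj = json.loads(Path(path).read_text())
    if "schema_version" not in obj:
        raise SchemaError(f"{path}: report lacks schema_version")
    return obj
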