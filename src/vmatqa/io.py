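"""Serialization: machine configs (YAML), plans (JSON/CSV), images (TIFF/text).

JSON is the canonical plan format and round-trips to full float precision;
the CSV export is a flat, lossy convenience (one row per control point, no
strip metadata).  Images are written as 32-bit float TIFF with the axis
metadata embedded in the image description, or as a diff-friendly plain-text
matrix with an axis header.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from . import __version__
from .machine import ControlPoint, MachineLimits, StripSpec, VmatPlan
from .simulator import DetectorModel, ErrorModel, FluenceImage

__all__ = [
    "RunConfig",
    "load_limits",
    "dump_limits",
    "plan_to_json",
    "plan_from_json",
    "write_plan",
    "read_plan",
    "write_plan_csv",
    "read_plan_csv",
    "write_image",
    "read_image",
    "write_trace_csv",
]


@dataclasses.dataclass
class RunConfig:
    """Bundle of machine, detector and error-model configuration plus seed."""

    limits: MachineLimits = dataclasses.field(default_factory=MachineLimits)
    detector: DetectorModel = dataclasses.field(default_factory=DetectorModel)
    error_model: ErrorModel = dataclasses.field(default_factory=ErrorModel)
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "limits" in raw:
            kw["limits"] = MachineLimits(**raw["limits"])
        if "detector" in raw:
            kw["detector"] = DetectorModel(**raw["detector"])
        if "error_model" in raw:
            em = dict(raw["error_model"])
            if "pixilation_lines" in em:
                em["pixilation_lines"] = [tuple(t) for t in em["pixilation_lines"]]
            kw["error_model"] = ErrorModel(**em)
        for k in ("seed", "output_dir", "verbosity"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)


def load_limits(path) -> MachineLimits:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "limits" in raw:
        raw = raw["limits"]
    return MachineLimits(**raw)


def dump_limits(limits: MachineLimits, path) -> None:
    Path(path).write_text(yaml.safe_dump({"limits": dataclasses.asdict(limits)}))


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

def plan_to_json(plan: VmatPlan) -> dict:
    return {
        "format": "vmatqa-plan",
        "version": __version__,
        "name": plan.name,
        "energy_label": plan.energy_label,
        "notes": plan.notes,
        "segment_dr": plan.segment_dr,
        "strip_specs": [dataclasses.asdict(s) for s in plan.strip_specs]
        if plan.strip_specs else None,
        "control_points": [
            {
                "cum_mu": cp.cum_mu,
                "gantry_angle": cp.gantry_angle,
                "bank_a": cp.bank_a.tolist(),
                "bank_b": cp.bank_b.tolist(),
                "jaw_left": cp.jaw_left,
                "jaw_right": cp.jaw_right,
                "collimator_angle": cp.collimator_angle,
            }
            for cp in plan.control_points
        ],
    }


def plan_from_json(doc: dict) -> VmatPlan:
    try:
        cps = [
            ControlPoint(
                cum_mu=c["cum_mu"], gantry_angle=c["gantry_angle"],
                bank_a=np.array(c["bank_a"]), bank_b=np.array(c["bank_b"]),
                jaw_left=c.get("jaw_left", -20.0),
                jaw_right=c.get("jaw_right", 20.0),
                collimator_angle=c.get("collimator_angle", 0.0),
            )
            for c in doc["control_points"]
        ]
        specs = ([StripSpec(**s) for s in doc["strip_specs"]]
                 if doc.get("strip_specs") else None)
        return VmatPlan(
            name=doc["name"], control_points=cps,
            energy_label=doc.get("energy_label", "6MV"),
            strip_specs=specs, segment_dr=doc.get("segment_dr"),
            notes=doc.get("notes", ""),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed plan document: {exc}") from exc


def write_plan(path, plan: VmatPlan) -> None:
    Path(path).write_text(json.dumps(plan_to_json(plan), indent=1))


def read_plan(path) -> VmatPlan:
    return plan_from_json(json.loads(Path(path).read_text()))


_CSV_FIELDS = (["cum_mu", "gantry", "jaw_l", "jaw_r", "coll"]
               + [f"a{i + 1:02d}" for i in range(40)]
               + [f"b{i + 1:02d}" for i in range(40)])


def write_plan_csv(path, plan: VmatPlan) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for cp in plan.control_points:
            w.writerow([repr(float(cp.cum_mu)), repr(float(cp.gantry_angle)),
                        repr(float(cp.jaw_left)), repr(float(cp.jaw_right)),
                        repr(float(cp.collimator_angle))]
                       + [repr(float(v)) for v in cp.bank_a]
                       + [repr(float(v)) for v in cp.bank_b])


def read_plan_csv(path, name: Optional[str] = None) -> VmatPlan:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError("empty plan CSV")
    cps = []
    for r in rows:
        try:
            cps.append(ControlPoint(
                cum_mu=float(r["cum_mu"]), gantry_angle=float(r["gantry"]),
                bank_a=np.array([float(r[f"a{i + 1:02d}"]) for i in range(40)]),
                bank_b=np.array([float(r[f"b{i + 1:02d}"]) for i in range(40)]),
                jaw_left=float(r["jaw_l"]), jaw_right=float(r["jaw_r"]),
                collimator_angle=float(r.get("coll", 0.0)),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed plan CSV row: {exc}") from exc
    return VmatPlan(name=name or Path(path).stem, control_points=cps)


# ---------------------------------------------------------------------------
# images and traces
# ---------------------------------------------------------------------------

def write_image(path, image: FluenceImage) -> None:
    """Write 32-bit float TIFF (axis metadata in the description) or text."""
    path = Path(path)
    meta = {"x0": float(image.x[0]), "dx": float(np.diff(image.x).mean()),
            "y0": float(image.y[0]), "dy": float(np.diff(image.y).mean()),
            "provenance": image.provenance}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.data.astype(np.float32),
                         description=json.dumps(meta))
    else:
        with open(path, "w") as fh:
            fh.write("# vmatqa fluence image\n")
            fh.write(f"# x: {meta['x0']!r} {meta['dx']!r} {len(image.x)}\n")
            fh.write(f"# y: {meta['y0']!r} {meta['dy']!r} {len(image.y)}\n")
            np.savetxt(fh, image.data)


def read_image(path) -> FluenceImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            meta = json.loads(tf.pages[0].description or "{}")
        x = meta["x0"] + meta["dx"] * np.arange(data.shape[1])
        y = meta["y0"] + meta["dy"] * np.arange(data.shape[0])
        return FluenceImage(data=data, x=x, y=y,
                            provenance=meta.get("provenance", {}))
    header = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split(":")
            if len(parts) == 2 and parts[0].strip() in ("x", "y"):
                v = parts[1].split()
                header[parts[0].strip()] = (float(v[0]), float(v[1]), int(v[2]))
    data = np.loadtxt(path)
    x0, dx, nx = header["x"]
    y0, dy, ny = header["y"]
    return FluenceImage(data=np.atleast_2d(data),
                        x=x0 + dx * np.arange(nx), y=y0 + dy * np.arange(ny))


def write_trace_csv(path, trace) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "cum_mu", "gantry_deg", "active_bin", "rate_mu_s",
                    "jaw_left", "jaw_right"]
                   + [f"a{i + 1:02d}" for i in range(40)]
                   + [f"b{i + 1:02d}" for i in range(40)])
        for i in range(len(trace.t)):
            w.writerow([trace.t[i], trace.cum_mu[i], trace.gantry[i],
                        trace.active_bin[i], trace.rate[i],
                        trace.jaw_left[i], trace.jaw_right[i]]
                       + list(trace.bank_a[i]) + list(trace.bank_b[i]))
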