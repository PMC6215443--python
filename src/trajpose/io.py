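"""Plain-text file formats: model spec, vector fields, ROIs, postures.

Formats
-------
* Model spec — versioned header line ``# trajpose-model v1`` followed by a
  JSON document (full-precision floats, lossless round-trip).
* Vector field — whitespace-delimited table with a header row:
  ``x y z <ux uy uz per component> bone roi``; coordinates and unit-vector
  components written with 17 significant digits (well past the 6-decimal
  floor, and lossless for doubles).
* ROI file — header row then ``label bone cx cy cz radius mode`` with
  mode in {compressive, tensile}.
* Posture file — ``key_deg: value`` lines, one per joint angle.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from trajpose.bone_stress import CrossSection
from trajpose.fabric_correspondence import SphericalROI, VectorField
from trajpose.musculoskeletal import ACTUATED_DOFS, MuscleSpec, Posture
from trajpose.synthetic_limb import SpeciesTemplate

__all__ = [
    "write_model_spec", "read_model_spec",
    "write_vector_field", "read_vector_field",
    "write_rois", "read_rois",
    "write_posture", "read_posture",
]

_MODEL_HEADER = "# trajpose-model v1"
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Model spec
# ---------------------------------------------------------------------------

def write_model_spec(path, template: SpeciesTemplate) -> None:
    doc = {
        "name": template.name,
        "total_body_mass": template.total_body_mass,
        "right_hindlimb_mass": template.right_hindlimb_mass,
        "pelvis_segment_mass": template.pelvis_segment_mass,
        "segment_lengths": template.segment_lengths,
        "segment_masses": template.segment_masses,
        "pelvis_com_offset_anterior": template.pelvis_com_offset_anterior,
        "knee_axis_obliquity_deg": template.knee_axis_obliquity_deg,
        "cross_sections": {
            b: {"a_ap": c.a_ap, "a_ml": c.a_ml, "wall_fraction": c.wall_fraction}
            for b, c in template.cross_sections.items()
        },
        "epiphysis_radii": template.epiphysis_radii,
        "muscles": [
            {
                "name": m.name,
                "active": m.active,
                "group": m.group,
                "path": [[seg, list(xyz)] for seg, xyz in m.path],
            }
            for m in template.muscle_roster
        ],
    }
    Path(path).write_text(_MODEL_HEADER + "\n" + json.dumps(doc, indent=1) + "\n")


def read_model_spec(path) -> SpeciesTemplate:
    text = Path(path).read_text()
    first, _, rest = text.partition("\n")
    if first.strip() != _MODEL_HEADER:
        raise ValueError(f"{path}: missing model-spec header {_MODEL_HEADER!r}")
    doc = json.loads(rest)
    roster = tuple(
        MuscleSpec(
            name=m["name"],
            path=tuple((seg, tuple(xyz)) for seg, xyz in m["path"]),
            active=m["active"],
            group=m["group"],
        )
        for m in doc["muscles"]
    )
    return SpeciesTemplate(
        name=doc["name"],
        total_body_mass=doc["total_body_mass"],
        right_hindlimb_mass=doc["right_hindlimb_mass"],
        pelvis_segment_mass=doc["pelvis_segment_mass"],
        segment_lengths=doc["segment_lengths"],
        segment_masses=doc["segment_masses"],
        pelvis_com_offset_anterior=doc["pelvis_com_offset_anterior"],
        cross_sections={
            b: CrossSection(**c) for b, c in doc["cross_sections"].items()
        },
        epiphysis_radii=doc["epiphysis_radii"],
        muscle_roster=roster,
        knee_axis_obliquity_deg=doc.get("knee_axis_obliquity_deg", 0.0),
    )


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

def write_vector_field(path, field: VectorField) -> None:
    cols: Dict[str, np.ndarray] = {
        "x": field.points[:, 0],
        "y": field.points[:, 1],
        "z": field.points[:, 2],
    }
    for comp in field.components:
        arr = field.axes[comp]
        for i, suffix in enumerate("xyz"):
            cols[f"{comp}_u{suffix}"] = arr[:, i]
    cols["bone"] = field.bone
    cols["roi"] = (
        np.where(field.roi == "", "-", field.roi)
        if field.roi is not None
        else np.array(["-"] * len(field), dtype=object)
    )
    pd.DataFrame(cols).to_csv(path, sep=" ", index=False, float_format=_FLOAT_FMT)


def read_vector_field(path) -> VectorField:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    if not {"x", "y", "z", "bone"}.issubset(df.columns):
        raise ValueError(f"{path}: not a vector-field table (missing x/y/z/bone)")
    comps = sorted({c[:-3] for c in df.columns if c.endswith(("_ux", "_uy", "_uz"))})
    axes = {
        comp: df[[f"{comp}_ux", f"{comp}_uy", f"{comp}_uz"]].to_numpy(dtype=float)
        for comp in comps
    }
    roi = None
    if "roi" in df.columns:
        roi = df["roi"].astype(str).replace("-", "").to_numpy(dtype=object)
    return VectorField(
        bone=df["bone"].to_numpy(dtype=object),
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
        axes=axes,
        roi=roi,
    )


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def write_rois(path, rois: Sequence[SphericalROI]) -> None:
    rows = [
        {
            "label": r.label, "bone": r.bone,
            "cx": r.centre[0], "cy": r.centre[1], "cz": r.centre[2],
            "radius": r.radius, "mode": r.mode,
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, sep=" ", index=False, float_format=_FLOAT_FMT)


def read_rois(path) -> List[SphericalROI]:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    return [
        SphericalROI(
            label=row["label"], bone=row["bone"],
            centre=(float(row["cx"]), float(row["cy"]), float(row["cz"])),
            radius=float(row["radius"]), mode=row["mode"],
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Postures
# ---------------------------------------------------------------------------

def write_posture(path, posture: Posture) -> None:
    lines = [f"{dof}_deg: {_FLOAT_FMT % getattr(posture, dof)}" for dof in ACTUATED_DOFS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_posture(path) -> Posture:
    values: Dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        key = key.strip()
        if not key.endswith("_deg"):
            raise ValueError(f"{path}: expected '<dof>_deg: value', got {line!r}")
        dof = key[:-4]
        if dof not in ACTUATED_DOFS:
            raise ValueError(f"{path}: unknown joint angle {dof!r}")
        values[dof] = float(val)
    missing = set(ACTUATED_DOFS) - set(values)
    if missing:
        raise ValueError(f"{path}: missing angles {sorted(missing)}")
    return Posture(**values)
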