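"""Species-scale limb templates and synthetic fabric fields.

Three templates are provided at the printed scales of the study system: a
large tyrannosaurid-scale model, a troodontid-scale model and a
chicken-scale model.  Printed masses, femur lengths and COM offsets are
used where available; everything else (segment length ratios, cross-section
sizes, muscle path geometry) is a documented default scaled off the femur
length, sufficient to give the downstream statics and stress machinery a
fully determined, well-posed model.

Synthetic cancellous-fabric fields are generated with a known ground
truth: unit axes are drawn from a bipolar Watson distribution whose modal
axis at each lattice point is the compressive (or, in tensile regions,
tensile) principal stress axis of the forward model evaluated at a hidden
"true" posture.  Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from trajpose.bone_stress import BONES, CrossSection, stress_trajectory_field
from trajpose.fabric_correspondence import SphericalROI, VectorField
from trajpose.musculoskeletal import (
    ModelSpec,
    MuscleSpec,
    Posture,
    scale_com_isometric,
    static_optimization,
)

__all__ = [
    "SpeciesTemplate",
    "FabricScenario",
    "TEMPLATE_NAMES",
    "build_species_template",
    "scale_template",
    "default_rois",
    "build_lattice",
    "sample_watson",
    "generate_fabric_field",
    "write_fixtures",
]

TEMPLATE_NAMES: Tuple[str, ...] = (
    "large-tyrannosaurid-scale",
    "troodontid-scale",
    "chicken-scale",
)

#: Default chicken-scale total mass, back-derived from the reserve-actuator
#: proportionality 1,000 N*m : 1,767,308 N*m :: mass : 2,757 kg.  A default,
#: not a printed value.
CHICKEN_DEFAULT_MASS = 2757.0 * 1000.0 / 1767308.0

# limb mass split among segments (per-segment values are not printed)
_LIMB_MASS_FRACTIONS = {"femur": 0.60, "tibiotarsus": 0.30, "tarsometatarsus": 0.07}

# outer mediolateral semi-axis of each bone's section, fraction of its length
_SECTION_ML_FRAC = {"femur": 0.065, "tibiotarsus": 0.055,
                    "tarsometatarsus": 0.06, "pes": 0.08}
_SECTION_AP_RATIO = 0.85      # a_ap = ratio * a_ml
_WALL_FRACTION = 0.35
_EPIPHYSIS_FACTOR = 1.8       # epiphysis radius = factor * a_ml


@dataclass(frozen=True)
class SpeciesTemplate:
    """Complete parameterization of one species-scale limb model."""

    name: str
    total_body_mass: float
    right_hindlimb_mass: float
    pelvis_segment_mass: float
    segment_lengths: Dict[str, float]
    segment_masses: Dict[str, float]
    pelvis_com_offset_anterior: float
    cross_sections: Dict[str, CrossSection]
    epiphysis_radii: Dict[str, float]
    muscle_roster: Tuple[MuscleSpec, ...]
    knee_axis_obliquity_deg: float = 0.0

    def __post_init__(self):
        if abs(self.pelvis_segment_mass - (self.total_body_mass - self.right_hindlimb_mass)) > 0:
            raise ValueError("pelvis mass must equal total minus right hindlimb mass exactly")
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise ValueError("segment lengths must be strictly positive")
        if any(v <= 0 for v in self.segment_masses.values()):
            raise ValueError("segment masses must be strictly positive")

    @property
    def femur_length(self) -> float:
        return self.segment_lengths["femur"]


@dataclass
class FabricScenario:
    """Recipe for one synthetic fabric field with a hidden true posture."""

    true_posture: Posture
    axial_concentration: float = 50.0  # Watson kappa; inf = zero dispersion
    lattice_spacing: Optional[float] = None  # metres; None = bone length / 40
    rois: Optional[List[SphericalROI]] = None
    rng_seed: int = 0
    bones: Tuple[str, ...] = BONES

    def __post_init__(self):
        if self.axial_concentration < 0:
            raise ValueError("axial_concentration (kappa) must be >= 0")
        if self.lattice_spacing is not None and self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive")


# ---------------------------------------------------------------------------
# Muscle roster
# ---------------------------------------------------------------------------
# Path geometry table.  Pelvis points are (x, y, z) in fractions of femur
# length in the pelvis frame (origin at the hip).  Points on limb segments
# are (x, y) in units of a width scale W = 0.18 * femur length and an axial
# fraction along the segment (0 proximal, 1 distal).  Activity flags follow
# the study's activity mask; group tags follow its muscle-group definitions
# (abductor = IFE; medial rotators = ITC + PIFI1 + PIFI2 in the fossil
# templates, the iliotrochanterici — represented by ITC — in the
# chicken-scale template).

_P = "pelvis"
_F = "femur"
_T = "tibiotarsus"
_M = "tarsometatarsus"
_E = "pes"

_MUSCLE_TABLE = [
    # name, active, group, [(segment, spec)...]
    ("IT1", True, "other", [(_P, (0.12, -0.05, 0.16)), (_F, (1.3, -0.4, 0.90)), (_T, (1.2, -0.2, 0.05))]),
    ("IT2", True, "other", [(_P, (0.02, -0.06, 0.17)), (_F, (1.3, -0.4, 0.90)), (_T, (1.2, -0.2, 0.05))]),
    ("IT3", True, "other", [(_P, (-0.10, -0.05, 0.15)), (_F, (1.3, -0.4, 0.90)), (_T, (1.2, -0.2, 0.05))]),
    ("AMB", True, "other", [(_P, (0.10, 0.01, 0.00)), (_F, (1.2, 0.0, 0.92)), (_T, (1.2, 0.0, 0.06))]),
    ("FMTE", True, "other", [(_F, (0.0, -1.1, 0.45)), (_F, (1.3, -0.4, 0.90)), (_T, (1.2, -0.2, 0.05))]),
    ("FMTI", True, "other", [(_F, (0.0, 1.0, 0.50)), (_F, (1.3, 0.3, 0.90)), (_T, (1.2, 0.2, 0.05))]),
    ("ILFB", True, "other", [(_P, (-0.12, -0.03, 0.10)), (_T, (-0.6, -1.0, 0.12))]),
    ("IFE", True, "hip_abductor", [(_P, (0.04, -0.10, 0.14)), (_F, (0.2, -1.6, 0.12))]),
    ("ITC", True, "hip_medial_rotator", [(_P, (0.12, -0.05, 0.08)), (_F, (1.4, -1.0, 0.08))]),
    ("PIFI1", True, "hip_medial_rotator", [(_P, (0.16, 0.04, 0.02)), (_F, (1.2, 0.8, 0.10))]),
    ("PIFI2", True, "hip_medial_rotator", [(_P, (0.12, 0.00, 0.07)), (_F, (1.2, -0.6, 0.14))]),
    ("FTI1", True, "other", [(_P, (-0.10, 0.03, -0.02)), (_T, (-0.9, 0.5, 0.08))]),
    ("FTI3", True, "other", [(_P, (-0.13, 0.03, 0.02)), (_T, (-0.9, 0.4, 0.10))]),
    ("FTE", True, "other", [(_P, (-0.16, 0.00, 0.08)), (_T, (-1.0, -0.2, 0.08))]),
    ("ADD1", True, "other", [(_P, (-0.04, 0.05, -0.10)), (_F, (-0.6, 0.5, 0.50))]),
    ("ADD2", True, "other", [(_P, (-0.08, 0.05, -0.09)), (_F, (-0.6, 0.4, 0.55))]),
    ("PIFE1", False, "other", [(_P, (0.08, 0.03, -0.08)), (_F, (0.2, -1.0, 0.05))]),
    ("PIFE2", False, "other", [(_P, (0.06, 0.03, -0.11)), (_F, (0.2, -1.0, 0.05))]),
    ("PIFE3", False, "other", [(_P, (-0.07, 0.02, -0.08)), (_F, (-0.2, -1.0, 0.06))]),
    ("ISTR", True, "other", [(_P, (-0.11, -0.02, -0.03)), (_F, (-1.0, -1.0, 0.18))]),
    ("CFL", True, "other", [(_P, (-0.22, 0.01, 0.02)), (_F, (-1.0, 0.3, 0.35))]),
    ("CFB", True, "other", [(_P, (-0.15, 0.00, 0.03)), (_F, (-0.9, 0.1, 0.32))]),
    ("GL", True, "other", [(_F, (-1.0, -0.4, 0.93)), (_M, (-1.2, 0.0, 0.04)), (_M, (-1.0, 0.0, 0.25))]),
    ("GM", True, "other", [(_T, (-1.0, 0.5, 0.10)), (_M, (-1.2, 0.1, 0.04)), (_M, (-1.0, 0.1, 0.25))]),
    ("FDL", True, "other", [(_T, (-0.9, 0.0, 0.35)), (_M, (-1.1, 0.0, 0.05)), (_M, (-0.9, 0.0, 0.95)), (_E, (-0.8, 0.0, 0.45))]),
    ("FDB", True, "other", [(_M, (-1.0, 0.0, 0.60)), (_M, (-0.9, 0.0, 0.96)), (_E, (-0.7, 0.0, 0.40))]),
    ("FHL", True, "other", [(_T, (-0.9, -0.3, 0.40)), (_M, (-1.1, -0.1, 0.05)), (_M, (-0.9, -0.1, 0.95)), (_E, (-0.7, -0.2, 0.35))]),
    ("EDL", False, "other", [(_T, (1.0, 0.0, 0.10)), (_M, (1.2, 0.0, 0.04)), (_M, (0.9, 0.0, 0.96)), (_E, (0.7, 0.0, 0.40))]),
    ("EDB", False, "other", [(_M, (1.0, 0.0, 0.50)), (_M, (0.9, 0.0, 0.97)), (_E, (0.6, 0.0, 0.35))]),
    ("EHL", False, "other", [(_M, (1.0, 0.2, 0.45)), (_M, (0.9, 0.2, 0.96)), (_E, (0.6, 0.2, 0.30))]),
    ("TA", False, "other", [(_T, (1.1, 0.0, 0.08)), (_M, (1.0, 0.0, 0.15))]),
    ("FL", False, "other", [(_T, (0.0, -1.0, 0.20)), (_M, (-1.1, -0.2, 0.05)), (_M, (-0.9, -0.2, 0.30))]),
    ("FB", False, "other", [(_T, (0.0, -1.0, 0.35)), (_M, (0.0, -1.1, 0.10))]),
]

#: Names expected to be force-capable under the study's activity mask.
ACTIVE_MUSCLES = tuple(n for n, act, _, _ in _MUSCLE_TABLE if act)
INACTIVE_MUSCLES = tuple(n for n, act, _, _ in _MUSCLE_TABLE if not act)


def _build_roster(
    segment_lengths: Dict[str, float], chicken_grouping: bool
) -> Tuple[MuscleSpec, ...]:
    lf = segment_lengths["femur"]
    width = 0.18 * lf
    roster = []
    for name, active, group, path in _MUSCLE_TABLE:
        pts = []
        for seg, spec in path:
            if seg == _P:
                pts.append((seg, (spec[0] * lf, spec[1] * lf, spec[2] * lf)))
            else:
                pts.append(
                    (seg, (spec[0] * width, spec[1] * width,
                           -spec[2] * segment_lengths[seg]))
                )
        if chicken_grouping:
            # chicken-scale: IFE inactive; medial rotators are the
            # iliotrochanterici (represented here by ITC alone)
            if name == "IFE":
                active = False
            if name in ("PIFI1", "PIFI2"):
                group = "other"
        roster.append(MuscleSpec(name=name, path=tuple(pts), active=active, group=group))
    return tuple(roster)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

_TEMPLATE_PARAMS = {
    # name: (total mass, limb mass, femur length, length ratios rel. femur,
    #        pelvis COM offset, chicken-style grouping)
    "large-tyrannosaurid-scale": dict(
        total=2757.0,
        limb=342.7,
        femur=0.984,
        ratios={"tibiotarsus": 1.00, "tarsometatarsus": 0.55, "pes": 0.35},
        pelvis_com=scale_com_isometric(0.544, 1.265, 0.984),
        chicken=False,
    ),
    "troodontid-scale": dict(
        total=48.5,
        limb=5.65,
        femur=0.304,
        ratios={"tibiotarsus": 1.30, "tarsometatarsus": 0.75, "pes": 0.40},
        pelvis_com=scale_com_isometric(0.090, 0.163, 0.304),
        chicken=False,
    ),
    "chicken-scale": dict(
        total=CHICKEN_DEFAULT_MASS,
        limb=0.10 * CHICKEN_DEFAULT_MASS,
        femur=0.075,
        ratios={"tibiotarsus": 1.45, "tarsometatarsus": 0.85, "pes": 0.50},
        pelvis_com=scale_com_isometric(0.090, 0.163, 0.075),
        chicken=True,
    ),
}


def build_species_template(name: str) -> SpeciesTemplate:
    """Construct one of the three named species-scale templates."""
    if name not in _TEMPLATE_PARAMS:
        raise ValueError(
            f"unknown template {name!r}; valid templates: {', '.join(TEMPLATE_NAMES)}"
        )
    p = _TEMPLATE_PARAMS[name]
    total, limb, femur = p["total"], p["limb"], p["femur"]
    lengths = {"femur": femur}
    for seg, ratio in p["ratios"].items():
        lengths[seg] = ratio * femur
    masses = {seg: frac * limb for seg, frac in _LIMB_MASS_FRACTIONS.items()}
    masses["pes"] = limb - sum(masses.values())  # exact bookkeeping
    sections = {}
    epiphyses = {}
    for bone in BONES:
        a_ml = _SECTION_ML_FRAC[bone] * lengths[bone]
        sections[bone] = CrossSection(
            a_ap=_SECTION_AP_RATIO * a_ml, a_ml=a_ml, wall_fraction=_WALL_FRACTION
        )
        epiphyses[bone] = _EPIPHYSIS_FACTOR * a_ml
    return SpeciesTemplate(
        name=name,
        total_body_mass=total,
        right_hindlimb_mass=limb,
        pelvis_segment_mass=total - limb,
        segment_lengths=lengths,
        segment_masses=masses,
        pelvis_com_offset_anterior=p["pelvis_com"],
        cross_sections=sections,
        epiphysis_radii=epiphyses,
        muscle_roster=_build_roster(lengths, p["chicken"]),
    )


def scale_template(
    template: SpeciesTemplate, length_scale: float, mass_scale: float,
    name: Optional[str] = None,
) -> SpeciesTemplate:
    """Uniformly rescale a template's geometry and masses (for invariance checks)."""
    if length_scale <= 0 or mass_scale <= 0:
        raise ValueError("scales must be positive")
    s, m = length_scale, mass_scale
    lengths = {k: v * s for k, v in template.segment_lengths.items()}
    roster = tuple(
        MuscleSpec(
            name=mus.name,
            path=tuple((seg, (x * s, y * s, z * s)) for seg, (x, y, z) in mus.path),
            active=mus.active,
            group=mus.group,
        )
        for mus in template.muscle_roster
    )
    return SpeciesTemplate(
        name=name or f"{template.name}-x{s:g}",
        total_body_mass=template.total_body_mass * m,
        right_hindlimb_mass=template.right_hindlimb_mass * m,
        pelvis_segment_mass=(template.total_body_mass - template.right_hindlimb_mass) * m,
        segment_lengths=lengths,
        segment_masses={k: v * m for k, v in template.segment_masses.items()},
        pelvis_com_offset_anterior=template.pelvis_com_offset_anterior * s,
        cross_sections={
            k: CrossSection(a_ap=c.a_ap * s, a_ml=c.a_ml * s, wall_fraction=c.wall_fraction)
            for k, c in template.cross_sections.items()
        },
        epiphysis_radii={k: v * s for k, v in template.epiphysis_radii.items()},
        muscle_roster=roster,
        knee_axis_obliquity_deg=template.knee_axis_obliquity_deg,
    )


# ---------------------------------------------------------------------------
# ROIs and lattices
# ---------------------------------------------------------------------------

def default_rois(template: SpeciesTemplate) -> List[SphericalROI]:
    """Anatomically placed default ROI spheres, scaled to the template.

    ROI radius defaults to 20% of the containing epiphysis width
    (0.4 x epiphysis radius).
    """

    def _roi(label, bone, cx, cy, cz, mode="compressive"):
        re = template.epiphysis_radii[bone]
        return SphericalROI(
            label=label, bone=bone,
            centre=(cx * re, cy * re, cz * re),
            radius=0.4 * re, mode=mode,
        )

    lf = template.segment_lengths["femur"]
    re_f = template.epiphysis_radii["femur"]
    condyle_z = -(lf - re_f) / re_f  # distal epiphysis centre, in re units
    return [
        _roi("femoral_head", "femur", 0.0, 0.45, -1.0),
        _roi("lesser_trochanter", "femur", 0.35, -0.35, -0.9, mode="tensile"),
        _roi("medial_femoral_condyle", "femur", 0.0, 0.45, condyle_z),
        _roi("proximal_tibiotarsus", "tibiotarsus", 0.0, 0.0, -1.0),
        _roi("proximal_tarsometatarsus", "tarsometatarsus", 0.0, 0.0, -1.0),
        _roi("proximal_pes", "pes", 0.0, 0.0, -1.0),
    ]


def build_lattice(
    template: SpeciesTemplate,
    spacing: Optional[float] = None,
    bones: Sequence[str] = BONES,
) -> Tuple[np.ndarray, np.ndarray]:
    """Regular lattice of points inside each bone's capsule volume.

    Returns ``(bones, points)`` with points in bone-local coordinates.
    ``spacing`` is a single metre value; if None, each bone uses 1/40 of
    its own length.
    """
    all_bones: List[str] = []
    all_pts: List[np.ndarray] = []
    for bone in bones:
        length = template.segment_lengths[bone]
        c = template.cross_sections[bone].c_outer
        re = template.epiphysis_radii[bone]
        h = spacing if spacing is not None else length / 40.0
        xs = np.arange(-re, re + h / 2, h)
        zs = np.arange(-length, 0.0 + h / 2, h)
        gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        t = -pts[:, 2]
        rho = np.hypot(pts[:, 0], pts[:, 1])
        d_prox = np.linalg.norm(pts - np.array([0.0, 0.0, -re]), axis=1)
        d_dist = np.linalg.norm(pts - np.array([0.0, 0.0, -(length - re)]), axis=1)
        inside = np.where(
            t < re, d_prox <= re,
            np.where(t > length - re, d_dist <= re, rho <= c),
        )
        pts = pts[inside]
        all_bones.extend([bone] * len(pts))
        all_pts.append(pts)
    return np.array(all_bones, dtype=object), np.vstack(all_pts)


def _check_roi_coverage(template, rois, bones):
    for roi in rois:
        if roi.bone not in bones:
            raise ValueError(
                f"ROI {roi.label!r} lies on bone {roi.bone!r} which is not in "
                f"the lattice bones {tuple(bones)}"
            )
        length = template.segment_lengths[roi.bone]
        re = template.epiphysis_radii[roi.bone]
        c = np.asarray(roi.centre)
        lo = np.array([-re, -re, -length])
        hi = np.array([re, re, 0.0])
        if np.any(c - roi.radius < lo - 1e-12) or np.any(c + roi.radius > hi + 1e-12):
            raise ValueError(
                f"ROI {roi.label!r} sphere is not entirely covered by the "
                f"{roi.bone} lattice volume"
            )


# ---------------------------------------------------------------------------
# Watson axial sampling
# ---------------------------------------------------------------------------

def sample_watson(
    mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` unit axes from a bipolar Watson distribution around ``mu``.

    Density proportional to ``exp(kappa * (mu . x)^2)`` on the sphere,
    sampled by rejection from the uniform sphere; ``kappa = inf`` returns
    the modal axis exactly (zero dispersion).  Axial: returned axes are
    sign-canonicalized only by the caller if needed.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if math.isinf(kappa):
        return np.tile(mu, (n, 1))
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 256)
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t2 = (v @ mu) ** 2
        accept = rng.random(m) < np.exp(kappa * (t2 - 1.0))
        got = v[accept]
        take = min(len(got), n - filled)
        out[filled:filled + take] = got[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# Fabric field generation
# ---------------------------------------------------------------------------

def generate_fabric_field(
    template: SpeciesTemplate, scenario: FabricScenario
) -> VectorField:
    """Synthesize a fabric field whose modal axes follow the forward model.

    At each lattice point the modal axis is the compressive principal
    stress axis (s3) of the forward model at the scenario's true posture —
    or the tensile axis (s1) inside a tensile-mode ROI — and the sampled
    fabric axis is Watson-distributed about it with concentration kappa.
    """
    rois = scenario.rois if scenario.rois is not None else default_rois(template)
    _check_roi_coverage(template, rois, scenario.bones)
    bones, points = build_lattice(template, scenario.lattice_spacing, scenario.bones)

    model = ModelSpec.from_template(template)
    solution = static_optimization(model, scenario.true_posture)
    stress = stress_trajectory_field(
        model, scenario.true_posture, solution, bones, points
    )

    # label points with the ROI (first match wins; labels are unique)
    labels = np.array([""] * len(stress), dtype=object)
    modal_comp = np.array(["s3"] * len(stress), dtype=object)
    for roi in rois:
        m = (stress.bone == roi.bone) & (
            np.linalg.norm(stress.points - np.asarray(roi.centre), axis=1) <= roi.radius
        )
        m &= labels == ""
        labels[m] = roi.label
        if roi.mode == "tensile":
            modal_comp[m] = "s1"

    rng = np.random.default_rng(scenario.rng_seed)
    axes = np.empty((len(stress), 3))
    for i in range(len(stress)):
        mu = stress.axes[str(modal_comp[i])][i]
        axes[i] = sample_watson(mu, scenario.axial_concentration, 1, rng)[0]

    return VectorField(
        bone=stress.bone.copy(),
        points=stress.points.copy(),
        axes={"u1": axes},
        roi=labels,
        meta={
            "template": template.name,
            "kappa": scenario.axial_concentration,
            "rng_seed": scenario.rng_seed,
            "true_posture": scenario.true_posture.angles(),
            "n_skipped": stress.meta.get("n_skipped", 0),
        },
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(
    template: SpeciesTemplate, scenario: FabricScenario, directory
) -> Dict[str, Path]:
    """Write a complete synthetic dataset: model, fabric, ROIs, manifest.

    The files round-trip losslessly through the readers in
    :mod:`trajpose.io`.
    """
    from trajpose import io  # local import: io depends on this module's types

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rois = scenario.rois if scenario.rois is not None else default_rois(template)
    fabric = generate_fabric_field(template, scenario)

    paths = {
        "model": directory / "model.json",
        "fabric": directory / "fabric.tsv",
        "rois": directory / "rois.tsv",
        "posture": directory / "true_posture.txt",
        "manifest": directory / "manifest.json",
    }
    io.write_model_spec(paths["model"], template)
    io.write_vector_field(paths["fabric"], fabric)
    io.write_rois(paths["rois"], rois)
    io.write_posture(paths["posture"], scenario.true_posture)
    manifest = {
        "format": "trajpose-manifest v1",
        "template": template.name,
        "rng_seed": scenario.rng_seed,
        "axial_concentration": scenario.axial_concentration,
        "lattice_spacing": scenario.lattice_spacing,
        "bones": list(scenario.bones),
        "true_posture": scenario.true_posture.angles(),
        "n_lattice_points": len(fabric),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
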