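"""Iterative posture refinement driven by the correspondence score.

Greedy coordinate descent with fixed per-DOF step sizes, formalizing the
few-posture hand iteration of the source workflow: each round enumerates
coordinate-wise +/- step candidates, evaluates the stress-vs-fabric
correspondence score of each, accepts the best strictly improving one and
stops when no candidate improves (or the iteration cap is reached).  The
search itself is deterministic; all randomness lives in fabric generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from trajpose.bone_stress import stress_trajectory_field
from trajpose.fabric_correspondence import (
    CorrespondenceReport,
    SphericalROI,
    VectorField,
    correspondence_score,
)
from trajpose.musculoskeletal import (
    ACTUATED_DOFS,
    InfeasibleActivationError,
    InfeasiblePostureError,
    LoadCase,
    ModelSpec,
    Posture,
    forward_kinematics,
    inverse_static_moments,
    moment_arm_matrix,
    static_optimization,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "HipArticulationVariant",
    "enumerate_candidates",
    "evaluate_posture",
    "search",
    "apply_hip_variant",
    "foot_placement_diagnostics",
]


@dataclass
class SearchConfig:
    base_posture: Posture
    step_sizes: Dict[str, float] = field(
        default_factory=lambda: {d: 5.0 for d in ACTUATED_DOFS}
    )
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    max_iterations: int = 50
    improvement_tolerance: float = 0.0  # degrees
    min_roi_points: int = 10
    dofs: Tuple[str, ...] = ACTUATED_DOFS  # subset of DOFs to perturb

    def __post_init__(self):
        for d in self.dofs:
            if d not in ACTUATED_DOFS:
                raise ValueError(f"unknown DOF {d!r}")
            step = self.step_sizes.get(d, 0.0)
            if step <= 0:
                raise ValueError(f"step size for {d!r} must be > 0 (got {step})")
        if self.improvement_tolerance < 0:
            raise ValueError("improvement_tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class HipArticulationVariant:
    """Parametric change of hip articulation.

    The femoral head (and everything distal to the hip) translates medially
    by ``medial_translation``; ``extra_abduction`` / ``extra_lar`` are added
    to every evaluated posture.
    """

    medial_translation: float = 0.0
    extra_abduction: float = 0.0
    extra_lar: float = 0.0


@dataclass
class SearchResult:
    posture: Posture
    score: float
    report: CorrespondenceReport
    trace: List[Dict[str, object]]
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(current: Posture, config: SearchConfig) -> List[Posture]:
    """Coordinate-wise +/- step perturbations, clipped to bounds, deduplicated."""
    bounds = config.bounds or {d: (-1e9, 1e9) for d in ACTUATED_DOFS}
    out: List[Posture] = []
    seen = {tuple(current.as_array())}
    for dof in config.dofs:
        lo, hi = bounds.get(dof, (-1e9, 1e9))
        for sign in (+1.0, -1.0):
            val = getattr(current, dof) + sign * config.step_sizes[dof]
            val = min(max(val, lo), hi)
            cand = current.replace(**{dof: val})
            key = tuple(cand.as_array())
            if key not in seen:
                seen.add(key)
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_posture(
    model: ModelSpec,
    posture: Posture,
    fabric: VectorField,
    rois: Sequence[SphericalROI],
    load_case: Optional[LoadCase] = None,
    min_roi_points: int = 10,
) -> Tuple[float, Optional[CorrespondenceReport]]:
    """End-to-end correspondence score of one posture.

    Solves the statics, computes the stress trajectory field at the fabric's
    lattice points and scores the agreement.  Infeasible postures or
    activation sets score +inf (rejected by the search, not fatal).
    """
    try:
        solution = static_optimization(model, posture, load_case=load_case)
        stress = stress_trajectory_field(
            model, posture, solution, fabric.bone, fabric.points, load_case=load_case
        )
    except (InfeasiblePostureError, InfeasibleActivationError):
        return math.inf, None
    report = correspondence_score(stress, fabric, rois, min_points=min_roi_points)
    if not report.ok or math.isnan(report.overall_score):
        return math.inf, report
    return report.overall_score, report


def _restrict_to_rois(fabric: VectorField, rois: Sequence[SphericalROI]) -> VectorField:
    mask = np.zeros(len(fabric), dtype=bool)
    for roi in rois:
        mask |= (fabric.bone == roi.bone) & (
            np.linalg.norm(fabric.points - np.asarray(roi.centre), axis=1) <= roi.radius
        )
    return fabric.mask(mask)


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------

def search(
    model: ModelSpec,
    fabric: VectorField,
    rois: Sequence[SphericalROI],
    config: SearchConfig,
    load_case: Optional[LoadCase] = None,
) -> SearchResult:
    """Greedy descent on the correspondence score from the base posture.

    Each round evaluates all candidates of :func:`enumerate_candidates`
    around the incumbent, accepts the best candidate whose score improves
    by more than the tolerance (ties broken by smallest angular change,
    then DOF order) and terminates when no candidate improves or the
    iteration cap is hit.  The trace records every evaluated posture.
    """
    fabric_sub = _restrict_to_rois(fabric, rois)
    cache: Dict[Tuple[float, ...], Tuple[float, Optional[CorrespondenceReport]]] = {}

    def cached_eval(p: Posture):
        key = tuple(p.as_array())
        if key not in cache:
            cache[key] = evaluate_posture(
                model, p, fabric_sub, rois, load_case=load_case,
                min_roi_points=config.min_roi_points,
            )
        return cache[key]

    trace: List[Dict[str, object]] = []

    def log(iteration, posture, score, report, accepted):
        row: Dict[str, object] = {"iteration": iteration, "accepted": accepted,
                                  "score": score}
        row.update({d: getattr(posture, d) for d in ACTUATED_DOFS})
        if report is not None:
            row.update({f"dev_{r.label}": r.deviation for r in report.rois})
        trace.append(row)

    current = config.base_posture
    score, report = cached_eval(current)
    if math.isinf(score):
        raise InfeasiblePostureError(
            f"base posture is not evaluable: {config.base_posture}"
        )
    log(0, current, score, report, True)

    converged = False
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        ranked = []
        for ci, cand in enumerate(enumerate_candidates(current, config)):
            c_score, c_report = cached_eval(cand)
            log(iteration, cand, c_score, c_report, False)
            if math.isinf(c_score):
                continue
            change = float(np.abs(cand.as_array() - current.as_array()).sum())
            ranked.append((c_score, change, ci, cand, c_report))
        improving = [r for r in ranked
                     if r[0] < score - config.improvement_tolerance]
        if not improving:
            converged = True
            break
        best = min(improving, key=lambda r: (r[0], r[1], r[2]))
        score, current, report = best[0], best[3], best[4]
        log(iteration, current, score, report, True)

    return SearchResult(
        posture=current,
        score=score,
        report=report,
        trace=trace,
        n_iterations=iteration,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Hip articulation variant
# ---------------------------------------------------------------------------

def apply_hip_variant(model: ModelSpec, variant: HipArticulationVariant) -> ModelSpec:
    """Model with the femoral head translated medially within the acetabulum.

    The femur frame — and with it all distal joints and every muscle point
    level with or distal to the hip — shifts by the medial translation;
    pelvis-frame muscle origins stay put.  The abduction/LAR offsets of the
    variant are applied to postures via :meth:`HipArticulationVariant` by
    the caller (see :func:`variant_posture`).
    """
    acetab_width = 2.0 * model.template.epiphysis_radii["femur"]
    if abs(variant.medial_translation) > acetab_width:
        raise ValueError(
            f"medial translation {variant.medial_translation} m exceeds the "
            f"acetabular width {acetab_width:.3f} m"
        )
    return dc_replace(
        model,
        hip_offset=(
            model.hip_offset[0],
            model.hip_offset[1] + variant.medial_translation,
            model.hip_offset[2],
        ),
    )


def variant_posture(posture: Posture, variant: HipArticulationVariant) -> Posture:
    """Posture with the variant's abduction/LAR offsets added."""
    return posture.replace(
        hip_abduction=posture.hip_abduction + variant.extra_abduction,
        hip_lar=posture.hip_lar + variant.extra_lar,
    )


def foot_placement_diagnostics(
    model: ModelSpec, posture: Posture, load_case: Optional[LoadCase] = None
) -> Dict[str, float]:
    """Step-width and hip-height diagnostics for a (variant) configuration.

    Step width is twice the mediolateral offset of the centre of pressure
    from the body midline (the pelvis origin plane), reported both in
    metres and as a fraction of hip height.
    """
    frames = forward_kinematics(model, posture, load_case=load_case, ground=True)
    step_width = 2.0 * abs(float(frames.cop[1]))
    h = frames.hip_height
    return {
        "hip_height": h,
        "step_width": step_width,
        "step_width_ratio": step_width / h if h > 0 else math.inf,
    }
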