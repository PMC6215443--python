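"""Beam-theory bone loading: internal loads, section stresses, stress axes.

Each long bone is idealized as a straight beam along its segment's long
axis, with a hollow-elliptical cross-section and hemispherical epiphyses
(a capsule volume).  Internal loads at a cross-section station are the
resultant of all point loads applied distal to the cut: the transmitted
force/moment at the distal joint, muscle forces at attachment and via
points, the segment weight, and (for the pes) the ground reaction force.

Section coordinates are the bone's local frame: ``x`` anterior, ``y``
mediolateral, ``z`` proximal (the distal joint sits at local
``(0, 0, -L)``).  Tension is positive.  Epiphyseal stress directions use a
joint-resultant surrogate: the compressive principal axis is taken along
the joint contact force transmitted through that epiphysis, with the
tensile axis orthogonal in the plane it spans with the bone long axis.
This surrogate is a modelling construction and is labelled as such in
reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from trajpose.musculoskeletal import (
    ACTUATED_DOFS,
    SEGMENTS,
    ActivationSolution,
    LimbFrames,
    LoadCase,
    ModelSpec,
    Posture,
    forward_kinematics,
    max_muscle_force,
    muscle_path_points,
)
from trajpose.fabric_correspondence import VectorField

__all__ = [
    "CrossSection",
    "BoneLoadState",
    "StressState",
    "BONES",
    "internal_loads",
    "joint_forces",
    "section_stresses",
    "principal_orientation",
    "shear_bending_ratio",
    "fit_local_long_axis",
    "stress_trajectory_field",
    "midshaft_state",
]

#: Bones with a beam representation (the pes is load-bearing but short;
#: it still gets a capsule so its proximal epiphysis can carry an ROI).
BONES: Tuple[str, ...] = ("femur", "tibiotarsus", "tarsometatarsus", "pes")

_PROXIMAL_JOINT = {"femur": "hip", "tibiotarsus": "knee",
                   "tarsometatarsus": "ankle", "pes": "mtp"}
_DISTAL_JOINT = {"femur": "knee", "tibiotarsus": "ankle",
                 "tarsometatarsus": "mtp", "pes": "toe"}


# ---------------------------------------------------------------------------
# Cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSection:
    """Hollow-elliptical cross-section with a geometrically similar bore.

    ``a_ap`` / ``a_ml`` are the outer semi-axes along the local anterior and
    mediolateral directions; ``wall_fraction`` t means the inner boundary is
    the outer one scaled by ``1 - t`` (t = 1 gives a solid section).
    """

    a_ap: float
    a_ml: float
    wall_fraction: float = 0.3

    def __post_init__(self):
        if self.a_ap <= 0 or self.a_ml <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.wall_fraction <= 1.0:
            raise ValueError("wall_fraction must be in (0, 1]")

    @property
    def inner_scale(self) -> float:
        return 1.0 - self.wall_fraction

    @property
    def area(self) -> float:
        s = self.inner_scale
        return math.pi * self.a_ap * self.a_ml * (1.0 - s * s)

    @property
    def i_ml(self) -> float:
        """Second moment about the mediolateral axis (= integral of x^2 dA)."""
        s = self.inner_scale
        return math.pi / 4.0 * self.a_ap ** 3 * self.a_ml * (1.0 - s ** 4)

    @property
    def i_ap(self) -> float:
        """Second moment about the anterior axis (= integral of y^2 dA)."""
        s = self.inner_scale
        return math.pi / 4.0 * self.a_ml ** 3 * self.a_ap * (1.0 - s ** 4)

    @property
    def j_polar(self) -> float:
        return self.i_ml + self.i_ap

    @property
    def c_outer(self) -> float:
        """Outermost fibre distance from the centroid."""
        return max(self.a_ap, self.a_ml)

    def boundary(self, n: int = 360) -> np.ndarray:
        """(n, 2) points on the outer boundary."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return np.column_stack([self.a_ap * np.cos(t), self.a_ml * np.sin(t)])


# ---------------------------------------------------------------------------
# Load states and stress states
# ---------------------------------------------------------------------------

@dataclass
class BoneLoadState:
    """Internal load resultant at one station along a bone.

    ``force_local`` / ``moment_local`` are the resultants of all loads
    distal to the cut, expressed in the bone's local frame about the
    station point on the axis.
    """

    station: float  # metres from the proximal joint
    force_local: np.ndarray
    moment_local: np.ndarray

    @property
    def axial_force(self) -> float:
        """Normal force N; tension positive (distal resultant pulls away)."""
        return -float(self.force_local[2])

    @property
    def torque(self) -> float:
        """Torque about the distally directed long axis."""
        return -float(self.moment_local[2])

    @property
    def m_ap(self) -> float:
        """Bending moment component about the local anterior axis."""
        return float(self.moment_local[0])

    @property
    def m_ml(self) -> float:
        """Bending moment component about the local mediolateral axis."""
        return float(self.moment_local[1])

    @property
    def bending_magnitude(self) -> float:
        return math.hypot(self.m_ap, self.m_ml)

    @property
    def shear_force(self) -> float:
        return float(np.hypot(self.force_local[0], self.force_local[1]))


@dataclass
class StressState:
    """Stresses at one cross-section station."""

    sigma_max: float
    sigma_min: float
    tau_max: float
    sigma_bending: float
    theta_principal: float  # degrees from the local long-axis, in [0, 45]
    neutral_axis_angle: float  # degrees from the mediolateral axis, [-90, 90]
    neutral_axis_defined: bool = True
    principal_defined: bool = True


def _axial_stress_coeffs(load: BoneLoadState, section: CrossSection) -> Tuple[float, float, float]:
    """sigma_zz(x, y) = c0 + c1*x + c2*y on the section."""
    if section.area <= 0:
        raise ValueError("zero-area section")
    c0 = load.axial_force / section.area
    c1 = float(load.moment_local[1]) / section.i_ml
    c2 = -float(load.moment_local[0]) / section.i_ap
    return c0, c1, c2


def section_stresses(load: BoneLoadState, section: CrossSection, n_boundary: int = 360) -> StressState:
    """Evaluate extreme normal stresses, torsional shear and derived metrics.

    Normal stress from N/A plus the two bending terms on the outer fibre;
    shear from the torque via tau = T*rho/J (engineering approximation with
    J the polar second moment).  ``sigma_bending`` is half the normal-stress
    range across the section, equal to (|sigma_max| + |sigma_min|)/2
    whenever bending dominates so the extremes straddle zero, and zero
    under purely axial load.
    """
    c0, c1, c2 = _axial_stress_coeffs(load, section)
    pts = section.boundary(n_boundary)
    sig = c0 + c1 * pts[:, 0] + c2 * pts[:, 1]
    i_max = int(np.argmax(sig))
    i_min = int(np.argmin(sig))
    sigma_max = float(sig[i_max])
    sigma_min = float(sig[i_min])
    sigma_bending = 0.5 * (sigma_max - sigma_min)

    t = load.torque
    tau_max = abs(t) * section.c_outer / section.j_polar

    pure_axial = math.isclose(sigma_max, sigma_min, rel_tol=1e-12, abs_tol=1e-9)
    if pure_axial and abs(t) < 1e-12:
        # purely axial: neither the bending direction nor the principal
        # inclination carry information
        na_angle, na_defined = float("nan"), False
        theta, p_defined = float("nan"), abs(sigma_max) > 0
        if p_defined:
            theta = 0.0
    else:
        if pure_axial:
            na_angle, na_defined = float("nan"), False
        else:
            # neutral axis: zero line of c1*x + c2*y + c0; its direction is
            # (-c2, c1); angle measured from the mediolateral (y) axis,
            # positive toward anterior, folded to [-90, 90]
            ang = math.degrees(math.atan2(-c2, c1))
            na_angle = (ang + 90.0) % 180.0 - 90.0
            na_defined = True
        # orientation metric: principal inclination evaluated at
        # the extreme tensile and compressive fibres, then averaged
        rho_max = float(np.hypot(*pts[i_max]))
        rho_min = float(np.hypot(*pts[i_min]))
        th1 = principal_orientation(sigma_max, t * rho_max / section.j_polar)
        th3 = principal_orientation(sigma_min, t * rho_min / section.j_polar)
        vals = [v for v in (th1, th3) if not math.isnan(v)]
        theta = float(np.mean(vals)) if vals else float("nan")
        p_defined = bool(vals)

    return StressState(
        sigma_max=sigma_max,
        sigma_min=sigma_min,
        tau_max=tau_max,
        sigma_bending=sigma_bending,
        theta_principal=theta,
        neutral_axis_angle=na_angle,
        neutral_axis_defined=na_defined,
        principal_defined=p_defined,
    )


def beam_stress_components(
    section: CrossSection,
    axial_force,
    m_ap,
    m_ml,
    torque,
    x,
    y,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam stress components at in-section points ``(x, y)``.

    Returns ``(sigma_zz, tau_xz, tau_yz)``: axial normal stress from N/A
    plus both bending terms, and the torsional shear field (circular-shaft
    pattern normalized by the polar second moment).  All load arguments may
    be scalars or arrays broadcastable against ``x``/``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sigma = (
        axial_force / section.area
        + m_ml / section.i_ml * x
        - m_ap / section.i_ap * y
    )
    tau_x = -torque * y / section.j_polar
    tau_y = +torque * x / section.j_polar
    return sigma, tau_x, tau_y


def principal_axes_from_components(
    sigma: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Unit eigen-axes (s1 tensile, s3 compressive) of the beam stress tensor."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    tau_x = np.atleast_1d(np.asarray(tau_x, dtype=float))
    tau_y = np.atleast_1d(np.asarray(tau_y, dtype=float))
    tensors = np.zeros((len(sigma), 3, 3))
    tensors[:, 2, 2] = sigma
    tensors[:, 0, 2] = tensors[:, 2, 0] = tau_x
    tensors[:, 1, 2] = tensors[:, 2, 1] = tau_y
    _, vecs = np.linalg.eigh(tensors)
    return vecs[:, :, 2], vecs[:, :, 0]


def principal_orientation(sigma_axial: float, tau: float) -> float:
    """Inclination of the principal stress axes to the bone long axis.

    Mohr-circle closed form, folded to [0, 45] degrees: 0 in pure bending
    (principal axes parallel/perpendicular to the long axis), 45 in pure
    torsion.  Returns NaN when both inputs are zero (undefined state).
    """
    if sigma_axial == 0.0 and tau == 0.0:
        return float("nan")
    theta = 0.5 * math.degrees(math.atan2(2.0 * tau, sigma_axial))
    m = abs(theta) % 90.0
    return min(m, 90.0 - m)


def shear_bending_ratio(state: StressState) -> float:
    """Ratio of maximum shear to bending stress; inf flags pure torsion."""
    if state.sigma_bending <= 0.0:
        return math.inf
    return state.tau_max / state.sigma_bending


# ---------------------------------------------------------------------------
# Point loads along the chain
# ---------------------------------------------------------------------------

@dataclass
class _PointLoad:
    position: np.ndarray  # global
    force: np.ndarray     # global
    moment: np.ndarray    # global couple (zero except transmitted joint loads)


def _muscle_point_loads(
    model: ModelSpec, solution: ActivationSolution, frames: LimbFrames
) -> Dict[str, List[_PointLoad]]:
    """Forces each muscle applies to each segment at its path points."""
    fmax = max_muscle_force(model)
    loads: Dict[str, List[_PointLoad]] = {s: [] for s in SEGMENTS}
    for mus in model.muscles:
        f = solution.activations.get(mus.name, 0.0) * fmax
        if f <= 0.0:
            continue
        pts = muscle_path_points(model, mus, frames)
        n = len(pts)
        for i, (seg, _) in enumerate(mus.path):
            pull = np.zeros(3)
            if i > 0:
                d = pts[i - 1] - pts[i]
                pull += d / np.linalg.norm(d)
            if i < n - 1:
                d = pts[i + 1] - pts[i]
                pull += d / np.linalg.norm(d)
            loads[seg].append(_PointLoad(pts[i].copy(), f * pull, np.zeros(3)))
    return loads


def _chain_loads(
    model: ModelSpec,
    posture: Posture,
    solution: ActivationSolution,
    load_case: Optional[LoadCase] = None,
):
    """All point loads on each limb segment, plus transmitted joint loads.

    Returns ``(frames, seg_loads, joint_transmission)`` where
    ``joint_transmission[joint]`` is the (force, moment) the proximal
    segment exerts on the distal one across that joint, expressed globally
    with the moment about the joint centre.
    """
    if load_case is None:
        load_case = model.default_load_case()
    frames = forward_kinematics(model, posture, load_case=load_case, ground=False)
    seg_loads = _muscle_point_loads(model, solution, frames)
    g = model.g
    masses = model.segment_masses

    # weights
    for seg in SEGMENTS[1:]:
        seg_loads[seg].append(
            _PointLoad(frames.segment_coms[seg].copy(),
                       np.array([0.0, 0.0, -masses[seg] * g]), np.zeros(3))
        )
    # ground reaction on the pes
    seg_loads["pes"].append(
        _PointLoad(frames.cop.copy(),
                   np.array([0.0, 0.0, load_case.grf_magnitude]), np.zeros(3))
    )
    # MTP reserve actuator: pure couple between tarsometatarsus and pes
    axis = -(frames.rotations["tarsometatarsus"] @ np.array([0.0, 1.0, 0.0]))
    reserve_couple = solution.reserve_moment * axis
    seg_loads["pes"].append(
        _PointLoad(frames.joint_centres["mtp"].copy(), np.zeros(3), reserve_couple)
    )
    seg_loads["tarsometatarsus"].append(
        _PointLoad(frames.joint_centres["mtp"].copy(), np.zeros(3), -reserve_couple)
    )

    # close equilibrium distal -> proximal
    transmission: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    order = [("pes", "mtp"), ("tarsometatarsus", "ankle"),
             ("tibiotarsus", "knee"), ("femur", "hip")]
    for seg, prox_joint in order:
        pj = frames.joint_centres[prox_joint]
        f_sum = np.zeros(3)
        m_sum = np.zeros(3)
        for pl in seg_loads[seg]:
            f_sum += pl.force
            m_sum += np.cross(pl.position - pj, pl.force) + pl.moment
        f_trans = -f_sum
        m_trans = -m_sum
        transmission[prox_joint] = (f_trans, m_trans)
        # reaction applied to the proximal segment at this joint
        prox_seg = SEGMENTS[SEGMENTS.index(seg) - 1]
        seg_loads[prox_seg].append(_PointLoad(pj.copy(), -f_trans, -m_trans))
    return frames, seg_loads, transmission


def joint_forces(
    model: ModelSpec,
    posture: Posture,
    solution: ActivationSolution,
    load_case: Optional[LoadCase] = None,
) -> Dict[str, np.ndarray]:
    """Global joint contact force transmitted across each joint (onto the
    distal segment)."""
    _, _, trans = _chain_loads(model, posture, solution, load_case)
    return {j: f for j, (f, _) in trans.items()}


def _bone_local_loads(model, frames, seg_loads, bone):
    """Loads on one bone in its local frame: (t, position, force, moment).

    ``t`` is the axial coordinate of the application point, metres from the
    proximal joint, increasing distally.
    """
    r = frames.rotations[bone]
    origin = frames.segment_origin(bone)
    out = []
    for pl in seg_loads[bone]:
        p_loc = r.T @ (pl.position - origin)
        f_loc = r.T @ pl.force
        m_loc = r.T @ pl.moment
        out.append((-p_loc[2], p_loc, f_loc, m_loc))
    return out


def _section_resultants(local_loads, stations: np.ndarray):
    """Vectorized distal-resultant force/moment at each station (local)."""
    n = len(stations)
    f_out = np.zeros((n, 3))
    m_out = np.zeros((n, 3))
    cut_pts = np.zeros((n, 3))
    cut_pts[:, 2] = -stations
    for t, p_loc, f_loc, m_loc in local_loads:
        mask = (t > stations)[:, None]
        lever = p_loc[None, :] - cut_pts
        m_contrib = np.cross(lever, f_loc[None, :]) + m_loc[None, :]
        f_out += mask * f_loc[None, :]
        m_out += mask * m_contrib
    return f_out, m_out


def internal_loads(
    model: ModelSpec,
    posture: Posture,
    solution: ActivationSolution,
    bone: str,
    load_case: Optional[LoadCase] = None,
    n_stations: int = 21,
) -> List[BoneLoadState]:
    """Internal load states at ``n_stations`` evenly spaced cuts along a bone."""
    if bone not in BONES:
        raise ValueError(f"unknown bone {bone!r}; expected one of {BONES}")
    if solution is None:
        raise ValueError("an ActivationSolution is required")
    frames, seg_loads, _ = _chain_loads(model, posture, solution, load_case)
    local_loads = _bone_local_loads(model, frames, seg_loads, bone)
    length = model.segment_lengths[bone]
    stations = np.linspace(0.0, length, n_stations)
    # nudge the end cuts inside so end-point loads fall on the correct side
    eps = 1e-9 * length
    stations_eval = np.clip(stations, eps, length - eps)
    f_out, m_out = _section_resultants(local_loads, stations_eval)
    return [
        BoneLoadState(station=float(s), force_local=f_out[i], moment_local=m_out[i])
        for i, s in enumerate(stations)
    ]


def midshaft_state(
    model: ModelSpec,
    posture: Posture,
    solution: ActivationSolution,
    bone: str = "femur",
    load_case: Optional[LoadCase] = None,
) -> StressState:
    """Stress state at the bone mid-shaft (50% of interarticular length)."""
    frames, seg_loads, _ = _chain_loads(model, posture, solution, load_case)
    local_loads = _bone_local_loads(model, frames, seg_loads, bone)
    length = model.segment_lengths[bone]
    f, m = _section_resultants(local_loads, np.array([0.5 * length]))
    load = BoneLoadState(station=0.5 * length, force_local=f[0], moment_local=m[0])
    return section_stresses(load, model.template.cross_sections[bone])


# ---------------------------------------------------------------------------
# Cylinder fit for the local long axis
# ---------------------------------------------------------------------------

def fit_local_long_axis(points: np.ndarray):
    """Least-squares cylinder fit to a mid-shaft point cloud.

    Returns ``(axis, centre, radius)``: the unit axis direction, a point on
    the axis, and the fitted radius.  The mid-shaft section plane is the
    plane through ``centre`` with normal ``axis``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
        raise ValueError("need >= 6 three-dimensional points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    axis0 = vt[0]

    def _axis_from(params):
        theta, phi = params[0], params[1]
        return np.array([
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ])

    theta0 = math.acos(np.clip(axis0[2], -1.0, 1.0))
    phi0 = math.atan2(axis0[1], axis0[0])

    def residuals(params):
        axis = _axis_from(params)
        # offset of the axis line from the centroid, in the plane normal to it
        basis = _plane_basis(axis)
        offset = params[2] * basis[0] + params[3] * basis[1]
        rel = centred - offset
        radial = rel - np.outer(rel @ axis, axis)
        d = np.linalg.norm(radial, axis=1)
        return d - d.mean()

    sol = optimize.least_squares(
        residuals, x0=[theta0, phi0, 0.0, 0.0], method="lm", xtol=1e-15, ftol=1e-15
    )
    axis = _axis_from(sol.x)
    basis = _plane_basis(axis)
    centre = centroid + sol.x[2] * basis[0] + sol.x[3] * basis[1]
    rel = pts - centre
    radial = rel - np.outer(rel @ axis, axis)
    radius = float(np.linalg.norm(radial, axis=1).mean())
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    return axis, centre, radius


def _plane_basis(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    b1 = np.cross(axis, helper)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    return b1, b2


# ---------------------------------------------------------------------------
# Stress trajectory field
# ---------------------------------------------------------------------------

def _capsule_radius(model: ModelSpec, bone: str) -> float:
    """Epiphysis (hemisphere) radius bounding the shaft region of a bone."""
    radii = getattr(model.template, "epiphysis_radii", None)
    if radii and bone in radii:
        return float(radii[bone])
    return 1.8 * model.template.cross_sections[bone].c_outer


def stress_trajectory_field(
    model: ModelSpec,
    posture: Posture,
    solution: ActivationSolution,
    lattice_bones: Sequence[str],
    lattice_points: np.ndarray,
    load_case: Optional[LoadCase] = None,
) -> VectorField:
    """Principal stress axes (s1 tensile, s3 compressive) on a lattice.

    ``lattice_points`` are bone-local coordinates, one row per point, with
    ``lattice_bones`` naming each point's bone.  Shaft points get the
    eigen-axes of the beam stress tensor (axial + bending normal stress,
    torsional shear); points inside an epiphyseal hemisphere get the
    joint-resultant surrogate.  Points outside any bone volume are skipped
    (their count is recorded in ``field.meta['n_skipped']``).
    """
    frames, seg_loads, trans = _chain_loads(model, posture, solution, load_case)
    bones_arr = np.asarray(lattice_bones, dtype=object)
    pts = np.asarray(lattice_points, dtype=float)

    out_bones: List[str] = []
    out_pts: List[np.ndarray] = []
    s1_axes: List[np.ndarray] = []
    s3_axes: List[np.ndarray] = []
    n_skipped = 0

    for bone in sorted(set(bones_arr.tolist())):
        if bone not in BONES:
            n_skipped += int(np.sum(bones_arr == bone))
            continue
        sel = bones_arr == bone
        p = pts[sel]
        length = model.segment_lengths[bone]
        r_cap = _capsule_radius(model, bone)
        section = model.template.cross_sections[bone]
        local_loads = _bone_local_loads(model, frames, seg_loads, bone)
        t = -p[:, 2]

        inside = (t > -r_cap - 1e-12) & (t < length + r_cap + 1e-12)
        n_skipped += int(np.sum(~inside))
        p = p[inside]
        t = t[inside]
        if len(p) == 0:
            continue

        shaft = (t >= r_cap) & (t <= length - r_cap)
        prox_epi = t < r_cap
        # shaft points: batch beam stress tensors
        if np.any(shaft):
            ps = p[shaft]
            ts = t[shaft]
            f_res, m_res = _section_resultants(local_loads, ts)
            sig, tau_x, tau_y = beam_stress_components(
                section,
                axial_force=-f_res[:, 2],
                m_ap=m_res[:, 0],
                m_ml=m_res[:, 1],
                torque=-m_res[:, 2],
                x=ps[:, 0],
                y=ps[:, 1],
            )
            a1, a3 = principal_axes_from_components(sig, tau_x, tau_y)
            for i in range(len(ps)):
                out_bones.append(bone)
                out_pts.append(ps[i])
                s1_axes.append(a1[i])
                s3_axes.append(a3[i])
        # epiphyseal points: joint-resultant surrogate
        for which, mask in (("prox", prox_epi), ("dist", ~shaft & ~prox_epi)):
            if not np.any(mask):
                continue
            if which == "prox":
                joint = _PROXIMAL_JOINT[bone]
                f_glob = trans[joint][0] if joint in trans else None
            else:
                joint = _DISTAL_JOINT[bone]
                # force the distal segment exerts on this bone = -transmitted
                f_glob = -trans[joint][0] if joint in trans else None
            if f_glob is None or np.linalg.norm(f_glob) < 1e-12:
                # no transmitted force (e.g. toe end): fall back to long axis
                a3 = np.array([0.0, 0.0, 1.0])
            else:
                a3 = frames.rotations[bone].T @ f_glob
                a3 = a3 / np.linalg.norm(a3)
            z = np.array([0.0, 0.0, 1.0])
            a1 = z - (z @ a3) * a3
            nrm = np.linalg.norm(a1)
            if nrm < 1e-9:
                a1 = np.array([1.0, 0.0, 0.0])
            else:
                a1 = a1 / nrm
            for q in p[mask]:
                out_bones.append(bone)
                out_pts.append(q)
                s1_axes.append(a1)
                s3_axes.append(a3)

    field = VectorField(
        bone=np.array(out_bones, dtype=object),
        points=np.array(out_pts) if out_pts else np.zeros((0, 3)),
        axes={
            "s1": _unit_rows(np.array(s1_axes)) if s1_axes else np.zeros((0, 3)),
            "s3": _unit_rows(np.array(s3_axes)) if s3_axes else np.zeros((0, 3)),
        },
    )
    field.meta["n_skipped"] = n_skipped
    return field


def _unit_rows(a: np.ndarray) -> np.ndarray:
    return a / np.linalg.norm(a, axis=1, keepdims=True)
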