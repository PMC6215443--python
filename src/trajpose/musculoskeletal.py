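"""Quasi-static single-limb musculoskeletal mechanics.

Coordinate conventions
----------------------
Global frame: ``x`` anterior, ``y`` mediolateral (left positive), ``z``
vertical (up).  The model is a right hindlimb hanging from a pelvis whose
orientation is fixed in all simulations; the hip joint centre is the origin
of the hip-fixed frame.  Ground placement translates the chain vertically so
the lowest foot contact point touches ``z = 0``.

Joint angles (degrees at every interface, radians internally):

* ``hip_extension`` — femur long-axis angle relative to the horizontal;
  90 means a vertical (columnar) femur, 0 a horizontal, anteriorly
  protracted femur.
* ``hip_abduction`` — positive moves the right femur away from the midline.
* ``hip_lar`` — long-axis rotation of the femur; positive is external
  rotation of the right femur.
* ``knee_flexion`` — angle of the tibiotarsus relative to the femur
  (0 = fully extended); positive flexion swings the shank posteriorly.
* ``ankle_flexion`` — angle of the tarsometatarsus relative to the
  tibiotarsus (0 = fully extended); positive swings the metatarsus
  anteriorly.
* ``mtp_angle`` — pes angle relative to the neutral (foot-flat) posture;
  positive is dorsiflexion (toes up).

Each segment's local frame has its origin at the proximal joint centre and
its ``-z`` axis running distally along the segment, so the distal joint sits
at local ``(0, 0, -L)``.  Muscle path points are stored in these local
frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "Posture",
    "MuscleSpec",
    "ModelSpec",
    "LoadCase",
    "ActivationSolution",
    "LimbFrames",
    "InfeasiblePostureError",
    "InfeasibleActivationError",
    "SEGMENTS",
    "ACTUATED_DOFS",
    "DOF_LIST",
    "forward_kinematics",
    "scale_com_isometric",
    "max_muscle_force",
    "scale_reserve_actuator",
    "muscle_path_points",
    "muscle_length",
    "moment_arm",
    "moment_arm_matrix",
    "inverse_static_moments",
    "static_optimization",
]

#: Segment names, proximal to distal.  "pelvis" is the fixed root.
SEGMENTS: Tuple[str, ...] = ("pelvis", "femur", "tibiotarsus", "tarsometatarsus", "pes")

#: The six actuated generalized coordinates.
ACTUATED_DOFS: Tuple[str, ...] = (
    "hip_extension",
    "hip_abduction",
    "hip_lar",
    "knee_flexion",
    "ankle_flexion",
    "mtp_angle",
)

#: Twelve bookkeeping degrees of freedom: six fixed pelvis coordinates plus
#: the six actuated joint coordinates.
DOF_LIST: Tuple[Tuple[str, bool], ...] = tuple(
    [(f"pelvis_{c}", False) for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [(d, True) for d in ACTUATED_DOFS]
)

_FD_STEP_RAD = 1e-5  # central-difference step for tendon excursion / virtual work


class InfeasiblePostureError(ValueError):
    """Raised when a posture places a joint below ground with the foot flat."""


class InfeasibleActivationError(RuntimeError):
    """Raised when no admissible activation set balances the required moments."""

    def __init__(self, message: str, dof: Optional[str] = None):
        super().__init__(message)
        self.dof = dof


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "hip_extension": (0.0, 90.0),
    "hip_abduction": (-45.0, 135.0),
    "hip_lar": (-45.0, 135.0),
    "knee_flexion": (-45.0, 135.0),
    "ankle_flexion": (-45.0, 135.0),
    "mtp_angle": (-45.0, 135.0),
}


@dataclass(frozen=True)
class Posture:
    """One joint-angle assignment, degrees, under the conventions above."""

    hip_extension: float = 70.0
    hip_abduction: float = 0.0
    hip_lar: float = 0.0
    knee_flexion: float = 50.0
    ankle_flexion: float = 40.0
    mtp_angle: float = 0.0

    def angles(self) -> Dict[str, float]:
        return {d: getattr(self, d) for d in ACTUATED_DOFS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, d) for d in ACTUATED_DOFS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "Posture":
        return cls(**dict(zip(ACTUATED_DOFS, map(float, values))))

    def replace(self, **kwargs: float) -> "Posture":
        return replace(self, **kwargs)

    def within_bounds(
        self, bounds: Optional[Dict[str, Tuple[float, float]]] = None
    ) -> bool:
        b = bounds or _DEFAULT_BOUNDS
        return all(
            b[d][0] - 1e-9 <= getattr(self, d) <= b[d][1] + 1e-9 for d in ACTUATED_DOFS
        )


@dataclass(frozen=True)
class MuscleSpec:
    """One musculotendon actuator.

    ``path`` is an ordered list of ``(segment_name, xyz)`` pairs, the points
    given in the segment's local frame (metres): origin first, then any via
    points, then the insertion.  ``group`` tags the functional role used by
    the normalized-moment report.
    """

    name: str
    path: Tuple[Tuple[str, Tuple[float, float, float]], ...]
    active: bool = True
    group: str = "other"

    def __post_init__(self):
        if len(self.path) < 2:
            raise ValueError(f"muscle {self.name!r}: path needs >= 2 points")
        for seg, _ in self.path:
            if seg not in SEGMENTS:
                raise ValueError(f"muscle {self.name!r}: unknown segment {seg!r}")


@dataclass
class LoadCase:
    """Quasi-static single-limb stance load.

    A vertical ground reaction force of ``grf_magnitude`` newtons acts at a
    centre of pressure fixed to the pes, ``cop_fraction`` of the pes length
    distal of the metatarsophalangeal joint.
    """

    grf_magnitude: float
    cop_fraction: float = 0.4

    def __post_init__(self):
        if self.grf_magnitude < 0:
            raise ValueError("grf_magnitude must be >= 0")
        if not 0.0 <= self.cop_fraction <= 1.0:
            raise ValueError("cop_fraction must lie within the pes (0..1)")


@dataclass
class ModelSpec:
    """Complete limb model: template geometry/masses plus model settings."""

    template: object  # SpeciesTemplate (duck-typed to avoid a module cycle)
    g: float = 9.81
    mtp_reserve_max: float = 1000.0
    knee_axis_obliquity_deg: float = 0.0
    com_fraction: float = 0.5  # segment COM position along the long axis
    #: femoral-head offset relative to the acetabulum (pelvis frame);
    #: +y moves the hip — and the whole limb distal to it — medially
    hip_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    posture_bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    @property
    def muscles(self) -> List[MuscleSpec]:
        return list(self.template.muscle_roster)

    @property
    def total_body_mass(self) -> float:
        return float(self.template.total_body_mass)

    @property
    def segment_lengths(self) -> Dict[str, float]:
        return dict(self.template.segment_lengths)

    @property
    def segment_masses(self) -> Dict[str, float]:
        return dict(self.template.segment_masses)

    @property
    def dof_list(self) -> Tuple[Tuple[str, bool], ...]:
        return DOF_LIST

    def fmax(self) -> float:
        return max_muscle_force(self)

    def default_load_case(self) -> LoadCase:
        return LoadCase(grf_magnitude=self.total_body_mass * self.g)

    @classmethod
    def from_template(cls, template, **kwargs) -> "ModelSpec":
        reserve = kwargs.pop("mtp_reserve_max", None)
        if reserve is None:
            # reserve scaled in proportion to total body mass from the
            # 1,000 N*m / 1.56 kg base point
            reserve = scale_reserve_actuator(
                1000.0, 1.56, float(template.total_body_mass)
            )
        obliquity = kwargs.pop(
            "knee_axis_obliquity_deg",
            getattr(template, "knee_axis_obliquity_deg", 0.0),
        )
        return cls(
            template=template,
            mtp_reserve_max=reserve,
            knee_axis_obliquity_deg=obliquity,
            **kwargs,
        )


@dataclass
class ActivationSolution:
    """Result of the static optimization at one posture."""

    posture: Posture
    activations: Dict[str, float]
    reserve_moment: float
    residuals: Dict[str, float]
    required_moments: Dict[str, float]
    objective: float

    def muscle_force(self, model: ModelSpec, name: str) -> float:
        return self.activations.get(name, 0.0) * max_muscle_force(model)


@dataclass
class LimbFrames:
    """Forward-kinematics output: frames, joint centres, COMs, hip height."""

    rotations: Dict[str, np.ndarray]
    joint_centres: Dict[str, np.ndarray]  # hip, knee, ankle, mtp, toe
    segment_coms: Dict[str, np.ndarray]
    cop: np.ndarray
    hip_height: float
    limb_com: np.ndarray
    body_com: np.ndarray
    ground_shift: float
    feasible: bool
    pelvis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def segment_origin(self, segment: str) -> np.ndarray:
        if segment == "pelvis":
            return self.pelvis_origin
        prox = {"femur": "hip", "tibiotarsus": "knee",
                "tarsometatarsus": "ankle", "pes": "mtp"}[segment]
        return self.joint_centres[prox]


# ---------------------------------------------------------------------------
# Elementary scaling operations
# ---------------------------------------------------------------------------

def scale_com_isometric(ref_offset: float, ref_femur: float, target_femur: float) -> float:
    """Isometrically scale a COM offset by the ratio of femur lengths."""
    if ref_offset <= 0 or ref_femur <= 0 or target_femur <= 0:
        raise ValueError("lengths must be strictly positive")
    return ref_offset * target_femur / ref_femur


def max_muscle_force(model: ModelSpec) -> float:
    """Maximum force capacity shared by every active muscle: two body weights."""
    m = model.total_body_mass
    if m <= 0:
        raise ValueError("total body mass must be positive")
    return 2.0 * m * model.g


def scale_reserve_actuator(base_moment: float, base_mass: float, target_mass: float) -> float:
    """Scale a reserve-actuator maximum in proportion to total body mass."""
    if base_mass <= 0 or target_mass <= 0:
        raise ValueError("masses must be strictly positive")
    return base_moment * target_mass / base_mass


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def segment_rotations(posture: Posture, knee_axis_obliquity_deg: float = 0.0) -> Dict[str, np.ndarray]:
    """Rotation matrix (local -> global) for every segment at ``posture``."""
    ext = math.radians(posture.hip_extension)
    abd = math.radians(posture.hip_abduction)
    lar = math.radians(posture.hip_lar)
    knee = math.radians(posture.knee_flexion)
    ankle = math.radians(posture.ankle_flexion)
    mtp = math.radians(posture.mtp_angle)
    skew = math.radians(knee_axis_obliquity_deg)

    r_f = _rot_y(ext - math.pi / 2) @ _rot_x(-abd) @ _rot_z(-lar)
    # knee flexes about a (possibly skewed) mediolateral axis of the femur
    r_knee = _rot_z(-skew) @ _rot_y(knee) @ _rot_z(skew)
    r_t = r_f @ r_knee
    r_tm = r_t @ _rot_y(-ankle)
    r_p = r_tm @ _rot_y(-(math.pi / 2 + mtp))
    return {
        "pelvis": np.eye(3),
        "femur": r_f,
        "tibiotarsus": r_t,
        "tarsometatarsus": r_tm,
        "pes": r_p,
    }


def forward_kinematics(
    model: ModelSpec,
    posture: Posture,
    load_case: Optional[LoadCase] = None,
    ground: bool = True,
    check_bounds: bool = True,
) -> LimbFrames:
    """Place all segments, joint centres, COMs and the COP for ``posture``.

    With ``ground=True`` the chain is translated vertically so the lowest
    foot contact point (MTP joint or toe tip) rests on ``z = 0``; the hip
    height ``h`` is measured in that frame.  With ``ground=False`` the hip
    stays at the origin (used by the statics, where only relative geometry
    matters).
    """
    if check_bounds and not posture.within_bounds(model.posture_bounds):
        raise InfeasiblePostureError(f"posture out of bounds: {posture}")
    lengths = model.segment_lengths
    rots = segment_rotations(posture, model.knee_axis_obliquity_deg)
    down = np.array([0.0, 0.0, -1.0])

    pelvis_origin = np.zeros(3)
    hip = np.asarray(model.hip_offset, dtype=float).copy()
    knee = hip + rots["femur"] @ (down * lengths["femur"])
    ankle = knee + rots["tibiotarsus"] @ (down * lengths["tibiotarsus"])
    mtp = ankle + rots["tarsometatarsus"] @ (down * lengths["tarsometatarsus"])
    toe = mtp + rots["pes"] @ (down * lengths["pes"])
    joints = {"hip": hip, "knee": knee, "ankle": ankle, "mtp": mtp, "toe": toe}

    shift = 0.0
    if ground:
        shift = -min(mtp[2], toe[2])
        for p in joints.values():
            p[2] += shift
        pelvis_origin = pelvis_origin + np.array([0.0, 0.0, shift])

    cop_frac = load_case.cop_fraction if load_case is not None else 0.4
    cop = joints["mtp"] + cop_frac * (joints["toe"] - joints["mtp"])

    frac = model.com_fraction
    coms = {
        "femur": joints["hip"] + rots["femur"] @ (down * frac * lengths["femur"]),
        "tibiotarsus": joints["knee"]
        + rots["tibiotarsus"] @ (down * frac * lengths["tibiotarsus"]),
        "tarsometatarsus": joints["ankle"]
        + rots["tarsometatarsus"] @ (down * frac * lengths["tarsometatarsus"]),
        "pes": joints["mtp"] + rots["pes"] @ (down * frac * lengths["pes"]),
    }
    coms["pelvis"] = pelvis_origin + np.array(
        [float(model.template.pelvis_com_offset_anterior), 0.0, 0.0]
    )

    masses = model.segment_masses
    limb_mass = sum(masses[s] for s in SEGMENTS[1:])
    limb_com = (
        sum(masses[s] * coms[s] for s in SEGMENTS[1:]) / limb_mass
        if limb_mass > 0
        else joints["hip"].copy()
    )
    pelvis_mass = float(model.template.pelvis_segment_mass)
    total = pelvis_mass + limb_mass
    body_com = (pelvis_mass * coms["pelvis"] + limb_mass * limb_com) / total

    feasible = True
    if ground:
        feasible = all(joints[j][2] >= -1e-9 for j in ("hip", "knee", "ankle"))

    return LimbFrames(
        rotations=rots,
        joint_centres=joints,
        segment_coms=coms,
        cop=cop,
        hip_height=float(joints["hip"][2]),
        limb_com=limb_com,
        body_com=body_com,
        ground_shift=shift,
        feasible=feasible,
        pelvis_origin=pelvis_origin,
    )


def hip_height(model: ModelSpec, posture: Posture) -> float:
    """Hip height above ground with the foot placed flat (metres)."""
    frames = forward_kinematics(model, posture, ground=True)
    if not frames.feasible:
        raise InfeasiblePostureError(f"posture places a joint below ground: {posture}")
    return frames.hip_height


# ---------------------------------------------------------------------------
# Muscle geometry
# ---------------------------------------------------------------------------

def muscle_path_points(model: ModelSpec, muscle: MuscleSpec, frames: LimbFrames) -> np.ndarray:
    """Global coordinates of a muscle's path points at a given configuration."""
    pts = np.empty((len(muscle.path), 3))
    for i, (seg, local) in enumerate(muscle.path):
        pts[i] = frames.segment_origin(seg) + frames.rotations[seg] @ np.asarray(
            local, dtype=float
        )
    return pts


def muscle_length(model: ModelSpec, muscle: MuscleSpec, posture: Posture) -> float:
    frames = forward_kinematics(model, posture, ground=False, check_bounds=False)
    pts = muscle_path_points(model, muscle, frames)
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if length <= 0.0:
        raise ValueError(f"muscle {muscle.name!r} has a degenerate zero-length path")
    return length


def _perturbed(posture: Posture, dof: str, delta_rad: float) -> Posture:
    return posture.replace(**{dof: getattr(posture, dof) + math.degrees(delta_rad)})


def moment_arm(model: ModelSpec, muscle: MuscleSpec, dof: str, posture: Posture) -> float:
    """Signed tendon-excursion moment arm ``r = -dL/dtheta`` (metres).

    Positive ``r`` means the muscle produces a positive moment about the
    DOF's positive rotation sense.  Central finite difference on the path
    length, with the joint angle in radians.
    """
    if dof not in ACTUATED_DOFS:
        raise ValueError(f"unknown or unactuated DOF {dof!r}")
    h = _FD_STEP_RAD
    lp = muscle_length(model, muscle, _perturbed(posture, dof, +h))
    lm = muscle_length(model, muscle, _perturbed(posture, dof, -h))
    return -(lp - lm) / (2.0 * h)


def _all_muscle_lengths(model: ModelSpec, posture: Posture) -> np.ndarray:
    """Path length of every muscle at one posture (single FK evaluation)."""
    frames = forward_kinematics(model, posture, ground=False, check_bounds=False)
    out = np.empty(len(model.muscles))
    for i, mus in enumerate(model.muscles):
        pts = muscle_path_points(model, mus, frames)
        out[i] = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return out


def moment_arm_matrix(model: ModelSpec, posture: Posture) -> Tuple[np.ndarray, List[str]]:
    """Moment arms for every muscle (rows) and actuated DOF (columns).

    Same central-difference tendon-excursion definition as
    :func:`moment_arm`, batched over muscles to share kinematics.
    """
    muscles = model.muscles
    h = _FD_STEP_RAD
    mat = np.zeros((len(muscles), len(ACTUATED_DOFS)))
    for j, dof in enumerate(ACTUATED_DOFS):
        lp = _all_muscle_lengths(model, _perturbed(posture, dof, +h))
        lm = _all_muscle_lengths(model, _perturbed(posture, dof, -h))
        mat[:, j] = -(lp - lm) / (2.0 * h)
    return mat, [m.name for m in muscles]


# ---------------------------------------------------------------------------
# Inverse statics
# ---------------------------------------------------------------------------

def _external_points(model: ModelSpec, posture: Posture, load_case: LoadCase):
    """Segment COMs and COP in the hip-fixed frame (statics geometry)."""
    frames = forward_kinematics(model, posture, load_case=load_case,
                                ground=False, check_bounds=False)
    pts = [frames.segment_coms[s] for s in SEGMENTS[1:]] + [frames.cop]
    return np.array(pts)


def inverse_static_moments(
    model: ModelSpec, posture: Posture, load_case: Optional[LoadCase] = None
) -> Dict[str, float]:
    """Net moment (N*m) muscles + reserve must supply at each actuated DOF.

    Computed by the principle of virtual work: the generalized force of the
    external loads (segment weights and the vertical GRF at the COP) is
    differenced centrally with respect to each joint coordinate, and the
    required actuator moment is its negative.  Quasi-static; no inertial
    terms; the pelvis is fixed.
    """
    ground_frames = forward_kinematics(model, posture, load_case=load_case, ground=True)
    if not ground_frames.feasible:
        raise InfeasiblePostureError(f"posture places a joint below ground: {posture}")
    if load_case is None:
        load_case = model.default_load_case()
    masses = model.segment_masses
    g = model.g
    forces = np.array(
        [[0.0, 0.0, -masses[s] * g] for s in SEGMENTS[1:]]
        + [[0.0, 0.0, load_case.grf_magnitude]]
    )
    h = _FD_STEP_RAD
    moments: Dict[str, float] = {}
    for dof in ACTUATED_DOFS:
        pp = _external_points(model, _perturbed(posture, dof, +h), load_case)
        pm = _external_points(model, _perturbed(posture, dof, -h), load_case)
        dp = (pp - pm) / (2.0 * h)
        q_ext = float(np.sum(forces * dp))
        moments[dof] = -q_ext
    return moments


# ---------------------------------------------------------------------------
# Static optimization
# ---------------------------------------------------------------------------

def static_optimization(
    model: ModelSpec,
    posture: Posture,
    required_moments: Optional[Dict[str, float]] = None,
    load_case: Optional[LoadCase] = None,
    moment_arms: Optional[np.ndarray] = None,
) -> ActivationSolution:
    """Solve muscle activations balancing the required joint moments.

    Minimizes the sum of squared activations subject to moment equilibrium
    at every actuated DOF, activation bounds [0, 1] for active muscles,
    zero force for inactive muscles, and the bounded reserve actuator at
    the metatarsophalangeal joint.
    """
    if required_moments is None:
        required_moments = inverse_static_moments(model, posture, load_case)
    b = np.array([required_moments[d] for d in ACTUATED_DOFS])
    if not np.all(np.isfinite(b)):
        raise ValueError("required moments must be finite")

    muscles = model.muscles
    active_idx = [i for i, m in enumerate(muscles) if m.active]
    if moment_arms is None:
        moment_arms, _ = moment_arm_matrix(model, posture)
    fmax = max_muscle_force(model)
    n_dof = len(ACTUATED_DOFS)
    mtp_j = ACTUATED_DOFS.index("mtp_angle")

    # columns: one per active muscle (moment = a * Fmax * r), plus reserve
    n_a = len(active_idx)
    a_mat = np.zeros((n_dof, n_a + 1))
    for k, i in enumerate(active_idx):
        a_mat[:, k] = fmax * moment_arms[i, :]
    a_mat[mtp_j, n_a] = 1.0

    # feasibility screen: a DOF no actuator can influence must need ~0 moment
    scale = model.total_body_mass * model.g * max(model.segment_lengths.values())
    for j, dof in enumerate(ACTUATED_DOFS):
        if np.max(np.abs(a_mat[j, :])) < 1e-12 * scale and abs(b[j]) > 1e-9 * scale:
            raise InfeasibleActivationError(
                f"no actuator spans DOF {dof!r} but it requires "
                f"{b[j]:.3g} N*m", dof=dof,
            )

    # normalize the reserve column so every variable spans an O(1) range
    reserve_scale = max(model.mtp_reserve_max, 1e-12)
    a_var = a_mat.copy()
    a_var[:, n_a] *= reserve_scale
    lo = np.zeros(n_a + 1)
    hi = np.ones(n_a + 1)
    lo[n_a] = -1.0

    a_scaled = a_var / scale
    b_scaled = b / scale

    def objective(x):
        return float(np.dot(x[:n_a], x[:n_a]))

    def objective_grad(x):
        g_ = np.zeros_like(x)
        g_[:n_a] = 2.0 * x[:n_a]
        return g_

    def _residual(x):
        return a_var @ x - b

    def _penalty_start() -> np.ndarray:
        # bounded least squares on a stacked penalty system: heavy weight on
        # the equilibrium rows, unit weight on the activation-minimizing rows
        w = 1e6
        stack = np.vstack([w * a_scaled, np.eye(n_a, n_a + 1)])
        target = np.concatenate([w * b_scaled, np.zeros(n_a)])
        sol = optimize.lsq_linear(stack, target, bounds=(lo, hi), tol=1e-14)
        return np.clip(sol.x, lo, hi)

    def _slsqp(x0: np.ndarray):
        return optimize.minimize(
            objective,
            x0,
            jac=objective_grad,
            method="SLSQP",
            bounds=list(zip(lo, hi)),
            constraints=[
                {
                    "type": "eq",
                    "fun": lambda x: a_scaled @ x - b_scaled,
                    "jac": lambda x: a_scaled,
                }
            ],
            options={"maxiter": 500, "ftol": 1e-12},
        )

    tol = 1e-6 * scale
    x_lsq, *_ = np.linalg.lstsq(a_scaled, b_scaled, rcond=None)
    res = _slsqp(np.clip(x_lsq, lo, hi))
    best_x = res.x
    message = res.message
    if not res.success or np.max(np.abs(_residual(best_x))) > tol:
        # SLSQP can stall from a poor start on tightly constrained problems;
        # restart it from a feasibility-weighted penalty solution
        x_pen = _penalty_start()
        res2 = _slsqp(x_pen)
        candidates = [best_x, x_pen, res2.x]
        feas = [x for x in candidates if np.max(np.abs(_residual(x))) <= tol]
        if feas:
            best_x = min(feas, key=objective)
        else:
            best_x = min(candidates, key=lambda x: np.max(np.abs(_residual(x))))
        message = res2.message

    residual_vec = _residual(best_x)
    if np.max(np.abs(residual_vec)) > tol:
        worst = ACTUATED_DOFS[int(np.argmax(np.abs(residual_vec)))]
        raise InfeasibleActivationError(
            f"static optimization failed (worst DOF {worst!r}, residual "
            f"{np.max(np.abs(residual_vec)):.3g} N*m): {message}",
            dof=worst,
        )

    activations = {m.name: 0.0 for m in muscles}
    for k, i in enumerate(active_idx):
        activations[muscles[i].name] = float(np.clip(best_x[k], 0.0, 1.0))
    reserve = float(best_x[n_a]) * reserve_scale
    res_objective = objective(best_x)
    residuals = {d: float(residual_vec[j]) for j, d in enumerate(ACTUATED_DOFS)}
    return ActivationSolution(
        posture=posture,
        activations=activations,
        reserve_moment=reserve,
        residuals=residuals,
        required_moments=dict(required_moments),
        objective=float(res_objective),
    )
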