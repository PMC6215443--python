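"""Axial directional statistics: mean axes, angular deviations, scoring.

Fabric and stress directions are *axial* quantities (sign-free unit axes).
Mean directions are therefore computed as the principal eigenvector of the
orientation tensor (the mean of outer products), which is invariant to
sign flips of any subset of the input axes.  All angular deviations are
folded into [0, 90] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VectorField",
    "SphericalROI",
    "RoiResult",
    "CorrespondenceReport",
    "mean_axis",
    "orientation_tensor",
    "angular_deviation",
    "roi_deviation",
    "percent_reduction",
    "downsample_field",
    "stereonet_equal_angle",
    "stereonet_invert",
    "correspondence_score",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class VectorField:
    """A lattice of positions with one or more unit-axis components.

    ``bone`` tags each point with the bone whose local frame the point and
    axes are expressed in; ``axes`` maps a component name (``u1``, ``s1``,
    ``s3``) to an (N, 3) array of unit axes.  ``roi`` optionally labels
    points with the region they were generated for.
    """

    bone: np.ndarray
    points: np.ndarray
    axes: Dict[str, np.ndarray]
    roi: Optional[np.ndarray] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.points)
        for name, arr in self.axes.items():
            if len(arr) != n:
                raise ValueError(f"component {name!r} has {len(arr)} rows, expected {n}")
        if self.roi is not None and len(self.roi) != n:
            raise ValueError("roi labels must match point count")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def components(self) -> List[str]:
        return list(self.axes)

    def mask(self, mask: np.ndarray) -> "VectorField":
        return VectorField(
            bone=self.bone[mask],
            points=self.points[mask],
            axes={k: v[mask] for k, v in self.axes.items()},
            roi=self.roi[mask] if self.roi is not None else None,
            meta=dict(self.meta),
        )

    def in_roi(self, roi: "SphericalROI") -> "VectorField":
        m = (self.bone == roi.bone) & (
            np.linalg.norm(self.points - np.asarray(roi.centre), axis=1) <= roi.radius
        )
        return self.mask(m)


@dataclass(frozen=True)
class SphericalROI:
    """Anatomically placed sphere in a bone's local frame.

    ``mode`` selects which stress component the fabric is compared against:
    ``compressive`` regions compare the primary fabric axis with s3,
    ``tensile`` regions with s1.
    """

    label: str
    bone: str
    centre: Tuple[float, float, float]
    radius: float
    mode: str = "compressive"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"ROI {self.label!r}: radius must be positive")
        if self.mode not in ("compressive", "tensile"):
            raise ValueError(f"ROI {self.label!r}: mode must be compressive|tensile")

    @property
    def stress_component(self) -> str:
        return "s3" if self.mode == "compressive" else "s1"


@dataclass
class RoiResult:
    label: str
    deviation: float  # degrees
    mean_stress_axis: np.ndarray
    mean_fabric_axis: np.ndarray
    n_points: int
    ok: bool = True
    message: str = ""


@dataclass
class CorrespondenceReport:
    """Per-ROI angular deviations and the scalar driving the search."""

    rois: List[RoiResult]
    overall_score: float  # degrees; NaN if any ROI failed

    @property
    def ok(self) -> bool:
        return all(r.ok for r in self.rois)

    def as_dict(self) -> Dict[str, float]:
        return {r.label: r.deviation for r in self.rois}


# ---------------------------------------------------------------------------
# Axial statistics
# ---------------------------------------------------------------------------

def orientation_tensor(axes: np.ndarray) -> np.ndarray:
    """Mean of outer products of unit axes: the (3, 3) orientation tensor."""
    a = np.asarray(axes, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or len(a) == 0:
        raise ValueError("need a non-empty (N, 3) array of axes")
    return (a.T @ a) / len(a)


_EIGEN_TIE_TOL = 1e-9


def mean_axis(axes: np.ndarray, return_diagnostics: bool = False):
    """Principal eigenvector of the orientation tensor, canonically signed.

    Handles the sign ambiguity of axial data exactly; near-ties between the
    two largest eigenvalues are broken by the lexicographically smallest
    canonical axis among the tied eigenvectors and flagged in diagnostics.
    """
    t = orientation_tensor(axes)
    vals, vecs = np.linalg.eigh(t)
    tie = bool(vals[2] - vals[1] < _EIGEN_TIE_TOL)
    if tie:
        candidates = [_canonical(vecs[:, 2]), _canonical(vecs[:, 1])]
        if vals[2] - vals[0] < _EIGEN_TIE_TOL:
            candidates.append(_canonical(vecs[:, 0]))
        axis = min(candidates, key=lambda v: tuple(np.round(v, 12)))
    else:
        axis = _canonical(vecs[:, 2])
    if return_diagnostics:
        return axis, {"eigenvalues": vals[::-1], "tie": tie}
    return axis


def _canonical(v: np.ndarray) -> np.ndarray:
    """Fix the sign so the first nonzero component is positive."""
    v = v / np.linalg.norm(v)
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def angular_deviation(a: np.ndarray, b: np.ndarray) -> float:
    """Acute angle between two axes in degrees, in [0, 90] (sign-free)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-300 or nb < 1e-300:
        raise ValueError("zero vector has no direction")
    c = abs(float(a @ b)) / (na * nb)
    return math.degrees(math.acos(min(c, 1.0)))


# ---------------------------------------------------------------------------
# ROI comparison and scoring
# ---------------------------------------------------------------------------

def roi_deviation(
    stress: VectorField,
    fabric: VectorField,
    roi: SphericalROI,
    min_points: int = 10,
) -> RoiResult:
    """Angular deviation between mean stress and mean fabric axes in a ROI."""
    comp = roi.stress_component
    s_sel = stress.in_roi(roi)
    f_sel = fabric.in_roi(roi)
    n = min(len(s_sel), len(f_sel))
    if len(f_sel) < min_points:
        raise ValueError(
            f"ROI {roi.label!r}: only {len(f_sel)} fabric points inside "
            f"(minimum {min_points})"
        )
    if len(s_sel) < min_points:
        raise ValueError(
            f"ROI {roi.label!r}: only {len(s_sel)} stress points inside "
            f"(minimum {min_points})"
        )
    if comp not in s_sel.axes:
        raise ValueError(f"ROI {roi.label!r}: stress field lacks component {comp!r}")
    ms = mean_axis(s_sel.axes[comp])
    mf = mean_axis(f_sel.axes["u1"])
    return RoiResult(
        label=roi.label,
        deviation=angular_deviation(ms, mf),
        mean_stress_axis=ms,
        mean_fabric_axis=mf,
        n_points=n,
    )


def percent_reduction(worst: float, best: float) -> int:
    """Percent reduction from worst to best deviation, nearest integer."""
    if worst <= 0:
        raise ValueError("worst deviation must be positive")
    return int(round(100.0 * (worst - best) / worst))


def correspondence_score(
    stress: VectorField,
    fabric: VectorField,
    rois: Sequence[SphericalROI],
    min_points: int = 10,
    weights: Optional[Dict[str, float]] = None,
) -> CorrespondenceReport:
    """Per-ROI deviations plus the overall (weighted-mean) score in degrees.

    Any ROI failure yields a partial report with ``ok=False`` entries and an
    undefined (NaN) overall score.
    """
    results: List[RoiResult] = []
    for roi in rois:
        try:
            results.append(roi_deviation(stress, fabric, roi, min_points=min_points))
        except ValueError as exc:
            results.append(
                RoiResult(
                    label=roi.label,
                    deviation=float("nan"),
                    mean_stress_axis=np.full(3, np.nan),
                    mean_fabric_axis=np.full(3, np.nan),
                    n_points=0,
                    ok=False,
                    message=str(exc),
                )
            )
    if all(r.ok for r in results) and results:
        if weights:
            w = np.array([weights.get(r.label, 1.0) for r in results])
        else:
            w = np.ones(len(results))
        score = float(np.average([r.deviation for r in results], weights=w))
    else:
        score = float("nan")
    return CorrespondenceReport(rois=results, overall_score=score)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_field(
    f: VectorField, grid_spacing: float, component: Optional[str] = None
) -> VectorField:
    """Resample a field onto a regular grid by local orientation averaging.

    At each grid node the axes of all points within one spacing radius are
    combined through the orientation tensor (no vector averaging, so
    antipodal axes cannot cancel); nodes with no neighbours are dropped.
    """
    if len(f) == 0:
        raise ValueError("cannot downsample an empty field")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    comps = [component] if component else f.components
    out_bone, out_pts, out_roi = [], [], []
    out_axes: Dict[str, List[np.ndarray]] = {c: [] for c in comps}
    for bone in sorted(set(f.bone.tolist())):
        sub = f.mask(f.bone == bone)
        lo = sub.points.min(axis=0)
        hi = sub.points.max(axis=0)
        if np.all(hi - lo < grid_spacing) and len(sub) > 1 and (
            np.max(hi - lo) < grid_spacing * 1e-9
        ):
            raise ValueError("grid spacing larger than field extent")
        ticks = [
            np.arange(lo[d], hi[d] + grid_spacing * 0.5, grid_spacing)
            for d in range(3)
        ]
        if any(len(t) == 0 for t in ticks):
            raise ValueError("grid spacing larger than field extent")
        gx, gy, gz = np.meshgrid(*ticks, indexing="ij")
        nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        for node in nodes:
            d = np.linalg.norm(sub.points - node, axis=1)
            near = d <= grid_spacing
            if not np.any(near):
                continue
            out_bone.append(bone)
            out_pts.append(node)
            if sub.roi is not None:
                labels = sub.roi[near]
                out_roi.append(labels[0] if len(set(labels.tolist())) == 1 else "")
            for c in comps:
                out_axes[c].append(mean_axis(sub.axes[c][near]))
    if not out_pts:
        raise ValueError("grid spacing larger than field extent")
    return VectorField(
        bone=np.array(out_bone, dtype=object),
        points=np.array(out_pts),
        axes={c: np.array(v) for c, v in out_axes.items()},
        roi=np.array(out_roi, dtype=object) if out_roi and f.roi is not None else None,
        meta=dict(f.meta),
    )


# ---------------------------------------------------------------------------
# Stereonet projection (equal-angle / Wulff)
# ---------------------------------------------------------------------------

def stereonet_equal_angle(axis: np.ndarray, hemisphere: str = "northern") -> Tuple[float, float]:
    """Project an axis onto the unit disc with the equal-angle formula.

    The axis is first folded into the requested hemisphere (northern keeps
    ``z >= 0``).  With plunge p the radius is ``tan((90 - p)/2)`` and the
    azimuth is preserved; returns Cartesian plot coordinates with north
    along +y and east along +x.  A vertical axis maps to the centre, a
    horizontal one to the primitive circle.
    """
    if hemisphere not in ("northern", "southern"):
        raise ValueError("hemisphere must be 'northern' or 'southern'")
    v = np.asarray(axis, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise ValueError("zero vector has no direction")
    v = v / n
    want_up = hemisphere == "northern"
    if (v[2] < 0 and want_up) or (v[2] > 0 and not want_up):
        v = -v
    plunge = math.degrees(math.asin(min(abs(v[2]), 1.0)))
    r = math.tan(math.radians(90.0 - plunge) / 2.0)
    trend = math.atan2(v[0], v[1])  # east = +x, north = +y
    return (r * math.sin(trend), r * math.cos(trend))


def plot_stereonet(
    roi_result: "RoiResult",
    hemisphere: str = "northern",
    ax=None,
):
    """Overplot a ROI's mean stress and fabric axes on an equal-angle net.

    Requires matplotlib (optional dependency).  Returns the axes object.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8)
    ax.add_patch(circle)
    for axis, label, marker in (
        (roi_result.mean_stress_axis, "stress", "o"),
        (roi_result.mean_fabric_axis, "fabric", "s"),
    ):
        x, y = stereonet_equal_angle(axis, hemisphere)
        ax.plot([x], [y], marker, label=label)
    ax.set_title(
        f"{roi_result.label}: {roi_result.deviation:.1f} deg "
        f"({hemisphere} hemisphere)"
    )
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def stereonet_invert(xy: Tuple[float, float], hemisphere: str = "northern") -> np.ndarray:
    """Inverse of :func:`stereonet_equal_angle` (returns the folded axis)."""
    x, y = xy
    r = math.hypot(x, y)
    plunge = 90.0 - 2.0 * math.degrees(math.atan(r))
    trend = math.atan2(x, y)
    cz = math.sin(math.radians(plunge))
    ch = math.cos(math.radians(plunge))
    v = np.array([ch * math.sin(trend), ch * math.cos(trend), cz])
    if hemisphere == "southern":
        v[2] = -v[2]
    return v
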