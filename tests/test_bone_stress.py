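import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajpose.bone_stress import (
    BoneLoadState,
    CrossSection,
    beam_stress_components,
    fit_local_long_axis,
    internal_loads,
    midshaft_state,
    principal_axes_from_components,
    principal_orientation,
    section_stresses,
    shear_bending_ratio,
    stress_trajectory_field,
    _section_resultants,
)
from trajpose.musculoskeletal import (
    LoadCase,
    ModelSpec,
    Posture,
    static_optimization,
)

from conftest import toy_template


# ---------------------------------------------------------------------------
# Cross-section closed forms
# ---------------------------------------------------------------------------

def _numeric_section_properties(section, n=4000):
    """Independent polar-grid integration oracle for A, I and J."""
    # integrate over the annulus between similar ellipses
    s = section.inner_scale
    u = np.linspace(s, 1.0, n)  # radial scale
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    uu, tt = np.meshgrid(u, t, indexing="ij")
    x = section.a_ap * uu * np.cos(tt)
    y = section.a_ml * uu * np.sin(tt)
    # area element for the scaled-ellipse parametrization
    da = section.a_ap * section.a_ml * uu * (u[1] - u[0]) * (t[1] - t[0])
    return {
        "area": float(np.sum(da)),
        "i_ml": float(np.sum(x ** 2 * da)),
        "i_ap": float(np.sum(y ** 2 * da)),
        "j_polar": float(np.sum((x ** 2 + y ** 2) * da)),
    }


class TestCrossSection:
    @pytest.mark.parametrize("a_ap,a_ml,wall", [(0.03, 0.05, 0.3), (0.04, 0.04, 1.0),
                                                (0.06, 0.02, 0.5)])
    def test_closed_forms_vs_integration(self, a_ap, a_ml, wall):
        sec = CrossSection(a_ap=a_ap, a_ml=a_ml, wall_fraction=wall)
        num = _numeric_section_properties(sec)
        assert sec.area == pytest.approx(num["area"], rel=1e-3)
        assert sec.i_ml == pytest.approx(num["i_ml"], rel=1e-3)
        assert sec.i_ap == pytest.approx(num["i_ap"], rel=1e-3)
        assert sec.j_polar == pytest.approx(num["j_polar"], rel=1e-3)

    def test_invalid_sections_rejected(self):
        with pytest.raises(ValueError):
            CrossSection(a_ap=0.0, a_ml=0.1)
        with pytest.raises(ValueError):
            CrossSection(a_ap=0.1, a_ml=0.1, wall_fraction=1.5)


# ---------------------------------------------------------------------------
# Internal loads
# ---------------------------------------------------------------------------

def _column_setup():
    """(Near-)massless vertical column, GRF up the joint line."""
    template = toy_template([], limb_mass=1e-12, total_mass=100.0)
    model = ModelSpec(template=template, mtp_reserve_max=1e4)
    posture = Posture(hip_extension=90, knee_flexion=0, ankle_flexion=0)
    load = LoadCase(grf_magnitude=500.0, cop_fraction=0.0)
    solution = static_optimization(model, posture, load_case=load)
    return model, posture, load, solution


class TestInternalLoads:
    def test_axial_column(self):
        model, posture, load, solution = _column_setup()
        states = internal_loads(model, posture, solution, "tibiotarsus", load)
        for s in states:
            assert s.axial_force == pytest.approx(-500.0, abs=1e-6)
            assert s.bending_magnitude == pytest.approx(0.0, abs=1e-6)
            assert s.torque == pytest.approx(0.0, abs=1e-9)

    def test_cantilever_closed_form(self):
        # direct check of the sectioning helper: a transverse tip load P on
        # a beam of length L gives bending moment P*L at the fixed end
        p, length = 123.0, 0.8
        loads = [(length, np.array([0.0, 0.0, -length]),
                  np.array([p, 0.0, 0.0]), np.zeros(3))]
        f, m = _section_resultants(loads, np.array([0.0, length / 2]))
        assert np.hypot(m[0, 0], m[0, 1]) == pytest.approx(p * length)
        assert np.hypot(m[1, 0], m[1, 1]) == pytest.approx(p * length / 2)
        assert f[0, 0] == pytest.approx(p)

    def test_station_equilibrium_consistency(self, troodontid_model, troodontid_solution):
        """Adjacent stations differ only by the loads applied between them."""
        states = internal_loads(
            troodontid_model, troodontid_solution.posture, troodontid_solution, "femur",
            n_stations=41,
        )
        # between stations with no applied load, the force resultant is
        # constant and the moment varies linearly; 60-85% of the femur is
        # free of attachments in the default roster
        mid = [s for s in states if 0.60 <= s.station / states[-1].station <= 0.85]
        for a, b in zip(mid, mid[1:]):
            np.testing.assert_allclose(a.force_local, b.force_local, atol=1e-8)

    def test_unknown_bone_rejected(self, troodontid_model, troodontid_solution):
        with pytest.raises(ValueError):
            internal_loads(troodontid_model, troodontid_solution.posture,
                           troodontid_solution, "humerus")

    def test_toy_muscle_free_body_oracle(self):
        """Single hip-to-femur muscle checked against hand statics."""
        from trajpose.musculoskeletal import MuscleSpec, max_muscle_force
        mus = MuscleSpec(
            name="puller",
            path=(("pelvis", (-0.3, 0.0, 0.0)), ("femur", (-0.05, 0.0, -0.6))),
        )
        template = toy_template([mus], limb_mass=1e-12, total_mass=100.0)
        model = ModelSpec(template=template, mtp_reserve_max=1e5)
        posture = Posture(hip_extension=90, knee_flexion=0, ankle_flexion=0)
        load = LoadCase(grf_magnitude=0.0, cop_fraction=0.0)
        required = {d: 0.0 for d in
                    ("hip_extension", "hip_abduction", "hip_lar",
                     "knee_flexion", "ankle_flexion", "mtp_angle")}
        sol = static_optimization(model, posture, required_moments=required, load_case=load)
        sol.activations["puller"] = 0.25  # prescribe activation directly
        f = 0.25 * max_muscle_force(model)
        states = internal_loads(model, posture, sol, "femur", load, n_stations=11)
        # hand statics: insertion at (x=-0.05, z=-0.6) local; origin at
        # (-0.3, 0, 0) global = local; pull direction from insertion to origin
        ins = np.array([-0.05, 0.0, -0.6])
        ori = np.array([-0.3, 0.0, 0.0])
        pull = (ori - ins) / np.linalg.norm(ori - ins)
        force_on_femur = f * pull
        for s in states:
            if s.station < 0.6:
                continue  # proximal of the insertion: reaction force region
            # distal to the insertion: no loads below the cut
            np.testing.assert_allclose(s.force_local, 0.0, atol=1e-6)
        s0 = states[0]  # just distal of the hip: everything below the cut
        np.testing.assert_allclose(
            s0.force_local, force_on_femur, atol=1e-5
        )


# ---------------------------------------------------------------------------
# Section stresses
# ---------------------------------------------------------------------------

def _load_state(n=0.0, m_ap=0.0, m_ml=0.0, torque=0.0, station=0.5):
    return BoneLoadState(
        station=station,
        force_local=np.array([0.0, 0.0, -n]),
        moment_local=np.array([m_ap, m_ml, -torque]),
    )


SEC = CrossSection(a_ap=0.03, a_ml=0.04, wall_fraction=0.4)


class TestSectionStresses:
    def test_pure_symmetric_bending(self):
        state = section_stresses(_load_state(m_ml=50.0), SEC)
        assert state.sigma_max == pytest.approx(-state.sigma_min, rel=1e-9)
        assert state.sigma_bending == pytest.approx(state.sigma_max, rel=1e-9)
        assert state.theta_principal == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_extremes(self):
        # superpose axial and bending so sigma_max = 30, sigma_min = -50 MPa:
        # half the range is 40 MPa
        sec = CrossSection(a_ap=0.03, a_ml=0.03, wall_fraction=1.0)
        bend = 40e6 * sec.i_ml / 0.03  # m_ml producing +/-40 MPa at the rim
        axial = -10e6 * sec.area
        state = section_stresses(_load_state(n=axial, m_ml=bend), sec)
        assert state.sigma_max == pytest.approx(30e6, rel=1e-6)
        assert state.sigma_min == pytest.approx(-50e6, rel=1e-6)
        assert state.sigma_bending == pytest.approx(40e6, rel=1e-6)
        # equals (|s_max| + |s_min|)/2 when the extremes straddle zero
        assert state.sigma_bending == pytest.approx(
            (abs(state.sigma_max) + abs(state.sigma_min)) / 2, rel=1e-9
        )

    def test_axial_only_degenerate(self):
        state = section_stresses(_load_state(n=-1000.0), SEC)
        assert state.sigma_bending == pytest.approx(0.0, abs=1e-9)
        assert not state.neutral_axis_defined
        assert math.isnan(state.neutral_axis_angle)

    def test_neutral_axis_mediolateral_bending(self):
        # bending about the anterior (x) axis: neutral axis along x -> +/-90
        state = section_stresses(_load_state(m_ap=30.0), SEC)
        assert abs(state.neutral_axis_angle) == pytest.approx(90.0, abs=1e-9)
        # bending about the mediolateral axis: neutral axis along y -> 0
        state = section_stresses(_load_state(m_ml=30.0), SEC)
        assert state.neutral_axis_angle == pytest.approx(0.0, abs=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            CrossSection(a_ap=0.0, a_ml=0.01)


class TestPrincipalOrientation:
    def test_pure_bending_zero(self):
        assert principal_orientation(10e6, 0.0) == pytest.approx(0.0)
        assert principal_orientation(-10e6, 0.0) == pytest.approx(0.0)

    def test_pure_torsion_45(self):
        assert principal_orientation(0.0, 5e6) == pytest.approx(45.0)
        assert principal_orientation(0.0, -5e6) == pytest.approx(45.0)

    def test_mixed_load_mohr(self):
        assert principal_orientation(10e6, 5e6) == pytest.approx(22.5, abs=1e-12)

    def test_undefined_state_flagged(self):
        assert math.isnan(principal_orientation(0.0, 0.0))

    @given(st.floats(-1e8, 1e8), st.floats(-1e8, 1e8))
    @settings(max_examples=200, deadline=None)
    def test_matches_eigenvector_oracle(self, sigma, tau):
        """Dual route: fold of the 2x2 stress-tensor eigenvector angle."""
        if sigma == 0.0 and tau == 0.0:
            return
        theta = principal_orientation(sigma, tau)
        t = np.array([[0.0, tau], [tau, sigma]])
        _, vecs = np.linalg.eigh(t)
        v = vecs[:, 1]  # major principal direction, components (transverse, axial)
        ang = math.degrees(math.atan2(abs(v[0]), abs(v[1])))
        folded = min(ang % 90.0, 90.0 - ang % 90.0)
        assert theta == pytest.approx(folded, abs=1e-6)


class TestShearBendingRatio:
    def test_pure_bending_zero(self):
        state = section_stresses(_load_state(m_ml=50.0), SEC)
        assert shear_bending_ratio(state) == pytest.approx(0.0, abs=1e-12)

    def test_equality_case(self):
        sec = CrossSection(a_ap=0.03, a_ml=0.03, wall_fraction=1.0)
        m = 40.0
        t = m * sec.j_polar / sec.i_ml  # tau_max == sigma_bending
        state = section_stresses(_load_state(m_ml=m, torque=t), sec)
        assert shear_bending_ratio(state) == pytest.approx(1.0, rel=1e-6)

    def test_pure_torsion_sentinel(self):
        state = section_stresses(_load_state(torque=10.0), SEC)
        assert math.isinf(shear_bending_ratio(state))

    def test_toy_load_set_vs_integration_oracle(self):
        """tau_max/sigma_bending from closed forms vs dense boundary scan."""
        sec = CrossSection(a_ap=0.025, a_ml=0.04, wall_fraction=0.35)
        state = section_stresses(_load_state(n=-2000.0, m_ap=12.0, m_ml=30.0,
                                             torque=18.0), sec, n_boundary=2000)
        # oracle: evaluate the stress fields on a very dense outer boundary
        t = np.linspace(0, 2 * math.pi, 100001)
        x, y = sec.a_ap * np.cos(t), sec.a_ml * np.sin(t)
        sig = (-2000.0 / sec.area + 30.0 / sec.i_ml * x - 12.0 / sec.i_ap * y)
        tau = 18.0 * np.hypot(x, y) / sec.j_polar
        sb = 0.5 * (sig.max() - sig.min())
        ratio_oracle = tau.max() / sb
        assert shear_bending_ratio(state) == pytest.approx(ratio_oracle, rel=1e-2)


# ---------------------------------------------------------------------------
# Cylinder fit
# ---------------------------------------------------------------------------

def _cylinder_points(axis, centre, radius, n=200, length=0.4, rng=None):
    rng = rng or np.random.default_rng(0)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    b1 = np.cross(axis, helper)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    t = rng.uniform(-length / 2, length / 2, n)
    phi = rng.uniform(0, 2 * math.pi, n)
    return (centre + np.outer(t, axis)
            + radius * (np.outer(np.cos(phi), b1) + np.outer(np.sin(phi), b2)))


class TestFitLocalLongAxis:
    def test_exact_cylinder(self):
        axis = np.array([0.2, -0.1, 0.97])
        axis /= np.linalg.norm(axis)
        pts = _cylinder_points(axis, np.array([0.1, 0.2, 0.3]), 0.05)
        fit_axis, centre, radius = fit_local_long_axis(pts)
        assert abs(fit_axis @ axis) > math.cos(1e-6)
        assert radius == pytest.approx(0.05, rel=1e-9)

    def test_noisy_cylinder_within_one_degree(self):
        rng = np.random.default_rng(42)
        axis = np.array([0.1, 0.3, 0.95])
        axis /= np.linalg.norm(axis)
        radius = 0.05
        pts = _cylinder_points(axis, np.zeros(3), radius, n=500, rng=rng)
        pts = pts + rng.normal(scale=0.01 * radius, size=pts.shape)
        fit_axis, _, _ = fit_local_long_axis(pts)
        dev = math.degrees(math.acos(min(abs(fit_axis @ axis), 1.0)))
        assert dev < 1.0

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation
        axis = np.array([0.0, 0.2, 0.98])
        axis /= np.linalg.norm(axis)
        pts = _cylinder_points(axis, np.zeros(3), 0.04)
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        a1, *_ = fit_local_long_axis(pts)
        a2, *_ = fit_local_long_axis(pts @ rot.T)
        assert abs(a2 @ (rot @ a1)) >= math.cos(1e-7)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_local_long_axis(np.zeros((4, 3)))
        line = np.outer(np.linspace(0, 1, 20), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            fit_local_long_axis(line)


# ---------------------------------------------------------------------------
# Trajectory field
# ---------------------------------------------------------------------------

class TestStressTrajectoryField:
    def test_axial_compression_shaft_axes(self):
        model, posture, load, solution = _column_setup()
        length = model.segment_lengths["tibiotarsus"]
        zs = np.linspace(-0.8 * length, -0.2 * length, 9)
        pts = np.column_stack([np.full(9, 0.001), np.zeros(9), zs])
        field = stress_trajectory_field(
            model, posture, solution, ["tibiotarsus"] * 9, pts, load
        )
        # all shaft compressive axes parallel the long axis (local z)
        assert np.all(np.abs(field.axes["s3"][:, 2]) > 1 - 1e-9)

    def test_pure_torsion_helical_axes(self):
        sec = CrossSection(a_ap=0.01, a_ml=0.01, wall_fraction=1.0)
        th = np.linspace(0, 2 * math.pi, 12, endpoint=False)
        x, y = 0.01 * np.cos(th), 0.01 * np.sin(th)
        sig, tx, ty = beam_stress_components(sec, 0.0, 0.0, 0.0, 3.0, x, y)
        a1, a3 = principal_axes_from_components(sig, tx, ty)
        for v in (a1, a3):
            ang = np.degrees(np.arccos(np.abs(v[:, 2])))
            np.testing.assert_allclose(ang, 45.0, atol=1e-9)
        # shear is tangential: principal axes have no radial component
        radial = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        np.testing.assert_allclose(np.sum(a1 * radial, axis=1), 0.0, atol=1e-9)

    def test_s1_s3_orthogonal_everywhere(self, troodontid_model, troodontid_solution,
                                         zero_noise_fabric):
        field = stress_trajectory_field(
            troodontid_model, troodontid_solution.posture, troodontid_solution,
            zero_noise_fabric.bone, zero_noise_fabric.points,
        )
        dots = np.abs(np.sum(field.axes["s1"] * field.axes["s3"], axis=1))
        assert dots.max() <= 1e-9

    def test_epiphyseal_axis_parallels_joint_force(self, troodontid_model,
                                                   troodontid_solution):
        from trajpose.bone_stress import joint_forces
        forces = joint_forces(troodontid_model, troodontid_solution.posture,
                              troodontid_solution)
        re = troodontid_model.template.epiphysis_radii["femur"]
        pt = np.array([[0.0, 0.0, -0.3 * re]])  # inside the proximal hemisphere
        field = stress_trajectory_field(
            troodontid_model, troodontid_solution.posture, troodontid_solution,
            ["femur"], pt,
        )
        frames_rot = None
        from trajpose.musculoskeletal import forward_kinematics
        frames = forward_kinematics(troodontid_model, troodontid_solution.posture,
                                    ground=False)
        f_local = frames.rotations["femur"].T @ forces["hip"]
        f_local /= np.linalg.norm(f_local)
        assert abs(field.axes["s3"][0] @ f_local) == pytest.approx(1.0, abs=1e-9)

    def test_points_outside_volume_skipped(self, troodontid_model, troodontid_solution):
        length = troodontid_model.segment_lengths["femur"]
        pts = np.array([[0.0, 0.0, -2.0 * length], [0.0, 0.0, -0.5 * length]])
        field = stress_trajectory_field(
            troodontid_model, troodontid_solution.posture, troodontid_solution,
            ["femur", "femur"], pts,
        )
        assert len(field) == 1
        assert field.meta["n_skipped"] == 1

    def test_midshaft_metrics_continuous_in_posture(self, troodontid_model,
                                                    troodontid_solution):
        """0.1 degree perturbations move theta_principal by < 1 degree."""
        base = midshaft_state(troodontid_model, troodontid_solution.posture,
                              troodontid_solution)
        for dof in ("hip_extension", "knee_flexion", "hip_lar"):
            p2 = troodontid_solution.posture.replace(
                **{dof: getattr(troodontid_solution.posture, dof) + 0.1}
            )
            sol2 = static_optimization(troodontid_model, p2)
            s2 = midshaft_state(troodontid_model, p2, sol2)
            assert abs(s2.theta_principal - base.theta_principal) < 1.0, dof
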