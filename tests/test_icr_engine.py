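"""Contact resolution, per-plane CRs, the 3D common center, and the sweep."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from mpsjc.geometry2d import CircleArc, CompositeProfile, Line2
from mpsjc.icr_engine import (
    ContactError,
    classify_shift,
    declination_angle,
    icr_3d,
    plane_cr,
    plane_contacts,
    resolve_contact,
    shift_ordering,
    solve_pose,
    surface_speed,
    sweep,
    transverse_accommodation,
    x_axis_obliquity,
)
from mpsjc.joint_model import JointModel, default_model

R = 11.0


def circle_profile(radius=10.0):
    return CompositeProfile([CircleArc(np.zeros(2), radius, -180.0, 179.9)],
                            check=False)


class TestResolveContact:
    def test_collinear_centers(self):
        prof = circle_profile(10.0)
        c = resolve_contact(prof, [0.0, -13.5], 3.5)
        assert np.allclose(c.point, [0.0, -10.0], atol=1e-9)
        # shared normal passes through both centers
        assert c.normal.distance_to([0.0, -13.5]) < 1e-9
        assert c.normal.distance_to([0.0, 0.0]) < 1e-9

    def test_point_support(self):
        prof = circle_profile(10.0)
        c = resolve_contact(prof, [10.0, 0.0], 0.0)
        assert np.allclose(c.point, [10.0, 0.0], atol=1e-9)

    def test_tangency_violation_raises(self):
        prof = circle_profile(10.0)
        with pytest.raises(ContactError):
            resolve_contact(prof, [0.0, -20.0], 3.5)

    def test_groove_contact_matches_brute_force(self, model):
        """Posed groove contact equals the dense-sampling distance minimizer."""
        theta = 40.0  # mid-groove for the tibial plane
        cfg = solve_pose(model, "tibial", theta)
        prof = model.head.tibial_plane_profile.transformed(cfg.pose)
        center = model.tibial_sesamoid.center_arr
        c = resolve_contact(prof, center, model.tibial_sesamoid.radius)
        s_grid = np.linspace(0, prof.length, 20001)
        d = [float(np.hypot(*(prof.point_at(s) - center))) for s in s_grid]
        s_best = s_grid[int(np.argmin(d))]
        assert np.allclose(c.point, prof.point_at(s_best), atol=1e-3)
        assert abs(np.hypot(*(c.point - center)) - model.tibial_sesamoid.radius) < 1e-6


class TestPlaneCR:
    def test_both_contacts_on_circle_give_center(self):
        prof = circle_profile(10.0)
        a = resolve_contact(prof, [13.0, 0.0], 3.0)
        b = resolve_contact(prof, [0.0, -13.0], 3.0)
        cr = plane_cr(a.normal, b.normal)
        assert cr.status == "unique"
        assert np.allclose(cr.point, [0.0, 0.0], atol=1e-9)

    def test_parallel_normals_reported(self):
        n1 = Line2(np.array([0.0, 0.0]), np.array([0.0, 1.0]))
        n2 = Line2(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        cr = plane_cr(n1, n2)
        assert cr.status == "parallel-normals"
        assert cr.point is None

    def test_tibial_groove_contact_shifts_cr_proximal(self, model):
        """In the tibial groove the sesamoid normal tilts proximally, so the
        CR lands at smaller x than the spherical center."""
        cfg = solve_pose(model, "tibial", 27.0)  # just after groove entry
        a, b = plane_contacts(model, "tibial", cfg)
        cr = plane_cr(a.normal, b.normal)
        assert cr.point[0] < cfg.pose.translation[0] - 1e-3

    def test_fibular_groove_contact_shifts_cr_distal(self, model):
        cfg = solve_pose(model, "fibular", 52.0)  # contact mid-flat
        a, c = plane_contacts(model, "fibular", cfg)
        cr = plane_cr(a.normal, c.normal)
        assert cr.point[0] > cfg.pose.translation[0] + 1e-3


class TestIcr3d:
    def test_concurrent_radial_lines(self, rng):
        lines = []
        for _ in range(3):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            lines.append((5.0 * d, d))
        res = icr_3d(lines)
        assert np.allclose(res.point3, 0.0, atol=1e-9)
        assert res.rms_residual < 1e-9

    def test_matches_numerical_minimizer(self):
        """Closed-form solution equals brute-force minimization on random
        perturbed line triples."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lines = []
            for _ in range(3):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                o = rng.normal(size=3) * 3 + rng.normal(size=3) * 0.1
                lines.append((o, d))

            def cost(p):
                tot = 0.0
                for o, d in lines:
                    w = p - o
                    w_perp = w - (w @ d) * d
                    tot += w_perp @ w_perp
                return tot

            res = icr_3d(lines)
            num = minimize(cost, x0=np.zeros(3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14,
                                    "maxiter": 5000})
            assert np.allclose(res.point3, num.x, atol=1e-5)

    def test_icr_x_between_plane_crs_during_groove_phase(self, model, trajectory):
        """With one plane in its groove, the common center's x lies between
        the spherical center and the shifted plane CR."""
        k = int(np.argmin(trajectory.cr_xy("tibial")[:, 0]))
        tib_x = trajectory.cr_xy("tibial")[k, 0]
        fib_x = trajectory.cr_xy("fibular")[k, 0]
        icr_x = trajectory.icr3d[k].point3[0]
        lo, hi = sorted([tib_x, fib_x])
        assert lo - 1e-6 <= icr_x <= hi + 1e-6

    def test_parallel_lines_degenerate(self):
        d = np.array([1.0, 0.0, 0.0])
        lines = [(np.array([0.0, float(i), 0.0]), d) for i in range(3)]
        with pytest.raises(Exception):
            icr_3d(lines)


class TestDeclinationAngle:
    def test_stance_is_15(self, model):
        cfg = solve_pose(model, "tibial", model.sweep.theta0_deg)
        a, _ = plane_contacts(model, "tibial", cfg)
        ang = declination_angle(cfg, a.normal, cfg.long_axis_world(model.head))
        assert abs(ang - 15.0) < 1e-6

    def test_parallel_axis_gives_zero(self):
        n = Line2(np.array([0.0, 0.0]), np.array([-1.0, 0.0]))
        cfg_like = None
        assert declination_angle(cfg_like, n, np.array([-1.0, 0.0])) < 1e-12

    def test_matches_arccos_oracle(self, rng):
        for _ in range(20):
            d = rng.normal(size=2)
            d /= np.linalg.norm(d)
            u = rng.normal(size=2)
            u /= np.linalg.norm(u)
            n = Line2(np.zeros(2), d)
            expect = math.degrees(math.acos(abs(float(d @ u))))
            assert abs(declination_angle(None, n, u) - expect) < 1e-9


class TestSweep:
    def test_sphere_degenerates_to_fixed_center(self, sphere_model):
        traj = sweep(sphere_model)
        R0 = sphere_model.head.sagittal_radius
        for plane in ("tibial", "fibular"):
            assert np.max(np.abs(traj.cr_xy(plane))) < 1e-9 * R0
        assert max(r.rms_residual for r in traj.icr3d) < 1e-9 * R0
        assert max(abs(r.point3[2]) for r in traj.icr3d) < 1e-9 * R0

    def test_tibial_cr_shifts_proximal_then_returns(self, model, trajectory):
        xs = trajectory.cr_xy("tibial")[:, 0]
        assert xs.min() < -0.1          # clear proximal excursion
        assert abs(xs[-1] - xs[0]) < 0.02 * model.head.sagittal_radius

    def test_fibular_cr_shifts_distal_then_returns(self, model, trajectory):
        xs = trajectory.cr_xy("fibular")[:, 0]
        assert xs.max() > 0.1
        assert abs(xs[-1] - xs[0]) < 0.02 * model.head.sagittal_radius

    def test_phalanx_normal_nearly_fixed(self, trajectory):
        assert trajectory.a_normal_drift_deg < 1.0

    def test_dataframe_shape(self, model, trajectory):
        df = trajectory.to_dataframe()
        assert len(df) == 2 * model.sweep.n_steps
        assert {"theta_deg", "plane", "cr_x", "icr_z"} <= set(df.columns)


class TestClassifyShift:
    def test_default_directions(self, model, trajectory):
        R0 = model.head.sagittal_radius
        ct = classify_shift(trajectory, "tibial", reference_radius=R0)
        cf = classify_shift(trajectory, "fibular", reference_radius=R0)
        assert ct.direction == "proximal"
        assert cf.direction == "distal"
        assert ct.return_theta is not None and cf.return_theta is not None

    def test_sphere_shows_no_shift(self, sphere_model):
        traj = sweep(sphere_model)
        for plane in ("tibial", "fibular"):
            c = classify_shift(traj, plane,
                               reference_radius=sphere_model.head.sagittal_radius)
            assert c.direction == "none"

    def test_onset_ordering_tibial_first(self, model, trajectory):
        ordered, on_t, on_f = shift_ordering(
            trajectory, reference_radius=model.head.sagittal_radius)
        assert ordered is True
        assert on_t < on_f

    def test_counter_model_orders_fibular_first(self, model):
        """Moving the tibial groove distally delays its engagement past the
        fibular one, inverting the onset order."""
        d = model.model_dump()
        d["head"]["tibial_groove"]["inception_deg"] = -40.0
        d["head"]["tibial_groove"]["termination_deg"] = -5.0
        d["head"]["tibial_groove"]["orientation_deg"] = 61.0
        counter = JointModel(**d)
        traj = sweep(counter)
        ordered, on_t, on_f = shift_ordering(
            traj, reference_radius=counter.head.sagittal_radius)
        assert ordered is False
        assert on_t > on_f

    def test_ordering_undefined_without_shift(self, sphere_model):
        traj = sweep(sphere_model)
        with pytest.raises(ValueError):
            shift_ordering(traj,
                           reference_radius=sphere_model.head.sagittal_radius)


class TestSurfaceSpeed:
    def test_zero_at_center(self):
        assert surface_speed([1.0, 2.0], [1.0, 2.0], 5.0) == 0.0

    def test_distal_cr_shift_slows_distal_edge_speeds_proximal_end(self):
        """A distal CR shift strictly reduces the distal edge's speed and
        strictly increases the proximal end's, at fixed angular rate."""
        distal_edge = np.array([R, 0.0])
        proximal_end = np.array([-R, 0.0])
        cr0 = np.array([0.0, 0.0])
        cr_shifted = np.array([1.5, 0.0])
        w = 1.0
        assert (surface_speed(distal_edge, cr_shifted, w)
                < surface_speed(distal_edge, cr0, w))
        assert (surface_speed(proximal_end, cr_shifted, w)
                > surface_speed(proximal_end, cr0, w))

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            surface_speed([1.0, 0.0], [0.0, 0.0], -1.0)


class TestObliquityAndAccommodation:
    def test_level_contacts_give_zero(self, model):
        d = model.model_dump()
        # mirror-symmetric sesamoid placement about the plantar axis
        d["tibial_sesamoid"]["center"] = (1.0, -14.465)
        d["fibular_sesamoid"]["center"] = (0.99, -14.465)
        m = JointModel(**d)
        ang, _ = x_axis_obliquity(m)
        assert abs(ang) < 0.1

    def test_default_obliquity_lateral_proximal(self, model):
        ang, label = x_axis_obliquity(model)
        assert ang > 0
        assert label == "lateral-proximal"

    def test_mirrored_obliquity_flips_sign(self, sphere_model):
        model = sphere_model
        ang0, _ = x_axis_obliquity(model)
        d = model.model_dump()
        d["tibial_sesamoid"]["center"], d["fibular_sesamoid"]["center"] = (
            tuple(d["fibular_sesamoid"]["center"]),
            tuple(d["tibial_sesamoid"]["center"]))
        d["tibial_sesamoid"]["label"], d["fibular_sesamoid"]["label"] = (
            "tibial", "fibular")
        mirrored = JointModel(**d)
        # swapping positions violates the normal ordering on purpose
        ang1, label1 = x_axis_obliquity(mirrored)
        assert abs(ang1 + ang0) < 1e-6
        assert label1 == "medial-distal"

    def test_two_degree_abduction_accommodated(self, model):
        change = transverse_accommodation(model, angle_deg=2.0)
        assert change < 0.01 * model.head.sagittal_radius

    def test_model_translation_equivariance(self, model):
        """Translating the whole apparatus translates every CR with it."""
        shift = np.array([3.0, -2.0])
        d = model.model_dump()
        for key in ("tibial_sesamoid", "fibular_sesamoid", "phalanx"):
            c = d[key]["center"]
            d[key]["center"] = (c[0] + shift[0], c[1] + shift[1])
        moved = JointModel(**d)
        t0 = sweep(model)
        t1 = sweep(moved)
        for plane in ("tibial", "fibular"):
            assert np.allclose(t1.cr_xy(plane), t0.cr_xy(plane) + shift,
                               atol=1e-7)
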