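"""Center-of-rotation computations for the posed joint.

The construction: at each declination angle the metatarsal's rigid pose is
fixed in rotation and solved in translation from simultaneous tangency to
the phalanx support and the active-plane sesamoid.  The contact point with
each platform body is the profile point whose inward normal passes through
the body's center; intersecting the phalanx-contact normal with the
sesamoid-contact normal yields that plane's center of rotation (CR).  While
both contacts ride the spherical part of the head, every normal passes
through the sphere center and the CR sits exactly there; a groove tilts the
sesamoid normal and shifts the CR proximally or distally along the
phalanx normal.  Combining the three contact normals (tibial, fibular,
phalanx) as 3D lines at their plane offsets gives the common instantaneous
center -- the "sphere of rotation" -- as the least-squares closest point,
with the residual measuring how far the three normals are from concurrency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, root

from .geometry2d import (
    CompositeProfile,
    GeometryError,
    Line2,
    ParallelLinesError,
    RigidTransform2,
    intersect_lines,
)
from .joint_model import JointConfiguration, JointModel, SweepSpec

__all__ = [
    "ContactError",
    "Contact",
    "PlaneCR",
    "ICRResult",
    "Trajectory",
    "ShiftClassification",
    "resolve_contact",
    "solve_pose",
    "plane_cr",
    "icr_3d",
    "declination_angle",
    "sweep",
    "classify_shift",
    "shift_ordering",
    "surface_speed",
    "x_axis_obliquity",
    "transverse_accommodation",
]

PARALLEL_TOL_RAD = 1e-8
TANGENCY_TOL = 1e-6


class ContactError(GeometryError):
    """Tangency could not be established for a contact."""


@dataclass(frozen=True)
class Contact:
    """A resolved contact: profile point, parameter and shared normal."""

    point: np.ndarray
    s: float
    normal: Line2


@dataclass(frozen=True)
class PlaneCR:
    """Per-plane center of rotation (platform frame)."""

    plane: Literal["tibial", "fibular", "generic"]
    point: Optional[np.ndarray]
    status: Literal["unique", "parallel-normals"]


@dataclass(frozen=True)
class ICRResult:
    """Least-squares common center of the three contact normals."""

    point3: np.ndarray
    rms_residual: float


@dataclass
class ShiftClassification:
    plane: str
    direction: Literal["proximal", "distal", "none"]
    onset_theta: Optional[float]
    return_theta: Optional[float]
    max_excursion: float


@dataclass
class Trajectory:
    """Everything the sweep computed, on a common theta grid."""

    thetas: np.ndarray
    tibial_cr: list[PlaneCR]
    fibular_cr: list[PlaneCR]
    icr3d: list[ICRResult]
    contacts: dict[str, list[Contact]]  # keys: A_tibial, A_fibular, B, C
    sphere_centers: dict[str, np.ndarray]  # per-plane posed head centers (n,2)
    a_normal_drift_deg: float = 0.0

    def cr_xy(self, plane: str) -> np.ndarray:
        crs = self.tibial_cr if plane == "tibial" else self.fibular_cr
        out = np.empty((len(crs), 2))
        centers = self.sphere_centers[plane]
        for i, cr in enumerate(crs):
            # parallel normals: on-ridge and in-groove CRs coincide at the
            # spherical center
            out[i] = centers[i] if cr.status == "parallel-normals" else cr.point
        return out

    def icr_points(self) -> np.ndarray:
        return np.array([r.point3 for r in self.icr3d])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, th in enumerate(self.thetas):
            for plane in ("tibial", "fibular"):
                cr = (self.tibial_cr if plane == "tibial" else self.fibular_cr)[i]
                xy = self.cr_xy(plane)[i]
                icr = self.icr3d[i]
                ses = self.contacts["B" if plane == "tibial" else "C"][i]
                rows.append({
                    "theta_deg": th, "plane": plane,
                    "cr_x": xy[0], "cr_y": xy[1], "cr_status": cr.status,
                    "icr_x": icr.point3[0], "icr_y": icr.point3[1],
                    "icr_z": icr.point3[2], "icr_residual": icr.rms_residual,
                    "contact_x": ses.point[0], "contact_y": ses.point[1],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def resolve_contact(profile: CompositeProfile, center, radius: float,
                    tol: float = TANGENCY_TOL) -> Contact:
    """Contact point between a posed convex profile and a circular body.

    The contact is the profile point closest to the body center; tangency
    requires that distance to equal the body radius within ``tol``.  The
    returned normal is the profile's inward normal there, which passes
    through the body center (the shared normal of tangent curves).
    """
    center = np.asarray(center, dtype=float)
    s, point, dist = profile.project(center)
    if abs(dist - radius) > tol:
        raise ContactError(
            f"no tangency: center-to-profile distance {dist:.6g} != radius {radius:.6g}")
    return Contact(point, s, profile.normal_line_at(s))


def solve_pose(model: JointModel, plane: str, theta_deg: float,
               warm: Optional[np.ndarray] = None) -> JointConfiguration:
    """Rigid pose of the head at declination ``theta`` in one sagittal plane.

    Rotation is fixed at ``-theta``; the translation is the root of the two
    tangency residuals (phalanx support and the plane's sesamoid).
    """
    prof = model.head.profile(plane)
    ses = model.sesamoid(plane)
    bodies = [(model.phalanx.center_arr, model.phalanx.radius),
              (ses.center_arr, ses.radius)]
    Rinv = RigidTransform2(theta_deg, np.zeros(2)).matrix  # rotation only

    def resid(t):
        out = np.empty(2)
        for i, (c, r) in enumerate(bodies):
            c_bone = Rinv @ (c - t)
            out[i] = prof.project(c_bone)[2] - r
        return out

    x0 = np.zeros(2) if warm is None else np.asarray(warm, dtype=float)
    # Levenberg-Marquardt is robust across the mildly non-smooth arc
    # junctions; a Powell-hybrid polish then drives the tangency residual
    # to machine precision.
    best_x, best_r = x0, float(np.max(np.abs(resid(x0))))
    if best_r < 1e-12:
        return JointConfiguration.from_theta(theta_deg, best_x)
    for attempt in range(2):
        sol = least_squares(resid, best_x, method="lm", xtol=1e-15, ftol=1e-15)
        r = float(np.max(np.abs(sol.fun)))
        if r < best_r:
            best_x, best_r = sol.x, r
        pol = root(resid, best_x, method="hybr", options={"xtol": 1e-14})
        r = float(np.max(np.abs(pol.fun)))
        if r < best_r:
            best_x, best_r = pol.x, r
        if best_r < 1e-10:
            break
    if best_r > TANGENCY_TOL:
        raise ContactError(
            f"pose tangency failed at theta={theta_deg:.3f} deg in the "
            f"{plane} plane (residual {best_r:.3g})")
    return JointConfiguration.from_theta(theta_deg, best_x)


def posed_profile(model: JointModel, plane: str,
                  config: JointConfiguration) -> CompositeProfile:
    return model.head.profile(plane).transformed(config.pose)


def plane_contacts(model: JointModel, plane: str,
                   config: JointConfiguration) -> tuple[Contact, Contact]:
    """(phalanx contact A, sesamoid contact) in the given plane's pose."""
    prof = posed_profile(model, plane, config)
    ses = model.sesamoid(plane)
    a = resolve_contact(prof, model.phalanx.center_arr, model.phalanx.radius)
    b = resolve_contact(prof, ses.center_arr, ses.radius)
    return a, b


def plane_cr(normal_A: Line2, normal_B: Line2, plane: str = "generic",
             parallel_tol: float = PARALLEL_TOL_RAD) -> PlaneCR:
    """Intersect the two contact normals to locate the plane's CR."""
    try:
        p = intersect_lines(normal_A, normal_B, parallel_tol)
    except ParallelLinesError:
        return PlaneCR(plane, None, "parallel-normals")
    return PlaneCR(plane, p, "unique")


def icr_3d(lines: list[tuple[np.ndarray, np.ndarray]]) -> ICRResult:
    """Least-squares closest point to several 3D lines (origin, unit dir).

    Solves the normal equations ``sum_i (I - d_i d_i^T) (p - a_i) = 0``;
    the residual is the RMS point-to-line distance, zero iff the lines are
    concurrent.  Raises for a rank-deficient system (all lines parallel).
    """
    M = np.zeros((3, 3))
    b = np.zeros(3)
    for a, d in lines:
        a = np.asarray(a, dtype=float)
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        P = np.eye(3) - np.outer(d, d)
        M += P
        b += P @ a
    if np.linalg.cond(M) > 1e12:
        raise GeometryError("degenerate geometry: lines do not determine a point")
    p = np.linalg.solve(M, b)
    d2 = []
    for a, d in lines:
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        w = p - np.asarray(a, dtype=float)
        w_perp = w - (w @ d) * d
        d2.append(float(w_perp @ w_perp))
    return ICRResult(p, math.sqrt(max(np.mean(d2), 0.0)))


def declination_angle(config: JointConfiguration, normal_A: Line2,
                      long_axis_world: np.ndarray) -> float:
    """Angle (deg, in [0, 90]) between the A-normal and the long axis."""
    u = np.asarray(long_axis_world, dtype=float)
    u = u / np.hypot(*u)
    c = abs(float(normal_A.direction @ u))
    return math.degrees(math.acos(min(c, 1.0)))


def _line3(line: Line2, z: float, incline_scale: float = 0.0
           ) -> tuple[np.ndarray, np.ndarray]:
    """Lift an in-plane normal line to 3D at plane offset ``z``.

    ``incline_scale`` > 0 adds the spherical inclination toward the
    mid-plane: on a sphere of radius ``incline_scale`` the surface normal
    at an off-center section points at the 3D center, so the lifted line
    is given a z-component of ``-z`` per ``incline_scale`` of in-plane
    travel.  With the default 0 the line stays in its plane.
    """
    o = np.array([line.origin[0], line.origin[1], z])
    if incline_scale > 0.0:
        d = np.array([line.direction[0] * incline_scale,
                      line.direction[1] * incline_scale, -z])
    else:
        d = np.array([line.direction[0], line.direction[1], 0.0])
    return o, d / np.linalg.norm(d)


def sweep(model: JointModel, sweep_spec: Optional[SweepSpec] = None) -> Trajectory:
    """Run the full declination sweep and collect CRs, contacts and ICRs."""
    spec = sweep_spec or model.sweep
    thetas = spec.grid()
    tib_cr, fib_cr, icrs = [], [], []
    contacts = {"A_tibial": [], "A_fibular": [], "B": [], "C": []}
    centers = {"tibial": np.empty((len(thetas), 2)),
               "fibular": np.empty((len(thetas), 2))}
    warm = {"tibial": None, "fibular": None}
    a_dirs = []
    prev_s = {}
    for i, th in enumerate(thetas):
        per_plane = {}
        for plane in ("tibial", "fibular"):
            try:
                cfg = solve_pose(model, plane, th, warm=warm[plane])
            except ContactError as e:
                raise ContactError(f"sweep step {i} (theta={th:.2f}): {e}") from e
            warm[plane] = cfg.pose.translation
            centers[plane][i] = cfg.pose.translation  # posed head center
            a, bc = plane_contacts(model, plane, cfg)
            per_plane[plane] = (cfg, a, bc)
            # groove contact transitions must be continuous
            key = (plane, "ses")
            if key in prev_s:
                ds_max = 2.0 * model.head.profile(plane).length / max(spec.n_steps, 1)
                step_lim = max(ds_max, 2.0 * model.head.sagittal_radius
                               * math.radians(thetas[1] - thetas[0]) * 2.0)
                if abs(bc.s - prev_s[key]) > step_lim:
                    raise ContactError(
                        f"contact jump at step {i} (theta={th:.2f} deg)")
            prev_s[key] = bc.s
        cfg_t, a_t, b = per_plane["tibial"]
        cfg_f, a_f, c = per_plane["fibular"]
        contacts["A_tibial"].append(a_t)
        contacts["A_fibular"].append(a_f)
        contacts["B"].append(b)
        contacts["C"].append(c)
        tib_cr.append(plane_cr(a_t.normal, b.normal, "tibial"))
        fib_cr.append(plane_cr(a_f.normal, c.normal, "fibular"))
        a_dirs.append(a_t.normal.direction)
        # three contact normals as 3D lines at their plane offsets; the
        # phalanx normal is shared (its drift across planes is recorded)
        a_mean = Line2(0.5 * (a_t.normal.origin + a_f.normal.origin),
                       0.5 * (a_t.normal.direction + a_f.normal.direction))
        R = model.head.sagittal_radius
        icrs.append(icr_3d([
            _line3(a_mean, 0.0),
            _line3(b.normal, model.tibial_sesamoid.z_offset, incline_scale=R),
            _line3(c.normal, model.fibular_sesamoid.z_offset, incline_scale=R),
        ]))
    a_dirs = np.array(a_dirs)
    drift = math.degrees(math.acos(min(1.0, float(
        np.min(a_dirs @ a_dirs[0])))))
    return Trajectory(thetas, tib_cr, fib_cr, icrs, contacts, centers,
                      a_normal_drift_deg=drift)


def classify_shift(traj: Trajectory, plane: str,
                   excursion_tol: Optional[float] = None,
                   reference_radius: Optional[float] = None) -> ShiftClassification:
    """Classify the plane's CR excursion along x over the sweep.

    Direction is the sign of the maximal x-excursion beyond
    ``excursion_tol`` (default 0.005 of the reference radius): negative x
    is a proximal shift.  Onset is the first theta exceeding the tolerance
    and return the first theta after the peak back within it.
    """
    xs = traj.cr_xy(plane)[:, 0]
    if excursion_tol is None:
        R = reference_radius if reference_radius is not None else 11.0
        excursion_tol = 0.005 * R
    e = xs - xs[0]
    k = int(np.argmax(np.abs(e)))
    if abs(e[k]) <= excursion_tol:
        return ShiftClassification(plane, "none", None, None, float(np.max(np.abs(e))))
    direction = "proximal" if e[k] < 0 else "distal"
    over = np.abs(e) > excursion_tol
    onset = float(traj.thetas[int(np.argmax(over))])
    ret = None
    after = np.nonzero(~over[k:])[0]
    if len(after):
        ret = float(traj.thetas[k + int(after[0])])
    return ShiftClassification(plane, direction, onset, ret, float(abs(e[k])))


def shift_ordering(traj: Trajectory, excursion_tol: Optional[float] = None,
                   reference_radius: Optional[float] = None):
    """Does the tibial CR shift before the fibular one?

    Returns ``(ordered, onset_tibial, onset_fibular)``; ``ordered`` is True
    when the tibial onset strictly precedes the fibular one, "tie" when
    the onsets agree within one theta step, and undefined (ValueError)
    when either plane shows no shift.
    """
    ct = classify_shift(traj, "tibial", excursion_tol, reference_radius)
    cf = classify_shift(traj, "fibular", excursion_tol, reference_radius)
    if ct.direction == "none" or cf.direction == "none":
        raise ValueError("shift ordering undefined: a plane shows no shift")
    step = float(traj.thetas[1] - traj.thetas[0])
    if abs(ct.onset_theta - cf.onset_theta) <= step:
        return "tie", ct.onset_theta, cf.onset_theta
    return ct.onset_theta < cf.onset_theta, ct.onset_theta, cf.onset_theta


def surface_speed(point, cr, omega_deg_s: float) -> float:
    """Linear speed of a surface point about a center of rotation."""
    if omega_deg_s < 0:
        raise ValueError("omega must be >= 0")
    point = np.asarray(point, dtype=float)
    cr = np.asarray(cr, dtype=float)
    return math.radians(omega_deg_s) * float(np.hypot(*(point - cr)))


def x_axis_obliquity(model: JointModel, theta_deg: Optional[float] = None):
    """Obliquity of the transverse joint axis through the sesamoid contacts.

    The angle (deg) between the line joining the tibial and fibular contact
    points and the perpendicular to the metatarsal long axis in the
    transverse plane: zero when the contacts are level, positive (label
    "lateral-proximal") when the tibial contact is more distal.
    """
    th = model.sweep.theta0_deg if theta_deg is None else theta_deg
    pts = {}
    for plane in ("tibial", "fibular"):
        cfg = solve_pose(model, plane, th)
        _, bc = plane_contacts(model, plane, cfg)
        pts[plane] = np.array([bc.point[0], bc.point[1],
                               model.sesamoid(plane).z_offset])
    delta = pts["tibial"] - pts["fibular"]
    if np.linalg.norm(delta) < 1e-9:
        raise GeometryError("coincident sesamoid contacts")
    obliquity = math.degrees(math.atan2(delta[0], delta[2]))
    if obliquity > 1e-9:
        label = "lateral-proximal"
    elif obliquity < -1e-9:
        label = "medial-distal"
    else:
        label = "none"
    return obliquity, label


def transverse_accommodation(model: JointModel, angle_deg: float = 2.0,
                             n_checks: int = 25) -> float:
    """Max sagittal CR change under a small transverse (abduction) rotation.

    A rotation about the dorsal-plantar axis through the head center leaves
    the spherical surface invariant; only the groove features translate
    within each sagittal plane, by ``z_i * sin(angle)``, equivalent to a
    shift of the groove's polar position.  Returns the largest change in
    any plane CR across a coarse sweep.
    """
    head_dict = model.head.model_dump()
    for plane, attr in (("tibial", "tibial_groove"), ("fibular", "fibular_groove")):
        z = model.sesamoid(plane).z_offset
        dphi = math.degrees(z * math.sin(math.radians(angle_deg))
                            / model.head.sagittal_radius)
        for key in ("inception_deg", "termination_deg", "orientation_deg"):
            head_dict[attr][key] += dphi
    shifted = model.model_copy(update={"head": type(model.head)(**head_dict)})
    spec = model.sweep.model_copy(update={"n_steps": n_checks})
    t0 = sweep(model, spec)
    t1 = sweep(shifted, spec)
    worst = 0.0
    for plane in ("tibial", "fibular"):
        d = np.hypot(*(t0.cr_xy(plane) - t1.cr_xy(plane)).T)
        worst = max(worst, float(np.max(d)))
    return worst
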