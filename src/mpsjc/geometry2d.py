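"""Planar curve primitives for articular-surface modeling.

Everything the center-of-rotation constructions need lives here: circular
and elliptical arcs, composite convex profiles with C1 junctions, tangent
and inward-normal queries, line intersection, and least-squares fitting of
circles and grooved profiles to digitized section contours.

Conventions
-----------
* Lengths are model units (nominally mm); angles are **degrees** at every
  public interface and radians internally.
* Profiles are traversed counterclockwise, so the inward normal is the
  tangent rotated by +90 deg.
* The profile parameter is cumulative arc length from the start point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "GeometryError",
    "DomainError",
    "ParallelLinesError",
    "DegenerateFitError",
    "FitFailureError",
    "Line2",
    "CircleArc",
    "EllipseArc",
    "CompositeProfile",
    "RigidTransform2",
    "intersect_lines",
    "fit_circle",
    "fit_profile",
    "flattened_insert",
    "ProfileTemplate",
]

_UNIT_TOL = 1e-12
_PARALLEL_TOL = 1e-8  # radians


class GeometryError(Exception):
    """Base class for geometric failures."""


class DomainError(GeometryError):
    """Curve parameter outside the curve's domain."""


class ParallelLinesError(GeometryError):
    """Two lines have no unique intersection within tolerance."""


class DegenerateFitError(GeometryError):
    """Input points do not determine the requested shape."""


class FitFailureError(GeometryError):
    """Nonlinear profile fit did not converge."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise GeometryError("zero-length direction")
    return np.asarray(v, dtype=float) / n


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counterclockwise)."""
    return np.array([-v[1], v[0]])


def _dir(angle_rad: float) -> np.ndarray:
    return np.array([math.cos(angle_rad), math.sin(angle_rad)])


@dataclass(frozen=True)
class Line2:
    """An infinite oriented line given by a point and a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if not np.all(np.isfinite(o)) or not np.all(np.isfinite(d)):
            raise GeometryError("non-finite line components")
        n = float(np.hypot(d[0], d[1]))
        if abs(n - 1.0) > 1e-9:
            d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to(self, p: np.ndarray) -> float:
        w = np.asarray(p, dtype=float) - self.origin
        return abs(float(w[0] * self.direction[1] - w[1] * self.direction[0]))


@dataclass(frozen=True)
class RigidTransform2:
    """Proper rigid motion ``p -> R(angle) p + translation``."""

    angle_deg: float
    translation: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + np.asarray(self.translation, dtype=float)

    def apply_vec(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.matrix.T

    def apply_line(self, line: Line2) -> Line2:
        return Line2(self.apply(line.origin), self.apply_vec(line.direction))

    def inverse(self) -> "RigidTransform2":
        Rinv = self.matrix.T
        return RigidTransform2(-self.angle_deg, -(Rinv @ np.asarray(self.translation, dtype=float)))


@dataclass(frozen=True)
class CircleArc:
    """Counterclockwise circular arc.

    ``start_angle_deg`` / ``end_angle_deg`` are polar angles about the
    center; the arc runs CCW so ``end > start`` and the extent is in
    (0, 360].
    """

    center: np.ndarray
    radius: float
    start_angle_deg: float
    end_angle_deg: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not self.radius > 0:
            raise GeometryError("circle radius must be positive")
        ext = self.end_angle_deg - self.start_angle_deg
        if not (0.0 < ext <= 360.0):
            raise GeometryError("arc extent must be in (0, 360] degrees")

    # -- local parameterization: t = polar angle in radians ---------------
    @property
    def _t0(self) -> float:
        return math.radians(self.start_angle_deg)

    @property
    def _t1(self) -> float:
        return math.radians(self.end_angle_deg)

    @property
    def length(self) -> float:
        return self.radius * (self._t1 - self._t0)

    def point(self, t: float) -> np.ndarray:
        return self.center + self.radius * _dir(t)

    def tangent(self, t: float) -> np.ndarray:
        return np.array([-math.sin(t), math.cos(t)])

    def t_of_s(self, s: float) -> float:
        return self._t0 + s / self.radius

    def project(self, p: np.ndarray) -> tuple[float, float]:
        """Closest point; returns (local parameter t, distance)."""
        px, py = float(p[0]), float(p[1])
        cx, cy = float(self.center[0]), float(self.center[1])
        wx, wy = px - cx, py - cy
        ang = math.atan2(wy, wx)
        t0, t1 = self._t0, self._t1
        # bring ang into [t0, t0 + 2pi)
        ang = t0 + (ang - t0) % (2 * math.pi)
        best, best_d = None, math.inf
        for t in (min(max(ang, t0), t1), t0, t1):
            qx = cx + self.radius * math.cos(t)
            qy = cy + self.radius * math.sin(t)
            d = math.hypot(px - qx, py - qy)
            if d < best_d:
                best, best_d = t, d
        return best, best_d

    def transformed(self, g: RigidTransform2) -> "CircleArc":
        return CircleArc(
            g.apply(self.center),
            self.radius,
            self.start_angle_deg + g.angle_deg,
            self.end_angle_deg + g.angle_deg,
        )

    def to_dict(self) -> dict:
        return {
            "type": "circle",
            "center": [float(self.center[0]), float(self.center[1])],
            "radius": float(self.radius),
            "start_angle_deg": float(self.start_angle_deg),
            "end_angle_deg": float(self.end_angle_deg),
        }


@dataclass(frozen=True)
class EllipseArc:
    """Counterclockwise elliptical arc.

    Parameterized by the eccentric parameter t (degrees at the interface):
    ``P(t) = C + R(orientation) (a cos t, b sin t)``.  The flattening
    ``f = 1 - b/a`` lies in [0, 1).
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    orientation_deg: float
    start_param_deg: float
    end_param_deg: float
    _ltab: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (self.semi_major >= self.semi_minor > 0):
            raise GeometryError("ellipse requires a >= b > 0")
        ext = self.end_param_deg - self.start_param_deg
        if not (0.0 < ext <= 360.0):
            raise GeometryError("arc extent must be in (0, 360] degrees")
        # dense cumulative arc-length table for s <-> t conversion
        t = np.linspace(math.radians(self.start_param_deg),
                        math.radians(self.end_param_deg), 4097)
        speed = np.hypot(self.semi_major * np.sin(t), self.semi_minor * np.cos(t))
        from scipy.integrate import cumulative_trapezoid

        s = np.concatenate([[0.0], cumulative_trapezoid(speed, t)])
        object.__setattr__(self, "_ltab", (t, s))

    @property
    def flattening(self) -> float:
        return 1.0 - self.semi_minor / self.semi_major

    @property
    def _rot(self) -> np.ndarray:
        a = math.radians(self.orientation_deg)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s], [s, c]])

    @property
    def length(self) -> float:
        return float(self._ltab[1][-1])

    def point(self, t: float) -> np.ndarray:
        local = np.array([self.semi_major * math.cos(t), self.semi_minor * math.sin(t)])
        return self.center + self._rot @ local

    def tangent(self, t: float) -> np.ndarray:
        local = np.array([-self.semi_major * math.sin(t), self.semi_minor * math.cos(t)])
        return _unit(self._rot @ local)

    def t_of_s(self, s: float) -> float:
        tt, ss = self._ltab
        return float(np.interp(s, ss, tt))

    def project(self, p: np.ndarray) -> tuple[float, float]:
        p = np.asarray(p, dtype=float)
        t0 = math.radians(self.start_param_deg)
        t1 = math.radians(self.end_param_deg)

        def d(t):
            q = self.point(t)
            return float(np.hypot(*(p - q)))

        grid = np.linspace(t0, t1, 65)
        tb = grid[int(np.argmin([d(t) for t in grid]))]
        lo, hi = max(t0, tb - (t1 - t0) / 64), min(t1, tb + (t1 - t0) / 64)
        res = minimize_scalar(d, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        best = float(res.x)
        cands = [best, t0, t1]
        tstar = min(cands, key=d)
        return tstar, d(tstar)

    def transformed(self, g: RigidTransform2) -> "EllipseArc":
        return EllipseArc(
            g.apply(self.center),
            self.semi_major,
            self.semi_minor,
            self.orientation_deg + g.angle_deg,
            self.start_param_deg,
            self.end_param_deg,
        )

    def to_dict(self) -> dict:
        return {
            "type": "ellipse",
            "center": [float(self.center[0]), float(self.center[1])],
            "semi_major": float(self.semi_major),
            "semi_minor": float(self.semi_minor),
            "orientation_deg": float(self.orientation_deg),
            "start_param_deg": float(self.start_param_deg),
            "end_param_deg": float(self.end_param_deg),
        }


def arc_from_dict(d: dict):
    if d["type"] == "circle":
        return CircleArc(np.array(d["center"]), d["radius"],
                         d["start_angle_deg"], d["end_angle_deg"])
    if d["type"] == "ellipse":
        return EllipseArc(np.array(d["center"]), d["semi_major"], d["semi_minor"],
                          d["orientation_deg"], d["start_param_deg"], d["end_param_deg"])
    raise GeometryError(f"unknown arc type {d['type']!r}")


class CompositeProfile:
    """An open convex curve made of C1-joined circular/elliptical arcs.

    Adjacent arcs must meet with position error < 1e-9 and tangent error
    < 1e-6 rad; the outward normal must turn monotonically (convexity).
    The curve parameter is cumulative arc length.
    """

    POS_TOL = 1e-9
    TAN_TOL = 1e-6  # radians

    def __init__(self, arcs: Sequence, check: bool = True):
        if not arcs:
            raise GeometryError("profile needs at least one arc")
        self.arcs = list(arcs)
        self._lengths = np.array([a.length for a in self.arcs])
        self._cum = np.concatenate([[0.0], np.cumsum(self._lengths)])
        if check:
            violations = self.validate()
            if violations:
                raise GeometryError("invalid profile: " + "; ".join(violations))

    # ------------------------------------------------------------------
    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def validate(self) -> list[str]:
        out = []
        for i in range(len(self.arcs) - 1):
            a, b = self.arcs[i], self.arcs[i + 1]
            ta = a._t1 if isinstance(a, CircleArc) else math.radians(a.end_param_deg)
            tb = b._t0 if isinstance(b, CircleArc) else math.radians(b.start_param_deg)
            pa, pb = a.point(ta), b.point(tb)
            if float(np.hypot(*(pa - pb))) > 1e-7:
                out.append(f"position discontinuity at junction {i}")
            va, vb = a.tangent(ta), b.tangent(tb)
            ang = abs(math.atan2(va[0] * vb[1] - va[1] * vb[0], float(va @ vb)))
            if ang > self.TAN_TOL * 10:
                out.append(f"tangent discontinuity at junction {i}")
        # convexity: outward normal angle monotone along sampled parameters
        s = np.linspace(0.0, self.length, 400)
        angs = np.unwrap([math.atan2(t[1], t[0]) for t in (self.tangent_at(x) for x in s)])
        if np.any(np.diff(angs) < -1e-9):
            out.append("profile not convex (normal angle not monotone)")
        return out

    def _locate(self, s: float) -> tuple[int, float]:
        if not (-1e-12 <= s <= self.length + 1e-12):
            raise DomainError(f"parameter {s} outside [0, {self.length}]")
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self.arcs) - 1)
        return i, s - self._cum[i]

    def point_at(self, s: float) -> np.ndarray:
        i, ds = self._locate(s)
        a = self.arcs[i]
        return a.point(a.t_of_s(ds))

    def tangent_at(self, s: float) -> np.ndarray:
        i, ds = self._locate(s)
        a = self.arcs[i]
        return a.tangent(a.t_of_s(ds))

    def normal_line_at(self, s: float) -> Line2:
        """Inward-pointing normal line at arc-length parameter ``s``."""
        t = self.tangent_at(s)
        return Line2(self.point_at(s), _rot90(t))

    def project(self, p: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Global closest point: returns (s, point, distance)."""
        best = None
        for i, a in enumerate(self.arcs):
            t, d = a.project(p)
            if best is None or d < best[2]:
                if isinstance(a, CircleArc):
                    s_loc = (t - a._t0) * a.radius
                else:
                    tt, ss = a._ltab
                    s_loc = float(np.interp(t, tt, ss))
                best = (self._cum[i] + s_loc, a.point(t), d)
        return best

    def distances(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized unsigned distance from many points to the profile."""
        pts = np.asarray(pts, dtype=float)
        best = np.full(len(pts), np.inf)
        for a in self.arcs:
            if isinstance(a, CircleArc):
                w = pts - a.center
                ang = np.arctan2(w[:, 1], w[:, 0])
                ang = a._t0 + (ang - a._t0) % (2 * math.pi)
                d = np.full(len(pts), np.inf)
                for t in (np.clip(ang, a._t0, a._t1),
                          np.full(len(pts), a._t0), np.full(len(pts), a._t1)):
                    q = a.center + a.radius * np.column_stack([np.cos(t), np.sin(t)])
                    d = np.minimum(d, np.hypot(*(pts - q).T))
            else:
                d = np.array([a.project(p)[1] for p in pts])
            best = np.minimum(best, d)
        return best

    def transformed(self, g: RigidTransform2) -> "CompositeProfile":
        return CompositeProfile([a.transformed(g) for a in self.arcs], check=False)

    def sample(self, n: int) -> np.ndarray:
        s = np.linspace(0.0, self.length, n)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1,
                      0, len(self.arcs) - 1)
        out = np.empty((n, 2))
        for i, a in enumerate(self.arcs):
            m = idx == i
            if not m.any():
                continue
            ds = s[m] - self._cum[i]
            if isinstance(a, CircleArc):
                t = a._t0 + ds / a.radius
                out[m] = a.center + a.radius * np.column_stack(
                    [np.cos(t), np.sin(t)])
            else:
                out[m] = [a.point(a.t_of_s(x)) for x in ds]
        return out

    def to_dict(self) -> dict:
        return {"arcs": [a.to_dict() for a in self.arcs]}

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeProfile":
        return cls([arc_from_dict(a) for a in d["arcs"]], check=False)


# ---------------------------------------------------------------------------
# free functions


def tangent_at(profile: CompositeProfile, s: float) -> np.ndarray:
    """Unit tangent of a profile at arc-length parameter ``s``."""
    return profile.tangent_at(s)


def normal_line_at(profile: CompositeProfile, s: float) -> Line2:
    """Inward normal line of a profile at arc-length parameter ``s``."""
    return profile.normal_line_at(s)


def intersect_lines(l1: Line2, l2: Line2, parallel_tol: float = _PARALLEL_TOL) -> np.ndarray:
    """Intersection point of two lines.

    Raises :class:`ParallelLinesError` when the angle between the lines is
    below ``parallel_tol`` (radians); the caller decides what a missing
    intersection means (for CR sweeps it means the center is unchanged /
    at infinity).
    """
    d1, d2 = l1.direction, l2.direction
    cross = float(d1[0] * d2[1] - d1[1] * d2[0])
    if abs(cross) < math.sin(parallel_tol):
        raise ParallelLinesError("lines are parallel within tolerance")
    # solve l1.origin + t1 d1 = l2.origin + t2 d2
    rhs = l2.origin - l1.origin
    t1 = (rhs[0] * d2[1] - rhs[1] * d2[0]) / cross
    return l1.origin + t1 * d1


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through a point cloud.

    Kasa algebraic fit followed by a geometric Gauss-Newton refinement.
    Returns ``(center, radius, rms_residual)`` where the residual is the
    root-mean-square radial deviation.  Raises
    :class:`DegenerateFitError` for < 3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise DegenerateFitError("need at least 3 planar points")
    c0 = pts.mean(axis=0)
    q = pts - c0
    # collinearity test on centered coordinates
    sv = np.linalg.svd(q, compute_uv=False)
    if sv[-1] < 1e-12 * max(sv[0], 1.0):
        raise DegenerateFitError("points are collinear")
    A = np.column_stack([2 * q, np.ones(len(q))])
    b = (q ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = c0 + sol[:2]
    radius = math.sqrt(sol[2] + float(sol[:2] @ sol[:2]))

    def resid(p):
        return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

    out = least_squares(resid, x0=[center[0], center[1], radius], method="lm")
    center = out.x[:2]
    radius = float(out.x[2])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def flattened_insert(
    radius: float,
    phi1_deg: float,
    phi2_deg: float,
    flattening: float,
    flat_center_deg: float | None = None,
    flat_fraction: float = 0.5,
) -> list[CircleArc]:
    """Replace a circle segment by a C1 three-arc flattened chain.

    The segment of the circle (centered at the origin) between polar angles
    ``phi1_deg`` and ``phi2_deg`` is replaced by curl / flat / curl circular
    arcs that join the circle and each other with continuous tangents.  The
    flat arc has radius ``R / (1 - flattening)``; ``flat_center_deg`` is the
    polar direction of the flat arc's midpoint normal, which sets where the
    surface curvature is concentrated (toward the start or the end of the
    insert); ``flat_fraction`` is the fraction of the angular span the flat
    arc occupies.

    A single conic cannot do this asymmetrically (any conic tangent to a
    circle at two points is symmetric about the chord bisector), and a
    two-arc chain is geometrically impossible, hence three arcs.
    """
    if not (0.0 <= flattening < 1.0):
        raise GeometryError("flattening must be in [0, 1)")
    p1, p2 = math.radians(phi1_deg), math.radians(phi2_deg)
    if not p2 > p1:
        raise GeometryError("insert requires phi2 > phi1")
    if flat_center_deg is None:
        flat_center_deg = 0.5 * (phi1_deg + phi2_deg)
    nu = math.radians(flat_center_deg)
    beta = 0.5 * flat_fraction * (p2 - p1)
    if not (p1 < nu - beta and nu + beta < p2):
        raise GeometryError("flat arc does not fit inside the insert span")
    if flattening == 0.0:
        return [CircleArc(np.zeros(2), radius, phi1_deg, phi2_deg)]

    r_flat = radius / (1.0 - flattening)
    u1, u2 = _dir(p1), _dir(p2)
    n1, n2 = _dir(nu - beta), _dir(nu + beta)
    # K_f expressed from either end must agree:
    #   K_f = (R - r_a) u1 - (r_flat - r_a) n1 = (R - r_b) u2 - (r_flat - r_b) n2
    # linear in (r_a, r_b):
    A = np.column_stack([n1 - u1, -(n2 - u2)])
    rhs = radius * (u2 - u1) + r_flat * (n1 - n2)
    try:
        r_a, r_b = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise GeometryError("degenerate insert geometry") from e
    if not (0 < r_a <= radius * (1 + 1e-9) and 0 < r_b <= radius * (1 + 1e-9)):
        raise GeometryError(
            f"insert has no convex solution (curl radii {r_a:.3g}, {r_b:.3g})")
    K_a = (radius - r_a) * u1
    K_b = (radius - r_b) * u2
    K_f = K_a - (r_flat - r_a) * n1
    arcs = [
        CircleArc(K_a, float(r_a), phi1_deg, math.degrees(nu - beta)),
        CircleArc(K_f, float(r_flat), math.degrees(nu - beta), math.degrees(nu + beta)),
        CircleArc(K_b, float(r_b), math.degrees(nu + beta), phi2_deg),
    ]
    return arcs


@dataclass
class ProfileTemplate:
    """Declarative schema for :func:`fit_profile`.

    ``n_arcs == 1`` fits a plain circle; otherwise a grooved profile
    (dorsal circle + flattened three-arc insert) is fitted.  The span /
    orientation fields are initial guesses for the optimizer, in degrees.
    """

    n_arcs: int = 1
    span_deg: tuple[float, float] = (-110.0, 100.0)
    groove_phi1_deg: float = -55.0
    groove_phi2_deg: float = -20.0
    flattening: float = 0.1
    flat_center_deg: float | None = None
    flat_fraction: float = 0.5


def _grooved_profile_origin(radius, span, phi1, phi2, f, nu, frac) -> CompositeProfile:
    """Grooved profile about the origin; helper shared with joint_model."""
    arcs = [CircleArc(np.zeros(2), radius, span[0], phi1)]
    arcs += flattened_insert(radius, phi1, phi2, f, nu, frac)
    arcs += [CircleArc(np.zeros(2), radius, phi2, span[1])]
    return CompositeProfile(arcs, check=False)


def fit_profile(points: np.ndarray, template: ProfileTemplate):
    """Fit a composite profile to one section contour.

    Returns ``(profile, params, rms_residual)``; ``params`` is a dict of the
    recovered generating parameters (center, radius, and for grooved
    templates the flattening, groove span and flat-arc attitude).  Raises
    :class:`FitFailureError` on optimizer failure.
    """
    pts = np.asarray(points, dtype=float)
    if template.n_arcs <= 1:
        center, radius, rms = fit_circle(pts)
        prof = CompositeProfile(
            [CircleArc(center, radius, template.span_deg[0], template.span_deg[1])],
            check=False)
        return prof, {"center": center, "radius": radius, "flattening": 0.0}, rms

    c0, r0, _ = fit_circle(pts)
    nu0 = template.flat_center_deg
    if nu0 is None:
        nu0 = 0.5 * (template.groove_phi1_deg + template.groove_phi2_deg)

    span = template.span_deg
    frac = template.flat_fraction

    def build(x):
        cx, cy, R, phi1, phi2, f, nu = x
        prof = _grooved_profile_origin(R, span, phi1, phi2, f, nu, frac)
        return prof.transformed(RigidTransform2(0.0, np.array([cx, cy])))

    def resid(x):
        try:
            prof = build(x)
        except GeometryError:
            return np.full(len(pts), 1e3)
        return prof.distances(pts)

    x0 = np.array([c0[0], c0[1], r0, template.groove_phi1_deg,
                   template.groove_phi2_deg, max(template.flattening, 1e-3), nu0])
    # the template pins the groove family: spans and flat attitude may move
    # only moderately, so the fitted curvature skew (which end of the groove
    # carries the sharp curl) cannot flip under digitization noise
    lo = [c0[0] - r0, c0[1] - r0, 0.5 * r0,
          template.groove_phi1_deg - 8.0, template.groove_phi2_deg - 8.0,
          0.0, nu0 - 6.0]
    hi = [c0[0] + r0, c0[1] + r0, 1.5 * r0,
          template.groove_phi1_deg + 8.0, template.groove_phi2_deg + 8.0,
          0.6, nu0 + 6.0]
    out = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12, max_nfev=600,
                        x_scale=[1.0, 1.0, 1.0, 1.0, 1.0, 0.05, 1.0])
    if not np.all(np.isfinite(out.x)) or out.cost > 1e3:
        raise FitFailureError(f"profile fit did not converge: {out.message}")
    # unbounded quadratic polish for the noiseless/low-noise regime
    polish = least_squares(resid, out.x, method="lm", xtol=1e-15, ftol=1e-15,
                           max_nfev=300)
    if polish.cost <= out.cost and np.all(polish.x[:6] >= np.array(lo)[:6] - 1.0):
        out = polish
    cx, cy, R, phi1, phi2, f, nu = out.x
    rms = float(np.sqrt(np.mean(out.fun ** 2)))
    params = {
        "center": np.array([cx, cy]),
        "radius": float(R),
        "groove_phi1_deg": float(phi1),
        "groove_phi2_deg": float(phi2),
        "flattening": float(f),
        "flat_center_deg": float(nu),
    }
    return build(out.x), params, rms
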