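"""Synthetic sagittal C-T section stack with known ground truth.

Emulates a digitized specimen: an ordered series of sagittal section
contours at 0.5-mm spacing across the metatarsal head.  The mid-head
section through the inter-sesamoidal ridge (crista) is circular; sections
medial of it cut the tibial sesamoid groove and sections lateral of it the
fibular groove, with the flattening deepest at each groove's trough
section.  The landmark locator recovers the crista and trough sections
from the contours alone; the model builder turns them into a posable
joint model, closing the loop from "imaging" to kinematics.

Contours are open curves over the distal-plantar articular region (like
shadow drawings of the articular edge), sampled uniformly in arc length
with isotropic Gaussian digitization noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from pydantic import BaseModel, Field, model_validator

from . import defaults as D
from .geometry2d import (
    DegenerateFitError,
    FitFailureError,
    GeometryError,
    ProfileTemplate,
    _grooved_profile_origin,
    fit_circle,
    fit_profile,
)
from .joint_model import (
    GrooveSpec,
    JointModel,
    MetatarsalHead,
    PhalanxContact,
    SesamoidBody,
    SweepSpec,
)

__all__ = [
    "MissingLandmarkError",
    "StackGenSpec",
    "Section",
    "SectionStack",
    "generate_stack",
    "locate_landmarks",
    "stack_to_model",
]

SECTION_SPACING = 0.5  # mm between successive C-T sections


class MissingLandmarkError(GeometryError):
    """A required landmark could not be located in the stack."""


class StackGenSpec(BaseModel):
    """Generating parameters of a synthetic section stack.

    Indices follow the specimen convention: low indices lateral, high
    indices medial, so the fibular trough index < crista index < tibial
    trough index.  ``noise_sigma`` is the isotropic per-point digitization
    noise (mm).
    """

    n_sections: int = D.STACK_N_SECTIONS
    crista_index: int = D.STACK_CRISTA_INDEX
    tibial_trough_index: int = D.STACK_TIBIAL_TROUGH_INDEX
    fibular_trough_index: int = D.STACK_FIBULAR_TROUGH_INDEX
    sagittal_radius: float = D.SAGITTAL_RADIUS
    transverse_radius: float = D.TRANSVERSE_RADIUS
    span_deg: tuple[float, float] = D.PROFILE_SPAN_DEG
    tibial_groove_deg: tuple[float, float] = D.TIBIAL_GROOVE_DEG
    fibular_groove_deg: tuple[float, float] = D.FIBULAR_GROOVE_DEG
    flattening: float = Field(default=D.STACK_FLATTENING, ge=0.0, lt=1.0)
    tibial_orientation_deg: float = D.TIBIAL_ORIENTATION_DEG
    fibular_orientation_deg: float = D.FIBULAR_ORIENTATION_DEG
    flat_fraction: float = D.FLAT_FRACTION
    noise_sigma: float = Field(default=D.STACK_NOISE_SIGMA, ge=0.0)
    points_per_section: int = Field(default=D.STACK_POINTS_PER_SECTION, ge=20)
    seed: int = 0

    @model_validator(mode="after")
    def _ordering(self):
        if not (1 <= self.fibular_trough_index < self.crista_index
                < self.tibial_trough_index <= self.n_sections):
            raise ValueError(
                "landmark ordering must be fibular < crista < tibial within the stack")
        return self

    @property
    def crista_z(self) -> float:
        return self.crista_index * SECTION_SPACING


@dataclass(frozen=True)
class Section:
    index: int
    z: float
    points: np.ndarray  # (n, 2) contour samples


@dataclass
class SectionStack:
    """An indexed series of section contours at 0.5-mm spacing."""

    sections: list[Section]
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        idx = [s.index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise GeometryError("section indices must be strictly increasing")
        for s in self.sections:
            if abs(s.z - s.index * SECTION_SPACING) > 1e-9:
                raise GeometryError("section spacing must be exactly 0.5 mm")

    def section(self, index: int) -> Section:
        for s in self.sections:
            if s.index == index:
                return s
        raise KeyError(f"no section with index {index}")

    # -- disk I/O: one CSV per section, x,y header, 9 significant digits --
    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.sections:
            lines = ["x,y"]
            lines += [f"{p[0]:.9g},{p[1]:.9g}" for p in s.points]
            (outdir / f"section_{s.index:03d}.csv").write_text(
                "\n".join(lines) + "\n")
        if self.ground_truth is not None:
            (outdir / "ground_truth.json").write_text(
                json.dumps(self.ground_truth, sort_keys=True, indent=2) + "\n")

    @classmethod
    def read_dir(cls, indir) -> "SectionStack":
        indir = Path(indir)
        sections = []
        for f in sorted(indir.glob("section_*.csv")):
            index = int(f.stem.split("_")[1])
            pts = np.loadtxt(f, delimiter=",", skiprows=1)
            sections.append(Section(index, index * SECTION_SPACING, pts))
        if not sections:
            raise GeometryError(f"no section CSVs found in {indir}")
        gt = None
        gt_file = indir / "ground_truth.json"
        if gt_file.exists():
            gt = json.loads(gt_file.read_text())
        return cls(sections, gt)


# ---------------------------------------------------------------------------
# generation

# Transverse depth law of each groove, as a function of the normalized
# medial-lateral coordinate u = (z - z_crista) / (z_trough - z_crista):
# a steep ramp away from the narrow crista ridge plus a bump peaked at the
# trough, decaying to a plateau toward the head margin.  Only the crista
# section itself is groove-free.
_RAMP_W, _RAMP_P = 0.6, 0.02
_PEAK_W = 0.12


def _depth_profile(u: float) -> float:
    if u <= 0.0:
        return 0.0
    ramp = _RAMP_W * min(u, 1.0) ** _RAMP_P
    peak = (1.0 - _RAMP_W) * math.exp(-(((u - 1.0) / _PEAK_W) ** 2))
    return ramp + peak


def _section_radius(spec: StackGenSpec, z: float) -> float:
    dz = (z - spec.crista_z) / spec.transverse_radius
    frac = max(1.0 - dz * dz, 0.0625)  # floor: head margins stay finite
    return spec.sagittal_radius * math.sqrt(frac)


def _section_profile(spec: StackGenSpec, index: int):
    """Noise-free contour geometry of one section (profile, flattening)."""
    z = index * SECTION_SPACING
    r = _section_radius(spec, z)
    if index > spec.crista_index:
        u = (z - spec.crista_z) / (
            spec.tibial_trough_index * SECTION_SPACING - spec.crista_z)
        f = spec.flattening * _depth_profile(u)
        groove = spec.tibial_groove_deg
        nu = spec.tibial_orientation_deg - 90.0
    elif index < spec.crista_index:
        u = (spec.crista_z - z) / (
            spec.crista_z - spec.fibular_trough_index * SECTION_SPACING)
        f = spec.flattening * _depth_profile(u)
        groove = spec.fibular_groove_deg
        nu = spec.fibular_orientation_deg - 90.0
    else:
        f, groove, nu = 0.0, spec.tibial_groove_deg, None
    prof = _grooved_profile_origin(r, spec.span_deg, groove[0], groove[1],
                                   f, nu, spec.flat_fraction)
    return prof, f


def generate_stack(spec: StackGenSpec) -> SectionStack:
    """Deterministically generate a synthetic stack from its spec."""
    rng = np.random.default_rng(spec.seed)
    sections = []
    gt_flat = {}
    for index in range(1, spec.n_sections + 1):
        prof, f = _section_profile(spec, index)
        pts = prof.sample(spec.points_per_section)
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
        sections.append(Section(index, index * SECTION_SPACING, pts))
        gt_flat[index] = f
    gt = {
        "spec": spec.model_dump(),
        "landmarks": {
            "crista_index": spec.crista_index,
            "tibial_trough_index": spec.tibial_trough_index,
            "fibular_trough_index": spec.fibular_trough_index,
        },
        "section_flattening": {str(k): v for k, v in gt_flat.items()},
    }
    return SectionStack(sections, gt)


# ---------------------------------------------------------------------------
# landmark location


def _section_deviation(points: np.ndarray):
    """Robust per-section deviation profile below the baseline circle.

    Fits the baseline circle to the full contour, iteratively excluding the
    most inward-deviating quarter (the groove region), then returns the
    plantar points' polar angles, their inward deviations, and the fitted
    radius, sorted by angle.
    """
    center, radius, _ = fit_circle(points)
    for _ in range(3):
        dev_all = radius - np.hypot(points[:, 0] - center[0],
                                    points[:, 1] - center[1])
        # exclude inward outliers (the groove) by a robust scale estimate
        scale = 1.4826 * float(np.median(np.abs(dev_all - np.median(dev_all))))
        keep = dev_all <= 2.0 * max(scale, 1e-6)
        if keep.sum() < 10:
            raise MissingLandmarkError("section contour too sparse")
        center, radius, _ = fit_circle(points[keep])
    ang = np.degrees(np.arctan2(points[:, 1] - center[1],
                                points[:, 0] - center[0]))
    mask = ang < 0.0
    if mask.sum() < 10:
        raise MissingLandmarkError("section lacks plantar contour points")
    a = ang[mask]
    dev = radius - np.hypot(points[mask, 0] - center[0],
                            points[mask, 1] - center[1])
    order = np.argsort(a)
    return a[order], dev[order], float(radius)


_WINDOW_DEG = 30.0


def _window_mean(a: np.ndarray, dev: np.ndarray, center_deg: float) -> float:
    w = (a >= center_deg - _WINDOW_DEG / 2) & (a <= center_deg + _WINDOW_DEG / 2)
    if w.sum() < 8:
        return math.nan
    return float(dev[w].mean())


def _sliding_extrema(a: np.ndarray, dev: np.ndarray):
    """(max window mean, its center angle, min window mean) over windows."""
    best, best_c, worst = -np.inf, math.nan, np.inf
    for c in np.arange(a[0] + _WINDOW_DEG / 2, a[-1] - _WINDOW_DEG / 2 + 1e-9,
                       _WINDOW_DEG / 4):
        m = _window_mean(a, dev, c)
        if math.isnan(m):
            continue
        if m > best:
            best, best_c = m, c
        worst = min(worst, m)
    if not np.isfinite(best):
        raise MissingLandmarkError("no usable plantar window")
    return best, best_c, worst


def _refine_extremum(depths: np.ndarray, indices: np.ndarray, i_best: int,
                     sign: float, halfwin: int = 2) -> int:
    """Round the vertex of a local quadratic fit around an extremum
    (sign=+1 for a depth maximum, -1 for the crista minimum)."""
    j = int(np.where(indices == i_best)[0][0])
    lo, hi = max(j - halfwin, 0), min(j + halfwin + 1, len(indices))
    if hi - lo < 3:
        return i_best
    x = indices[lo:hi].astype(float)
    c = np.polyfit(x, sign * depths[lo:hi], 2)
    if c[0] >= 0:
        return i_best
    vertex = -c[1] / (2 * c[0])
    vertex = min(max(vertex, x[0]), x[-1])
    return int(round(vertex))


def locate_landmarks(stack: SectionStack,
                     detection_factor: float = 4.0) -> tuple[int, int, int]:
    """Recover (crista, tibial trough, fibular trough) section indices.

    Per section, groove depth is the largest sliding-window mean of inward
    deviations below a robust baseline circle, normalized by the section
    radius.  The two groove troughs are the two separated peaks of the
    (lightly smoothed) depth profile, refined by a local quadratic vertex;
    the crista is the depth minimum between them, re-measured in the fixed
    angular windows where the grooves actually run, so its statistic is
    not inflated by the sliding maximum.  Raises
    :class:`MissingLandmarkError` for stacks without detectable grooves:
    depth peaks must stand above the noise floor estimated from outward
    deviations (which a groove cannot produce) and must keep a consistent
    angular position across neighboring sections.
    """
    if len(stack.sections) < 5:
        raise MissingLandmarkError("need at least 5 sections")
    rows = []
    for s in stack.sections:
        try:
            a, dev, radius = _section_deviation(s.points)
            dmax, dcenter, dmin = _sliding_extrema(a, dev)
        except (DegenerateFitError, MissingLandmarkError):
            continue
        rows.append((s.index, dmax / radius, dcenter, dmin / radius, radius, a, dev))
    if len(rows) < 5:
        raise MissingLandmarkError("fewer than 5 usable sections")
    radii = np.array([r[4] for r in rows])
    # landmarks live on substantial mid-head sections, not head margins
    rows = [r for r, keep in zip(rows, radii > 0.85 * radii.max()) if keep]
    if len(rows) < 5:
        raise MissingLandmarkError("fewer than 5 usable mid-head sections")
    indices = np.array([r[0] for r in rows])
    depths = np.array([r[1] for r in rows])

    smooth = depths.copy()
    smooth[1:-1] = 0.25 * depths[:-2] + 0.5 * depths[1:-1] + 0.25 * depths[2:]
    # noise scale from the high-frequency residual of the depth profile;
    # genuine groove structure is smooth across sections and does not
    # contribute
    resid = depths - smooth
    noise_floor = 1.4826 * float(np.median(np.abs(resid - np.median(resid)))) + 1e-12
    j1 = int(np.argmax(smooth))
    far = np.abs(indices - indices[j1]) >= 6
    if not far.any():
        raise MissingLandmarkError("stack too narrow to separate two grooves")
    j2 = int(np.argmax(np.where(far, smooth, -np.inf)))
    p_fib, p_tib = sorted([j1, j2])

    troughs = {}
    centers = {}
    for name, j in (("fibular", p_fib), ("tibial", p_tib)):
        if smooth[j] < detection_factor * noise_floor:
            raise MissingLandmarkError(
                f"{name} groove depth ({smooth[j]:.3g}) indistinguishable "
                f"from the noise floor ({noise_floor:.3g})")
        c_best = rows[j][2]
        neigh = [rows[k][2] for k in (j - 1, j + 1) if 0 <= k < len(rows)]
        # a real groove runs at a consistent angular position through the
        # adjacent sections; isolated noise maxima wander
        if neigh and max(abs(c - c_best) for c in neigh) > 15.0:
            raise MissingLandmarkError(
                f"{name} depth peak at section {rows[j][0]} is not "
                "angularly consistent with its neighbors (no coherent groove)")
        troughs[name] = _refine_extremum(smooth, indices, int(indices[j]),
                                         sign=1.0)
        centers[name] = c_best

    between = (indices > troughs["fibular"]) & (indices < troughs["tibial"])
    if between.sum() < 3:
        raise MissingLandmarkError("troughs leave no inter-trough valley")
    v_idx, v_dep = [], []
    for r, m in zip(rows, between):
        if not m:
            continue
        vals = [_window_mean(r[5], r[6], centers[n]) / r[4]
                for n in ("tibial", "fibular")]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            v_idx.append(r[0])
            v_dep.append(sum(vals))
    if len(v_idx) < 3:
        raise MissingLandmarkError("inter-trough valley too sparse")
    v_idx = np.array(v_idx)
    v_dep = np.array(v_dep)
    # the valley is cliff-shaped at the narrow crista ridge: the raw
    # argmin is the right estimator (a quadratic vertex would be biased)
    crista = int(v_idx[int(np.argmin(v_dep))])
    return crista, troughs["tibial"], troughs["fibular"]


# ---------------------------------------------------------------------------
# model recovery


def _pooled_groove_fit(stack: SectionStack, trough_idx: int, side: str,
                       span0: tuple[float, float], orient0: float,
                       flat_fraction: float):
    """Recover one groove's angular geometry by pooling flank sections.

    The groove's inception/termination angles and flat-arc attitude are
    shared by every section that cuts the groove; pooling the sections
    around the trough (each with its own depth) breaks most of the span/
    attitude/depth trade-off of a single-section fit.  The residual
    degeneracy is the sign of the curvature skew (which end of the groove
    carries the sharp curl): under digitization noise the two signs can
    fit a contour almost equally well, so the template constrains the
    relative skew to the anatomical family of the groove being fitted --
    tibial grooves curve sharply right at their inception, fibular
    grooves at their termination -- and the data determine its magnitude.
    Returns (phi1, phi2, nu, f_trough).
    """
    indices = sorted(s.index for s in stack.sections)
    secs = [i for i in range(trough_idx - 4, trough_idx + 5) if i in indices]
    prep = []
    for i in secs:
        pts = stack.section(i).points
        center, r, _ = fit_circle(pts)
        for _ in range(3):
            dev_all = r - np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
            scale = 1.4826 * float(np.median(np.abs(dev_all - np.median(dev_all))))
            keep = dev_all <= 2.0 * max(scale, 1e-6)
            center, r, _ = fit_circle(pts[keep])
        prep.append((pts - center, r))
    span_lo, span_hi = D.PROFILE_SPAN_DEG
    rel0 = (orient0 - 90.0) - 0.5 * (span0[0] + span0[1])

    def resid(x):
        p1, p2, rel = x[:3]
        nu = 0.5 * (p1 + p2) + rel
        fs = x[3:]
        out = []
        for (pts, r), f in zip(prep, fs):
            try:
                prof = _grooved_profile_origin(r, (span_lo, span_hi), p1, p2,
                                               float(np.clip(f, 0.0, 0.55)),
                                               nu, flat_fraction)
            except GeometryError:
                out.append(np.full(len(pts), 1e3))
                continue
            out.append(prof.distances(pts))
        return np.concatenate(out)

    n = len(secs)
    if rel0 < 0:        # tibial family: curl at inception
        rel_lo, rel_hi = -8.0, -0.5
    else:               # fibular family: curl at termination
        rel_lo, rel_hi = 0.5, 8.0
    lo = [span0[0] - 8.0, span0[1] - 8.0, rel_lo] + [0.0] * n
    hi = [span0[0] + 8.0, span0[1] + 8.0, rel_hi] + [0.55] * n
    x0 = np.array([span0[0], span0[1], rel0] + [0.25] * n)
    out = least_squares(resid, x0, bounds=(lo, hi),
                        x_scale=[1.0, 1.0, 1.0] + [0.05] * n,
                        xtol=1e-11, ftol=1e-11, gtol=1e-11, max_nfev=400)
    if not np.all(np.isfinite(out.x)):
        raise FitFailureError(f"{side} groove pooled fit failed: {out.message}")
    # unbounded quadratic polish; kept only while it honors the family
    polish = least_squares(resid, out.x, method="lm", xtol=1e-15, ftol=1e-15,
                           max_nfev=200)
    px = polish.x
    if (polish.cost <= out.cost
            and lo[0] <= px[0] <= hi[0] and lo[1] <= px[1] <= hi[1]
            and rel_lo - 0.5 <= px[2] <= rel_hi + 0.5):
        out = polish

    rms = math.sqrt(2.0 * out.cost / sum(len(p) for p, _ in prep))
    if rms < 1e-3:
        # essentially noise-free contours: the robust per-section centers
        # carry a small groove-induced bias, so refit jointly with every
        # section's center and radius free to make the round trip exact
        pts_list = [p for p, _ in prep]

        def full_resid(x):
            p1, p2, rel = x[:3]
            nu = 0.5 * (p1 + p2) + rel
            outr = []
            for k, pts in enumerate(pts_list):
                f = x[3 + k]
                cx, cy, r = x[3 + n + 3 * k: 6 + n + 3 * k]
                try:
                    prof = _grooved_profile_origin(
                        r, (span_lo, span_hi), p1, p2,
                        float(np.clip(f, 0.0, 0.55)), nu, flat_fraction)
                except GeometryError:
                    outr.append(np.full(len(pts), 1e3))
                    continue
                outr.append(prof.distances(pts - [cx, cy]))
            return np.concatenate(outr)

        xf0 = np.concatenate([out.x,
                              np.ravel([[0.0, 0.0, r] for _, r in prep])])
        full = least_squares(full_resid, xf0, method="lm", xtol=1e-15,
                             ftol=1e-15, max_nfev=2000, diff_step=1e-7)
        if full.cost <= out.cost:
            out = full

    p1, p2, rel = out.x[:3]
    f_trough = float(out.x[3 + secs.index(trough_idx)])
    return float(p1), float(p2), float(0.5 * (p1 + p2) + rel), f_trough


def stack_to_model(stack: SectionStack,
                   landmarks: Optional[tuple[int, int, int]] = None) -> JointModel:
    """Build a posable joint model from a section stack.

    The crista section yields the head radius by circle fit; each groove's
    angular span, flattening and flat-arc attitude come from a pooled fit
    of the sections flanking its trough.  Platform bodies and the sweep
    use the package defaults scaled to the recovered radius.
    """
    if landmarks is None:
        landmarks = locate_landmarks(stack)
    crista_idx, tib_idx, fib_idx = landmarks
    try:
        _, radius, _ = fit_circle(stack.section(crista_idx).points)
    except DegenerateFitError as e:
        raise GeometryError(f"crista section {crista_idx}: {e}") from e

    grooves = {}
    for name, idx, span0, orient0 in (
            ("tibial", tib_idx, D.TIBIAL_GROOVE_DEG, D.TIBIAL_ORIENTATION_DEG),
            ("fibular", fib_idx, D.FIBULAR_GROOVE_DEG, D.FIBULAR_ORIENTATION_DEG)):
        try:
            p1, p2, nu, f = _pooled_groove_fit(stack, idx, name, span0, orient0,
                                               D.FLAT_FRACTION)
        except GeometryError as e:
            raise GeometryError(f"{name} trough section {idx}: {e}") from e
        grooves[name] = GrooveSpec(
            inception_deg=p1,
            termination_deg=p2,
            flattening=f,
            orientation_deg=nu + 90.0,
            flat_fraction=D.FLAT_FRACTION,
        )

    head = MetatarsalHead(
        sagittal_radius=radius,
        transverse_radius=radius * D.TRANSVERSE_RADIUS / D.SAGITTAL_RADIUS,
        tibial_groove=grooves["tibial"],
        fibular_groove=grooves["fibular"],
    )
    scale = radius / D.SAGITTAL_RADIUS

    def ses(label, angle, zoff):
        d = radius + D.SESAMOID_RADIUS
        a = math.radians(angle)
        return SesamoidBody(label=label, center=(d * math.cos(a), d * math.sin(a)),
                            z_offset=zoff, radius=D.SESAMOID_RADIUS)

    return JointModel(
        head=head,
        tibial_sesamoid=ses("tibial", D.TIBIAL_ANGLE_DEG,
                            (tib_idx - crista_idx) * SECTION_SPACING),
        fibular_sesamoid=ses("fibular", D.FIBULAR_ANGLE_DEG,
                             (fib_idx - crista_idx) * SECTION_SPACING),
        phalanx=PhalanxContact(center=(radius + D.PHALANX_RADIUS * scale, 0.0),
                               radius=D.PHALANX_RADIUS * scale),
        sweep=SweepSpec(),
    )
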