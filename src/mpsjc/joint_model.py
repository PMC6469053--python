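"""Domain model of the metatarso-phalangeal-sesamoid joint complex.

The metatarsal head rotates over a functionally stationary "platform"
formed by the two sesamoids and the proximal phalanx base.  The head is
represented plane-wise by three sagittal sections: the crista section
(pure circle), and the tibial and fibular groove sections (circle with a
flattened three-arc insert).  The configuration of the joint at an instant
is the declination angle theta plus the rigid pose it induces.

All public angles are degrees, lengths are model units (nominally mm).
Platform frame: +x distal, +y dorsal, +z medial (right foot); a
"proximal shift" is a decrease in x.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import defaults as D
from .geometry2d import (
    CircleArc,
    CompositeProfile,
    GeometryError,
    RigidTransform2,
    flattened_insert,
)

SCHEMA_VERSION = 1


class GrooveSpec(BaseModel):
    """A sesamoid groove on the head circle.

    The groove replaces the circle between ``inception_deg`` (proximal
    junction, the reference point T or F) and ``termination_deg`` (where
    groove depth has completely diminished) by a flattened C1 insert.
    ``orientation_deg`` is the attitude of the flat surface's mid-tangent
    relative to the metatarsal long axis; it places the flat within the
    groove and thereby selects where the surface curvature concentrates.
    """

    inception_deg: float
    termination_deg: float
    flattening: float = Field(ge=0.0, lt=1.0)
    orientation_deg: float
    flat_fraction: float = Field(default=D.FLAT_FRACTION, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.inception_deg < self.termination_deg:
            raise ValueError("groove inception must precede termination")
        return self

    @property
    def flat_center_deg(self) -> float:
        """Polar direction of the flat arc's midpoint normal."""
        return self.orientation_deg - 90.0


class SesamoidBody(BaseModel):
    """A sesamoid modeled as a circle in its sagittal plane at ``z_offset``."""

    label: Literal["tibial", "fibular"]
    center: tuple[float, float]
    z_offset: float
    radius: float = Field(gt=0.0)

    @property
    def center_arr(self) -> np.ndarray:
        return np.array(self.center, dtype=float)


class PhalanxContact(BaseModel):
    """Circular support for the proximal phalanx base (radius 0 = point)."""

    center: tuple[float, float]
    radius: float = Field(ge=0.0)

    @property
    def center_arr(self) -> np.ndarray:
        return np.array(self.center, dtype=float)


class SweepSpec(BaseModel):
    """Declination-angle sweep from static stance to terminal propulsion."""

    theta0_deg: float = D.THETA0_DEG
    thetaM_deg: float = D.THETA_M_DEG
    n_steps: int = Field(default=D.N_STEPS, ge=2)

    @model_validator(mode="after")
    def _range(self):
        if not self.thetaM_deg > self.theta0_deg:
            raise ValueError("thetaM must exceed theta0")
        if not (12.0 <= self.theta0_deg <= 20.0):
            warnings.warn("theta0 outside the typical 12-20 deg stance range",
                          stacklevel=2)
        if not (65.0 <= self.thetaM_deg <= 75.0):
            warnings.warn("thetaM outside the typical 65-75 deg terminal range",
                          stacklevel=2)
        return self

    def grid(self) -> np.ndarray:
        return np.linspace(self.theta0_deg, self.thetaM_deg, self.n_steps)


class MetatarsalHead(BaseModel):
    """The rotating element: a spherical head with two plantar grooves.

    ``distal_flattening`` > 0 inserts an additional flattened region on the
    distal (phalanx-facing) arc; it models the flattened articular surface
    of hallux limitus / rigidus morphology and is 0 for a normal head.
    """

    sagittal_radius: float = Field(gt=0.0)
    transverse_radius: float = Field(gt=0.0)
    span_deg: tuple[float, float] = D.PROFILE_SPAN_DEG
    tibial_groove: GrooveSpec
    fibular_groove: GrooveSpec
    long_axis: tuple[float, float] = (-1.0, 0.0)
    shaft_length: float = D.SHAFT_LENGTH_MM
    distal_flattening: float = Field(default=0.0, ge=0.0, lt=1.0)
    distal_flat_span_deg: tuple[float, float] = (25.0, 55.0)

    @property
    def long_axis_arr(self) -> np.ndarray:
        v = np.array(self.long_axis, dtype=float)
        return v / np.hypot(*v)

    def _grooved(self, groove: GrooveSpec) -> CompositeProfile:
        R = self.sagittal_radius
        arcs = [CircleArc(np.zeros(2), R, self.span_deg[0], groove.inception_deg)]
        arcs += flattened_insert(R, groove.inception_deg, groove.termination_deg,
                                 groove.flattening, groove.flat_center_deg,
                                 groove.flat_fraction)
        if self.distal_flattening > 0.0:
            a, b = self.distal_flat_span_deg
            arcs += [CircleArc(np.zeros(2), R, groove.termination_deg, a)]
            arcs += flattened_insert(R, a, b, self.distal_flattening)
            arcs += [CircleArc(np.zeros(2), R, b, self.span_deg[1])]
        else:
            arcs += [CircleArc(np.zeros(2), R, groove.termination_deg,
                               self.span_deg[1])]
        return CompositeProfile(arcs, check=False)

    @cached_property
    def crista_profile(self) -> CompositeProfile:
        """Sagittal section through the inter-sesamoidal ridge: a circle."""
        if self.distal_flattening > 0.0:
            a, b = self.distal_flat_span_deg
            arcs = [CircleArc(np.zeros(2), self.sagittal_radius, self.span_deg[0], a)]
            arcs += flattened_insert(self.sagittal_radius, a, b, self.distal_flattening)
            arcs += [CircleArc(np.zeros(2), self.sagittal_radius, b, self.span_deg[1])]
            return CompositeProfile(arcs, check=False)
        return CompositeProfile(
            [CircleArc(np.zeros(2), self.sagittal_radius, *self.span_deg)],
            check=False)

    @cached_property
    def tibial_plane_profile(self) -> CompositeProfile:
        return self._grooved(self.tibial_groove)

    @cached_property
    def fibular_plane_profile(self) -> CompositeProfile:
        return self._grooved(self.fibular_groove)

    def profile(self, plane: str) -> CompositeProfile:
        return {"tibial": self.tibial_plane_profile,
                "fibular": self.fibular_plane_profile,
                "crista": self.crista_profile}[plane]


class JointModel(BaseModel):
    """A fully specified joint: head, platform bodies, and sweep."""

    schema_version: int = SCHEMA_VERSION
    units: dict = {"length": "mm", "angle": "deg"}
    head: MetatarsalHead
    tibial_sesamoid: SesamoidBody
    fibular_sesamoid: SesamoidBody
    phalanx: PhalanxContact
    sweep: SweepSpec = SweepSpec()

    def sesamoid(self, plane: str) -> SesamoidBody:
        return self.tibial_sesamoid if plane == "tibial" else self.fibular_sesamoid

    # canonical JSON (sorted keys) so that serialization round-trips are
    # byte-identical
    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "JointModel":
        return cls.model_validate(json.loads(text))


@dataclass(frozen=True)
class JointConfiguration:
    """The metatarsal pose at one declination angle.

    ``pose`` maps bone-frame coordinates to the platform frame; its
    rotation is fixed at ``-theta`` (the bone rotates clockwise, plantar-
    flexing over the platform, as declination grows) and its translation
    is solved from the two tangency constraints.
    """

    theta_deg: float
    pose: RigidTransform2

    @classmethod
    def from_theta(cls, theta_deg: float,
                   translation=(0.0, 0.0)) -> "JointConfiguration":
        return cls(theta_deg, RigidTransform2(-theta_deg, np.asarray(translation, float)))

    def long_axis_world(self, head: MetatarsalHead) -> np.ndarray:
        return self.pose.apply_vec(head.long_axis_arr)


@dataclass(frozen=True)
class Violation:
    invariant: str
    field: str
    message: str

    def __str__(self):
        return f"[{self.invariant}] {self.field}: {self.message}"


def default_model() -> JointModel:
    """The reference joint model used throughout the package.

    theta runs 15 -> 70 deg; the tibial sesamoid sits more distal than the
    fibular one and its groove inception is more distal; the transverse
    radius slightly exceeds the sagittal radius.
    """
    head = MetatarsalHead(
        sagittal_radius=D.SAGITTAL_RADIUS,
        transverse_radius=D.TRANSVERSE_RADIUS,
        tibial_groove=GrooveSpec(
            inception_deg=D.TIBIAL_GROOVE_DEG[0],
            termination_deg=D.TIBIAL_GROOVE_DEG[1],
            flattening=D.GROOVE_FLATTENING,
            orientation_deg=D.TIBIAL_ORIENTATION_DEG,
        ),
        fibular_groove=GrooveSpec(
            inception_deg=D.FIBULAR_GROOVE_DEG[0],
            termination_deg=D.FIBULAR_GROOVE_DEG[1],
            flattening=D.GROOVE_FLATTENING,
            orientation_deg=D.FIBULAR_ORIENTATION_DEG,
        ),
    )
    return JointModel(
        head=head,
        tibial_sesamoid=SesamoidBody(
            label="tibial", center=D.sesamoid_center(D.TIBIAL_ANGLE_DEG),
            z_offset=D.TIBIAL_Z_MM, radius=D.SESAMOID_RADIUS),
        fibular_sesamoid=SesamoidBody(
            label="fibular", center=D.sesamoid_center(D.FIBULAR_ANGLE_DEG),
            z_offset=D.FIBULAR_Z_MM, radius=D.SESAMOID_RADIUS),
        phalanx=PhalanxContact(center=(D.SAGITTAL_RADIUS + D.PHALANX_RADIUS, 0.0),
                               radius=D.PHALANX_RADIUS),
        sweep=SweepSpec(),
    )


def validate(model: JointModel) -> list[Violation]:
    """Check every cross-field invariant; violations are data, not errors."""
    v: list[Violation] = []
    head = model.head
    if head.transverse_radius < head.sagittal_radius:
        v.append(Violation(
            "radius-ordering", "head.transverse_radius",
            "transverse radius must be >= the sagittal (crista) radius"))
    if not model.tibial_sesamoid.z_offset > model.fibular_sesamoid.z_offset:
        v.append(Violation(
            "sesamoid-plane-order", "tibial_sesamoid.z_offset",
            "tibial plane must be medial (+z) of the fibular plane"))
    if not model.tibial_sesamoid.center[0] > model.fibular_sesamoid.center[0]:
        v.append(Violation(
            "sesamoid-order", "tibial_sesamoid.center",
            "tibial sesamoid must sit more distal (+x) than the fibular"))
    if not head.tibial_groove.inception_deg > head.fibular_groove.inception_deg:
        v.append(Violation(
            "groove-inception-order", "head.tibial_groove.inception_deg",
            "tibial groove inception must be more distal than the fibular"))
    for name, groove in (("tibial", head.tibial_groove),
                         ("fibular", head.fibular_groove)):
        s0, s1 = head.span_deg
        if not (s0 < groove.inception_deg < groove.termination_deg < s1):
            v.append(Violation("groove-span", f"head.{name}_groove",
                               "groove must lie inside the profile span"))
    # geometric feasibility + convexity of the composed profiles
    for plane in ("tibial", "fibular", "crista"):
        try:
            prof = head.profile(plane)
        except GeometryError as e:
            v.append(Violation("profile-construction", f"head.{plane}", str(e)))
            continue
        for msg in prof.validate():
            v.append(Violation("profile-invariant", f"head.{plane}", msg))
    # groove plane profiles must share the crista's dorsal circle
    if not v:
        R = head.sagittal_radius
        for plane in ("tibial", "fibular"):
            prof = head.profile(plane)
            dorsal = prof.point_at(prof.length * 0.98)
            if abs(np.hypot(*dorsal) - R) > 1e-6:
                v.append(Violation(
                    "shared-dorsal-arc", f"head.{plane}",
                    "groove profile must share the crista's dorsal circle"))
    return v
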