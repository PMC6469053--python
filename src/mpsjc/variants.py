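"""Variant joint morphologies and their qualitative ICR predictions.

Clinically discussed deviations from normal joint geometry (proximally
positioned sesamoids, a rounded or flattened metatarsal edge, an everted
sesamoid apparatus, a more distal tibial sesamoid, a short metatarsal)
are encoded as parameter presets.  Each preset carries the direction in
which the common instantaneous center is expected to displace; the check
runs declination sweeps on the base and variant models and compares.

Measurement note.  For a spherical head the least-squares common center
of the contact normals is exactly the sphere center, which tangency
closure pins regardless of where the sesamoids sit -- so frontal
repositioning cannot move that point.  Directional predictions are
therefore measured on the functional center of the joint axis: the
sweep-mean of the per-plane centers of rotation embedded at their plane
offsets (identical to the 3D ICR when the normals are concurrent, but
sensitive to which planes carry the rotation).  The compound label
"lateral-proximal" follows from the obliquity of the transverse axis
through the sesamoid contacts (a more distal tibial contact tilts that
axis), so it is assessed from the axis obliquity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

from .geometry2d import GeometryError
from .icr_engine import Trajectory, sweep, x_axis_obliquity
from .joint_model import JointModel, validate

__all__ = [
    "VariantError",
    "VariantSpec",
    "PredictionCheck",
    "apply_variant",
    "check_prediction",
    "load_preset",
    "preset_names",
    "builtin_presets",
]

Displacement = Literal["proximal", "distal", "medial-plantar",
                       "lateral-proximal", "none"]

# direction axes for nearest-label binning of a 3D displacement
# (platform frame: +x distal, +y dorsal, +z medial)
_AXES: dict[str, np.ndarray] = {
    "proximal": np.array([-1.0, 0.0, 0.0]),
    "distal": np.array([1.0, 0.0, 0.0]),
    "medial-plantar": np.array([0.0, -1.0, 1.0]) / math.sqrt(2),
    "lateral-proximal": np.array([-1.0, 0.0, -1.0]) / math.sqrt(2),
}


class VariantError(GeometryError):
    """A variant transform produced an invalid model."""


class VariantSpec(BaseModel):
    """A named morphology edit plus its predicted ICR response.

    ``transform`` is a list of JSON-serializable operations applied in
    order; supported ops:

    * ``{"op": "translate_sesamoids", "dx": .., "dy": ..}`` -- both bodies
    * ``{"op": "translate_sesamoid", "label": .., "dx": .., "dy": ..}``
    * ``{"op": "rotate_sesamoids_frontal", "angle_deg": ..}`` -- rotate the
      sesamoid pair about the metatarsal long axis through the head center
      (positive = everted bone, pair swings medial); in the three-plane
      representation this moves the plane offsets while each sesamoid's
      in-plane tangency distance is preserved
    * ``{"op": "rotate_sesamoids_arc", "angle_deg": ..}`` -- slide both
      sesamoids along the articular arc about the head center (negative =
      seated more proximal)
    * ``{"op": "scale_head_radius", "factor": ..}``
    * ``{"op": "set", "path": "a.b.c", "value": ..}``
    * ``{"op": "scale", "path": "a.b.c", "factor": ..}``
    """

    name: str
    description: str = ""
    transform: list[dict] = Field(default_factory=list)
    predicted_displacement: Displacement = "none"
    predicted_mobility: Literal["increased-frontal", "restricted-sagittal",
                                "none"] = "none"


@dataclass
class PredictionCheck:
    """Outcome of testing one preset against a base model."""

    name: str
    confirmed: bool
    predicted: str
    measured_label: str
    displacement: np.ndarray          # sweep-mean ICR displacement (x, y, z)
    obliquity_base: float
    obliquity_variant: float
    metrics: dict = field(default_factory=dict)


def _dig(d: dict, path: str):
    keys = path.split(".")
    for k in keys[:-1]:
        d = d[k]
    return d, keys[-1]


def apply_variant(model: JointModel, spec: VariantSpec) -> JointModel:
    """Apply a preset's transform; the result must still be a valid model."""
    data = model.model_dump()
    for op in spec.transform:
        kind = op["op"]
        if kind == "translate_sesamoids":
            for key in ("tibial_sesamoid", "fibular_sesamoid"):
                c = data[key]["center"]
                data[key]["center"] = (c[0] + op.get("dx", 0.0),
                                       c[1] + op.get("dy", 0.0))
        elif kind == "translate_sesamoid":
            key = f"{op['label']}_sesamoid"
            c = data[key]["center"]
            data[key]["center"] = (c[0] + op.get("dx", 0.0),
                                   c[1] + op.get("dy", 0.0))
        elif kind == "rotate_sesamoids_frontal":
            a = math.radians(op["angle_deg"])
            for key in ("tibial_sesamoid", "fibular_sesamoid"):
                y = data[key]["center"][1]
                z = data[key]["z_offset"]
                data[key]["z_offset"] = -y * math.sin(a) + z * math.cos(a)
        elif kind == "rotate_sesamoids_arc":
            a = math.radians(op["angle_deg"])
            for key in ("tibial_sesamoid", "fibular_sesamoid"):
                x, y = data[key]["center"]
                r, ang = math.hypot(x, y), math.atan2(y, x) + a
                data[key]["center"] = (r * math.cos(ang), r * math.sin(ang))
        elif kind == "scale_head_radius":
            f = op["factor"]
            data["head"]["sagittal_radius"] *= f
            data["head"]["transverse_radius"] *= f
        elif kind == "set":
            parent, leaf = _dig(data, op["path"])
            parent[leaf] = op["value"]
        elif kind == "scale":
            parent, leaf = _dig(data, op["path"])
            parent[leaf] = parent[leaf] * op["factor"]
        else:
            raise VariantError(f"unknown transform op {kind!r}")
    out = JointModel(**data)
    violations = validate(out)
    if violations:
        raise VariantError(
            "variant produces an invalid model: "
            + "; ".join(str(v) for v in violations))
    return out


def _cr_scatter(traj: Trajectory) -> float:
    pts = np.vstack([traj.cr_xy("tibial"), traj.cr_xy("fibular")])
    return float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))


def _nearest_label(delta: np.ndarray) -> str:
    u = delta / np.linalg.norm(delta)
    return max(_AXES, key=lambda k: float(u @ _AXES[k]))


def axis_center_mean(traj: Trajectory, model: JointModel) -> np.ndarray:
    """Sweep-mean functional center of the joint axis.

    The per-plane centers of rotation, embedded at their plane offsets,
    anchor the instantaneous rotation axis; their sweep-mean midpoint
    coincides with the 3D ICR when the three normals are concurrent.
    """
    pts = []
    for plane in ("tibial", "fibular"):
        xy = traj.cr_xy(plane)
        z = model.sesamoid(plane).z_offset
        pts.append(np.column_stack([xy, np.full(len(xy), z)]).mean(axis=0))
    return 0.5 * (pts[0] + pts[1])


def check_prediction(base: JointModel, spec: VariantSpec,
                     base_traj: Optional[Trajectory] = None,
                     excursion_tol: Optional[float] = None) -> PredictionCheck:
    """Measure a preset's ICR displacement and compare with its prediction.

    Directional predictions are binned to the nearest direction axis (or,
    for "lateral-proximal", read off the transverse-axis obliquity);
    "none" predictions are vacuously confirmed when the displacement
    stays below the excursion tolerance.
    """
    R = base.head.sagittal_radius
    tol = 0.005 * R if excursion_tol is None else excursion_tol
    variant = apply_variant(base, spec)
    if base_traj is None:
        base_traj = sweep(base)
    var_traj = sweep(variant)
    delta = axis_center_mean(var_traj, variant) - axis_center_mean(base_traj, base)
    ob_base, _ = x_axis_obliquity(base)
    ob_var, _ = x_axis_obliquity(variant)
    metrics = {
        "cr_scatter_base": _cr_scatter(base_traj),
        "cr_scatter_variant": _cr_scatter(var_traj),
        "displacement_norm": float(np.linalg.norm(delta)),
        "icr_mean_base": base_traj.icr_points().mean(axis=0),
        "icr_mean_variant": var_traj.icr_points().mean(axis=0),
    }
    pred = spec.predicted_displacement
    if pred == "none":
        label = "none" if np.linalg.norm(delta) < tol else _nearest_label(delta)
        confirmed = label == "none"
    elif pred == "lateral-proximal":
        label = "lateral-proximal" if (ob_var > ob_base and ob_var > 0) else "none"
        confirmed = label == "lateral-proximal"
    else:
        label = _nearest_label(delta) if np.linalg.norm(delta) > 0 else "none"
        confirmed = label == pred
    return PredictionCheck(spec.name, confirmed, pred, label, delta,
                           ob_base, ob_var, metrics)


# ---------------------------------------------------------------------------
# shipped presets


def builtin_presets() -> dict[str, VariantSpec]:
    out = {}
    root = resources.files("mpsjc").joinpath("presets")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            spec = VariantSpec.model_validate(json.loads(entry.read_text()))
            out[spec.name] = spec
    return out


def preset_names() -> list[str]:
    return list(builtin_presets())


def load_preset(name: str) -> VariantSpec:
    presets = builtin_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    return presets[name]
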