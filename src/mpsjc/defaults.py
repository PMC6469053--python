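"""Default numeric values for the reference joint model.

These defaults are **illustrative**: the source morphometrics for this kind
of model are qualitative (a circular crista section, flattened sesamoid
grooves, a more distal tibial sesamoid, declination running from roughly
15 deg at stance to roughly 70 deg at terminal propulsion).  Sizes below are
plausible adult first-metatarsal values chosen once so that every stated
qualitative relation holds; they are not measurements.

All lengths in mm, all angles in degrees.  Platform frame: +x distal,
+y dorsal, +z medial (right foot).
"""

import math

# metatarsal head
SAGITTAL_RADIUS = 11.0       # crista (sagittal) articular radius
TRANSVERSE_RADIUS = 12.0     # dorsal-view radius; slightly larger -> flatter
PROFILE_SPAN_DEG = (-110.0, 100.0)   # articular arc covered by each section

# sesamoids and phalanx (platform frame, stance pose)
SESAMOID_RADIUS = 3.5
PHALANX_RADIUS = 6.0
TIBIAL_ANGLE_DEG = -75.0     # polar angle of the tibial sesamoid about the head
FIBULAR_ANGLE_DEG = -97.0    # fibular sits more proximal (more negative)
TIBIAL_Z_MM = 4.0            # +z medial; matches 8 sections x 0.5 mm
FIBULAR_Z_MM = -4.0

# grooves (bone-frame polar angles on the head circle)
# The tibial groove curves sharply right at its inception with its flat
# surface angled toward perpendicular to the long axis; the fibular groove
# runs flat from proximal with its sharp curvature at the distal end.
TIBIAL_GROOVE_DEG = (-52.0, -12.0)
FIBULAR_GROOVE_DEG = (-70.0, -30.0)
GROOVE_FLATTENING = 0.15
TIBIAL_ORIENTATION_DEG = 52.0    # flat mid-tangent vs long axis (perpendicular-ish)
FIBULAR_ORIENTATION_DEG = 46.0   # more parallel to the long axis
FLAT_FRACTION = 0.35

# declination sweep
THETA0_DEG = 15.0
THETA_M_DEG = 70.0
N_STEPS = 200

SHAFT_LENGTH_MM = 60.0       # nominal metatarsal shaft length (descriptive)

# synthetic C-T section stack (the digitized-specimen emulator)
# The imaged specimen's grooves are conspicuous flattened surfaces, so the
# stack generator uses a deeper flattening than the idealized kinematic
# default; the landmark pipeline recovers whatever the stack contains.
STACK_N_SECTIONS = 48
STACK_CRISTA_INDEX = 23
STACK_TIBIAL_TROUGH_INDEX = 31
STACK_FIBULAR_TROUGH_INDEX = 15
STACK_FLATTENING = 0.4
STACK_NOISE_SIGMA = 0.005 * SAGITTAL_RADIUS
STACK_POINTS_PER_SECTION = 600


def sesamoid_center(angle_deg: float, radius: float = SESAMOID_RADIUS):
    """Stance-pose platform center of a sesamoid tangent to the head sphere."""
    d = SAGITTAL_RADIUS + radius
    a = math.radians(angle_deg)
    return (d * math.cos(a), d * math.sin(a))
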