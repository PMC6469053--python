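# mpsjc — a geometric center-of-rotation model of the first metatarso-phalangeal-sesamoid joint

The first metatarso-phalangeal-sesamoid joint complex (MPSJC) couples the
first metatarsal head to the proximal phalanx and to the two sesamoid
bones riding in grooves on the head's plantar surface.  During propulsion
the sesamoids and phalanx act as a functionally stationary *platform*
over which the metatarsal head rotates, and all of the joint's motion is
organized around its instantaneous center of rotation (ICR).  `mpsjc`
implements a plane-wise geometric model of that construction for
researchers in foot biomechanics and functional morphology:

* **Per-plane centers of rotation.**  In each sagittal plane the contact
  point between two tangent convex bodies carries a shared normal line;
  intersecting the phalanx-contact normal with the sesamoid-contact
  normal locates that plane's center of rotation, `O_T` (tibial plane)
  and `O_F` (fibular plane).  While both contacts ride the spherical part
  of the head every normal is a radius and the CR is exactly the head
  center.
* **The common center ("sphere of rotation").**  The three contact
  normals, lifted to 3-D at their sagittal-plane offsets with the
  spherical inclination toward the mid-plane, are combined into the
  least-squares closest point `p* = argmin Σᵢ ‖(I − dᵢdᵢᵀ)(p − aᵢ)‖²`,
  with the RMS point-to-line distance reported as the concurrency
  residual.
* **Groove-induced CR shifts.**  Each sesamoid groove is a flattened,
  C¹-continuous three-arc insert in the head circle.  Where the surface
  curvature concentrates at the groove's *inception* (tibial morphology)
  the contact normal leads the radial direction and the CR shifts
  **proximally**; curvature concentrated at the *termination* (fibular
  morphology) makes it lag and the CR shifts **distally**.  Because the
  tibial groove begins more distal than the fibular one, the tibial shift
  starts earlier in the declination sweep, and both CRs return to the
  head center once groove depth has diminished.
* **Variant morphologies.**  Clinically discussed deviations (proximally
  seated sesamoids, a rounded or flattened distal edge, an everted
  sesamoid apparatus, a distally positioned tibial sesamoid, a short
  metatarsal) ship as presets with machine-checkable directional
  predictions for the joint center.
* **A synthetic specimen.**  A generator emulates a digitized stack of
  0.5-mm sagittal C-T sections across the head — circular at the
  inter-sesamoidal ridge (crista), grooved on either flank — with known
  ground truth, and a landmark locator plus profile-fitting pipeline
  recovers the crista/trough sections and a posable joint model from the
  contours alone.

## Worked example

```python
from mpsjc import default_model, sweep, classify_shift, shift_ordering

model = default_model()                 # 11 mm head, theta 15..70 deg
traj = sweep(model)

R = model.head.sagittal_radius
for plane in ("tibial", "fibular"):
    c = classify_shift(traj, plane, reference_radius=R)
    print(plane, c.direction, round(c.onset_theta, 1), round(c.max_excursion, 3))
print(shift_ordering(traj, reference_radius=R)[0])
```

prints

```
tibial proximal 24.1 0.307
fibular distal 32.4 0.298
True
```

i.e. the tibial-plane CR shifts proximally by up to 0.31 mm beginning at
a declination of about 24°, the fibular-plane CR shifts distally by a
similar amount beginning later (about 32°), and the tibial shift indeed
precedes the fibular one — the model's central kinematic result.  Both
CRs return to the head center by terminal declination.

The same sweep from the command line, with a plot:

```bash
mpsjc sweep --steps 200 --out trajectory.csv --plot sweep.svg
mpsjc simulate-stack --outdir sections --seed 7
mpsjc landmarks --sections sections --out landmarks.json
mpsjc variant --variant all --report variants.csv
```

## Layout

| module | contents |
| --- | --- |
| `mpsjc.geometry2d` | arcs, composite convex profiles, tangents/normals, line intersection, circle and grooved-profile fitting |
| `mpsjc.joint_model` | domain types (head, grooves, sesamoids, phalanx, sweep), the reference model, validation |
| `mpsjc.icr_engine` | pose solving, contact resolution, plane CRs, 3-D common center, declination sweep, shift classification |
| `mpsjc.variants` | morphology presets and prediction checking |
| `mpsjc.synthetic_sections` | section-stack generator, landmark locator, stack-to-model recovery |
| `mpsjc.cli_io` | `mpsjc` command-line tool |

See `docs/methods.md` for the model's assumptions, parameters and
numerical choices.
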