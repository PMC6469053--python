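# Methods

## Coordinate conventions and the platform frame

The sesamoids and the proximal phalanx base are treated as one
functionally stationary unit (the *platform*); the metatarsal head
rotates over it.  All computations use a platform-fixed frame: +x distal,
+y dorsal, +z medial (right foot).  A "proximal shift" is a decrease in
x.  Angles are degrees at every interface and radians internally; lengths
are millimetres.

Three-dimensionality is represented plane-wise: three parallel sagittal
planes — the fibular groove plane, the crista plane and the tibial groove
plane — at fixed z-offsets, mirroring how sequential sagittal sections
isolate those structures in a specimen.  The z-offsets of the reference
model (±4 mm) equal the landmark-section separations of the synthetic
specimen (8 sections × 0.5 mm).

## Articular profiles

Each sagittal section of the head is a convex, C¹ composite curve of
circular arcs (elliptical arcs are supported as primitives).  The crista
section is a pure circle of radius R.  A groove section replaces the
circle between the groove's *inception* (the proximal reference point on
the profile) and its *termination* (where groove depth has completely
diminished) by a **three-arc flattened insert**: a sharp "curl" arc, a
flat arc of radius `R/(1−f)` (f = flattening), and a second curl arc.
Solving the C¹ closure is a 2×2 linear system; the groove is fully
specified by its span, its flattening and the *orientation* of the flat
arc's mid-tangent relative to the metatarsal long axis, which places the
flat within the span and thereby selects which end carries the sharp
curl.  Two facts motivated this family:

* a single conic inserted C¹-tangent into a circle is necessarily
  symmetric about the chord bisector, and a two-arc circular insert is
  geometrically impossible, so three arcs is the minimal asymmetric
  C¹ construction;
* where the curvature concentrates decides the kinematics: curvature at
  the inception makes the surface normal lead the radial direction
  through the groove (CR shifts proximally — tibial morphology, whose
  surface curves sharply right at its inception toward perpendicular to
  the long axis), curvature at the termination makes it lag (CR shifts
  distally — fibular morphology, whose flat runs from proximal, more
  parallel to the long axis).

## Pose, contacts and centers of rotation

At declination angle θ the head's rotation is fixed at −θ (the bone
plantarflexes clockwise over the platform as θ grows from stance to
terminal propulsion) and its translation is solved per plane from
simultaneous tangency to the phalanx support and that plane's sesamoid
(Levenberg–Marquardt plus a Powell-hybrid polish; tangency residual
< 1e-10 in practice).  Contacts are resolved by exact projection onto the
composite profile; the shared normal at a contact passes through the
contacting body's center.  The plane CR is the intersection of the
phalanx-contact normal with the sesamoid-contact normal; parallel normals
(within 1e-8 rad) are reported as a status and interpreted by the sweep
layer as "CR at the spherical center", which is the correct limit.

The declination angle itself is *measured*, not assumed: it is the angle
between the phalanx-contact normal and the metatarsal long axis, and for
the reference model the measured value equals the commanded θ to 1e-6.
The phalanx-contact normal is treated as fixed across the sweep in the
shift-attribution argument; the implementation computes it at every step
and records its drift (0.08° for the reference model; a 1° bound is
asserted in tests).

For the 3-D common center, each sesamoid normal is lifted to its plane
offset with the spherical inclination toward the mid-plane (a surface
normal of a sphere at an off-center section points at the 3-D center; at
a groove trough the transverse depth gradient vanishes, so the underlying
spherical inclination survives).  The common center minimizes the sum of
squared distances to the three lines (closed-form normal equations); the
RMS distance is the concurrency residual, identically zero for a
spherical head and up to ≈0.1 mm during groove passage of the reference
model.

## Reference model parameters

All values are illustrative defaults declared once in `mpsjc/defaults.py`
— the source morphology is qualitative, so sizes were chosen once as
plausible adult values and not revisited:

| parameter | value | note |
| --- | --- | --- |
| sagittal (crista) radius R | 11 mm | head sphere |
| transverse radius | 12 mm | slightly larger, flatter dorsal view |
| sesamoid radius | 3.5 mm | both sesamoids |
| phalanx support radius | 6 mm | circular support, contact A |
| tibial sesamoid polar angle | −75° | more distal |
| fibular sesamoid polar angle | −97° | more proximal |
| plane offsets | ±4 mm | tibial medial, fibular lateral |
| tibial groove span | −52°…−12° | inception more distal |
| fibular groove span | −70°…−30° | begins more proximal |
| groove flattening f | 0.15 | kinematic default |
| flat-arc orientations | 52° / 46° | tibial more perpendicular |
| flat fraction | 0.35 | span fraction occupied by the flat arc |
| sweep | 15°→70°, 200 steps | stance to terminal propulsion |
| shift tolerance | 0.005 R | classification threshold |

With these defaults the tibial CR excursion is ≈0.31 mm proximal with
onset at ≈24°, the fibular ≈0.30 mm distal with onset at ≈32°, both
returning exactly to the stance CR once the grooves blend back into the
circle before θ_M.  Onset ordering resolves whenever the groove-entry
angles differ by at least ~2° at the default 200-step grid.

## Variant presets and their measurement

For a perfectly spherical head the least-squares common center *is* the
sphere center, which tangency closure pins regardless of where the
sesamoids sit; frontal repositioning therefore cannot move that point,
and directional variant predictions are measured on the **functional
axis center**: the sweep-mean of the per-plane CRs embedded at their
plane offsets (identical to the common center when the normals are
concurrent).  The compound label "lateral-proximal" is read from the
obliquity of the transverse axis through the two sesamoid contacts, the
construction from which that label originates.  Directional labels are
assigned by nearest direction axis (proximal, distal, medial-plantar,
lateral-proximal); "none" predictions are vacuously confirmed below the
shift tolerance.

Preset realizations worth noting:

* *proximal_sesamoids* seats both sesamoids 16° more proximally along
  the articular arc (a pure −x translation changes the two planes'
  tangency distances in opposite directions and cancels).  The proximal
  mean shift arises from end-range groove engagement — the clinically
  described end-range restriction.
* *everted_position* rotates the sesamoid pair about the long axis; in
  the plane-wise representation this moves the plane offsets medially
  while each sesamoid's in-plane tangency distance is preserved (the
  cylinder-consistent projection of the rotation).
* *flattened_head* and *short_metatarsal* carry mobility notes rather
  than a center direction; their displacement predictions are "none".

A 2° transverse-plane (abduction) rotation about the dorsal-plantar axis
through the head center leaves the spherical surface invariant and only
translates the groove features within each plane; the resulting change in
any plane CR is < 0.04 mm (< 0.004 R) for the reference model — the
model accommodates this motion.

## The synthetic specimen

The stack generator emulates a digitized series of 48 sagittal sections
at exactly 0.5-mm spacing: section radius follows a transverse-ellipse
law with a floor at the head margins; the crista section (index 23) is
the unique circular one; groove flattening follows a steep ramp away from
the narrow crista ridge plus a bump peaked at each trough (tibial index
31, fibular index 15), decaying to a plateau toward the margins.  The
imaged specimen's grooves are conspicuous structures, so the stack uses a
deeper flattening (0.4) than the kinematic default.  Contours are open
curves over the distal-plantar articular region, sampled uniformly in
arc length (600 points) with isotropic Gaussian noise (default 0.5 % of
R, emulating digitization error).  What the generator does *not* emulate:
cortical/trabecular image texture, segmentation artifacts, out-of-plane
blur, or anatomical asymmetries beyond the parameterized family — so
passing tests demonstrate the pipeline's correctness on idealized
digitized contours, not robustness to raw imaging data.

The landmark locator computes, per section, a robust baseline circle
(iterative inward-outlier exclusion at 2×MAD), the largest sliding-window
mean of inward deviations (30° windows) normalized by the section radius,
then takes the two separated peaks of the lightly smoothed depth profile
as the troughs (quadratic-vertex refinement) and the depth minimum
between them — re-measured in the grooves' fixed angular windows — as the
crista.  Missing-groove detection requires the peaks to stand above a
noise floor estimated from the high-frequency residual of the depth
profile *and* to keep a consistent angular position across neighboring
sections; a groove-less spherical stack fails both.  At the default
noise the landmarks are recovered exactly in ≈90 % of stack realizations
and within ±1 section in ≈95–98 %; accuracy is non-increasing in noise.

Model recovery fits the crista section with a circle (radius recovered to
≲0.1 %) and each groove with a **pooled fit** of the nine sections
flanking its trough, sharing the angular parameters with per-section
depths.  Pooling breaks most of the span/attitude/depth trade-off that
makes single-section fits unreliable; the one quantity that remains
nearly unidentifiable under noise is the *sign* of the curvature skew, so
the template constrains the relative skew to the anatomical family of the
groove being fitted (tibial: curl at inception; fibular: curl at
termination) and the data determine its magnitude.  On noise-free stacks
the recovery is exact to ≤2e-6 relative (the unsigned point-to-profile
distance has arc-switching kinks that floor the optimizer there).

## Numerical choices and degenerate inputs

* Parallel-line tolerance 1e-8 rad; tangency tolerance 1e-6 mm;
  C¹ junction tolerances 1e-9 (position) and 1e-6 rad (tangent).
* Circle fitting: Kåsa algebraic fit followed by geometric Gauss–Newton;
  exact on noiseless data, collinear input raises a degenerate-fit error.
* Zero flattening degenerates the groove insert to the original circle
  segment exactly, so the spherical limit is represented without special
  cases (CRs at the center to machine precision).
* Contact bodies with zero radius are point supports; contact resolution
  then returns the projection point itself.
* Ties in shift-onset ordering (within one θ step) are reported as
  "tie" rather than silently ordered.
* ω for surface-speed comparisons defaults to 1 °/s; the comparisons are
  ratios, so the absolute rate is irrelevant.

## Known limitations

* Plane-wise 3-D: no continuous articular surface, no coupling of the
  three planes through a shared rigid pose (each plane's tangency is
  closed independently; the recorded phalanx-normal drift bounds the
  inconsistency).
* Quasi-static geometry only: no forces, pressures, inertia or tendon
  action; consequences of ground-reactive force are out of scope.
* The groove family is a specific three-arc construction; real grooves
  are not exact arc chains, and the skew-sign identifiability limit noted
  above is a property of fitting within this family at realistic
  digitization noise.
* Declination is measured against the phalanx-contact normal; measuring
  against the ground plane would differ when the platform is inclined.
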