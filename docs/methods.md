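# Methods

## The model

The capitellum is treated as a sphere of radius `R_b` carrying an articular
cartilage shell of thickness `t` over an anterior cap (half-angle 65° about
the anteroposterior axis). The anatomical frame is right-handed and metric
(mm): mediolateral (ML, pointing medial), proximodistal (PD, pointing
proximal), anteroposterior (AP, pointing anterior), with its origin at the
sphere centre. Everything downstream — area numbering, diameters, coverage —
is computed in this frame, which makes all metrics invariant under rigid
motions of the scene.

A lesion footprint is an elliptic region in *angle* space: a surface
direction `u` belongs to the footprint when
`(asin(u·PD)/αv)² + (asin(u·ML)/αh)² ≤ 1`. Its straight-line (chord) extent
in the AP projection at surface radius `R` is `2R sin α` per half-angle.
This closed form is the ground truth for the phantom's lesion diameters and
the inverse map (`angular_extent_for_extents`) turns requested millimetre
extents into angular half-extents.

## Phantom generator

The phantom exists so that every stage is testable without clinical data.
Both volumes are produced by evaluating one analytic anatomy at each grid's
world coordinates; the CT grid is pulled back through the inverse of the
configured rigid transform, so the two modalities genuinely live in
different world frames with a known mapping and no resampling artefacts.
Defaults are the study conditions used throughout the tests:

| parameter | default | why |
|---|---|---|
| MRI voxel | 0.4 mm iso | thin-slice 3D traction MRI |
| CT voxel | 0.5 mm iso | thin-slice CT |
| grid | 96³ voxels | holds the capitellum plus shaft with margin |
| bone radius | 11 mm | adolescent capitellum scale |
| cartilage thickness | 2.5 mm | traction-visible shell |
| lesion extents | spanning ≈8–20 mm | the range of the validation cohort |
| noise | additive Gaussian, σ=2 (MRI classes 0/60/100) | mild acquisition noise, seeded |
| landmarks | 4 (epicondylar tip, capitellar pole, shaft cortex, medial equator) | the manual four-point protocol; extras on a posterior spiral |

Intensity classes are synthetic constants, not calibrated HU/MR units,
because the workflow being modelled set its thresholds manually per
scanner. Bone carries a proximal shaft and a lateral epicondylar bump; both
exist purely to break the rotational symmetry that a bare sphere would
leave unconstrained during registration.

Lesion features, each independently switchable:

* **fissure** — a 0.6 mm slab of low intensity through the full shell
  thickness, oriented along the surface normal (it *penetrates* the
  surface by construction); a tangential mid-depth slab spanning 15 % of
  the thickness is generated as a negative control;
* **protrusion / flattening** — the outer cartilage radius is raised or
  lowered by a fixed height inside the footprint (hard-edged);
* **defect** — the shell is absent inside the footprint;
* **SSB** — a lens-shaped fragment (footprint directions, outer 3 mm of
  bone) separated by a 1.5 mm low-intensity cleft; `ssb_cleft_planes < 3`
  leaves a central bridge so the fragment stays connected, the
  counterexample for the three-plane criterion;
* **sclerosis** — a 1.5 mm band of elevated CT intensity beneath the cleft
  floor.

What the phantom does **not** emulate: realistic elbow anatomy (trochlea,
radius, ulna), MR pulse-sequence contrast, partial-volume and bias-field
effects, traction biomechanics, or operator variability in manual
segmentation. Passing the recovery tests therefore demonstrates the
geometric and algorithmic correctness of the pipeline, not clinical-grade
segmentation performance on scanner data.

## Finding detectors

The original workflow relied on an operator's eye; here each finding is an
explicit criterion with free parameters validated only on the phantom:

* **ACF**: connected low-intensity components inside the cartilage envelope
  (morphological closing of the cartilage mask) qualify when their
  principal axis lies within 30° of the local surface normal **or** they
  span ≥ 80 % of the local shell thickness. The span clause is what accepts
  thin full-thickness slabs whose principal axis is tangential.
* **ASD / ACD** share a "cap map": cartilage voxels are binned by their
  direction sines from the cap centre; each bin records outer/inner radius
  and thickness. The reference surface radius is the *median* of per-bin
  outer radii — a least-squares sphere is dragged toward a deformity that
  covers a quarter of the cap, the median is not. Bins near the cap rim are
  excluded (partially filled bins and the shell's cut face fake
  irregularities there). ASD: contiguous interior patches with radial
  residual beyond ±0.5 mm, closed morphologically so a fissure gap does not
  split one deformity into two. ACD: interior holes of the populated map
  plus sub-0.5 mm-thickness bins, opened morphologically so the line-like
  surface trace of a fissure is not mistaken for an areal defect; minimum
  area 3 mm².
* **SSB**: 26-connected bone components disjoint from the largest one,
  verified to be 8-disconnected from the main bone in every occupied slice
  of all three orthogonal planes. The test is symmetric under axis
  relabelling.
* **Sclerosis**: bone voxels above the 90th percentile of the bone
  intensity distribution, largest component kept.
* **SSB-underneath**: the finding's surface patch and the fragment are both
  projected to direction space (anterior hemisphere only) and intersected
  with a 2° tolerance.

When an anatomical frame is supplied, its origin is used as the cap centre;
an algebraic sphere fit on a partial, thick shell is biased toward the cap
and is only the fallback when no frame is given.

## Registration

Landmark registration is the Kabsch/Umeyama least-squares rigid fit
(scipy's `align_vectors`), correspondence by order/name, rotation forced to
determinant +1 — a mirrored solution would silently flip anatomy. It is
exact on noiseless correspondences.

"Global registration" is realized as point-to-point ICP: nearest-neighbour
correspondence on a KD-tree, full rigid re-fit per iteration, convergence on
the relative change of the correspondence rmsd (the trace is
non-increasing). Two robustness choices matter on cross-modality meshes:
the bone meshes are Taubin-smoothed (10 iterations, volume-preserving)
before matching to suppress voxelization noise, and the worst 5 % of
correspondences are trimmed each iteration because the field-of-view cut
faces of the two grids do not correspond to each other. Symmetric
(bidirectional) matching was evaluated and rejected: the two volumes cover
different shaft lengths, so reverse correspondences are systematically
wrong. With these settings the true transform is recovered to ≲0.7°/0.1 mm
from 0.2 mm-noise landmarks across seeds; uniform subsampling (6000
vertices) keeps each refinement under a second.

Fusion applies one transform to all MRI-frame models (humerus + cartilage,
rigidly linked), hides the MRI humerus, and leaves CT-frame models — the
bone and the red SSB overlay — untouched.

## Lesion analysis

The articular surface is elliptical in the AP view; the ellipse is fitted
(scikit-image) to a densely resampled convex outline of the projected
cartilage. Areas 1–4 are the quadrants cut by the PD and ML axes through
the ellipse centre, numbered from anteromedial; since the ML axis points
medial on either side, area 1 stays anteromedial for left elbows. Boundary
points go to the lower-numbered adjacent area (centre → area 1).

Diameters are straight-line extents of the AP-projected footprint along PD
(vertical) and ML (horizontal) — caliper-style, not geodesic. An empty
footprint yields absent diameters (the unmeasurable-lesion case).

Stability and grading are codified as stated in the README. One design
decision deserves a note: a surface deformity *without* subchondral
separation is graded II, not III, so that grades III/IV coincide exactly
with the unstable lesions — the two rules are used together downstream and
an inconsistent pair would produce reports that contradict themselves. The
findings-only variant used for the table fixtures (where per-finding SSB
was not recorded) grades any deformity III and a lone fissure II; it
reproduces the predicted grade of all sixteen validation cases.

The procedure rule: reconstruction when unstable with maximum diameter
> 10 mm; drilling for small grade-IV lesions or stable lesions refractory
to conservative therapy; free-body removal appended when free bodies are
present.

## Surgical simulation

Resection partitions the cartilage mesh by face centroid against the
footprint; boundary faces go to the resection side (surgical margins err
toward removing diseased tissue). Graft coverage is computed on an AP-plane
raster (0.2 mm cells): a cell is covered when its centre lies inside the
projected silhouette of any graft mesh — an exact point-in-projected-
triangle test, verified in the tests against an independent ray-casting
oracle (Möller–Trumbore). Coverage is monotone in the number of grafts.
Step-off is the extreme radial deviation of graft vertices over the
footprint from the reference cap; seating depth and off-site collision
volume are evaluated on a 0.5 mm sample grid against the host bone
occupancy (they require the bone mask; graft containment is analytic per
shape). Drilling is a zero-width entry→target segment (optionally widened
to the drill diameter as a five-ray capsule); cartilage breach is a
segment–mesh test, sclerosis penetration a mask lookup at half-voxel steps,
and a posteroanterior plan that breaches cartilage is flagged invalid.

## Concordance statistics

The five validation tables are packaged as CSV fixtures with embedded
SHA-256 checksums; case 1 has no measurable lesion and is left blank, case
15 carries the detached-lesion flags. The corresponding rate is
matches/total with the percentage rounded half-away-from-zero to one
decimal (15/16 → 93.8). The rank-sum test defaults to the tie-corrected
normal approximation without continuity correction; a seeded raw
permutation test (counting permutations whose U deviates from its null
mean at least as much as observed) is the independent oracle. The two agree
within 0.01–0.015 on the diameter columns. The printed p-value of the
source for the vertical comparison (0.78) matches the exact U distribution
that *ignores* ties (0.775); the tie-aware permutation null puts it near
0.75. The package reports the tie-aware value and documents the
discrepancy rather than selecting the method that matches the printout.
The interquartile convention is selectable (`numpy.percentile` methods)
because the printed IQRs of the source tables are not reproducible under
any single standard convention.

## Numerical choices and limitations

* Iso-surfacing runs on a Gaussian-smoothed (σ = 1 voxel) copy of the
  binary mask; a raw binary marching-cubes surface overestimates area by
  ~9 % through staircase artefacts, the smoothed one is within 1 %.
* Rotation distances are computed through quaternions; the arccos-of-trace
  formula loses precision below ~10⁻⁶ degrees.
* The footprint rasterizer marks every voxel a dense sub-voxel surface
  sampling passes through; centre-in-region sampling can fall almost two
  voxels short at the footprint apexes through angular quantization.
* All detector thresholds (angle 30°, span 0.8, height 0.5 mm, thickness
  0.5 mm, area 3 mm², percentile 90) are this package's explicit choices,
  validated on the phantom only; clinical data would require per-scanner
  calibration of both intensity thresholds and these criteria.
* The ICP stand-in for the undisclosed commercial "global registration" is
  point-to-point; partial-overlap clinical meshes may need higher trim
  fractions or a point-to-plane variant.
* Problem sizes in the test- and acceptance-suites (96³ phantoms, 6000-point
  ICP subsamples, 10–50 seeded trials, 10⁵ permutation resamples) were
  chosen as the smallest at which the measured quantities are stable to
  well within their tolerances.
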