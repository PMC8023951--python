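# Methods

## The measurement model

Two CT examinations of the same hip are treated as rigid scenes.  Two
bodies are assumed rigid between examinations: the pelvic bone (the
*reference*) and the cup implant.  Each body yields a rigid transform
mapping exam-1 world coordinates (DICOM LPS, mm) into exam-2 coordinates:
`T_ref` from registering the bone, `T_imp` from registering the cup.  The
migration of the cup relative to the pelvis, expressed in the exam-1 pelvis
frame, is `M = T_ref⁻¹ ∘ T_imp`; it is the identity exactly when cup and
pelvis moved as one (pure patient repositioning).

`M` is decomposed into 6 degrees of freedom.  A rotation matrix's raw
translation column depends on where the world origin happens to be, so the
reported translation is the displacement of a fixed anatomical point — the
centroid of the implant's exam-1 mask: `t_report = t + (R − I)·c`.
Rotations are intrinsic x→y→z Euler angles in degrees (`R = Rx·Ry·Rz`),
stated in every output record as `intrinsic-xyz-deg-LPS`.  At gimbal lock
(|ry| within 1e-6° of 90°) the x/z split is undefined; the tie rule sets
`rz = 0` and flags the result.  Total translation is the Euclidean norm of
the reported translation vector.

### Assumptions

* Both bodies are truly rigid; bone remodelling between examinations is
  handled only through common-region masking (below), not modelled.
* Both examinations use the same modality and comparable protocols, so a
  mono-modal mean-squared-difference metric is appropriate.
* The world frames of both examinations are calibrated (standard CT
  geometry); no gantry tilt or variable slice spacing (such volumes are
  rejected on read rather than resolved).

## Rigid-body definition

Bodies are defined by HU thresholds, held constant within a cohort (the
clinical workflow optimizes them manually once per cohort):

* **Bone**: voxels in `[250, 2000)` HU, minus a 3-voxel dilation of
  everything at or above the bead-detection threshold (implant metal,
  beads, and their partial-volume rims all move with the wrong body or are
  fiducials of their own), then the largest 26-connected component.
* **Implant**: voxels ≥ 2000 HU, largest component.
* **Beads**: suprathreshold 26-connected components whose physical volume
  falls in a bead-sized window (default 0.1–4 mm³), outside a dilated
  exclusion mask of the implant.  Sub-voxel centroids weight each voxel of
  the component *plus its one-voxel partial-volume shoulder* by HU excess
  above the local background (median of the surrounding shell).  Weighting
  above the detection threshold instead quantizes centroids toward voxel
  centers once the threshold climbs; the shoulder-weighted estimator stays
  near 0.1 voxel mean error on noiseless phantoms.  Two accepted beads
  closer than a merge distance (1 mm) abort with an ambiguity error rather
  than silently merging.
* Implant beads sit in low-HU cement/liner space and blur far dimmer than
  bone-embedded beads, so the implant bead pass uses its own lower
  threshold (500 HU); at that level the bone body itself is suprathreshold
  but rejects itself through the size window.

## Registration

**Bead mode** (reference series 2, or implant-by-beads): beads detected in
both examinations are split into bone vs implant sets by the cup's bounding
sphere, matched by mutual nearest neighbours under a coarse centroid
alignment (8 mm gate), superimposed in closed form, re-matched at 2 mm, and
re-solved.  The solver is the standard least-squares superposition:
centroid alignment plus the rotation from the SVD of the cross-covariance
with reflection correction.  Partial matching is deliberate — beads may be
missing from either examination.

**Surface mode** (series 1): the transform minimizes the mean-squared HU
difference between exam A and exam B resampled through the transform,
evaluated over the body's mask.  The optimizer works on a 6-parameter
chart — rotation vector about the mask centroid (scaled by the mask's mean
lever arm so all parameters move the image comparably) plus translation —
with L-BFGS-B over three deterministic resolution levels: mask-point
strides 4/2/1 paired with Gaussian smoothing of 2/1/0.5 voxels and
cubic-spline interpolation.  The 0.5-voxel smoothing retained at the finest
level suppresses voxel-sampling alias in the metric without erasing
sub-voxel information.  There is no stochastic sampling anywhere, so
registration needs no seed.  Exhausting the iteration budget raises a
convergence error carrying the last iterate.

**Common-region masking**: after a coarse first registration, reference
voxels whose |ΔHU| against the mapped second examination exceeds a residual
threshold (default 150 HU) are dropped — changed morphology (e.g.
osteolysis) and regions outside the shared field of view leave the
reference — and the registration is re-run on the surviving mask.  The
surface pipeline always runs exactly one such refinement pass.  If fewer
than half the voxels survive, the examinations do not share enough
morphology and the measurement aborts.

**Verification** mirrors the clinical color-coded check numerically: the
fraction of mask voxels with |ΔHU| within tolerance (default 3× the noise
sigma for bone; 300 HU for the metal body, whose ~5000 HU/mm edge gradients
make the tissue tolerance meaningless) decides green vs red, with a green
cutoff of 0.90.  For perfectly aligned pure-noise voxels the 3σ tolerance
admits ~96.6%, and genuine edge voxels add interpolation residue, so a 0.95
cutoff would flag well-converged registrations red.  In strict mode a red
status raises instead of returning a result.

## The synthetic phantom

The generator emulates the double-examination design, not a particular
patient: a thick-walled half-ellipsoid bone shell (700 HU) with a
hemispherical socket at its apex; a hemispherical metal cup shell
(3000 HU) seated in the socket; three asymmetric spherical "screw hole"
cutouts through the cup shell — without them a hemisphere's rotation about
its own axis is unobservable from its surface, as it is for a featureless
real cup; ~1 mm tantalum beads (4000 HU — tantalum is far denser than
implant alloys) rejection-sampled into the bone wall and the cup's cement
space with explicit clearances; soft-tissue background at −50 HU.

Rasterization is anti-aliased: voxels whose neighbourhood is not uniform
are supersampled 3× per axis (the average of 27 membership evaluations),
all other voxels take their center value, which is exact for them.  A
Gaussian PSF blur (default σ 0.4 mm ≈ sharp bone-kernel FWHM 0.9 mm) and
additive Gaussian HU noise (default σ 20) follow.  Default grid 160³ at
0.6 mm isotropic spacing; `PhantomSpec.scaled_default` scales the
macroscopic geometry to other grids while keeping physical properties
(bead radius, HU, blur, noise) fixed.

A double examination rasterizes exam 1 at identity and exam 2 with the
whole anatomy moved by a repositioning transform, the implant additionally
by the migration under test (`pose = repositioning ∘ migration`); noise is
independent per exam.  Simulated repositioning draws a rotation of
0.5–2° about a random axis and a 1–5 mm shift — the residual misalignment
after the radiographer recenters the patient; neither the clinical workflow
nor the literature pins a number, so this is a stated assumption.

**What the phantom does not model**: beam hardening and metal artefacts
(clinical protocols here use no artefact reduction), scanner-specific
reconstruction kernels, bone texture/trabecular structure, soft-tissue
heterogeneity, femur and stem.  Passing tests therefore demonstrate the
correctness and noise behaviour of the *measurement machinery* under
CT-like image formation, not clinical performance on real scans.

Because voxel values integrate over grid-aligned boxes, a rotated
re-examination genuinely differs from a rotated image (the effective PSF is
orientation-dependent) — as in real CT.  With the default sharp kernel this
aliasing, a property of the data, dominates sub-0.05-voxel registration
comparisons; the noiseless registration property tests therefore use a
band-limited phantom (blur σ = one voxel), where the registration reaches
~0.01-voxel inverse-consistency and the limit is interpolation, not data.

## Precision statistics

For each of the seven measures (tx, ty, tz, TT, rx, ry, rz) over a cohort
of double examinations: precision = SD × t at (1+confidence)/2 with n−1
degrees of freedom.  SD is mean-subtracted with an n−1 denominator by
default; an about-zero variant (RMS against the known true value of zero)
is available behind a flag.  TT precision is computed on the per-exam TT
values, not derived from per-axis precisions.  Normality is screened per
measure with a one-sample KS test against a normal with the sample's own
mean and SD; since parameters are estimated from the sample, the p-value is
calibrated by seeded Monte-Carlo (Lilliefors; 2000 simulations by
default).  A fresh N(0,σ) measurement divided by an independent sample SD
is exactly t-distributed, so ±precision covers a fresh measurement at
exactly the nominal confidence — the property the Monte-Carlo coverage test
checks.  Effective dose is the exact product DLP × k with unit bookkeeping;
k defaults to the adult-pelvis 0.015 mSv/(mGy·cm) and is configurable.

## Numerical choices and degenerate inputs

* Rotation matrices are validated to orthonormality 1e-8 and det +1;
  optimizer output is projected onto SO(3) via SVD before validation.
* Point superposition requires ≥3 non-collinear pairs (second singular
  value of the centered source above 1e-8 of the first); fewer or collinear
  configurations raise a degenerate-geometry error.
* Component-size ties in `largest_components` break by the lowest linear
  C-order index at which each component occurs.
* Bead sets order by descending peak HU, then lexicographic position.
* Euler angles wrap to (−180°, 180°]; gimbal tie rule `rz = 0`.
* Empty threshold masks are legal results; empty *component* results and
  insufficient bead matches are errors.
* All randomness (bead placement, noise, KS Monte-Carlo, study
  repositioning) flows from explicit integer seeds via `SeedSequence`;
  registration is deterministic by construction.

## Problem sizes used by the shipped tests and acceptance script

Chosen as the package's own defaults for a single-CPU run: unit tests use
64³–96³ phantoms; end-to-end registration-accuracy, zero-migration and
migration-recovery studies run at 128³ × 0.6 mm (the default geometry
scaled by 0.8 — at 96³ the cup spans too few voxels and acquires a ~0.3°
orientation bias, while 128³ reproduces default-scale behaviour at ~40% of
the cost); the acceptance script simulates cohorts of 6 double examinations
per registration mode and 5 injected-migration pairs at the same grid.
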