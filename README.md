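# ctmigrate

CT-based implant motion analysis for hip arthroplasty: measure the
rigid-body motion of an acetabular cup relative to the pelvis between two
CT examinations, and estimate the precision of that measurement from
double examinations.

Early migration of a hip implant — fractions of a millimetre within the
first years — predicts later clinical loosening.  The reference technique,
radiostereometric analysis (RSA), needs implanted tantalum beads, a stereo
X-ray laboratory, and loses data when beads are occluded.  `ctmigrate`
implements the CT alternative: the same pair of CT volumes is registered
twice, once on the pelvic bone (the *reference* rigid body, defined either
by its surface anatomy or by bone-embedded beads) and once on the cup (the
*implant* rigid body, by its metal surface or implant beads).  If the bone
registration maps exam-1 world coordinates to exam-2 as `T_ref` and the
implant registration as `T_imp`, the cup's motion relative to the pelvis,
expressed in the exam-1 pelvis frame, is

```
M = T_ref⁻¹ ∘ T_imp
```

`M` is reported in 6 degrees of freedom — translations `(tx, ty, tz)` in mm
along the CT DICOM (LPS) axes, evaluated at the implant centroid, and
intrinsic x→y→z Euler rotations `(rx, ry, rz)` in degrees — plus the total
translation `TT = √(tx² + ty² + tz²)`.

**Precision from double examinations.**  Two consecutive scans with the
patient repositioned in between contain, by design, zero true cup-vs-pelvis
motion; whatever `M` the pipeline measures is method error.  For a cohort of
n patients the per-axis precision is

```
precision = SD(measurements) × t₀.₉₇₅(n−1)
```

the half-width of the interval covering 95% of repeat measurements
(Student-t critical value with n−1 degrees of freedom).  Each measure is
screened for normality with a Kolmogorov–Smirnov test (Lilliefors form,
Monte-Carlo p-value).  Effective radiation dose is `DLP × k` with the
pelvic conversion constant k (default 0.015 mSv/(mGy·cm)).

Because no clinical CT data can ship with a code package, `ctmigrate`
includes a synthetic phantom generator that emulates the study design:
pelvis-like bone shell, seated metal cup with screw holes, ~1 mm tantalum
beads, CT point-spread blur and HU noise, patient repositioning — with
exact ground truth for every bead and pose.

## Worked example

Generate a double examination with a known 1 mm cup migration along x,
then measure it:

```
$ ctmigrate phantom --seed 7 --grid 128 --out pair/ \
      --repositioning "1,0.5,-0.8,3,-2,4" --migration "0,0,0,1,0,0"
$ ctmigrate measure --exam1 pair/exam1.mha --exam2 pair/exam2.mha \
      --reference surface --implant surface --out result.json
{
 "tx": 1.0204287689012357,
 "ty": -0.030346641609412812,
 "tz": 0.004042332042939156,
 "total_translation": 1.020887913292447,
 "rx": -0.10313633760463858,
 "ry": 0.004020107344814505,
 "rz": 0.027895756829536822
}
```

The injected 1 mm x-translation is recovered to 0.02 mm; the remaining
entries are the method's noise floor at this grid size.  `result.json`
additionally stores the full resolved configuration, the package version,
and the green/red verification record of both registrations.

A precision study over a directory of such results:

```
$ ctmigrate precision --results results_dir/ --confidence 0.95 --out report.csv
```

emits the cohort table (n, x, y, z, TT translations in mm; x, y, z
rotations in degrees, each with SD, t critical value, precision, and
normality statistics).

From Python, the same pipeline is three calls:

```python
from ctmigrate import (PhantomSpec, RigidTransform, simulate_double_exam,
                       measure_pair, MeasureConfig)

spec = PhantomSpec.scaled_default((128, 128, 128))
repo = RigidTransform.from_axis_angle([0, 0, 1], 1.0, translation=(3, -2, 4))
exam1, exam2, truth = simulate_double_exam(
    spec, repo, RigidTransform.identity(), seeds=(1, 2))
result = measure_pair(exam1, exam2, MeasureConfig(reference_mode="beads"))
print(result.total_translation, result.rotations)
```

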