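# cardiomotion

Patient- and segment-specific **cardiac motion estimation** for stereotactic
arrhythmia radioablation (STAR) treatment planning.

Ventricular tachycardia can be treated non-invasively by delivering a single
25 Gy fraction to the arrhythmogenic substrate (the clinical target volume,
CTV) in the left ventricle. Even under breath-hold, the heartbeat moves the
CTV by several millimetres, so the internal target volume (ITV) margin must
account for cardiac motion — ideally per patient and per LV segment.
`cardiomotion` estimates that motion from two ECG-gated contrast CT
reconstructions (end-diastole and end-systole) and is aimed at medical
physicists and researchers preparing STAR plans or studying cardiac motion
surrogates such as the ICD lead tip.

## Method

Given the end-diastolic volume `I_ED` (moving) and end-systolic volume
`I_ES` (fixed) on a shared grid:

1. **Deformable registration** (multi-resolution demons) estimates a dense
   displacement field `u` in voxel units on the ED grid such that a material
   point at ED position `q` sits at `q + u(q)` at end-systole; millimetre
   displacements follow from the CT pixel spacing and slice thickness.
2. **Registration quality** is checked inside the union of the original and
   displaced LV myocardium voxels via

   `MSE = (1/N) Σᵢ (I_origᵢ − I_dispᵢ)²` and the Pearson correlation
   `r = Σ(I_orig − Ī_orig)(I_disp − Ī_disp) / √(Σ(I_orig − Ī_orig)² Σ(I_disp − Ī_disp)²)`,

   which must decrease / increase respectively.
3. The **AHA 17-segment model** partitions the LV myocardium mask from three
   landmarks (apex, mitral-base center, anterior RV insertion).
4. `u` is applied to the contour points of the CTV, the 17 segments and the
   ICD lead tip; motion is reported as signed center-of-mass components
   along RL/AP/SI with 3D magnitude, plus per-point statistics.
5. **Concordance** of ICD-tip vs CTV/segment motion across cases uses the
   Pearson coefficient, the Wilcoxon signed-rank test (exact for n ≤ 15) and
   the Euclidean distance between paired motion series, supporting the
   question of when lead-tip tracking is an adequate motion surrogate.

Because clinical ECG-gated CTs cannot be bundled, the package includes a
synthetic deforming-heart phantom (ellipsoidal-shell LV with textured wall,
RV blood pool and ICD lead marker) whose end-systolic geometry is the image
of the end-diastolic geometry under a closed-form contraction + twist — so
every estimate can be verified against exact ground truth. See
`docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from cardiomotion import PhantomSpec, register
from cardiomotion.phantom import emit_case, analytic_displacement
from cardiomotion.motion import summarize_structure

# default phantom: 96^3 voxels at 1 mm, radial scale 0.9,
# longitudinal scale 0.95, twist 0.2 deg/mm
case = emit_case(PhantomSpec())
field = register(case.ed, case.es)          # ED -> ES motion field

ctv = case.ground_truth.ed_structures["CTV"]
summary = summarize_structure(field, ctv)
true = analytic_displacement(ctv.points, case.spec).mean(axis=0)

print(f"CTV CoM motion (RL, AP, SI): "
      f"({summary.com.rl:+.2f}, {summary.com.ap:+.2f}, {summary.com.si:+.2f}) mm")
print(f"CTV CoM motion 3D: {summary.com.magnitude_3d:.2f} mm")
print(f"analytic ground truth 3D:  {np.linalg.norm(true):.2f} mm")
print(f"recovery error: {np.linalg.norm(summary.com.as_vector() - true):.2f} mm")
print(f"per-point 3D motion: {summary.pointwise['mag_3d']['mean']:.2f} "
      f"+/- {summary.pointwise['mag_3d']['sd']:.2f} mm over {summary.n_points} points")
```

prints (~30 s on one core):

```
CTV CoM motion (RL, AP, SI): (-2.43, -1.55, +1.07) mm
CTV CoM motion 3D: 3.07 mm
analytic ground truth 3D:  3.18 mm
recovery error: 0.26 mm
per-point 3D motion: 3.14 +/- 0.38 mm over 250 points
```

The CTV on this phantom moves ~3 mm between phases; the pipeline recovers
its CoM motion to a quarter millimetre, and the per-point mean exceeding the
CoM magnitude quantifies the non-rigid part of the motion.

The same workflow is available from the shell:

```bash
cardiomotion phantom --out case --seed 0
cardiomotion run --config config.json      # register -> segment -> motion -> maps
cardiomotion report --motion-csv out/motion.csv --out bullseye.png
```

A run writes the displacement field (NIfTI + JSON sidecar), the AHA label
map, per-structure motion CSVs, ICD-tip/segment distance tables, 17-segment
bull's-eye maps, and a manifest that makes the run byte-reproducible.

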