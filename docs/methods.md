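# Methods

`cardiomotion` estimates heartbeat-induced motion of radiotherapy target
structures from a pair of ECG-gated cardiac CT reconstructions — one at
end-diastole (ED), one at end-systole (ES) — for stereotactic arrhythmia
radioablation (STAR) planning. This note records the model, the parameter
choices and their rationale, what the verification phantom does and does not
emulate, and the numerical conventions.

## Processing chain

1. **Non-rigid registration.** The ED volume is registered to the ES volume
   with a multi-resolution demons scheme (SimpleITK's classic
   `DemonsRegistrationFilter` inside an explicit Gaussian pyramid), producing
   a dense displacement field in voxel units on the ED grid.
2. **Quality control.** Inside a region of interest formed by the union of
   the ED myocardium mask and its field-displaced copy, the mean squared HU
   error `MSE = (1/N) Σ (I_orig − I_disp)²` and the Pearson correlation `r`
   between the ES image and the displaced ED image are compared with the
   same quantities before registration. A successful registration lowers the
   MSE and raises the PCC.
3. **AHA 17-segment partition.** The LV myocardium mask is divided into the
   standard 6 basal / 6 mid / 4 apical segments plus apical cap from three
   landmarks (epicardial apex, mitral-base center, anterior RV insertion).
4. **Motion quantification.** The field is sampled trilinearly at the mm
   contour points of each structure (CTV, 17 segments, ICD lead tip),
   converted to mm per axis via the voxel spacing, and summarised as the
   signed center-of-mass (CoM) motion along RL/AP/SI plus 3D magnitude,
   together with per-point motion statistics (mean/sd/median/min/max of
   |RL|, |AP|, |SI| and 3D magnitude). Because the wall deforms non-rigidly,
   CoM motion alone understates local motion; the per-point 3D mean is
   always ≥ the CoM magnitude (Jensen), and the gap measures non-rigidity.
5. **Concordance.** Across cases, ICD-tip motion is compared with CTV and
   segment motion by Pearson correlation (p from the t-transform with n−2
   degrees of freedom), the two-sided Wilcoxon signed-rank test, and the
   Euclidean distance `sqrt(Σ_cases (a_i − b_i)²)`.

## Field direction convention

The `DisplacementField` is a *forward motion field*: a material point at ED
position `q` (voxel units) maps to ES position `q + u(q)`. Applying the
field to ED contours therefore yields their ES positions directly.
`warp_volume(v, u)` resamples `v` at `q + u(q)`, which pulls the **ES**
volume back onto the ED grid; to displace the **ED** volume into the ES
frame (the "registered ED CT" used by the quality metrics), the field is
first inverted by fixed-point iteration (`invert_field`, solving
`v(x) = −u(x + v(x))`; convergent for the smooth sub-voxel-gradient fields
produced here, residual composition error < 0.05 voxel). Internally the
demons solver runs with the ED volume as its reference image, which yields
this forward field directly.

## Registration parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| pyramid levels | 3 | – | captures ~5 mm motion from coarse scale |
| iterations per level | 100/100/100 | – | converged on phantoms; more iterations do not change the equilibrium |
| update smoothing sigma | 1.0 | voxel | fluid-like regularisation of each demons step |
| field smoothing sigma | 0.5 | voxel | see below |
| convergence tolerance | 1e-3 | voxel RMS update | early stop, e.g. for self-registration |

Heavier field (elastic-like) smoothing systematically shrinks the
recovered motion toward zero near weakly textured wall patches; on deforming
phantoms a field sigma of 1.0 voxel left worst-segment CoM errors of
~0.7 mm, while 0.5 voxel with the 1.0-voxel update smoothing reaches
~0.4 mm without visible field noise. Both sigmas and the schedule remain
user-configurable per run. Registration runs single-threaded, so repeated
runs are bit-identical.

## The verification phantom

Real ECG-gated patient CTs cannot ship with the package, so correctness is
demonstrated on a synthetic deforming heart with closed-form ground truth.

**Geometry.** A truncated half-ellipsoid LV shell (epicardial semi-axes
30×26 mm, wall 10 mm, base-to-apex 70 mm — adult-LV scale), contrast blood
pool (400 HU) inside, myocardium at 150 HU, background −50 HU; an anterior
RV blood-pool crescent (300 HU) carrying an ICD lead rendered as a
2 mm-radius, 10 mm-long capsule at 2000 HU whose tip is the tracked marker;
a CTV sampled as ~250 points of a sphere intersected with the wall
(emulating an RTSS contour cloud). Default grid 96³ at 1 mm isotropic.

**Deformation.** ED→ES is a separable analytic contraction about the long
axis: short-axis scaling (default 0.9), long-axis scaling (0.95), and twist
(0.2°/mm of ED long-axis distance from the base, apex rotating most). It is
smooth and exactly invertible, so the ES image is rendered by evaluating the
ED geometry at exactly inverse-transformed coordinates and every structure's
true displacement is known analytically. This is a kinematic stand-in, not a
biomechanical model: it exercises every pipeline stage with exact ground
truth, which is all the verification requires.

**Wall texture — why it exists.** A homogeneous shell makes motion
tangential to iso-intensity surfaces (the twist, most of the longitudinal
shortening) invisible to *any* intensity-based registration — the aperture
problem. Measured on such a shell, demons recovers the radial component to
0.4 voxel while the tangential error stays near the full tangential motion.
Real myocardium is not homogeneous (trabeculation, non-uniform contrast
enhancement), so the phantom carries a smooth material-attached HU
heterogeneity: a band-limited Gaussian random field (amplitude 40 HU,
correlation length 6 mm, cubic-spline interpolated) evaluated in material
coordinates, hence deforming exactly with the ground truth. Likewise the RV
pool exists because an isolated bright marker in static background has its
motion systematically under-recovered; embedded in deforming contrast blood
it is tracked to ~0.4 mm.

**What the phantom does not emulate,** and hence what passing tests do not
show about patient data: respiratory motion (the clinical CTs are
breath-hold), CT physics (beam hardening, metal artefacts around the lead,
dose-dependent noise correlation — phantom noise is white, 5 HU, and shares
its realisation between phases so that an identity deformation yields
bit-identical volumes), multi-chamber anatomy, valve plane motion, and
through-plane intensity inflow. Accuracy numbers from the phantom are
best-case for well-contrasted, artefact-free acquisitions.

## AHA partition conventions

The long-axis coordinate `t` runs 0→1 from base center to apex by
projection. The apical cap (17) is myocardium distal to the cavity's apical
extent `t_cap`; `[0, t_cap]` splits into equal basal/mid/apical thirds. The
circumferential angle starts at the RV-insertion direction and increases
anterior → anteroseptal, with 60° sectors (basal/mid) and 90° sectors offset
45° (apical, so the apical-anterior sector straddles the reference). These
conventions, and `t_cap`, are recorded in the label-map metadata. Sector
boundaries are half-open; a voxel exactly on a boundary joins the
counter-clockwise sector. Landmarks are inputs (phantom ground truth or
user annotation); automatic segmentation is out of scope.

## Statistics conventions

* **Wilcoxon signed-rank:** zero differences dropped by default (`pratt`
  available); exact two-sided p by enumeration of all 2ⁿ sign assignments of
  the observed ranks for n ≤ 15 (valid under ties), else normal
  approximation with tie correction and 0.5 continuity correction; ≥5
  nonzero pairs required.
* **Pearson p:** two-sided, `t = r·sqrt((n−2)/(1−r²))` with n−2 df;
  constant inputs raise an error (reported as NaN in cross-case tables).
* **Euclidean distance:** per direction on *signed* CoM components and in 3D
  on magnitudes, not normalised by case count — the convention is written
  into output metadata since either choice is defensible.
* **Tip selection:** with several RV leads, the tip whose CoM is most
  inferior along SI is analysed; ties break by structure name.
* Points outside the field grid are clamped to the edge and counted; a
  structure with >1 % clamped points fails the run.

## Problem sizes and determinism

The shipped tests verify ground-truth recovery on the default 96³ phantom
(~30 s including registration on one core) and run the remaining properties
on 48³–96³ phantoms; `scripts/acceptance.py` re-generates everything from
scratch (default phantom, a self-registration null, and a 6-case battery
with varied contraction for the concordance statistics) in about one minute.
All randomness flows from explicit seeds; registration, rendering, CSV and
manifest outputs are byte-reproducible (manifests record versions,
parameters and input hashes, never timestamps).

## Known limitations

* Tangential motion recovery depends on wall texture; in texture-poor
  patches the smoothing equilibrium under-estimates motion (worst-segment
  CoM error ~0.4–0.6 mm across phantom noise seeds at the default settings).
* The demons variant is single-channel and intensity-conserving; contrast
  differences between phases would need histogram matching upstream.
* The AHA partition assumes a roughly convex LV with a well-defined long
  axis; severely remodelled ventricles may need manual landmark care.
* DICOM-RT ingestion is a minimal adapter (contour points only, no holes/
  ruled surfaces); the native exchange format is the JSON point set.
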