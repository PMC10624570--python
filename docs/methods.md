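# Methods

## Problem

In MR-guided adaptive radiotherapy of prostate cancer a new MRI is acquired
at every treatment fraction, and the planning delineations of the clinical
target volume (CTV) and the organs at risk (OARs: bladder, rectum) must be
transferred to the daily anatomy. This package implements and compares five
contour-propagation strategies on synthetic pelvic phantom cohorts:

1. **copy** — rigid copying of the planning contours (the crop around the
   CTV centroid plays the role of the clinical rigid pre-alignment);
2. **bspline** — classical multi-stage B-spline deformable registration of
   the planning image onto the fraction image, followed by contour
   propagation with the resulting dense displacement field (DDF);
3. **bm** — a generic 3D U-Net segmentation network trained on many
   patients' planning scans (one network per structure);
4. **psm** — the baseline network fine-tuned per patient on its own
   augmented planning scan;
5. **ddfm** — a 3D U-Net that takes the (planning, fraction) image pair and
   predicts the DDF directly; a parameter-free spatial transformer layer
   warps the planning image and contours with it.

## Conventions

Volumes are arrays indexed `(x, y, z)` with axial slices along `z`, physical
voxel spacing in mm, and voxel centres at `index * spacing`. Displacement
fields are stored in millimetres with the *backward* warping convention:
the propagated value at fixed-grid (fraction) point `x` is sampled from the
moving (planning) volume at `x + u(x)`, with trilinear interpolation and
border clamping. Binary masks are propagated by linear interpolation of the
{0,1} map followed by thresholding at 0.5; slice-thickness resampling of
masks uses nearest neighbour instead.

## Synthetic phantoms

No public MR-Linac dataset exists, so every experiment runs on synthetic
cohorts that reproduce the *statistical structure* of the clinical problem
rather than its image appearance. A patient is a set of geometric
primitives: a bladder ellipsoid, a rectum tube, a CTV ellipsoid and an
elliptical body cylinder, rendered as piecewise-constant tissue intensities
(fluid-bright bladder 0.9, dark rectum 0.15, intermediate prostate 0.55,
muscle/fat body 0.30 on an arbitrary 0–1 scale, emulating bSSFP contrast
qualitatively only) plus additive Gaussian noise (SD 0.02) and an optional
smooth multiplicative bias field (off by default so that noiseless renders
take the configured means exactly).

Fraction scans are **re-rendered from deformed geometry**, not produced by
warping the planning masks: bladder and rectum volumes are rescaled by
factors drawn uniformly from ×[0.6, 1.8] and ×[0.7, 1.5] respectively, the
CTV receives a small rigid Gaussian shift (SD 1.5 mm), and a smooth random
background deformation (B-spline, ≤ 2 mm) displaces the OAR centres. This
matters: genuine organ-volume change — which a smooth displacement field
cannot express — therefore exists in the ground truth, which is exactly the
failure mode the deformation-network comparison probes. Inter-patient
variability comes from jittering organ centres (± 2.5 mm) and axes (± 12 %).
All randomness flows through one seed hierarchy (cohort → patient →
fraction), so cohorts are exactly reproducible.

What the phantoms do *not* model: realistic MR physics (no Bloch
simulation, coils, artefacts), soft-tissue texture, sliding interfaces,
inter-observer contouring variability, and contour style differences
between hospitals. Passing tests therefore demonstrate correctness of the
algorithms and the *direction* of method differences under controlled
anatomy change, not clinical-level performance numbers.

## Network and training

One encoder–decoder serves all deep strategies: each resolution level has
two 3×3×3 convolutions with instance normalisation and PReLU, downsampling
by stride-2 convolution, upsampling by 2×2×2 transposed convolution with
skip concatenation; a final 3×3×3 convolution forms either a 1-channel
sigmoid segmentation head or a 3-channel displacement head. The
displacement head works in voxel units internally (scale-free learning) and
its weights start near zero so training begins at the identity transform;
conversion to millimetres happens at the module boundary. Because no deep
learning framework is available in the target environment, the package
carries its own compact reverse-mode autodiff core (numpy), including a
trilinear grid sampler differentiable in both the image and the field; its
gradients are verified against finite differences in the test suite.

The deformation objective is

```
L_tot = λ_DDF (λ_DDF,L2 · L2(u, u_gt) + λ_DDF,reg · L_bend(u))
      + λ_seg · L_dice + λ_img · L_img
```

with defaults λ_DDF = 1, λ_DDF,L2 = 0, λ_DDF,reg = 10, λ_seg = 100,
λ_img = 1 (the tuned at-once / true-pairs / L2-image configuration). The
L2-to-ground-truth term exists only for synthetically generated pairs with a
known field. Bending energy is the mean over interior voxels of the summed
squared second spatial derivatives of the three field components (mixed
terms doubled, central differences, spacing-aware); it vanishes exactly on
affine fields. Reductions use means, not sums, so weights transfer across
grid sizes. The multi-scale Dice loss averages a squared-denominator
soft-Dice term over Gaussian-smoothed copies of prediction and target
(default scales 0/2/4 voxels); the squared-denominator form equals plain
soft Dice on binary masks but stays exactly zero for identical smoothed
(non-binary) maps, which keeps the term calibrated across scales.

Training regimes: the baseline model minimises soft Dice on planning scans
(Adam, lr 1e-3); patient-specific fine-tuning continues from the baseline on
one patient's planning scan with augmentation (random affine + elastic +
intensity perturbations) re-sampled every step (lr 1e-4); the deformation
model trains through the spatial transformer on either synthetic pairs with
known fields (random smooth B-spline fields, or fields pooled from the
registration benchmark — the "realistic" variant) or true planning–fraction
pairs without ground-truth field. A progressive schedule is available: with
n levels, stage s trains on inputs resolution-degraded by factor
2^(n−1−s) (block-mean pooling then nearest upsampling back to the full
grid, so divisibility constraints never change), epochs split evenly with
the remainder on the final full-resolution stage. No optimiser or learning
rate is prescribed by the protocol this package follows; Adam with the
rates above is this package's choice and both are exposed in config.
The deformation network is trained once with all structures in the
segmentation loss by default (a per-structure option exists in config);
at desk scale the shared network is the practical choice and the
comparison is unaffected because all methods share the test set.

## Registration benchmark

The classical comparator is a generic multi-resolution B-spline
registration written against this package's own primitives: cubic B-spline
control-point offsets (three stages, control spacing 32/16/8 voxels by
default) are optimised by L-BFGS-B on mean-squared intensity difference (or
1−NCC) plus a bending-energy penalty (weight 0.01) on the dense field. The
similarity gradient with respect to the dense field comes from the
differentiable sampler and is projected onto the control lattice by the
exact adjoint of the tensor-product B-spline interpolation operator, so the
optimiser receives exact gradients. Stages run coarse to fine; each stage
optimises an additive correction to the accumulated field. This is a
standard recipe, not a reproduction of any particular tool's staging.

## Evaluation protocol

Per fraction and structure: DSC, HD95 and HDavg. Surface voxels are
foreground voxels with a face-adjacent background neighbour; directed
surface distances are Euclidean (mm, spacing-aware); HD95 is the maximum of
the two directed 95th percentiles (linear-interpolation percentiles) and
HDavg the mean of the two directed means — symmetric conventions chosen so
tests are exact. The rectum is evaluated only on axial slices spanning the
planning PTV (CTV dilated isotropically by 5 mm, a config knob) plus a
15 mm margin above and below its ends — 10 extra slices at 1.5 mm
thickness; bladder and CTV use the full grid. Empty predictions score
DSC 0 with distances flagged missing.

Aggregation is two-stage to avoid biasing towards patients with many
fractions: fraction metrics are first averaged per patient, then the cohort
mean and SD are taken over per-patient means. Normality of per-patient
means is checked with a one-sample Kolmogorov–Smirnov test against a normal
with estimated parameters (the plain KS p-value is conservative when
parameters are estimated — Lilliefors caveat, accepted and documented);
methods are compared with two-sided paired t-tests at α = 0.05, without
multiple-testing correction (none is part of the protocol). Zero-variance
differences and both-empty masks are flagged degenerate rather than
propagated silently.

## Problem sizes

Clinical-scale inputs are 192³ voxels at 1.5 mm; all defaults in this
package are desk-scale so the full pipeline runs on one CPU: phantoms are
generated on 24³–64³ grids at 1.5–4 mm over the same 96 mm physical box,
cropped to 16³–48³ around the CTV centroid, with networks of 4–5 levels and
4–16 base channels, cohorts of ~5 training and ~3 test patients with 3
fractions, and 40–200 training epochs. Synthetic ground-truth fields for
supervised deformation training use ~5 control points and ≤ 10 mm
amplitude — the proportional analogue, on a 96 mm box, of 10 control points
and ≤ 35 mm on the clinical 288 mm box. The supervised deformation-recovery
experiment uses the widest network (16 base channels) and a pure
field-regression objective, the configuration that recovers held-out fields
best at this scale; even so its single-pass endpoint-error reduction
plateaus around 40–45 % of the zero-field baseline, because the
piecewise-constant phantom leaves the field unobservable over much of the
grid and the CPU step budget is limited — the warped-contour accuracy is
nevertheless high (DSC ≈ 0.94). The clinical-scale settings (192³, five
levels, 200/300/500 epochs, 125 training pairs) remain expressible in the
config schema but are not exercised by the tests.

## Known limitations

* Phantom appearance is far simpler than bSSFP anatomy; absolute metric
  values are optimistic (e.g. B-spline registration is stronger here than
  on clinical data because the images are nearly piecewise constant).
  Only directional comparisons between methods carry over — and not all of
  them do: on clinical data, deformation networks are reported to fail on
  organs with substantial volume change, but the phantom bladder is a
  bright homogeneous ellipsoid whose whole extent fits inside the network's
  receptive field at desk scale, so the deformation model inflates it
  easily and matches the segmentation models at most seeds. The package
  measures and reports this divergence rather than tuning the phantom until
  the clinical ordering appears.
* The B-spline benchmark is a generic recipe; it is not numerically
  comparable to any specific clinical registration implementation.
* The crop-based rigid alignment quantises to whole voxels, so a residual
  sub-voxel (up to half-voxel) misalignment remains between planning and
  fraction grids — intentional, as it emulates imperfect manual alignment,
  but it bounds the rigid-copy ceiling except in the zero-change scenario.
* No dosimetric evaluation and no physician grading; geometric metrics only.
* Deformation fields are unconstrained apart from bending energy: no
  diffeomorphism guarantee, no folding correction.
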