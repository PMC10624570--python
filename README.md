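# contourprop

Contour-propagation strategies for daily MR-guided adaptive radiotherapy of
prostate cancer, compared on synthetic pelvic phantom cohorts.

At every treatment fraction on an MR-Linac a fresh MRI is acquired, and the
planning contours of the clinical target volume (CTV) and the organs at risk
(bladder, rectum) must be transferred to the daily anatomy. This package
implements the competing strategies end to end and evaluates them with a
common geometric and statistical protocol:

* **rigid copying** of the planning contours (the crop around the CTV
  centroid stands in for the clinical rigid alignment);
* **multi-stage B-spline deformable registration** (L-BFGS-B on cubic
  B-spline control points, exact adjoint gradients, bending-energy
  regularised) with contour propagation;
* **baseline segmentation networks (BM)** — a 3D U-Net per structure
  (two 3×3×3 convolutions per level, instance norm, PReLU, strided
  downsampling, up-convolutions) trained on many patients' planning scans;
* **patient-specific models (PSM)** — the baseline fine-tuned on one
  patient's augmented planning scan;
* **deformation models (DDFM)** — the same U-Net predicting a dense
  displacement field (DDF) from the (planning, fraction) pair, applied
  through a differentiable spatial transformer, trained with

  `L = λ_DDF(λ_L2·‖u−u_gt‖² + λ_reg·BendingEnergy(u)) + λ_seg·Dice + λ_img·Sim`

  with defaults λ_DDF=1, λ_L2=0, λ_reg=10, λ_seg=100, λ_img=1, on either
  synthetic pairs with known ground-truth fields or true planning–fraction
  pairs.

Evaluation: Dice similarity coefficient (DSC), 95th-percentile (HD95) and
average (HDavg) Hausdorff surface distance per fraction; the rectum is
scored only on slices spanning the PTV ± 15 mm; metrics are averaged per
patient first, then over patients; Kolmogorov–Smirnov normality check and
two-sided paired t-tests at α = 0.05 compare methods.

Because no public MR-Linac dataset exists, a first-class phantom module
generates reproducible cohorts whose fraction anatomies genuinely change
volume (bladder ×[0.6, 1.8], rectum ×[0.7, 1.5], small CTV shifts, smooth
background deformation) — fraction masks are re-rendered from deformed
geometry, never warped, so organ volume change that a smooth displacement
field cannot express exists in the ground truth. The networks run on a
small self-contained numpy autodiff core (no GPU framework required); see
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import dataclasses
from contourprop import (AnatomyParams, VariationParams, make_planning_case,
                         sample_fraction_case, bspline_register,
                         propagate_contours, rigid_copy, dsc)

# one synthetic patient: planning scan + one fraction with a fuller bladder
case = make_planning_case(AnatomyParams(grid_shape=(32, 32, 32),
                                        spacing_mm=(3.0, 3.0, 3.0), seed=7))
case = sample_fraction_case(case, VariationParams(
    bladder_volume_factor_range=(1.5, 1.5), ctv_shift_sd_mm=0.0,
    elastic_amplitude_mm=0.0, seed=1), n_fractions=1)
frac = case.fractions[0]

copied = rigid_copy(case.planning_structures, frac.image)
ddf = bspline_register(frac.image, case.planning_image)
registered = propagate_contours(case.planning_structures, ddf)

for name in ("bladder", "rectum", "ctv"):
    print(f"{name:8s} copy DSC {dsc(copied.masks[name], frac.structures.masks[name]):.3f}"
          f"  B-spline DSC {dsc(registered.masks[name], frac.structures.masks[name]):.3f}")
```

prints

```
bladder  copy DSC 0.811  B-spline DSC 0.962
rectum   copy DSC 0.829  B-spline DSC 0.844
ctv      copy DSC 1.000  B-spline DSC 0.966
```

The bladder volume grew ×1.5 between planning and fraction, so rigidly
copied contours overlap poorly (DSC 0.81) while deformable registration
recovers most of the change (0.96). The CTV did not move, so rigid copying
is perfect there and registration can only lose accuracy — the same
ordering the full experiment shows for near-rigid targets.

The full comparison (cohort generation → BM/PSM/DDFM training → benchmarks
→ metrics → report) runs from a YAML config:

```
contourprop run --config experiment.yaml
contourprop generate --out cohort_dir --seed 1 --n-patients 3
```

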