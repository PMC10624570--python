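"""Canonical desk-scale replication experiments.

These builders define the study conditions used by the acceptance checks and
by `scripts/acceptance.py`: a five-method comparison on a cohort whose test
fractions undergo large bladder volume change with a near-rigid CTV, a
supervised deformation-recovery experiment on synthetic ground-truth fields,
and a registration-recovery experiment on a phantom warped by a known smooth
field.  Problem sizes are the package's desk-scale defaults (see
docs/methods.md); all randomness derives from the single seed argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .benchmarks import bspline_register, default_stages, propagate_contours
from .evaluation import dsc
from .grid_ops import crop_around_centroid, random_bspline_ddf, warp_image, \
    warp_mask
from .losses import LossWeights
from .network import NetworkSpec, predict_ddf
from .phantom import (AnatomyParams, AnatomyPrior, VariationParams,
                      make_cohort, make_planning_case)
from .pipeline import ExperimentConfig
from .training import TrainingConfig, make_supervised_pairs, train_ddfm

# scaled analogue of the clinical-size synthetic training fields
# (10 control points / <=35 mm on a 288 mm box -> 5 / <=10 mm on 96 mm)
FIELD_CONTROL_POINTS = 5
FIELD_AMPLITUDE_MM = 10.0
SMALL_FIELD_AMPLITUDE_MM = 4.0


def comparison_config(out_dir: str, seed: int) -> ExperimentConfig:
    """Five-method comparison; test fractions have large bladder filling
    change (volume factor 1.75-1.85) and a near-rigid CTV."""
    return ExperimentConfig(
        out_dir=out_dir, seed=seed,
        test_variation=VariationParams(
            bladder_volume_factor_range=(1.75, 1.85),
            rectum_volume_factor_range=(1.1, 1.4),
            ctv_shift_sd_mm=0.0, elastic_amplitude_mm=1.0),
    )


def _cropped_cohort(n_patients: int, seed: int, crop=(16, 16, 16),
                    spacing: float = 4.0):
    base = AnatomyParams(grid_shape=(24, 24, 24),
                         spacing_mm=(spacing,) * 3)
    cohort = make_cohort(n_patients, AnatomyPrior(base=base),
                         VariationParams(), seed=seed, n_fractions=1)
    out = []
    for c in cohort:
        img, st = crop_around_centroid(c.planning_image,
                                       c.planning_structures, "ctv", crop)
        out.append(dataclasses.replace(c, planning_image=img,
                                       planning_structures=st, fractions=[]))
    return out


def ddf_recovery_experiment(seed: int, epochs: int = 200,
                            n_train_patients: int = 8,
                            n_test_patients: int = 2) -> dict:
    """Train a deformation network on synthetic ground-truth fields
    (resampled on the fly per epoch) and measure held-out recovery.

    Pure supervised field regression (L2-to-truth dominant, light bending
    penalty): the configuration that recovers fields best at desk scale.
    Returns mean endpoint error of the prediction and of the zero-field
    baseline, the relative reduction, and the warped-contour DSC on
    small-deformation held-out pairs.
    """
    cases = _cropped_cohort(n_train_patients + n_test_patients, seed=seed * 100 + 1)
    train_cases = cases[:n_train_patients]
    test_cases = cases[n_train_patients:]

    def on_the_fly(epoch, rng):
        return make_supervised_pairs(
            train_cases, n_per_case=2,
            field_control_points=FIELD_CONTROL_POINTS,
            field_amplitude_mm=FIELD_AMPLITUDE_MM,
            seed=int(rng.integers(2 ** 31)))

    cfg = TrainingConfig(
        regime="DDFM", ddfm_data_variant="gt_synthetic_ddf",
        epochs=epochs, batch_size=2, learning_rate=3e-3,
        weights=LossWeights(lambda_ddf=1.0, lambda_ddf_l2=1.0,
                            lambda_ddf_reg=1.0, lambda_seg=0.0,
                            lambda_img=0.0),
        network=NetworkSpec(n_levels=4, base_channels=16),
        seed=seed)
    model = train_ddfm(on_the_fly, cfg)

    test_pairs = make_supervised_pairs(
        test_cases, n_per_case=4, field_control_points=FIELD_CONTROL_POINTS,
        field_amplitude_mm=FIELD_AMPLITUDE_MM, seed=seed * 100 + 2)
    epe, epe0 = [], []
    for pr in test_pairs:
        pred = predict_ddf(model, pr.planning_image, pr.fraction_image)
        epe.append(np.linalg.norm(pred.vectors - pr.gt_ddf.vectors, axis=0).mean())
        epe0.append(np.linalg.norm(pr.gt_ddf.vectors, axis=0).mean())

    small_pairs = make_supervised_pairs(
        test_cases, n_per_case=4, field_control_points=FIELD_CONTROL_POINTS,
        field_amplitude_mm=SMALL_FIELD_AMPLITUDE_MM, seed=seed * 100 + 3)
    dscs = []
    for pr in small_pairs:
        pred = predict_ddf(model, pr.planning_image, pr.fraction_image)
        for name, mask in pr.planning_masks.items():
            dscs.append(dsc(warp_mask(mask, pred), pr.fraction_masks[name]))

    return {"epe_mm": float(np.mean(epe)),
            "epe_zero_field_mm": float(np.mean(epe0)),
            "epe_reduction": float(1.0 - np.mean(epe) / np.mean(epe0)),
            "warped_contour_dsc": float(np.mean(dscs)),
            "model": model}


def registration_recovery_experiment(seed: int, grid: int = 48,
                                     spacing: float = 2.0,
                                     amplitude_mm: float = 6.0) -> dict:
    """Warp a phantom by a known smooth field and register it back."""
    params = AnatomyParams(grid_shape=(grid,) * 3, spacing_mm=(spacing,) * 3,
                           seed=seed)
    case = make_planning_case(params)
    img = case.planning_image
    gt = random_bspline_ddf(img.shape, img.spacing_mm, FIELD_CONTROL_POINTS,
                            amplitude_mm, seed=seed + 1)
    warped = warp_image(img, gt)
    truth = {n: warp_mask(m, gt) for n, m in case.planning_structures.masks.items()}
    rec = bspline_register(warped, img, default_stages(spacing))
    prop = propagate_contours(case.planning_structures, rec)
    dscs = {n: dsc(prop.masks[n], truth[n]) for n in truth}
    return {"epe_mm": float(np.linalg.norm(rec.vectors - gt.vectors,
                                           axis=0).mean()),
            "mean_gt_displacement_mm": float(np.linalg.norm(gt.vectors,
                                                            axis=0).mean()),
            "contour_dsc": dscs}
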