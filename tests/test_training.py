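"""Training regimes: schedules, augmentation, loss descent, fine-tuning."""

import dataclasses

import numpy as np
import pytest

from contourprop.grid_ops import crop_around_centroid
from contourprop.losses import ConfigurationError, LossWeights
from contourprop.network import NetworkSpec, predict_segmentation
from contourprop.phantom import (AnatomyPrior, VariationParams, make_cohort)
from contourprop.training import (AugmentParams, DataError, RegistrationPair,
                                  TrainingConfig, augment_case,
                                  finetune_patient, make_supervised_pairs,
                                  progressive_schedule, train_baseline,
                                  train_ddfm)
from tests.conftest import small_anatomy

TINY_NET = NetworkSpec(n_levels=3, base_channels=2)


@pytest.fixture(scope="module")
def tiny_cohort():
    cohort = make_cohort(3, AnatomyPrior(base=small_anatomy()),
                         VariationParams(seed=0), seed=55, n_fractions=1)
    out = []
    for c in cohort:
        img, st = crop_around_centroid(c.planning_image, c.planning_structures,
                                       "ctv", (24, 24, 24))
        out.append(dataclasses.replace(c, planning_image=img,
                                       planning_structures=st, fractions=[]))
    return out


class TestProgressiveSchedule:
    def test_five_levels_two_hundred_epochs(self):
        stages = progressive_schedule(5, 200)
        assert [f for f, _ in stages] == [16, 8, 4, 2, 1]
        assert all(len(r) == 40 for _, r in stages)

    def test_remainder_goes_to_final_stage(self):
        stages = progressive_schedule(2, 3)
        assert [len(r) for _, r in stages] == [1, 2]

    def test_factors_strictly_decreasing_to_one(self):
        for n, e in [(3, 9), (4, 11), (5, 25)]:
            factors = [f for f, _ in progressive_schedule(n, e)]
            assert factors == sorted(factors, reverse=True)
            assert factors[-1] == 1
            assert len(set(factors)) == len(factors)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            progressive_schedule(4, 3)


class TestAugmentation:
    def test_zero_amplitudes_are_identity(self, planning_case):
        img, st = augment_case(planning_case.planning_image,
                               planning_case.planning_structures,
                               AugmentParams.none(), seed=3)
        np.testing.assert_array_equal(img.data, planning_case.planning_image.data)
        for n in st.masks:
            np.testing.assert_array_equal(
                st.masks[n], planning_case.planning_structures.masks[n])

    def test_determinism_under_seed(self, planning_case):
        a1 = augment_case(planning_case.planning_image,
                          planning_case.planning_structures,
                          AugmentParams(), seed=11)
        a2 = augment_case(planning_case.planning_image,
                          planning_case.planning_structures,
                          AugmentParams(), seed=11)
        np.testing.assert_array_equal(a1[0].data, a2[0].data)
        np.testing.assert_array_equal(a1[1].masks["bladder"],
                                      a2[1].masks["bladder"])

    def test_rotation_preserves_mask_volume_within_voxelization_error(
            self, planning_case):
        params = AugmentParams(rotation_deg=10.0, translation_mm=0.0,
                               scale_range=(1.0, 1.0),
                               elastic_amplitude_mm=0.0, noise_sd=0.0,
                               intensity_scale_range=(1.0, 1.0))
        _, st = augment_case(planning_case.planning_image,
                             planning_case.planning_structures, params, seed=4)
        for n in ("bladder", "ctv"):
            v0 = int(planning_case.planning_structures.masks[n].sum())
            v1 = int(st.masks[n].sum())
            assert abs(v1 - v0) / v0 < 0.05


class TestBaselineTraining:
    def test_loss_decreases_and_missing_structure_rejected(self, tiny_cohort):
        cfg = TrainingConfig(regime="BM", epochs=8, batch_size=2,
                             learning_rate=1e-3, network=TINY_NET, seed=0)
        model = train_baseline(tiny_cohort, "bladder", cfg)
        assert model.history[-1]["seg"] < model.history[0]["seg"]
        broken = [dataclasses.replace(
            c, planning_structures=dataclasses.replace(
                c.planning_structures,
                masks={k: v for k, v in c.planning_structures.masks.items()
                       if k != "rectum"})) for c in tiny_cohort]
        with pytest.raises(DataError):
            train_baseline(broken, "rectum", cfg)
        with pytest.raises(DataError):
            train_baseline(tiny_cohort[:1], "bladder", cfg)

    def test_training_is_deterministic_under_seed(self, tiny_cohort):
        cfg = TrainingConfig(regime="BM", epochs=3, batch_size=2,
                             network=TINY_NET, seed=9)
        m1 = train_baseline(tiny_cohort, "bladder", cfg)
        m2 = train_baseline(tiny_cohort, "bladder", cfg)
        assert m1.history[-1]["seg"] == m2.history[-1]["seg"]


class TestFineTuning:
    def test_memorizes_single_planning_case_without_augmentation(self, tiny_cohort):
        base_cfg = TrainingConfig(regime="BM", epochs=15, batch_size=2,
                                  learning_rate=1e-3, network=TINY_NET, seed=1)
        bm = train_baseline(tiny_cohort, "bladder", base_cfg)
        ft_cfg = TrainingConfig(regime="PSM", epochs=60, batch_size=1,
                                learning_rate=3e-3, network=TINY_NET, seed=2,
                                augmentation=AugmentParams.none())
        psm = finetune_patient(bm, tiny_cohort[0], "bladder", ft_cfg)
        assert psm.history[-1]["seg"] < 0.1  # near-perfect memorization
        assert psm.n_parameters == bm.n_parameters
        prob = predict_segmentation(psm, tiny_cohort[0].planning_image)
        truth = tiny_cohort[0].planning_structures.masks["bladder"]
        overlap = 2 * ((prob > 0.5) & (truth > 0)).sum() / (
            (prob > 0.5).sum() + truth.sum())
        assert overlap > 0.85

    def test_missing_contour_rejected(self, tiny_cohort):
        cfg = TrainingConfig(regime="PSM", epochs=1, network=TINY_NET)
        bm = train_baseline(tiny_cohort, "bladder",
                            TrainingConfig(regime="BM", epochs=1,
                                           network=TINY_NET))
        with pytest.raises(DataError):
            finetune_patient(bm, tiny_cohort[0], "prostate_bed", cfg)


class TestDdfmTraining:
    def test_supervised_field_regression_reduces_l2(self, tiny_cohort):
        pairs = make_supervised_pairs(tiny_cohort, n_per_case=2,
                                      field_amplitude_mm=5.0, seed=3)
        cfg = TrainingConfig(
            regime="DDFM", ddfm_data_variant="gt_synthetic_ddf", epochs=10,
            batch_size=2, learning_rate=1e-3,
            weights=LossWeights(lambda_ddf=1.0, lambda_ddf_l2=1.0,
                                lambda_ddf_reg=0.0, lambda_seg=0.0,
                                lambda_img=0.0),
            network=NetworkSpec(n_levels=3, base_channels=2, in_channels=2,
                                head="displacement"),
            seed=4)
        model = train_ddfm(pairs, cfg)
        assert model.history[-1]["ddf_l2"] < model.history[0]["ddf_l2"]

    def test_variant_data_mismatch_is_a_configuration_error(self, tiny_cohort):
        pairs = make_supervised_pairs(tiny_cohort, n_per_case=1, seed=1)
        stripped = [dataclasses.replace(p, gt_ddf=None) for p in pairs]
        cfg = TrainingConfig(regime="DDFM", ddfm_data_variant="gt_synthetic_ddf",
                             epochs=1, network=NetworkSpec(
                                 n_levels=3, base_channels=2, in_channels=2,
                                 head="displacement"),
                             weights=LossWeights(lambda_ddf_l2=1.0))
        with pytest.raises(ConfigurationError):
            train_ddfm(stripped, cfg)
        no_frac_masks = [dataclasses.replace(p, fraction_masks=None)
                         for p in pairs]
        cfg2 = dataclasses.replace(cfg, ddfm_data_variant="true_pairs")
        with pytest.raises(ConfigurationError):
            train_ddfm(no_frac_masks, cfg2)

    def test_progressive_schedule_runs_and_descends(self, tiny_cohort):
        pairs = make_supervised_pairs(tiny_cohort, n_per_case=1,
                                      field_amplitude_mm=4.0, seed=6)
        cfg = TrainingConfig(
            regime="DDFM", ddfm_data_variant="gt_synthetic_ddf",
            schedule="progressive", epochs=9, batch_size=1,
            weights=LossWeights(lambda_ddf=1.0, lambda_ddf_l2=1.0,
                                lambda_ddf_reg=0.0, lambda_seg=0.0,
                                lambda_img=0.0),
            network=NetworkSpec(n_levels=3, base_channels=2, in_channels=2,
                                head="displacement"),
            seed=7)
        model = train_ddfm(pairs, cfg)
        factors = [h["factor"] for h in model.history]
        assert factors == [4, 4, 4, 2, 2, 2, 1, 1, 1]
        # descent is only comparable within a stage (fixed resolution)
        assert model.history[2]["ddf_l2"] < model.history[0]["ddf_l2"]
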