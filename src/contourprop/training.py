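"""Training regimes: baseline segmentation, patient-specific fine-tuning,
and deformation-network variants.

Three regimes are supported:

* **BM** — a generic segmentation network trained on many patients'
  planning scans for one structure;
* **PSM** — the baseline network fine-tuned on a single patient's planning
  scan with on-the-fly augmentation resampled at every step;
* **DDFM** — a displacement network trained through the spatial transformer
  with the weighted objective of :mod:`contourprop.losses`, on either
  synthetic pairs with known ground-truth fields (random smooth fields or
  registration-derived "realistic" fields) or on true planning--fraction
  pairs without a ground-truth field.

Training can run at once or on a progressive multi-resolution schedule that
starts from heavily resolution-degraded inputs and adds detail stage by
stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .grid_ops import (DisplacementField, StructureSet, VolumeImage,
                       random_bspline_ddf, warp_image, warp_mask)
from .losses import (ConfigurationError, LossWeights, bending_energy,
                     ddf_l2_loss, image_similarity_loss, multiscale_dice_loss,
                     soft_dice_loss, total_loss)
from .network import NetworkSpec, UNet3D, build_network
from .phantom import PatientCase


class DataError(ValueError):
    pass


@dataclass
class AugmentParams:
    """On-the-fly augmentation: affine + elastic + intensity perturbations."""

    rotation_deg: float = 5.0
    translation_mm: float = 3.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    elastic_amplitude_mm: float = 2.0
    elastic_control_points: int = 5
    noise_sd: float = 0.01
    intensity_scale_range: tuple[float, float] = (0.95, 1.05)

    @classmethod
    def none(cls) -> "AugmentParams":
        return cls(rotation_deg=0.0, translation_mm=0.0, scale_range=(1.0, 1.0),
                   elastic_amplitude_mm=0.0, noise_sd=0.0,
                   intensity_scale_range=(1.0, 1.0))


@dataclass
class TrainingConfig:
    regime: str = "BM"  # BM | PSM | DDFM
    ddfm_data_variant: str = "true_pairs"  # gt_synthetic_ddf | gt_realistic_ddf | true_pairs
    schedule: str = "at_once"  # at_once | progressive
    epochs: int = 60
    batch_size: int = 2
    learning_rate: float = 1e-3
    weights: LossWeights = field(default_factory=LossWeights)
    image_loss: str = "l2"
    dice_scales: tuple[float, ...] = (0.0, 2.0, 4.0)
    augmentation: AugmentParams = field(default_factory=AugmentParams)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.regime not in ("BM", "PSM", "DDFM"):
            raise ConfigurationError(f"unknown regime '{self.regime}'")
        if self.regime == "DDFM" and self.ddfm_data_variant not in (
                "gt_synthetic_ddf", "gt_realistic_ddf", "true_pairs"):
            raise ConfigurationError(
                f"unknown DDFM data variant '{self.ddfm_data_variant}'")
        self.weights.validate()


@dataclass
class RegistrationPair:
    """One planning->fraction training sample for the deformation network."""

    planning_image: VolumeImage
    fraction_image: VolumeImage
    planning_masks: dict[str, np.ndarray]
    fraction_masks: dict[str, np.ndarray] | None = None
    gt_ddf: DisplacementField | None = None


# -- segmentation training ---------------------------------------------------

def _seg_step(model: UNet3D, image: np.ndarray, mask: np.ndarray) -> ad.Tensor:
    x = ad.Tensor(np.asarray(image, dtype=np.float32)[np.newaxis])
    prob = ad.sigmoid(model.forward(x))
    return soft_dice_loss(prob, mask.astype(np.float32)[np.newaxis])


def train_baseline(planning_cases: list[PatientCase], structure: str,
                   config: TrainingConfig) -> UNet3D:
    """Train a generic single-structure segmentation network (BM)."""
    config.validate()
    if len(planning_cases) < 2:
        raise DataError("baseline training needs at least 2 planning cases")
    for case in planning_cases:
        if structure not in case.planning_structures.masks:
            raise DataError(f"case {case.patient_id} lacks structure '{structure}'")
    spec = dataclasses.replace(config.network, head="segmentation", in_channels=1)
    model = build_network(spec, seed=config.seed)
    opt = ad.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    model.history = []
    order = np.arange(len(planning_cases))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses_ep = []
        opt.zero_grad()
        pending = 0
        for idx in order:
            case = planning_cases[idx]
            loss = _seg_step(model, case.planning_image.data,
                             case.planning_structures.masks[structure])
            loss.backward()
            losses_ep.append(loss.item())
            pending += 1
            if pending == config.batch_size:
                _scale_grads(model, 1.0 / pending)
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            _scale_grads(model, 1.0 / pending)
            opt.step()
            opt.zero_grad()
        model.history.append({"epoch": epoch, "seg": float(np.mean(losses_ep)),
                              "total": float(np.mean(losses_ep))})
    return model


def _scale_grads(model: UNet3D, factor: float) -> None:
    for p in model.params:
        if p.grad is not None:
            p.grad *= factor


def finetune_patient(base_model: UNet3D, planning_case: PatientCase,
                     structure: str, config: TrainingConfig) -> UNet3D:
    """Patient-specific fine-tuning (PSM) on one augmented planning scan.

    All parameters are updated from the baseline initialisation; the
    augmentation is re-sampled at every step.
    """
    config.validate()
    if structure not in planning_case.planning_structures.masks:
        raise DataError(f"planning case lacks structure '{structure}'")
    model = base_model.clone()
    opt = ad.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    model.history = []
    for epoch in range(config.epochs):
        img_aug, st_aug = augment_case(planning_case.planning_image,
                                       planning_case.planning_structures,
                                       config.augmentation,
                                       seed=int(rng.integers(2 ** 31)))
        loss = _seg_step(model, img_aug.data, st_aug.masks[structure])
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.history.append({"epoch": epoch, "seg": loss.item(),
                              "total": loss.item()})
    return model


def augment_case(image: VolumeImage, structures: StructureSet,
                 params: AugmentParams, seed: int = 0
                 ) -> tuple[VolumeImage, StructureSet]:
    """Random affine + elastic deformation + intensity perturbation.

    The same geometric transform is applied to the image (linear
    interpolation) and to every mask (linear + 0.5 threshold); intensity
    noise and scaling touch the image only.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    shape = image.shape
    sp = np.asarray(image.spacing_mm)
    angles = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg, size=3))
    scale = rng.uniform(*params.scale_range)
    trans = rng.uniform(-params.translation_mm, params.translation_mm, size=3)

    identity = (np.allclose(angles, 0) and np.isclose(scale, 1.0)
                and np.allclose(trans, 0) and params.elastic_amplitude_mm == 0)
    if identity:
        img_out = image.data.copy()
        masks_out = {k: v.copy() for k, v in structures.masks.items()}
    else:
        R = _rotation_matrix(angles)
        center = (np.asarray(shape) - 1) * sp / 2.0
        grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)),
                            indexing="ij")
        pts = np.stack([g - c for g, c in zip(grids, center)])
        back = np.einsum("ij,jxyz->ixyz", R.T / scale, pts)
        u = back - pts - trans.reshape(3, 1, 1, 1)
        if params.elastic_amplitude_mm > 0:
            el = random_bspline_ddf(shape, image.spacing_mm,
                                    n_control_points=max(params.elastic_control_points, 4),
                                    max_displacement_mm=params.elastic_amplitude_mm,
                                    seed=rng)
            u = u + el.vectors
        ddf = DisplacementField(u, image.spacing_mm, image.origin_mm)
        img_out = warp_image(image, ddf).data
        masks_out = {k: warp_mask(v, ddf) for k, v in structures.masks.items()}

    gain = rng.uniform(*params.intensity_scale_range)
    img_out = img_out * gain
    if params.noise_sd > 0:
        img_out = img_out + rng.normal(0.0, params.noise_sd, size=shape)
    return (VolumeImage(img_out, image.spacing_mm, image.origin_mm),
            StructureSet(masks_out, structures.spacing_mm, structures.origin_mm))


def _rotation_matrix(angles) -> np.ndarray:
    ax, ay, az = angles
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# -- deformation-network training --------------------------------------------

def make_supervised_pairs(cases: list[PatientCase], n_per_case: int = 2,
                          structures: tuple[str, ...] = ("bladder", "rectum", "ctv"),
                          field_control_points: int = 5,
                          field_amplitude_mm: float = 6.0,
                          realistic_pool: list[DisplacementField] | None = None,
                          seed: int = 0) -> list[RegistrationPair]:
    """Build (planning, warped-planning, gt field) samples for supervised
    deformation training, by warping each planning scan with random smooth
    fields (or with fields drawn from a registration-derived pool)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for case in cases:
        for _ in range(n_per_case):
            if realistic_pool is not None:
                gt = realistic_pool[int(rng.integers(len(realistic_pool)))]
            else:
                gt = random_bspline_ddf(case.planning_image.shape,
                                        case.planning_image.spacing_mm,
                                        n_control_points=field_control_points,
                                        max_displacement_mm=field_amplitude_mm,
                                        seed=rng)
            frac_img = warp_image(case.planning_image, gt)
            frac_masks = {s: warp_mask(case.planning_structures.masks[s], gt)
                          for s in structures
                          if s in case.planning_structures.masks}
            pairs.append(RegistrationPair(
                planning_image=case.planning_image,
                fraction_image=frac_img,
                planning_masks={s: case.planning_structures.masks[s]
                                for s in structures
                                if s in case.planning_structures.masks},
                fraction_masks=frac_masks,
                gt_ddf=gt))
    return pairs


def pairs_from_cases(cases: list[PatientCase],
                     structures: tuple[str, ...] = ("bladder", "rectum", "ctv")
                     ) -> list[RegistrationPair]:
    """True planning--fraction pairs (no ground-truth field)."""
    pairs = []
    for case in cases:
        for frac in case.fractions:
            pairs.append(RegistrationPair(
                planning_image=case.planning_image,
                fraction_image=frac.image,
                planning_masks={s: case.planning_structures.masks[s]
                                for s in structures
                                if s in case.planning_structures.masks},
                fraction_masks={s: frac.structures.masks[s] for s in structures
                                if s in frac.structures.masks},
                gt_ddf=frac.gt_ddf))
    return pairs


def _degrade(arr: np.ndarray, factor: int) -> np.ndarray:
    """Resolution degradation at constant grid size: block-mean then repeat."""
    if factor == 1:
        return arr
    a = arr
    for axis in range(a.ndim - 3, a.ndim):
        n = a.shape[axis]
        if n % factor:
            raise ValueError("grid not divisible by the downsample factor")
        a = a.reshape(a.shape[:axis] + (n // factor, factor) + a.shape[axis + 1:])
        a = a.mean(axis=axis + 1)
    for axis in range(a.ndim - 3, a.ndim):
        a = np.repeat(a, factor, axis=axis)
    return a


def progressive_schedule(n_levels: int, total_epochs: int
                         ) -> list[tuple[int, range]]:
    """Coarse-to-fine stages: factor 2^(n_levels-1-s), even epoch split with
    the remainder assigned to the final full-resolution stage."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if total_epochs < n_levels:
        raise ValueError("need at least one epoch per stage")
    base = total_epochs // n_levels
    rem = total_epochs - base * n_levels
    stages = []
    start = 0
    for s in range(n_levels):
        n_ep = base + (rem if s == n_levels - 1 else 0)
        stages.append((2 ** (n_levels - 1 - s), range(start, start + n_ep)))
        start += n_ep
    return stages


def _ddfm_step(model: UNet3D, pair: RegistrationPair, config: TrainingConfig,
               factor: int = 1) -> tuple[ad.Tensor, dict]:
    sp = np.asarray(pair.planning_image.spacing_mm, dtype=np.float32)
    p_img = _degrade(np.asarray(pair.planning_image.data, dtype=np.float32), factor)
    f_img = _degrade(np.asarray(pair.fraction_image.data, dtype=np.float32), factor)
    x = ad.Tensor(np.stack([p_img, f_img]))
    out_vox = model.forward(x)
    u_mm = out_vox * sp.reshape(3, 1, 1, 1)

    components: dict = {}
    has_gt = pair.gt_ddf is not None
    components["ddf_reg"] = bending_energy(u_mm, tuple(sp))
    if has_gt and config.weights.lambda_ddf * config.weights.lambda_ddf_l2 > 0:
        gt = _degrade(pair.gt_ddf.vectors.astype(np.float32), factor)
        components["ddf_l2"] = ddf_l2_loss(u_mm, gt)
    if config.weights.lambda_seg > 0:
        if not pair.planning_masks or pair.fraction_masks is None:
            raise ConfigurationError("segmentation loss requires planning and "
                                     "fraction contours")
        seg_terms = []
        for name, pmask in pair.planning_masks.items():
            warped = ad.grid_sample(
                ad.Tensor(_degrade(pmask.astype(np.float32), factor)[np.newaxis]),
                out_vox)
            target = _degrade(pair.fraction_masks[name].astype(np.float32),
                              factor)[np.newaxis]
            seg_terms.append(multiscale_dice_loss(warped, target,
                                                  config.dice_scales))
        total_seg = seg_terms[0]
        for t in seg_terms[1:]:
            total_seg = total_seg + t
        components["seg"] = total_seg * (1.0 / len(seg_terms))
    if config.weights.lambda_img > 0:
        warped_img = ad.grid_sample(ad.Tensor(p_img[np.newaxis]), out_vox)
        components["img"] = image_similarity_loss(
            warped_img, ad.Tensor(f_img[np.newaxis]), kind=config.image_loss)
    loss = total_loss(components, config.weights, has_gt)
    log = {k: v.item() if isinstance(v, ad.Tensor) else float(v)
           for k, v in components.items()}
    return loss, log


def train_ddfm(pairs, config: TrainingConfig) -> UNet3D:
    """Train the displacement network on registration pairs.

    `pairs` is a list of RegistrationPair, or a callable `(epoch, rng) ->
    list` for on-the-fly pair generation (the ground-truth-field variants
    resample their random fields per epoch this way).
    """
    config = dataclasses.replace(config, regime="DDFM")
    config.validate()
    spec = dataclasses.replace(config.network, head="displacement", in_channels=2)
    model = build_network(spec, seed=config.seed)
    opt = ad.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    model.history = []

    def get_pairs(epoch):
        got = pairs(epoch, rng) if callable(pairs) else pairs
        for pr in got:
            if config.ddfm_data_variant.startswith("gt_") and pr.gt_ddf is None:
                raise ConfigurationError(
                    f"variant {config.ddfm_data_variant} requires ground-truth DDFs")
            if (config.ddfm_data_variant == "true_pairs"
                    and config.weights.lambda_seg > 0 and pr.fraction_masks is None):
                raise ConfigurationError(
                    "true_pairs variant requires fraction contours for the "
                    "segmentation loss")
        return got

    if config.schedule == "progressive":
        stages = progressive_schedule(spec.n_levels, config.epochs)
    else:
        stages = [(1, range(config.epochs))]

    for factor, epoch_range in stages:
        for epoch in epoch_range:
            ep_pairs = get_pairs(epoch)
            order = rng.permutation(len(ep_pairs))
            logs = []
            opt.zero_grad()
            pending = 0
            for idx in order:
                loss, log = _ddfm_step(model, ep_pairs[idx], config, factor)
                loss.backward()
                log["total"] = loss.item()
                logs.append(log)
                pending += 1
                if pending == config.batch_size:
                    _scale_grads(model, 1.0 / pending)
                    opt.step()
                    opt.zero_grad()
                    pending = 0
            if pending:
                _scale_grads(model, 1.0 / pending)
                opt.step()
                opt.zero_grad()
            entry = {"epoch": epoch, "factor": factor}
            for key in logs[0]:
                entry[key] = float(np.mean([lg[key] for lg in logs]))
            model.history.append(entry)
    return model
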