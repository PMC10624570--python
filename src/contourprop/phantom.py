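"""Synthetic pelvic phantom cohorts for contour-propagation experiments.

Each patient has a planning scan (image + physician-style structure masks
for bladder, rectum and CTV) and any number of fraction scans whose anatomy
genuinely differs from the planning day: bladder and rectum volumes are
rescaled by random factors, the CTV receives a small rigid shift, and a
smooth random background deformation displaces the organs-at-risk.  Fraction
masks are re-rendered from the deformed geometry rather than produced by
warping the planning masks, so inter-fraction organ volume change — the
phenomenon a smooth displacement field cannot express — exists in the ground
truth.

Intensities emulate bSSFP-like soft-tissue contrast only qualitatively:
piecewise-constant tissue means (fluid-filled bladder bright, rectum dark,
prostate intermediate) plus additive Gaussian noise and an optional smooth
multiplicative bias field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nifti
from .grid_ops import (DisplacementField, StructureSet, VolumeImage,
                       random_bspline_ddf)


class GeometryError(ValueError):
    """A structure does not fit inside the grid with the required margin."""


def _default_means() -> dict[str, float]:
    return {"background": 0.05, "body": 0.30, "bladder": 0.90,
            "rectum": 0.15, "ctv": 0.55}


@dataclass
class AnatomyParams:
    """Geometric and intensity parameters of one patient's pelvic anatomy.

    Lengths are millimetres on a grid whose voxel centres sit at
    ``index * spacing``. Defaults describe a desk-scale 64^3 pelvis at
    1.5 mm isotropic spacing.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    bladder_center: tuple[float, float, float] = (48.0, 30.0, 62.0)
    bladder_axes: tuple[float, float, float] = (13.0, 13.0, 13.0)
    rectum_centerline: tuple[float, float, float, float] = (48.0, 70.0, 18.0, 78.0)
    rectum_radius: float = 7.0
    ctv_center: tuple[float, float, float] = (48.0, 48.0, 44.0)
    ctv_axes: tuple[float, float, float] = (14.0, 12.0, 12.0)
    intensity_means: dict[str, float] = field(default_factory=_default_means)
    noise_sd: float = 0.02
    bias_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(a <= 0 for a in self.bladder_axes + self.ctv_axes) or self.rectum_radius <= 0:
            raise GeometryError("all axes and radii must be positive")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        margin = 2 * np.asarray(self.spacing_mm)
        for name, lo, hi in self._bounds():
            if np.any(np.asarray(lo) < margin) or np.any(np.asarray(hi) > extent - margin):
                raise GeometryError(f"structure '{name}' does not fit inside "
                                    f"the grid with a 2-voxel margin")

    def _bounds(self):
        bc, ba = np.asarray(self.bladder_center), np.asarray(self.bladder_axes)
        cc, ca = np.asarray(self.ctv_center), np.asarray(self.ctv_axes)
        x0, y0, z0, z1 = self.rectum_centerline
        r = self.rectum_radius
        yield "bladder", bc - ba, bc + ba
        yield "ctv", cc - ca, cc + ca
        yield "rectum", (x0 - r, y0 - r, z0), (x0 + r, y0 + r, z1)


@dataclass
class VariationParams:
    """Inter-fraction anatomical change model.

    Volume factors are multiplicative and drawn uniformly from the given
    ranges; the CTV shift is an isotropic Gaussian rigid offset; the elastic
    amplitude bounds a smooth random background deformation that displaces
    the organs-at-risk.
    """

    bladder_volume_factor_range: tuple[float, float] = (0.6, 1.8)
    rectum_volume_factor_range: tuple[float, float] = (0.7, 1.5)
    ctv_shift_sd_mm: float = 1.5
    elastic_amplitude_mm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.bladder_volume_factor_range,
                       self.rectum_volume_factor_range):
            if lo <= 0 or hi <= 0 or hi < lo:
                raise ValueError("volume factor ranges must be positive and ordered")
        if self.ctv_shift_sd_mm < 0 or self.elastic_amplitude_mm < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class FractionCase:
    """One fraction scan: image, ground-truth masks, generating parameters."""

    image: VolumeImage
    structures: StructureSet
    anatomy: AnatomyParams
    variation_record: dict
    gt_ddf: DisplacementField | None = None


@dataclass
class PatientCase:
    """Planning scan plus fraction scans of one synthetic patient."""

    patient_id: str
    planning_image: VolumeImage
    planning_structures: StructureSet
    anatomy: AnatomyParams
    fractions: list[FractionCase] = field(default_factory=list)


# -- rendering -------------------------------------------------------------

def _coords_mm(params: AnatomyParams):
    axes = [np.arange(n) * s for n, s in zip(params.grid_shape, params.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, axes) -> np.ndarray:
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, axes))
    return (q <= 1.0).astype(np.uint8)


def _tube(coords, centerline, radius) -> np.ndarray:
    x0, y0, z0, z1 = centerline
    X, Y, Z = coords
    return (((X - x0) ** 2 + (Y - y0) ** 2 <= radius ** 2)
            & (Z >= z0) & (Z <= z1)).astype(np.uint8)


def _body(coords, params: AnatomyParams) -> np.ndarray:
    extent = np.asarray(params.grid_shape) * np.asarray(params.spacing_mm)
    center = extent / 2.0
    axes = (0.48 * extent[0], 0.44 * extent[1])
    X, Y, _ = coords
    return ((((X - center[0]) / axes[0]) ** 2
             + ((Y - center[1]) / axes[1]) ** 2) <= 1.0).astype(np.uint8)


def render_anatomy(params: AnatomyParams, rng: np.random.Generator | None = None
                   ) -> tuple[VolumeImage, StructureSet]:
    """Render image and disjoint binary masks from geometric primitives.

    Overlaps are resolved by priority CTV > bladder > rectum (the target
    volume keeps its voxels when an inflated organ presses against it).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    coords = _coords_mm(params)
    ctv = _ellipsoid(coords, params.ctv_center, params.ctv_axes)
    bladder = _ellipsoid(coords, params.bladder_center, params.bladder_axes)
    rectum = _tube(coords, params.rectum_centerline, params.rectum_radius)
    bladder &= ~ctv.astype(bool)
    rectum &= ~(ctv | bladder).astype(bool)
    body = _body(coords, params)

    means = params.intensity_means
    img = np.full(params.grid_shape, means["background"], dtype=np.float64)
    img[body > 0] = means["body"]
    img[bladder > 0] = means["bladder"]
    img[rectum > 0] = means["rectum"]
    img[ctv > 0] = means["ctv"]
    if params.bias_amplitude > 0:
        lowres = rng.uniform(-1.0, 1.0, size=(4, 4, 4))
        zoom = [n / 4 for n in params.grid_shape]
        bias = 1.0 + params.bias_amplitude * ndimage.zoom(lowres, zoom, order=3,
                                                          mode="nearest")
        img *= bias
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=params.grid_shape)

    masks = StructureSet({"bladder": bladder.astype(np.uint8),
                          "rectum": rectum.astype(np.uint8),
                          "ctv": ctv.astype(np.uint8)},
                         params.spacing_mm)
    return VolumeImage(img, params.spacing_mm), masks


def make_planning_case(params: AnatomyParams, patient_id: str = "p000") -> PatientCase:
    """Generate a planning scan with physician-style contours."""
    image, structures = render_anatomy(params)
    return PatientCase(patient_id, image, structures, params)


def _scaled(axes, factor):
    return tuple(a * factor ** (1.0 / 3.0) for a in axes)


def sample_fraction_case(planning: PatientCase, variation: VariationParams,
                         n_fractions: int = 1) -> PatientCase:
    """Populate `planning` with freshly rendered fraction scans.

    Each fraction re-renders the anatomy after rescaling organ volumes,
    rigidly shifting the CTV, and displacing the organs-at-risk by a smooth
    random background deformation; the generating parameters are recorded in
    the fraction's variation_record for later recovery checks.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    variation.validate()
    rng = np.random.default_rng(variation.seed)
    base = planning.anatomy
    fractions = []
    for k in range(n_fractions):
        f_b = rng.uniform(*variation.bladder_volume_factor_range)
        f_r = rng.uniform(*variation.rectum_volume_factor_range)
        ctv_shift = rng.normal(0.0, variation.ctv_shift_sd_mm, size=3)
        if variation.elastic_amplitude_mm > 0:
            elastic = random_bspline_ddf(base.grid_shape, base.spacing_mm,
                                         n_control_points=4,
                                         max_displacement_mm=variation.elastic_amplitude_mm,
                                         seed=rng)
            disp_at = _field_sampler(elastic, base.spacing_mm)
        else:
            disp_at = lambda p: np.zeros(3)
        bladder_shift = disp_at(base.bladder_center)
        x0, y0, z0, z1 = base.rectum_centerline
        rectum_shift = disp_at(((x0 + x0) / 2, y0, (z0 + z1) / 2))
        frac_params = dataclasses.replace(
            base,
            bladder_center=tuple(np.asarray(base.bladder_center) + bladder_shift),
            bladder_axes=_scaled(base.bladder_axes, f_b),
            rectum_centerline=(x0 + rectum_shift[0], y0 + rectum_shift[1], z0, z1),
            rectum_radius=base.rectum_radius * np.sqrt(f_r),
            ctv_center=tuple(np.asarray(base.ctv_center) + ctv_shift),
            seed=int(rng.integers(2 ** 31)),
        )
        image, structures = render_anatomy(frac_params)
        record = {"bladder_volume_factor": float(f_b),
                  "rectum_volume_factor": float(f_r),
                  "ctv_shift_mm": [float(v) for v in ctv_shift],
                  "bladder_shift_mm": [float(v) for v in bladder_shift],
                  "fraction_index": k}
        fractions.append(FractionCase(image, structures, frac_params, record))
    return dataclasses.replace(planning, fractions=fractions)


def _field_sampler(ddf: DisplacementField, spacing):
    def sample(point_mm):
        idx = np.asarray(point_mm) / np.asarray(spacing)
        vec = [ndimage.map_coordinates(ddf.vectors[c], idx.reshape(3, 1),
                                       order=1, mode="nearest")[0]
               for c in range(3)]
        return np.asarray(vec)
    return sample


@dataclass
class AnatomyPrior:
    """Distribution over AnatomyParams for inter-patient variability."""

    base: AnatomyParams = field(default_factory=AnatomyParams)
    center_jitter_mm: float = 2.5
    axes_jitter_frac: float = 0.12

    def sample(self, rng: np.random.Generator) -> AnatomyParams:
        def jc(center):
            return tuple(np.asarray(center)
                         + rng.uniform(-self.center_jitter_mm,
                                       self.center_jitter_mm, size=3))

        def ja(axes):
            return tuple(np.asarray(axes)
                         * (1.0 + rng.uniform(-self.axes_jitter_frac,
                                              self.axes_jitter_frac, size=3)))

        b = self.base
        x0, y0, z0, z1 = b.rectum_centerline
        jxy = rng.uniform(-self.center_jitter_mm, self.center_jitter_mm, size=2)
        return dataclasses.replace(
            b,
            bladder_center=jc(b.bladder_center),
            bladder_axes=ja(b.bladder_axes),
            ctv_center=jc(b.ctv_center),
            ctv_axes=ja(b.ctv_axes),
            rectum_centerline=(x0 + jxy[0], y0 + jxy[1], z0, z1),
            rectum_radius=b.rectum_radius * (1.0 + rng.uniform(
                -self.axes_jitter_frac, self.axes_jitter_frac)),
            seed=int(rng.integers(2 ** 31)),
        )


def make_cohort(n_patients: int, anatomy_prior: AnatomyPrior | None = None,
                variation: VariationParams | None = None, seed: int = 0,
                n_fractions: int = 3) -> list[PatientCase]:
    """Generate a cohort of synthetic patients with fraction scans.

    All randomness flows from the cohort seed through per-patient and
    per-fraction child seeds, so cohorts are reproducible.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    prior = anatomy_prior or AnatomyPrior()
    variation = variation or VariationParams()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        params = prior.sample(rng)
        case = make_planning_case(params, patient_id=f"p{i:03d}")
        var_i = dataclasses.replace(variation, seed=int(rng.integers(2 ** 31)))
        case = sample_fraction_case(case, var_i, n_fractions=n_fractions)
        cohort.append(case)
    return cohort


def derive_ptv(ctv: np.ndarray, margin_mm: float,
               spacing_mm=(1.5, 1.5, 1.5)) -> np.ndarray:
    """PTV = spacing-aware isotropic Euclidean dilation of the CTV."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    ctv = np.asarray(ctv, dtype=bool)
    if margin_mm == 0:
        return ctv.astype(np.uint8)
    dist = ndimage.distance_transform_edt(~ctv, sampling=spacing_mm)
    return (dist <= margin_mm).astype(np.uint8)


# -- disk round trip ---------------------------------------------------------

def save_case(case: PatientCase, directory: str | Path) -> None:
    """Write a case as NIfTI files plus a JSON sidecar of parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nifti.save_image(case.planning_image, directory / "planning_image.nii.gz")
    nifti.save_structures(case.planning_structures, directory, prefix="planning_")
    sidecar = {"patient_id": case.patient_id,
               "anatomy": _params_dict(case.anatomy),
               "fractions": []}
    for k, frac in enumerate(case.fractions):
        nifti.save_image(frac.image, directory / f"fraction{k:02d}_image.nii.gz")
        nifti.save_structures(frac.structures, directory, prefix=f"fraction{k:02d}_")
        if frac.gt_ddf is not None:
            nifti.save_ddf(frac.gt_ddf, directory / f"fraction{k:02d}_ddf.nii.gz")
        sidecar["fractions"].append(frac.variation_record)
    (directory / "case.json").write_text(json.dumps(sidecar, indent=2))


def _params_dict(params: AnatomyParams) -> dict:
    d = dataclasses.asdict(params)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
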