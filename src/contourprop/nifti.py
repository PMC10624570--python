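"""NIfTI read/write for volumes, masks and displacement fields.

The affine carries spacing and origin (axis-aligned RAS); displacement
fields are written as 5D ``(X, Y, Z, 1, 3)`` volumes with the NIfTI vector
intent code, millimetre units.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid_ops import DisplacementField, StructureSet, VolumeImage

_VECTOR_INTENT = 1007  # NIFTI_INTENT_VECTOR


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def _grid_from_affine(aff: np.ndarray):
    spacing = tuple(np.linalg.norm(aff[:3, i]) for i in range(3))
    origin = tuple(aff[:3, 3])
    return spacing, origin


def save_image(image: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(image.data, dtype=np.float32),
                          _affine(image.spacing_mm, image.origin_mm))
    nib.save(img, str(path))


def load_image(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_mask(mask: np.ndarray, spacing_mm, origin_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                          _affine(spacing_mm, origin_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return (np.asarray(img.dataobj) > 0.5).astype(np.uint8)


def save_structures(structures: StructureSet, directory: str | Path,
                    prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.masks.items():
        save_mask(mask, structures.spacing_mm, structures.origin_mm,
                  directory / f"{prefix}{name}.nii.gz")


def load_structures(directory: str | Path, names, prefix: str = "") -> StructureSet:
    directory = Path(directory)
    masks = {}
    spacing, origin = (1.5, 1.5, 1.5), (0.0, 0.0, 0.0)
    for name in names:
        path = directory / f"{prefix}{name}.nii.gz"
        img = nib.load(str(path))
        spacing, origin = _grid_from_affine(img.affine)
        masks[name] = (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
    return StructureSet(masks, spacing, origin)


def save_ddf(ddf: DisplacementField, path: str | Path) -> None:
    # (3, X, Y, Z) -> (X, Y, Z, 1, 3) per NIfTI vector-volume convention
    data = np.moveaxis(ddf.vectors, 0, -1)[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data.astype(np.float32),
                          _affine(ddf.spacing_mm, ddf.origin_mm))
    img.header["intent_code"] = _VECTOR_INTENT
    nib.save(img, str(path))


def load_ddf(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5:
        data = data[:, :, :, 0, :]
    return DisplacementField(np.moveaxis(data, -1, 0), spacing, origin)
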