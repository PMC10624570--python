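"""Core image geometry: volumes, structure sets, displacement fields, warping.

Conventions (shared by every propagation strategy in the package):

* arrays are indexed ``(x, y, z)`` with axial slices along ``z``;
* displacement fields are stored in millimetres in physical space with the
  backward-warping convention: the warped value at fixed-grid point ``x`` is
  sampled from the moving volume at ``x + u(x)``;
* out-of-bounds samples clamp to the border value;
* binary masks are propagated by linear interpolation followed by
  thresholding at 0.5 (slice resampling of masks uses nearest neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

Triple = tuple[float, float, float]


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with physical spacing and origin."""

    data: np.ndarray
    spacing_mm: Triple = (1.5, 1.5, 1.5)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def compatible_grid(self, other) -> bool:
        """Same shape and spacing; origins may differ (post rigid alignment)."""
        return (self.shape == other.shape
                and np.allclose(self.spacing_mm, other.spacing_mm))


@dataclass
class StructureSet:
    """Named binary masks (bladder, rectum, CTV, PTV, ...) on one grid."""

    masks: dict[str, np.ndarray]
    spacing_mm: Triple = (1.5, 1.5, 1.5)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError("structure masks do not share one grid")
        for name, m in self.masks.items():
            vals = np.unique(m)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError(f"mask '{name}' is not binary")
            self.masks[name] = np.asarray(m, dtype=np.uint8)

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def names(self):
        return list(self.masks)

    def copy(self) -> "StructureSet":
        return StructureSet({k: v.copy() for k, v in self.masks.items()},
                            self.spacing_mm, self.origin_mm)


@dataclass
class DisplacementField:
    """Dense 3-vector field, millimetre units, on the fixed (fraction) grid."""

    vectors: np.ndarray  # (3, X, Y, Z)
    spacing_mm: Triple = (1.5, 1.5, 1.5)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError("DisplacementField requires a (3, X, Y, Z) array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self):
        return self.vectors.shape[1:]

    def voxel_units(self) -> np.ndarray:
        """Vectors divided per-axis by the spacing (voxel displacement)."""
        sp = np.asarray(self.spacing_mm).reshape(3, 1, 1, 1)
        return self.vectors / sp


def zero_ddf(shape, spacing_mm=(1.5, 1.5, 1.5), origin_mm=(0.0, 0.0, 0.0)) -> DisplacementField:
    return DisplacementField(np.zeros((3,) + tuple(shape)), spacing_mm, origin_mm)


def _sample_coords(ddf: DisplacementField) -> np.ndarray:
    """Voxel-unit sample coordinates x + u(x) on the fixed grid."""
    shape = ddf.grid_shape
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                                indexing="ij"))
    return base + ddf.voxel_units()


def warp_image(moving: VolumeImage, ddf: DisplacementField,
               mode: str = "linear") -> VolumeImage:
    """Backward-warp `moving` by `ddf`: out(x) = moving(x + u(x))."""
    if moving.shape != ddf.grid_shape:
        raise GridMismatchError(
            f"moving grid {moving.shape} != field grid {ddf.grid_shape}")
    if mode not in ("linear", "nearest"):
        raise ValueError("mode must be 'linear' or 'nearest'")
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(np.asarray(moving.data, dtype=np.float64),
                                  _sample_coords(ddf), order=order,
                                  mode="nearest")
    return VolumeImage(out.astype(moving.data.dtype, copy=False)
                       if mode == "nearest" else out,
                       moving.spacing_mm, moving.origin_mm)


def warp_mask(mask: np.ndarray, ddf: DisplacementField) -> np.ndarray:
    """Propagate a binary mask: linear interpolation then threshold at 0.5."""
    mask = np.asarray(mask)
    if mask.shape != ddf.grid_shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} != field grid {ddf.grid_shape}")
    interp = ndimage.map_coordinates(mask.astype(np.float64), _sample_coords(ddf),
                                     order=1, mode="nearest")
    return (interp > 0.5).astype(np.uint8)


def resample_slices(image: VolumeImage, target_thickness_mm: float,
                    mode: str = "linear") -> VolumeImage:
    """Regrid the z axis to a new slice thickness; x/y are untouched.

    Images use linear interpolation, contour masks nearest neighbour (pass
    mode='nearest'); nearest keeps masks binary.
    """
    if target_thickness_mm <= 0:
        raise ValueError("target thickness must be positive")
    sx, sy, sz = image.spacing_mm
    if np.isclose(target_thickness_mm, sz):
        return VolumeImage(image.data.copy(), image.spacing_mm, image.origin_mm)
    nz = image.shape[2]
    extent = (nz - 1) * sz
    nz_new = int(np.floor(extent / target_thickness_mm)) + 1
    z_new = np.arange(nz_new) * target_thickness_mm / sz  # in old voxel units
    X, Y = image.shape[:2]
    coords = np.stack(np.meshgrid(np.arange(X, dtype=np.float64),
                                  np.arange(Y, dtype=np.float64),
                                  z_new, indexing="ij"))
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(image.data.astype(np.float64), coords,
                                  order=order, mode="nearest")
    if mode == "nearest":
        out = out.astype(image.data.dtype, copy=False)
    return VolumeImage(out, (sx, sy, target_thickness_mm), image.origin_mm)


def crop_around_centroid(image: VolumeImage, structures: StructureSet,
                         anchor: str, size_voxels) -> tuple[VolumeImage, StructureSet]:
    """Crop image + masks to `size_voxels` centred on the anchor's centroid.

    The centroid is rounded half-up per axis; windows reaching outside the
    grid are padded by border replication so the output always has the
    requested shape.  This crop plays the role of the clinical rigid
    pre-alignment of planning and fraction scans.
    """
    if anchor not in structures.masks:
        raise KeyError(f"anchor structure '{anchor}' not present")
    m = structures.masks[anchor]
    if m.sum() == 0:
        raise ValueError(f"anchor mask '{anchor}' is empty")
    size = tuple(int(s) for s in np.atleast_1d(size_voxels) * np.ones(3, dtype=int))
    centroid = np.array(np.nonzero(m), dtype=np.float64).mean(axis=1)
    center = np.floor(centroid + 0.5).astype(int)  # round half-up
    starts = center - np.asarray(size) // 2

    def window(arr, pad_edge: bool):
        lo = starts
        hi = starts + np.asarray(size)
        pad_lo = np.maximum(-lo, 0)
        pad_hi = np.maximum(hi - np.asarray(arr.shape), 0)
        sl = tuple(slice(max(l, 0), min(h, s))
                   for l, h, s in zip(lo, hi, arr.shape))
        cropped = arr[sl]
        if pad_lo.any() or pad_hi.any():
            cropped = np.pad(cropped, list(zip(pad_lo, pad_hi)),
                             mode="edge" if pad_edge else "constant")
        return cropped

    new_origin = tuple(o + s * sp for o, s, sp in
                       zip(image.origin_mm, starts, image.spacing_mm))
    out_img = VolumeImage(window(image.data, True), image.spacing_mm, new_origin)
    out_masks = {k: window(v, False) for k, v in structures.masks.items()}
    return out_img, StructureSet(out_masks, structures.spacing_mm, new_origin)


def random_bspline_ddf(shape, spacing_mm, n_control_points: int = 10,
                       max_displacement_mm: float = 35.0,
                       seed: int | np.random.Generator = 0) -> DisplacementField:
    """Smooth random displacement field from a cubic B-spline control lattice.

    Control-point offsets are drawn uniformly in [-max, +max] per component
    and act as B-spline coefficients, so the dense field is a convex
    combination of the offsets and every component stays within the bound.
    """
    if n_control_points < 4:
        raise ValueError("need at least 4 control points per axis")
    if max_displacement_mm < 0:
        raise ValueError("max_displacement must be >= 0")
    shape = tuple(int(s) for s in shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = rng.uniform(-max_displacement_mm, max_displacement_mm,
                         size=(3,) + (n_control_points,) * 3)
    if max_displacement_mm == 0:
        return DisplacementField(np.zeros((3,) + shape), spacing_mm)
    # map voxel index i in [0, D-1] onto control-lattice coordinate
    grids = [np.arange(n) * (n_control_points - 1) / max(n - 1, 1) for n in shape]
    coords = np.stack(np.meshgrid(*grids, indexing="ij"))
    vec = np.stack([ndimage.map_coordinates(coeffs[c], coords, order=3,
                                            prefilter=False, mode="nearest")
                    for c in range(3)])
    return DisplacementField(vec, spacing_mm)


def invert_ddf(ddf: DisplacementField, n_iter: int = 20) -> DisplacementField:
    """Fixed-point numerical inverse of a (small, smooth) backward field."""
    inv = np.zeros_like(ddf.vectors)
    sp = np.asarray(ddf.spacing_mm).reshape(3, 1, 1, 1)
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float64)
                                  for n in ddf.grid_shape), indexing="ij"))
    for _ in range(n_iter):
        coords = base + inv / sp
        samp = np.stack([ndimage.map_coordinates(ddf.vectors[c], coords,
                                                 order=1, mode="nearest")
                         for c in range(3)])
        inv = -samp
    return DisplacementField(inv, ddf.spacing_mm, ddf.origin_mm)
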