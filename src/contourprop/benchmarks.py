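"""Classical comparators: rigid contour copying and multi-resolution
B-spline deformable registration with contour propagation.

The registration optimises cubic B-spline control-point offsets by
quasi-Newton descent (L-BFGS-B) on an image-similarity term (mean squared
difference or one-minus-NCC) plus a bending-energy penalty on the dense
field.  Stages run coarse to fine; each stage optimises a correction that is
added to the field accumulated so far.  The gradient of the similarity with
respect to the dense field comes from the differentiable trilinear sampler,
and is projected onto the control lattice by the adjoint of the B-spline
interpolation operator, so the gradient is exact.

Because the planning and fraction scans are cropped around the CTV centroid
upstream, rigid copying is simply a transfer of the planning masks onto the
fraction grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import autodiff as ad
from .grid_ops import (DisplacementField, GridMismatchError, StructureSet,
                       VolumeImage, warp_mask)
from .losses import bending_energy, image_similarity_loss
from .phantom import PatientCase


@dataclass
class BsplineStage:
    control_grid_spacing_mm: float = 24.0
    iterations: int = 30
    similarity: str = "mse"  # mse | ncc
    regularization: float = 0.01  # weight of the bending-energy penalty

    def validate(self) -> None:
        if self.control_grid_spacing_mm <= 0:
            raise ValueError("control grid spacing must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.similarity not in ("mse", "ncc"):
            raise ValueError("similarity must be 'mse' or 'ncc'")


def default_stages(spacing_mm: float = 1.5) -> list[BsplineStage]:
    """Three-stage coarse-to-fine recipe: 32/16/8-voxel control spacing."""
    return [BsplineStage(32 * spacing_mm, iterations=30),
            BsplineStage(16 * spacing_mm, iterations=30),
            BsplineStage(8 * spacing_mm, iterations=40)]


def rigid_copy(planning_structures: StructureSet, fraction_grid) -> StructureSet:
    """Transfer the planning masks unchanged onto the fraction grid."""
    target_shape = (fraction_grid.shape if hasattr(fraction_grid, "shape")
                    else tuple(fraction_grid))
    if planning_structures.shape != tuple(target_shape):
        raise GridMismatchError(
            f"planning grid {planning_structures.shape} != fraction grid "
            f"{tuple(target_shape)}")
    out = planning_structures.copy()
    if hasattr(fraction_grid, "origin_mm"):
        out.origin_mm = tuple(fraction_grid.origin_mm)
    return out


def _cubic_bspline(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax < 1
    m2 = (ax >= 1) & (ax < 2)
    out[m1] = (4.0 - 6.0 * ax[m1] ** 2 + 3.0 * ax[m1] ** 3) / 6.0
    out[m2] = (2.0 - ax[m2]) ** 3 / 6.0
    return out


def _basis_matrix(n_vox: int, spacing: float, ctrl_spacing: float) -> np.ndarray:
    """Dense (n_vox x n_ctrl) cubic B-spline basis, boundary clamped."""
    t = np.arange(n_vox) * spacing / ctrl_spacing + 1.0
    n_ctrl = max(4, int(np.ceil(t.max())) + 3)
    B = np.zeros((n_vox, n_ctrl))
    base = np.floor(t).astype(int) - 1
    for off in range(4):
        k = np.clip(base + off, 0, n_ctrl - 1)
        w = _cubic_bspline(t - (base + off))
        np.add.at(B, (np.arange(n_vox), k), w)
    return B


def bspline_register(fixed: VolumeImage, moving: VolumeImage,
                     stages: list[BsplineStage] | None = None
                     ) -> DisplacementField:
    """Multi-stage B-spline registration; returns the dense mm backward field
    mapping points of the fixed (fraction) grid into the moving (planning)
    volume."""
    if not fixed.compatible_grid(moving):
        raise GridMismatchError("fixed and moving images are on different grids")
    if stages is None:
        stages = default_stages(fixed.spacing_mm[0])
    if not stages:
        raise ValueError("need at least one registration stage")
    for st in stages:
        st.validate()
    spac = [st.control_grid_spacing_mm for st in stages]
    if any(b > a for a, b in zip(spac, spac[1:])):
        warnings.warn("stage control spacings are not coarse-to-fine")

    shape = fixed.shape
    sp = np.asarray(fixed.spacing_mm)
    fx = np.asarray(fixed.data, dtype=np.float64)
    mv = ad.Tensor(np.asarray(moving.data, dtype=np.float64)[np.newaxis])
    u_total = np.zeros((3,) + shape)
    history: list[list[float]] = []

    for st in stages:
        Bs = [_basis_matrix(n, s, st.control_grid_spacing_mm)
              for n, s in zip(shape, sp)]
        nc = tuple(B.shape[1] for B in Bs)
        stage_hist: list[float] = []

        def dense_from_ctrl(c):
            return np.stack([np.einsum("xi,yj,zk,ijk->xyz", Bs[0], Bs[1], Bs[2],
                                       c[comp], optimize=True)
                             for comp in range(3)])

        def adjoint(g):
            return np.stack([np.einsum("xi,yj,zk,xyz->ijk", Bs[0], Bs[1], Bs[2],
                                       g[comp], optimize=True)
                             for comp in range(3)])

        def objective(cflat):
            c = cflat.reshape((3,) + nc)
            u = u_total + dense_from_ctrl(c)
            u_t = ad.Tensor(u, requires_grad=True)
            disp_vox = u_t * (1.0 / sp.reshape(3, 1, 1, 1))
            warped = ad.grid_sample(mv, disp_vox)
            sim = image_similarity_loss(warped, fx[np.newaxis],
                                        kind="l2" if st.similarity == "mse" else "ncc")
            total = sim + st.regularization * bending_energy(u_t, tuple(sp))
            total.backward()
            g_ctrl = adjoint(u_t.grad)
            stage_hist.append(total.item())
            return total.item(), g_ctrl.ravel()

        c0 = np.zeros(3 * int(np.prod(nc)))
        res = optimize.minimize(objective, c0, jac=True, method="L-BFGS-B",
                                options={"maxiter": st.iterations,
                                         "maxcor": 10, "ftol": 1e-12,
                                         "gtol": 1e-10})
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError(f"registration diverged at stage "
                               f"{st.control_grid_spacing_mm} mm: {res.message}")
        u_total = u_total + dense_from_ctrl(res.x.reshape((3,) + nc))
        history.append(stage_hist)

    ddf = DisplacementField(u_total, fixed.spacing_mm, fixed.origin_mm)
    ddf.history = history
    return ddf


def propagate_contours(structures: StructureSet, ddf: DisplacementField,
                       rigid_ctv: bool = False) -> StructureSet:
    """Warp every planning mask by the field; the CTV may instead be rigidly
    copied (the clinical convention for the target volume)."""
    if structures.shape != ddf.grid_shape:
        raise GridMismatchError("structure grid does not match the field grid")
    out = {}
    for name, mask in structures.masks.items():
        if rigid_ctv and name.lower() == "ctv":
            out[name] = mask.copy()
        else:
            out[name] = warp_mask(mask, ddf)
    return StructureSet(out, structures.spacing_mm, structures.origin_mm)


def realistic_ddf_pool(cases: list[PatientCase],
                       stages: list[BsplineStage] | None = None
                       ) -> list[DisplacementField]:
    """Register every planning--fraction pair of the given patients and pool
    the resulting fields (training material for the 'realistic-field'
    deformation-network variant)."""
    pool = []
    for case in cases:
        for frac in case.fractions:
            pool.append(bspline_register(frac.image, case.planning_image, stages))
    return pool
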