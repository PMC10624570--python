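"""Training objectives for displacement and segmentation networks.

The total objective is a weighted sum

    L_tot = lam_ddf * (lam_ddf_l2 * L2(u, u_gt) + lam_ddf_reg * L_bend(u))
          + lam_seg * L_dice + lam_img * L_img

where the L2-to-ground-truth term exists only when a ground-truth field is
available.  Every component is implemented once and works both on plain
numpy arrays (evaluation) and on autodiff tensors (training), so each term
is independently testable outside a training loop.

Bending energy is the mean over interior voxels of the sum over the three
field components of all squared second spatial derivatives (mixed terms
doubled), central finite differences, spacing-aware; it vanishes on affine
fields.  Reductions use means rather than sums so loss magnitudes do not
depend on grid size and weights transfer between desk-scale and full-scale
grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .grid_ops import DisplacementField

DICE_EPS = 1e-5


class ConfigurationError(ValueError):
    pass


def _is_t(x) -> bool:
    return isinstance(x, ad.Tensor)


def _sum(x):
    return ad.sum_(x) if _is_t(x) else float(np.sum(x))


def _mean(x):
    return ad.mean(x) if _is_t(x) else float(np.mean(x))


def _smooth(x, sigma: float):
    if sigma <= 0:
        return x
    if _is_t(x):
        return ad.gaussian_smooth(x, sigma)
    return ndimage.gaussian_filter(np.asarray(x, dtype=np.float64),
                                   sigma=sigma, mode="constant", cval=0.0)


def _sqrt(x):
    return ad.power(x, 0.5) if _is_t(x) else float(np.sqrt(x))


def _val(x) -> float:
    return x.item() if _is_t(x) else float(x)


@dataclass
class LossWeights:
    """Weights of the total objective; defaults are the tuned configuration."""

    lambda_ddf: float = 1.0
    lambda_ddf_l2: float = 0.0
    lambda_ddf_reg: float = 10.0
    lambda_seg: float = 100.0
    lambda_img: float = 1.0

    def validate(self) -> None:
        for name in ("lambda_ddf", "lambda_ddf_l2", "lambda_ddf_reg",
                     "lambda_seg", "lambda_img"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _vectors_and_spacing(ddf, spacing_mm):
    if isinstance(ddf, DisplacementField):
        return ddf.vectors, ddf.spacing_mm
    if spacing_mm is None:
        spacing_mm = (1.0, 1.0, 1.0)
    return ddf, spacing_mm


def bending_energy(ddf, spacing_mm=None):
    """Mean squared second-derivative density of a displacement field.

    Accepts a DisplacementField, a (3, X, Y, Z) array, or an autodiff tensor
    (with `spacing_mm` for the latter two).  Derivatives are evaluated on
    the interior of the grid only, so affine fields give exactly zero.
    """
    u, spacing = _vectors_and_spacing(ddf, spacing_mm)
    shape = u.shape if not _is_t(u) else u.data.shape
    if any(n < 3 for n in shape[1:]):
        raise ValueError("bending energy needs >= 3 voxels per axis")
    h = [float(s) for s in spacing]

    def ax_slice(axis, sl):
        idx = [slice(None)] * 4
        idx[axis + 1] = sl
        return tuple(idx)

    def second(uu, axis):
        a = uu[ax_slice(axis, slice(2, None))]
        b = uu[ax_slice(axis, slice(1, -1))]
        c = uu[ax_slice(axis, slice(None, -2))]
        return (a - 2.0 * b + c) * (1.0 / h[axis] ** 2)

    def first(uu, axis):
        a = uu[ax_slice(axis, slice(2, None))]
        c = uu[ax_slice(axis, slice(None, -2))]
        return (a - c) * (1.0 / (2.0 * h[axis]))

    interior = tuple([slice(None)] + [slice(1, -1)] * 3)
    total = None
    n_interior = int(np.prod([n - 2 for n in shape[1:]])) * 3
    for axis in range(3):
        d2 = second(u, axis)
        # restrict the pure term to the common interior
        keep = [slice(1, -1)] * 3
        keep[axis] = slice(None)
        d2 = d2[tuple([slice(None)] + keep)]
        sq = d2 * d2
        total = sq if total is None else total + sq
    for ai in range(3):
        for aj in range(ai + 1, 3):
            dij = first(first(u, ai), aj)
            keep = [slice(1, -1)] * 3
            keep[ai] = slice(None)
            keep[aj] = slice(None)
            dij = dij[tuple([slice(None)] + keep)]
            total = total + 2.0 * (dij * dij)
    # mean over interior voxels, summed over the three components
    return _sum(total) * (3.0 / n_interior)


def soft_dice_loss(prediction, target, eps: float = DICE_EPS):
    """1 - soft Dice overlap; in [0, 1], ~0 on perfect agreement."""
    pshape = prediction.data.shape if _is_t(prediction) else np.shape(prediction)
    if tuple(pshape) != tuple(np.shape(target.data if _is_t(target) else target)):
        raise ValueError("prediction and target shapes differ")
    inter = _sum(prediction * target)
    denom = _sum(prediction) + _sum(target)
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def _soft_dice_sq(prediction, target, eps: float = DICE_EPS):
    # squared-denominator overlap: exact 0 on identical (even non-binary)
    # inputs, and identical to the plain form on binary masks
    inter = _sum(prediction * target)
    denom = _sum(prediction * prediction) + _sum(target * target)
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def multiscale_dice_loss(prediction, target, scales=(0.0, 2.0, 4.0)):
    """Mean Dice loss over Gaussian-smoothed copies of both inputs.

    Smoothing spreads thin structures so partially-overlapping masks still
    produce gradient signal; scale 0 is the unsmoothed loss.  Each term uses
    the squared-denominator overlap, which equals the plain soft Dice on
    binary masks and vanishes exactly whenever prediction == target, so the
    loss stays calibrated after smoothing turns masks into soft maps.
    """
    scales = list(scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s < 0 for s in scales):
        raise ValueError("scales must be >= 0")
    total = None
    for s in scales:
        term = _soft_dice_sq(_smooth(prediction, s), _smooth(target, s))
        total = term if total is None else total + term
    return total * (1.0 / len(scales))


def image_similarity_loss(a, b, kind: str = "l2"):
    """Mean-squared difference or one-minus global normalised cross-correlation."""
    if kind == "l2":
        d = a - b
        return _mean(d * d)
    if kind != "ncc":
        raise ValueError("kind must be 'l2' or 'ncc'")
    am = a - _mean(a)
    bm = b - _mean(b)
    va = _sum(am * am)
    vb = _sum(bm * bm)
    if _val(va) < 1e-12 or _val(vb) < 1e-12:
        warnings.warn("constant image under NCC; correlation defined as 0")
        return 1.0 if not (_is_t(a) or _is_t(b)) else ad.Tensor(np.float64(1.0))
    return 1.0 - _sum(am * bm) / _sqrt(va * vb)


def ddf_l2_loss(predicted, truth):
    """Mean squared component difference between two fields, mm^2."""
    p = predicted.vectors if isinstance(predicted, DisplacementField) else predicted
    t = truth.vectors if isinstance(truth, DisplacementField) else truth
    pshape = p.data.shape if _is_t(p) else np.shape(p)
    tshape = t.data.shape if _is_t(t) else np.shape(t)
    if tuple(pshape) != tuple(tshape):
        raise ValueError("fields are on different grids")
    d = p - t
    return _mean(d * d)


def total_loss(components: dict, weights: LossWeights, has_gt_ddf: bool):
    """Weighted sum of loss components.

    `components` maps {'ddf_l2', 'ddf_reg', 'seg', 'img'} to scalars (float
    or autodiff tensor). The L2-to-truth term is dropped whenever
    `has_gt_ddf` is false, regardless of its weight.
    """
    weights.validate()
    terms = []
    if has_gt_ddf and weights.lambda_ddf * weights.lambda_ddf_l2 > 0:
        terms.append(("ddf_l2", weights.lambda_ddf * weights.lambda_ddf_l2))
    if weights.lambda_ddf * weights.lambda_ddf_reg > 0:
        terms.append(("ddf_reg", weights.lambda_ddf * weights.lambda_ddf_reg))
    if weights.lambda_seg > 0:
        terms.append(("seg", weights.lambda_seg))
    if weights.lambda_img > 0:
        terms.append(("img", weights.lambda_img))
    total = 0.0
    for name, w in terms:
        if name not in components or components[name] is None:
            raise ConfigurationError(
                f"loss component '{name}' required by nonzero weight is missing")
        total = total + w * components[name]
    return total
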