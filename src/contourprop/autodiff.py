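"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a compact tensor autodiff core providing exactly the operations the
3D encoder--decoder networks and their training losses need: dense 3x3x3
convolutions (stride 1 and 2), 2x2x2 transposed convolutions, instance
normalisation, PReLU, sigmoid, channel concatenation, basic arithmetic with
broadcasting, slicing, reductions, Gaussian smoothing and a trilinear grid
sampler (the spatial transformer) that is differentiable in both the sampled
volume and the displacement argument.

Tensors carry ``(C, X, Y, Z)`` channel-first volumes or arbitrary arrays;
gradients are accumulated by topologically-sorted reverse traversal.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, True, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, True, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return Tensor(out_data, True, (a,), bw)


def getitem(a: Tensor, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] += g
        a._accum(full)

    return Tensor(out_data, True, (a,), bw)


def sum_(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.asarray(a.data.sum())
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accum(np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False))

    return Tensor(out_data, True, (a,), bw)


def mean(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return sum_(a) * (1.0 / a.data.size)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    if not (a.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        a._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, True, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, True, tuple(tensors), bw)


# -- neural-network primitives (channel-first volumes, no batch axis) -----

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3x3x3 'same' convolution on a (Cin, X, Y, Z) volume.

    stride 1 keeps the grid, stride 2 halves every axis (sizes must be even).
    Implemented as im2col + a single GEMM per direction.
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, D, H, W = x.data.shape
    cout = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)), mode="constant")
    if stride == 1:
        do, ho, wo = D, H, W
    elif stride == 2:
        do, ho, wo = D // 2, H // 2, W // 2
    else:
        raise ValueError("stride must be 1 or 2")
    nvox = do * ho * wo
    slices = []
    col = np.empty((cin, 27, nvox), dtype=x.data.dtype)
    k = 0
    for kz in range(3):
        for ky in range(3):
            for kx in range(3):
                sz = slice(kz, kz + stride * (do - 1) + 1, stride)
                sy = slice(ky, ky + stride * (ho - 1) + 1, stride)
                sx = slice(kx, kx + stride * (wo - 1) + 1, stride)
                slices.append((sz, sy, sx))
                col[:, k, :] = xp[:, sz, sy, sx].reshape(cin, nvox)
                k += 1
    col2 = col.reshape(cin * 27, nvox)
    w2 = w.data.reshape(cout, cin * 27)
    out_data = (w2 @ col2).reshape(cout, do, ho, wo)
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        gf = g.reshape(cout, nvox)
        if w.requires_grad:
            w._accum((gf @ col2.T).reshape(w.data.shape))
        if x.requires_grad:
            gcol = (w2.T @ gf).reshape(cin, 27, do, ho, wo)
            gxp = np.zeros_like(xp)
            for kk, (sz, sy, sx) in enumerate(slices):
                gxp[:, sz, sy, sx] += gcol[:, kk]
            x._accum(gxp[:, 1:-1, 1:-1, 1:-1])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    return Tensor(out_data, True, parents, bw)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2x2 transposed convolution with stride 2 (learned upsampling).

    x: (Cin, X, Y, Z); w: (Cin, Cout, 2, 2, 2); output (Cout, 2X, 2Y, 2Z).
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, D, H, W = x.data.shape
    cout = w.data.shape[1]
    out_data = np.empty((cout, 2 * D, 2 * H, 2 * W), dtype=x.data.dtype)
    for kz in range(2):
        for ky in range(2):
            for kx in range(2):
                out_data[:, kz::2, ky::2, kx::2] = np.tensordot(
                    w.data[:, :, kz, ky, kx], x.data, axes=([0], [0]))
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.reshape(cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
        for kz in range(2):
            for ky in range(2):
                for kx in range(2):
                    gs = g[:, kz::2, ky::2, kx::2]
                    if x.requires_grad:
                        gx += np.tensordot(w.data[:, :, kz, ky, kx], gs,
                                           axes=([1], [0]))
                    if w.requires_grad:
                        gw[:, :, kz, ky, kx] = np.tensordot(
                            x.data, gs, axes=([1, 2, 3], [1, 2, 3]))
        if x.requires_grad:
            x._accum(gx)
        if w.requires_grad:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))

    return Tensor(out_data, True, parents, bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over the spatial axes with affine rescale."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g4 = gamma.data.reshape(-1, 1, 1, 1)
    b4 = beta.data.reshape(-1, 1, 1, 1)
    out_data = g4 * xhat + b4
    parents = (x, gamma, beta)
    req = any(t.requires_grad for t in parents)
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=ax).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accum(g.sum(axis=ax).reshape(beta.data.shape))
        if x.requires_grad:
            gxh = g * g4
            m1 = gxh.mean(axis=ax, keepdims=True)
            m2 = (gxh * xhat).mean(axis=ax, keepdims=True)
            x._accum((gxh - m1 - xhat * m2) * inv)

    return Tensor(out_data, True, parents, bw)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with one learned slope per channel."""
    x, alpha = as_tensor(x), as_tensor(alpha)
    a4 = alpha.data.reshape(-1, 1, 1, 1)
    pos = x.data > 0
    out_data = np.where(pos, x.data, a4 * x.data)
    req = x.requires_grad or alpha.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if x.requires_grad:
            x._accum(np.where(pos, g, a4 * g))
        if alpha.requires_grad:
            alpha._accum((g * np.where(pos, 0.0, x.data)).sum(axis=(1, 2, 3))
                         .reshape(alpha.data.shape))

    return Tensor(out_data, True, (x, alpha), bw)


def gaussian_smooth(x: Tensor, sigma: float) -> Tensor:
    """Gaussian smoothing (zero-padded, so the operator is self-adjoint)."""
    x = as_tensor(x)
    if sigma <= 0:
        return x
    out_data = ndimage.gaussian_filter(x.data, sigma=sigma, mode="constant", cval=0.0)
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        x._accum(ndimage.gaussian_filter(g, sigma=sigma, mode="constant", cval=0.0))

    return Tensor(out_data, True, (x,), bw)


def grid_sample(moving: Tensor, disp_vox: Tensor) -> Tensor:
    """Backward trilinear warp: out(x) = moving(x + u(x)), u in voxel units.

    moving: (C, X, Y, Z); disp_vox: (3, X', Y', Z') displacement on the
    output grid. Out-of-bounds samples clamp to the border value, and the
    displacement gradient is zeroed where the sample is clamped.
    """
    moving, disp_vox = as_tensor(moving), as_tensor(disp_vox)
    C = moving.data.shape[0]
    dims = moving.data.shape[1:]
    out_shape = disp_vox.data.shape[1:]
    base = np.meshgrid(*(np.arange(n, dtype=disp_vox.data.dtype) for n in out_shape),
                       indexing="ij")
    coords = [base[i] + disp_vox.data[i] for i in range(3)]
    valid = [(c >= 0) & (c <= dims[i] - 1) for i, c in enumerate(coords)]
    cc = [np.clip(c, 0, dims[i] - 1) for i, c in enumerate(coords)]
    i0 = [np.minimum(np.floor(c).astype(np.intp), dims[i] - 2) if dims[i] > 1
          else np.zeros(out_shape, dtype=np.intp) for i, c in enumerate(cc)]
    f = [cc[i] - i0[i] for i in range(3)]

    corners = {}
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = np.minimum(i0[0] + dz, dims[0] - 1)
                iy = np.minimum(i0[1] + dy, dims[1] - 1)
                ix = np.minimum(i0[2] + dx, dims[2] - 1)
                corners[(dz, dy, dx)] = (iz, iy, ix)

    def wgt(d, axis):
        return f[axis] if d == 1 else 1.0 - f[axis]

    out_data = np.zeros((C,) + out_shape, dtype=moving.data.dtype)
    for (dz, dy, dx), (iz, iy, ix) in corners.items():
        w = wgt(dz, 0) * wgt(dy, 1) * wgt(dx, 2)
        out_data += moving.data[:, iz, iy, ix] * w

    req = moving.requires_grad or disp_vox.requires_grad
    if not (req and _GRAD_ENABLED):
        return Tensor(out_data)

    def bw(g):
        if disp_vox.requires_grad:
            gd = np.zeros_like(disp_vox.data)
            for (dz, dy, dx), (iz, iy, ix) in corners.items():
                val = moving.data[:, iz, iy, ix]
                sz = (1.0 if dz == 1 else -1.0) * wgt(dy, 1) * wgt(dx, 2)
                sy = (1.0 if dy == 1 else -1.0) * wgt(dz, 0) * wgt(dx, 2)
                sx = (1.0 if dx == 1 else -1.0) * wgt(dz, 0) * wgt(dy, 1)
                gv = (g * val).sum(axis=0)
                gd[0] += gv * sz
                gd[1] += gv * sy
                gd[2] += gv * sx
            for i in range(3):
                gd[i] *= valid[i]
            disp_vox._accum(gd)
        if moving.requires_grad:
            gm = np.zeros_like(moving.data)
            flat = gm.reshape(C, -1)
            for (dz, dy, dx), (iz, iy, ix) in corners.items():
                w = wgt(dz, 0) * wgt(dy, 1) * wgt(dx, 2)
                lin = (iz * dims[1] + iy) * dims[2] + ix
                contrib = g * w
                for ch in range(C):
                    np.add.at(flat[ch], lin.ravel(), contrib[ch].ravel())
            moving._accum(gm)

    return Tensor(out_data, True, (moving, disp_vox), bw)


class Adam:
    """Adam optimiser over a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (
                np.sqrt(self.v[i] / bc2) + self.eps)
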