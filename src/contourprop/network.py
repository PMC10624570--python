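"""3D encoder--decoder network shared by all deep propagation strategies.

One architecture serves two heads: a single-channel sigmoid segmentation
head (baseline and patient-specific models) and a 3-channel displacement
head whose output drives a differentiable spatial transformer (deformation
models).  Each resolution level applies two 3x3x3 convolutions with instance
normalisation and PReLU; downsampling uses stride-2 convolution and
upsampling transposed convolution, with skip concatenation.

The displacement head emits voxel-unit offsets internally; they are
converted to millimetres at the module boundary so that everything outside
the network speaks the same physical backward-warp convention as the
classical registration benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .grid_ops import DisplacementField, GridMismatchError, VolumeImage


@dataclass
class NetworkSpec:
    """Structural description of the encoder--decoder.

    Defaults are desk-scale (base 4 channels); the clinical-scale variant
    uses the same five levels on a 192^3 grid and wider channels via config.
    """

    n_levels: int = 5
    base_channels: int = 4
    in_channels: int = 1
    head: str = "segmentation"  # or "displacement"
    convs_per_level: int = 2

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if self.head not in ("segmentation", "displacement"):
            raise ValueError("head must be 'segmentation' or 'displacement'")

    @property
    def out_channels(self) -> int:
        return 1 if self.head == "segmentation" else 3

    @property
    def divisor(self) -> int:
        return 2 ** (self.n_levels - 1)

    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.n_levels)]


class UNet3D:
    """Parameter container + forward pass for the encoder--decoder."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.params: list[ad.Tensor] = []
        self._blocks: dict = {}
        rng = np.random.default_rng(seed)
        chans = spec.channels()

        def conv_param(cin, cout, k=3):
            fan_in = cin * k ** 3
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(cout, cin, k, k, k)).astype(np.float32)
            b = np.zeros(cout, dtype=np.float32)
            return self._register(w), self._register(b)

        def norm_act_param(c):
            gamma = self._register(np.ones(c, dtype=np.float32))
            beta = self._register(np.zeros(c, dtype=np.float32))
            alpha = self._register(np.full(c, 0.25, dtype=np.float32))
            return gamma, beta, alpha

        def block(cin, cout):
            layers = []
            c_prev = cin
            for _ in range(spec.convs_per_level):
                layers.append((conv_param(c_prev, cout), norm_act_param(cout)))
                c_prev = cout
            return layers

        # encoder: strided conv enters each level below the first
        self._blocks["enc"] = []
        c_prev = spec.in_channels
        for i, c in enumerate(chans):
            down = conv_param(c_prev, c) if i > 0 else None
            dna = norm_act_param(c) if i > 0 else None
            self._blocks["enc"].append((down, dna, block(c if i > 0 else c_prev, c)))
            c_prev = c
        # decoder
        self._blocks["dec"] = []
        for i in range(spec.n_levels - 2, -1, -1):
            c_hi, c_lo = chans[i + 1], chans[i]
            fan_in = c_hi * 8
            wup = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                             size=(c_hi, c_lo, 2, 2, 2)).astype(np.float32)
            bup = np.zeros(c_lo, dtype=np.float32)
            self._blocks["dec"].append(((self._register(wup), self._register(bup)),
                                        block(2 * c_lo, c_lo)))
        # head: plain 3x3x3 conv, zero-initialised bias, small weights
        wh, bh = conv_param(chans[0], spec.out_channels)
        if spec.head == "displacement":
            wh.data *= 0.01  # start close to the identity transform
        self._blocks["head"] = (wh, bh)

    def _register(self, arr) -> ad.Tensor:
        t = ad.Tensor(arr, requires_grad=True)
        self.params.append(t)
        return t

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params)

    def _check_shape(self, shape) -> None:
        d = self.spec.divisor
        if any(s % d for s in shape):
            raise ValueError(
                f"input shape {tuple(shape)} not divisible by 2^(n_levels-1)={d}")

    def _apply_block(self, x, layers):
        for (w, b), (gamma, beta, alpha) in layers:
            x = ad.conv3d(x, w, b)
            x = ad.instance_norm(x, gamma, beta)
            x = ad.prelu(x, alpha)
        return x

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """x: (in_channels, X, Y, Z) tensor -> (out_channels, X, Y, Z)."""
        self._check_shape(x.data.shape[1:])
        skips = []
        for i, (down, dna, layers) in enumerate(self._blocks["enc"]):
            if down is not None:
                w, b = down
                gamma, beta, alpha = dna
                x = ad.conv3d(x, w, b, stride=2)
                x = ad.instance_norm(x, gamma, beta)
                x = ad.prelu(x, alpha)
            x = self._apply_block(x, layers)
            skips.append(x)
        for j, ((wup, bup), layers) in enumerate(self._blocks["dec"]):
            skip = skips[self.spec.n_levels - 2 - j]
            x = ad.conv_transpose3d(x, wup, bup)
            x = ad.concat([x, skip], axis=0)
            x = self._apply_block(x, layers)
        wh, bh = self._blocks["head"]
        return ad.conv3d(x, wh, bh)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.params)}

    def load_state(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match the network spec")
            p.data = arr.astype(p.data.dtype, copy=True)

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        payload = dict(self.state_dict())
        payload["_spec"] = np.array([self.spec.n_levels, self.spec.base_channels,
                                     self.spec.in_channels,
                                     0 if self.spec.head == "segmentation" else 1,
                                     self.spec.convs_per_level, self.seed])
        np.savez(str(path), **payload)

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        data = np.load(str(path))
        nl, bc, ic, hd, cpl, seed = (int(v) for v in data["_spec"])
        spec = NetworkSpec(n_levels=nl, base_channels=bc, in_channels=ic,
                           head="segmentation" if hd == 0 else "displacement",
                           convs_per_level=cpl)
        model = cls(spec, seed=seed)
        model.load_state({k: data[k] for k in data.files if k != "_spec"})
        return model

    def clone(self) -> "UNet3D":
        other = UNet3D(self.spec, seed=self.seed)
        other.load_state(self.state_dict())
        return other


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet3D:
    """Deterministically initialised network; parameter count depends on spec only."""
    return UNet3D(spec, seed=seed)


def predict_segmentation(model: UNet3D, image: VolumeImage) -> np.ndarray:
    """Per-voxel foreground probability in [0, 1] (binarise at 0.5 to evaluate)."""
    if model.spec.head != "segmentation":
        raise ValueError("model does not have a segmentation head")
    with ad.no_grad():
        x = ad.Tensor(np.asarray(image.data, dtype=np.float32)[np.newaxis])
        out = ad.sigmoid(model.forward(x))
    return out.data[0].astype(np.float64)


def predict_ddf(model: UNet3D, planning: VolumeImage,
                fraction: VolumeImage) -> DisplacementField:
    """Predict the planning->fraction displacement field, millimetre units.

    Input is the 2-channel concatenation (planning, fraction) on one grid;
    the voxel-unit network output is scaled by the spacing at this boundary.
    """
    if model.spec.head != "displacement":
        raise ValueError("model does not have a displacement head")
    if not planning.compatible_grid(fraction):
        raise GridMismatchError("planning and fraction images are on different grids")
    with ad.no_grad():
        x = ad.Tensor(np.stack([planning.data, fraction.data]).astype(np.float32))
        out = model.forward(x)
    vec = out.data.astype(np.float64)
    sp = np.asarray(planning.spacing_mm).reshape(3, 1, 1, 1)
    return DisplacementField(vec * sp, planning.spacing_mm, planning.origin_mm)


def spatial_transform(moving, ddf: DisplacementField):
    """Differentiable trilinear warp with the same contract as warp_image.

    Accepts a VolumeImage or plain array (or autodiff tensor with a leading
    channel axis, used inside training losses); returns the matching type.
    """
    if isinstance(moving, ad.Tensor):
        return ad.grid_sample(moving, ad.Tensor(ddf.voxel_units()))
    if isinstance(moving, VolumeImage):
        if moving.shape != ddf.grid_shape:
            raise GridMismatchError("moving grid does not match the field grid")
        with ad.no_grad():
            out = ad.grid_sample(ad.Tensor(np.asarray(moving.data,
                                                      dtype=np.float64)[np.newaxis]),
                                 ad.Tensor(ddf.voxel_units()))
        return VolumeImage(out.data[0], moving.spacing_mm, moving.origin_mm)
    arr = np.asarray(moving, dtype=np.float64)
    if arr.shape != ddf.grid_shape:
        raise GridMismatchError("moving grid does not match the field grid")
    with ad.no_grad():
        out = ad.grid_sample(ad.Tensor(arr[np.newaxis]), ad.Tensor(ddf.voxel_units()))
    return out.data[0]
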