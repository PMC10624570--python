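"""Warping, resampling, cropping and random smooth fields."""

import numpy as np
import pytest

from contourprop.grid_ops import (DisplacementField, GridMismatchError,
                                  StructureSet, VolumeImage,
                                  crop_around_centroid, invert_ddf,
                                  random_bspline_ddf, resample_slices,
                                  warp_image, warp_mask, zero_ddf)
from contourprop.losses import bending_energy


def _img(data, spacing=(1.5, 1.5, 1.5)):
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing)


@pytest.mark.parametrize("mode", ["linear", "nearest"])
def test_zero_field_warp_is_identity(rng, mode):
    img = _img(rng.normal(size=(7, 6, 5)))
    out = warp_image(img, zero_ddf(img.shape), mode=mode)
    np.testing.assert_array_equal(out.data, img.data)


def test_integer_shift_matches_roll_oracle(rng):
    img = _img(rng.normal(size=(8, 8, 8)))
    u = np.zeros((3, 8, 8, 8))
    u[0] = 1.5  # one voxel along +x at 1.5 mm spacing (backward convention)
    out = warp_image(img, DisplacementField(u, img.spacing_mm))
    # out(i) = img(i+1); interior check avoids the clamped border
    np.testing.assert_allclose(out.data[:-1], img.data[1:], atol=1e-12)


def test_warp_matches_bruteforce_trilinear_oracle(rng):
    n = 8
    img = _img(rng.normal(size=(n, n, n)))
    u = random_bspline_ddf((n, n, n), img.spacing_mm, 4, 2.0, seed=3)
    out = warp_image(img, u)

    def sample(data, p):
        p = np.clip(p, 0, n - 1)
        i0 = np.minimum(np.floor(p).astype(int), n - 2)
        f = p - i0
        acc = 0.0
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    w = ((f[0] if dz else 1 - f[0]) * (f[1] if dy else 1 - f[1])
                         * (f[2] if dx else 1 - f[2]))
                    acc += w * data[i0[0] + dz, i0[1] + dy, i0[2] + dx]
        return acc

    uvox = u.voxel_units()
    for idx in [(0, 0, 0), (3, 4, 5), (7, 7, 7), (2, 6, 1)]:
        p = np.asarray(idx, dtype=float) + uvox[(slice(None),) + idx]
        assert out.data[idx] == pytest.approx(sample(img.data, p), abs=1e-6)


def test_warp_against_simpleitk_resampler(rng):
    SimpleITK = pytest.importorskip("SimpleITK")
    n = 12
    img = _img(rng.normal(size=(n, n, n)))
    ddf = random_bspline_ddf((n, n, n), img.spacing_mm, 4, 3.0, seed=9)
    ours = warp_image(img, ddf)

    sitk_img = SimpleITK.GetImageFromArray(np.ascontiguousarray(
        img.data.transpose(2, 1, 0)))
    sitk_img.SetSpacing(img.spacing_mm)
    field = np.ascontiguousarray(
        ddf.vectors.transpose(3, 2, 1, 0)).astype(np.float64)
    f_img = SimpleITK.GetImageFromArray(field, isVector=True)
    f_img.SetSpacing(img.spacing_mm)
    tx = SimpleITK.DisplacementFieldTransform(f_img)
    res = SimpleITK.Resample(sitk_img, sitk_img, tx, SimpleITK.sitkLinear, 0.0)
    theirs = SimpleITK.GetArrayFromImage(res).transpose(2, 1, 0)
    interior = (slice(2, -2),) * 3
    np.testing.assert_allclose(ours.data[interior], theirs[interior], atol=1e-6)


def test_mask_warp_shift_preserves_volume():
    mask = np.zeros((10, 10, 10), dtype=np.uint8)
    mask[4:7, 4:7, 4:7] = 1
    u = np.zeros((3, 10, 10, 10))
    u[1] = -1.5  # shift content one voxel toward +y
    out = warp_mask(mask, DisplacementField(u, (1.5, 1.5, 1.5)))
    assert out.sum() == mask.sum()
    np.testing.assert_array_equal(out[:, 5:8], mask[:, 4:7])
    assert set(np.unique(out)) <= {0, 1}


def test_expanding_field_grows_mask():
    mask = np.zeros((16, 16, 16), dtype=np.uint8)
    mask[6:10, 6:10, 6:10] = 1
    base = np.stack(np.meshgrid(*([np.arange(16.0)] * 3), indexing="ij"))
    u = -0.25 * (base - 7.5) * 1.5  # sample closer to centre -> magnify
    out = warp_mask(mask, DisplacementField(u, (1.5, 1.5, 1.5)))
    assert out.sum() > mask.sum()


def test_slice_resampling_linear_ramp_and_identity():
    ramp = np.tile(np.arange(10, dtype=float) * 3.0, (4, 4, 1))
    img = VolumeImage(ramp, (1.5, 1.5, 3.0))
    out = resample_slices(img, 1.5)
    assert out.spacing_mm[2] == 1.5
    expected = np.arange(out.shape[2]) * 1.5
    np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-12)
    same = resample_slices(img, 3.0)
    np.testing.assert_array_equal(same.data, img.data)


def test_slice_resampling_nearest_keeps_masks_binary():
    mask = (np.arange(8) % 2).astype(float).reshape(1, 1, 8) * np.ones((4, 4, 8))
    img = VolumeImage(mask, (1.5, 1.5, 3.0))
    out = resample_slices(img, 1.5, mode="nearest")
    assert set(np.unique(out.data)) <= {0.0, 1.0}
    with pytest.raises(ValueError):
        resample_slices(img, -1.0)


def test_crop_window_arithmetic_and_padding():
    img = _img(np.arange(20 ** 3, dtype=float).reshape(20, 20, 20))
    ctv = np.zeros((20, 20, 20), dtype=np.uint8)
    ctv[10, 10, 10] = 1
    st = StructureSet({"ctv": ctv}, img.spacing_mm)
    out_img, out_st = crop_around_centroid(img, st, "ctv", (8, 8, 8))
    np.testing.assert_array_equal(out_img.data, img.data[6:14, 6:14, 6:14])
    assert out_st.masks["ctv"][4, 4, 4] == 1
    # window beyond bounds still yields the requested shape
    ctv2 = np.zeros((20, 20, 20), dtype=np.uint8)
    ctv2[1, 1, 1] = 1
    out2, _ = crop_around_centroid(img, StructureSet({"ctv": ctv2},
                                                     img.spacing_mm),
                                   "ctv", (12, 12, 12))
    assert out2.shape == (12, 12, 12)
    with pytest.raises(ValueError):
        crop_around_centroid(img, StructureSet(
            {"ctv": np.zeros((20, 20, 20), dtype=np.uint8)}, img.spacing_mm),
            "ctv", (8, 8, 8))


def test_crop_identity_when_centered():
    img = _img(np.arange(8 ** 3, dtype=float).reshape(8, 8, 8))
    ctv = np.zeros((8, 8, 8), dtype=np.uint8)
    ctv[4, 4, 4] = 1
    out_img, _ = crop_around_centroid(img, StructureSet({"ctv": ctv},
                                                        img.spacing_mm),
                                      "ctv", (8, 8, 8))
    np.testing.assert_array_equal(out_img.data, img.data)


def test_random_field_respects_amplitude_bound_and_determinism():
    # tuned-visibility parameters: 10 control points, 35 mm cap
    f1 = random_bspline_ddf((24, 24, 24), (1.5, 1.5, 1.5), 10, 35.0, seed=11)
    f2 = random_bspline_ddf((24, 24, 24), (1.5, 1.5, 1.5), 10, 35.0, seed=11)
    assert np.abs(f1.vectors).max() <= 35.0 + 1e-9
    np.testing.assert_array_equal(f1.vectors, f2.vectors)
    f0 = random_bspline_ddf((8, 8, 8), (1.5, 1.5, 1.5), 5, 0.0, seed=1)
    assert np.abs(f0.vectors).max() == 0.0
    with pytest.raises(ValueError):
        random_bspline_ddf((8, 8, 8), (1.5, 1.5, 1.5), 3, 1.0, seed=1)


def test_warp_then_inverse_recovers_image():
    # smooth image so the residual reflects inversion, not interpolation noise
    ax = np.arange(16) * 1.5
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    img = _img(np.sin(X / 6.0) + np.cos(Y / 7.0) + np.sin(Z / 5.0))
    ddf = random_bspline_ddf((16, 16, 16), img.spacing_mm, 4, 2.0, seed=2)
    warped = warp_image(img, ddf)
    back = warp_image(warped, invert_ddf(ddf))
    interior = (slice(3, -3),) * 3
    mae = np.abs(back.data[interior] - img.data[interior]).mean()
    dyn = img.data.max() - img.data.min()
    assert mae < 0.01 * dyn


def test_fewer_control_points_mean_smoother_fields():
    energies = {n: [] for n in (4, 6, 8)}
    for seed in range(5):
        for n in energies:
            f = random_bspline_ddf((20, 20, 20), (1.5, 1.5, 1.5), n, 10.0,
                                   seed=seed)
            energies[n].append(bending_energy(f))
    means = {n: np.mean(v) for n, v in energies.items()}
    assert means[4] < means[6] < means[8]


def test_grid_mismatch_raises():
    img = _img(np.zeros((8, 8, 8)))
    with pytest.raises(GridMismatchError):
        warp_image(img, zero_ddf((6, 6, 6)))
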