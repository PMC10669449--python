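"""The Gabor wavelet bank: analytic values, band-pass behaviour, and
orientation selectivity."""

import numpy as np
import pytest
from scipy import ndimage

from dafdnet.gabor import (GaborBank, GaborParams, gabor_conv, make_gabor_bank,
                           make_gabor_kernel)

SIGMA = 2 * np.pi


def test_origin_value_matches_closed_form():
    # envelope and phase are both 1 at the origin (uncorrected kernel)
    for u, v in [(0, 1), (3, 2), (7, 4)]:
        p = GaborParams(u=u, v=v)
        k = make_gabor_kernel(p, dc_correct=False)
        center = k[p.kernel_size // 2, p.kernel_size // 2]
        expected = (p.k_magnitude ** 2 / SIGMA ** 2) * (1 - np.exp(-SIGMA ** 2 / 2))
        assert center.imag == pytest.approx(0.0, abs=1e-15)
        assert center.real == pytest.approx(expected, rel=1e-12)


def test_quarter_turn_orientation_is_rotated_kernel():
    k0 = make_gabor_kernel(GaborParams(U=8, u=0, v=1))
    k4 = make_gabor_kernel(GaborParams(U=8, u=4, v=1))
    # +90 degrees in (row, col) index space maps the u=0 wave onto u=4
    np.testing.assert_allclose(k4, np.rot90(k0, k=-1), atol=1e-10)


def test_scale_law_decreasing():
    mags = [GaborParams(v=v).k_magnitude for v in (1, 2, 3, 4)]
    assert mags == sorted(mags, reverse=True) and mags[-1] > 0
    assert mags[0] == pytest.approx(np.pi / 2)
    assert mags[1] == pytest.approx(np.pi / 4)


def test_kernels_are_zero_mean():
    bank = make_gabor_bank()
    for kern in bank.kernels:
        dc = abs(kern.sum())
        assert dc < 1e-6 * np.sqrt((np.abs(kern) ** 2).sum())


@pytest.mark.parametrize("U,scales,expected", [(8, (1, 2, 3, 4), 32), (1, (1,), 1), (8, (1,), 8)])
def test_bank_sizes(U, scales, expected):
    bank = make_gabor_bank(U=U, scales=scales)
    assert len(bank) == expected == bank.n_channels


def test_bank_order_is_scale_major():
    bank = make_gabor_bank(U=4, scales=(1, 2))
    assert [p.v for p in bank.params] == [1] * 4 + [2] * 4
    assert [p.u for p in bank.params] == [0, 1, 2, 3] * 2


def test_orientation_angles_cover_half_circle():
    bank = make_gabor_bank(U=8, scales=(1,))
    angles = [p.angle for p in bank.params]
    np.testing.assert_allclose(angles, np.arange(8) * np.pi / 8)


@pytest.mark.parametrize("bad", [
    lambda: GaborParams(kernel_size=14),
    lambda: GaborParams(v=0),
])
def test_invalid_params_raise(bad):
    with pytest.raises(ValueError):
        bad()


def test_orientation_out_of_range_raises():
    with pytest.raises(IndexError):
        GaborParams(U=8, u=8)


def test_empty_scales_rejected():
    with pytest.raises(ValueError):
        make_gabor_bank(scales=())


def test_constant_image_response_is_zero():
    bank = make_gabor_bank()
    level = 0.7
    resp = gabor_conv(np.full((48, 48), level, np.float32), bank)
    assert np.abs(resp).max() < 1e-4 * level


def _line_image(theta, size=96, level=0.8, drop=0.2):
    img = np.full((size, size), level, np.float32)
    c = (size - 1) / 2
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.abs(-(rr - c) * np.cos(theta) + (cc - c) * np.sin(theta))
    img[dist < 1.0] = level - drop
    return img


@pytest.mark.parametrize("theta_deg", [0, 22, 45, 90, 135, 158])
def test_dark_line_maximizes_nearest_orientation(theta_deg):
    bank = make_gabor_bank(scales=(1,))
    theta = np.deg2rad(theta_deg)
    resp = np.abs(gabor_conv(_line_image(theta), bank))
    best = int(np.argmax(resp.mean(axis=(0, 1))))
    prefs = np.array([bank.preferred_line_angle(u) for u in range(bank.U)])
    dist = np.minimum(np.abs(prefs - theta % np.pi), np.pi - np.abs(prefs - theta % np.pi))
    assert best == int(np.argmin(dist))


def test_rotating_image_permutes_orientation_channels():
    # smooth field rotated by pi/U shifts the orientation profile by one step
    size = 160
    rng = np.random.default_rng(3)
    img = ndimage.gaussian_filter(rng.standard_normal((size, size)), 1.0).astype(np.float32)
    img = (img - img.min()) / (np.ptp(img) + 1e-9)
    rot = ndimage.rotate(img, 180 / 8, reshape=False, order=3, mode="nearest")
    bank = make_gabor_bank(scales=(1,))
    r0 = np.abs(gabor_conv(img, bank))
    r1 = np.abs(gabor_conv(rot, bank))
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (c - bank.kernel_size) ** 2
    m0 = np.array([r0[..., u][disk].mean() for u in range(8)])
    m1 = np.array([r1[..., u][disk].mean() for u in range(8)])
    assert (np.abs(np.roll(m0, -1) - m1) / m1).max() < 0.05


def test_real_response_is_linear_in_image(rng):
    bank = make_gabor_bank(U=4, scales=(1,), response_mode="real")
    i1 = rng.random((32, 32)).astype(np.float32)
    i2 = rng.random((32, 32)).astype(np.float32)
    lhs = gabor_conv(2.0 * i1 + 0.5 * i2, bank)
    rhs = 2.0 * gabor_conv(i1, bank) + 0.5 * gabor_conv(i2, bank)
    np.testing.assert_allclose(lhs, rhs, atol=1e-4)


def test_magnitude_response_is_positively_homogeneous(rng):
    bank = make_gabor_bank(U=4, scales=(1,))
    img = rng.random((32, 32)).astype(np.float32)
    np.testing.assert_allclose(gabor_conv(3.0 * img, bank), 3.0 * gabor_conv(img, bank),
                               atol=1e-4)


def test_real_imag_mode_doubles_channels(rng):
    bank = make_gabor_bank(U=4, scales=(1,), response_mode="real+imag")
    assert bank.n_channels == 8
    assert gabor_conv(rng.random((16, 16)).astype(np.float32), bank).shape == (16, 16, 8)


def test_bank_json_roundtrip(tmp_path):
    bank = make_gabor_bank(U=6, scales=(1, 3), kernel_size=11, response_mode="real")
    path = tmp_path / "bank.json"
    bank.to_json(path)
    loaded = GaborBank.from_json(path)
    assert (loaded.U, loaded.scales, loaded.kernel_size, loaded.response_mode) == \
        (6, (1, 3), 11, "real")
    for a, b in zip(loaded.kernels, bank.kernels):
        np.testing.assert_allclose(a, b)
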