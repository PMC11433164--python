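"""Losses and metrics against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import ndimage

from voxsr.errors import ParameterError, ShapeError
from voxsr.nn import Tensor
from voxsr.objectives import (
    LossSpec,
    l1,
    mean_gradient_error,
    mixed_gradient_loss,
    mse,
    mss_loss,
    nrmse,
    psnr,
    sobel_gradient,
    ssim,
    ssim_loss,
    ssim_loss_t,
)
from voxsr.volumes import Volume


def _v(data):
    return Volume(data=np.asarray(data, dtype=np.float32))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        v = _v(rng.random((16, 16, 16)))
        assert ssim(v, v) == pytest.approx(1.0, abs=1e-7)
        assert ssim_loss(v, v) == pytest.approx(0.0, abs=1e-7)

    def test_constant_volumes_closed_form(self):
        # mu_a=0, mu_b=1, all (co)variances 0:
        # SSIM = c1*c2 / ((1+c1)*c2) = c1/(1+c1) with c1 = 1e-4
        a = _v(np.zeros((16, 16, 16)))
        b = _v(np.ones((16, 16, 16)))
        expect = 1e-4 / (1 + 1e-4)
        assert ssim(a, b) == pytest.approx(expect, rel=1e-6)

    def test_symmetry(self, rng):
        a, b = _v(rng.random((16, 16, 16))), _v(rng.random((16, 16, 16)))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        skimage = pytest.importorskip("skimage.metrics")
        a = rng.random((24, 24, 24))
        b = np.clip(a + 0.1 * rng.standard_normal(a.shape), 0, 1)
        ref = skimage.structural_similarity(
            a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
        assert ssim(_v(a), _v(b)) == pytest.approx(ref, abs=1e-7)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            ssim(_v(np.zeros((16, 16, 16))), _v(np.zeros((16, 16, 12))))

    def test_differentiable_loss_close_to_metric(self, rng):
        a = rng.random((20, 20, 20), dtype=np.float32)
        b = np.clip(a + 0.05 * rng.standard_normal(a.shape).astype(np.float32), 0, 1)
        loss = ssim_loss_t(Tensor(a[None]), b[None].astype(np.float32)).item()
        # border handling differs (zero pad, no crop) but the values agree
        assert loss == pytest.approx(ssim_loss(_v(a), _v(b)), abs=0.02)


class TestBasicErrors:
    def test_l1_examples_and_oracle(self, rng):
        v = _v(rng.random((6, 6, 6)))
        assert l1(v, v) == 0.0
        a = _v(np.zeros((6, 6, 6)))
        b = _v(np.full((6, 6, 6), 0.25))
        assert l1(a, b) == pytest.approx(0.25)
        x, y = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        brute = sum(
            abs(float(x[i, j, k]) - float(y[i, j, k]))
            for i in range(5) for j in range(5) for k in range(5)
        ) / 125
        assert l1(_v(x), _v(y)) == pytest.approx(brute, rel=1e-6)

    def test_mse_examples_and_oracle(self, rng):
        a = _v(np.zeros((6, 6, 6)))
        b = _v(np.full((6, 6, 6), 0.5))
        assert mse(a, a) == 0.0
        assert mse(a, b) == pytest.approx(0.25)
        x, y = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        brute = sum(
            (float(x[i, j, k]) - float(y[i, j, k])) ** 2
            for i in range(5) for j in range(5) for k in range(5)
        ) / 125
        assert mse(_v(x), _v(y)) == pytest.approx(brute, rel=1e-6)

    def test_psnr_closed_forms(self, rng):
        a = _v(np.zeros((6, 6, 6)))
        b = _v(np.full((6, 6, 6), 0.1))  # mse = 0.01
        assert psnr(a, b, 1.0) == pytest.approx(20.0)
        assert psnr(a, b, 2.0) - psnr(a, b, 1.0) == pytest.approx(6.0206, abs=1e-3)
        assert psnr(a, a) == np.inf
        x, y = _v(rng.random((6, 6, 6))), _v(rng.random((6, 6, 6)))
        assert psnr(x, y) == pytest.approx(10 * np.log10(1.0 / mse(x, y)))

    def test_nrmse(self, rng):
        gt = _v(np.zeros((6, 6, 6)))
        with pytest.raises(ParameterError):
            nrmse(gt, gt)  # degenerate ground-truth range
        gt.data[0, 0, 0] = 1.0
        assert nrmse(gt, gt) == 0.0
        a = _v(np.full((6, 6, 6), 0.5))
        b = _v(np.zeros((6, 6, 6)))
        b.data[0, 0, 0] = 1.0
        x, y = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        y[0, 0, 0] = 0.0
        y[0, 0, 1] = 1.0
        assert nrmse(_v(x), _v(y)) == pytest.approx(np.sqrt(mse(_v(x), _v(y))))


class TestSobel:
    def test_constant_volume_has_zero_gradient(self):
        g = sobel_gradient(_v(np.full((8, 8, 8), 0.7)))
        assert np.abs(g.magnitude).max() < 1e-6

    def test_linear_ramp_interior_gradient_is_32(self):
        # x-ramp: derivative kernel contributes 2, smoothing 4x4 -> 32
        x = np.arange(9, dtype=np.float32)
        v = _v(np.broadcast_to(x[:, None, None], (9, 9, 9)).copy())
        g = sobel_gradient(v)
        interior = (slice(2, -2),) * 3
        np.testing.assert_allclose(g.gx[interior], 32.0, atol=1e-5)
        np.testing.assert_allclose(g.gy[interior], 0.0, atol=1e-5)
        np.testing.assert_allclose(g.gz[interior], 0.0, atol=1e-5)

    def test_magnitude_is_euclidean_norm(self, rng):
        g = sobel_gradient(_v(rng.random((8, 8, 8))))
        np.testing.assert_allclose(
            g.magnitude ** 2, g.gx ** 2 + g.gy ** 2 + g.gz ** 2, rtol=1e-6
        )

    def test_matches_full_kernel_convolution_oracle(self, rng):
        v = rng.random((8, 8, 8))
        deriv, smooth = np.array([-1.0, 0, 1.0]), np.array([1.0, 2, 1.0])
        kx = deriv[:, None, None] * smooth[None, :, None] * smooth[None, None, :]
        ref = ndimage.correlate(v, kx, mode="reflect")
        got = sobel_gradient(Volume(data=v)).gx  # float64 in, float64 out
        np.testing.assert_allclose(got, ref, atol=1e-10)


class TestMixedGradientLoss:
    def test_lambda_zero_reduces_to_mse(self, rng):
        a, b = _v(rng.random((8, 8, 8))), _v(rng.random((8, 8, 8)))
        spec = LossSpec(kind="mgl", lambda_g=0.0)
        assert mixed_gradient_loss(a, b, spec) == pytest.approx(mse(a, b))

    def test_zero_at_equality(self, rng):
        a = _v(rng.random((8, 8, 8)))
        assert mixed_gradient_loss(a, a) == 0.0

    def test_matches_naive_convolution_oracle(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        deriv, smooth = np.array([-1.0, 0, 1.0]), np.array([1.0, 2, 1.0])
        mags = []
        for x in (a, b):
            comps = []
            for ax in range(3):
                kern = [smooth] * 3
                kern[ax] = deriv
                full = (
                    kern[0][:, None, None]
                    * kern[1][None, :, None]
                    * kern[2][None, None, :]
                )
                comps.append(ndimage.correlate(x, full, mode="reflect"))
            mags.append(np.sqrt(sum(c ** 2 for c in comps)))
        mge = ((mags[0] - mags[1]) ** 2).mean()
        got = mixed_gradient_loss(
            Volume(data=a), Volume(data=b), LossSpec(kind="mgl", lambda_g=1.0)
        )
        assert got == pytest.approx(((a - b) ** 2).mean() + mge, rel=1e-9)

    def test_monotone_in_lambda(self, rng):
        a, b = _v(rng.random((8, 8, 8))), _v(rng.random((8, 8, 8)))
        vals = [
            mixed_gradient_loss(a, b, LossSpec(kind="mgl", lambda_g=lg))
            for lg in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(x <= y for x, y in zip(vals, vals[1:]))


class TestMSSLoss:
    def test_single_scale_equals_base(self, rng):
        gt = _v(rng.random((8, 8, 8)))
        out = _v(rng.random((8, 8, 8)))
        got = mss_loss([out], gt, l1, LossSpec(mss_weights=(3.0,)))
        assert got == pytest.approx(l1(out, gt))

    def test_two_equal_weights_average(self):
        gt = _v(np.zeros((8, 8, 8)))
        full = _v(np.full((8, 8, 8), 0.2))     # l1 = 0.2
        half = _v(np.full((4, 4, 4), 0.4))     # upsampled l1 = 0.4
        got = mss_loss([full, half], gt, l1, LossSpec(mss_weights=(1.0, 1.0)))
        assert got == pytest.approx(0.3)

    def test_three_scale_hand_worked_example(self):
        # weights (1,2,3), per-scale losses (0.6,0.3,0.1)
        # -> (0.6 + 0.6 + 0.3)/6 = 0.25
        gt = _v(np.zeros((8, 8, 8)))
        outs = [
            _v(np.full((8, 8, 8), 0.6)),
            _v(np.full((4, 4, 4), 0.3)),
            _v(np.full((2, 2, 2), 0.1)),
        ]
        got = mss_loss(outs, gt, l1, LossSpec(mss_weights=(1.0, 2.0, 3.0)))
        assert got == pytest.approx(0.25)

    def test_invariant_under_weight_rescaling(self, rng):
        gt = _v(rng.random((8, 8, 8)))
        outs = [_v(rng.random((8, 8, 8))), _v(rng.random((4, 4, 4)))]
        a = mss_loss(outs, gt, l1, LossSpec(mss_weights=(1.0, 2.0)))
        b = mss_loss(outs, gt, l1, LossSpec(mss_weights=(5.0, 10.0)))
        assert a == pytest.approx(b, rel=1e-9)

    def test_weight_count_mismatch_rejected(self, rng):
        gt = _v(rng.random((8, 8, 8)))
        with pytest.raises(ParameterError):
            mss_loss([gt], gt, l1, LossSpec(mss_weights=(1.0, 1.0)))


def test_all_losses_nonnegative_and_zero_at_equality(rng):
    v = _v(rng.random((16, 16, 16)))
    assert ssim_loss(v, v) == pytest.approx(0.0, abs=1e-7)
    assert l1(v, v) == 0.0
    assert mse(v, v) == 0.0
    assert mean_gradient_error(v, v) == 0.0
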