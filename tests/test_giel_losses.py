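import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdnet import LossWeights, gradient_loss, l1_loss, l2_loss, sobel_gradients, ssim, ssim_loss, total_loss
from bdnet.giel_losses import (
    ABLATION_PRESETS,
    SOBEL_X,
    SOBEL_Y,
    gradient_loss_and_grad,
    l1_loss_and_grad,
    l2_loss_and_grad,
    ssim_loss_and_grad,
    total_loss_and_grad,
)


def _fd_grad(fn, x, t, eps=1e-6):
    num = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        num[idx] = (fn(xp, t)[0] - fn(xm, t)[0]) / (2 * eps)
    return num


class TestSobel:
    def test_kernels(self):
        assert SOBEL_X.sum() == 0 and SOBEL_Y.sum() == 0
        np.testing.assert_array_equal(SOBEL_Y, SOBEL_X.T)

    def test_constant_image_zero_response(self):
        gx, gy = sobel_gradients(np.full((9, 9), 0.7))
        np.testing.assert_allclose(gx, 0.0, atol=1e-12)
        np.testing.assert_allclose(gy, 0.0, atol=1e-12)

    def test_horizontal_ramp(self):
        c = 0.01
        z = np.tile(np.arange(16) * c, (16, 1))
        gx, gy = sobel_gradients(z)
        # interior of a linear ramp: correlation with the stencil sums to 8c
        np.testing.assert_allclose(gx[1:-1, 1:-1], 8 * c, atol=1e-12)
        np.testing.assert_allclose(gy[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_transpose_swaps_directions(self):
        rng = np.random.default_rng(0)
        z = rng.random((5, 5))
        gx, gy = sobel_gradients(z)
        gxt, gyt = sobel_gradients(z.T)
        np.testing.assert_allclose(gxt, gy.T, atol=1e-12)
        np.testing.assert_allclose(gyt, gx.T, atol=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            sobel_gradients(np.zeros((2, 5)))


class TestGradientLoss:
    def test_identical_images(self, phantom64):
        assert gradient_loss(phantom64, phantom64) == 0.0

    def test_insensitive_to_global_offset(self):
        rng = np.random.default_rng(1)
        a = rng.random((16, 16)) * 0.5
        assert gradient_loss(a, a + 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        assert gradient_loss(a, b) == pytest.approx(gradient_loss(b, a), rel=1e-12)

    def test_matches_bruteforce_on_4x4(self):
        """Oracle: direct per-pixel evaluation of the replicate-padded Sobel
        correlation and the mean-absolute reduction, over all 16 pixels."""
        rng = np.random.default_rng(3)
        a, b = rng.random((4, 4)), rng.random((4, 4))

        def brute_sobel(z, k):
            zp = np.pad(z, 1, mode="edge")
            out = np.zeros_like(z)
            for i in range(4):
                for j in range(4):
                    out[i, j] = np.sum(k * zp[i : i + 3, j : j + 3])
            return out

        expected = np.abs(brute_sobel(a, SOBEL_X) - brute_sobel(b, SOBEL_X)).mean()
        expected += np.abs(brute_sobel(a, SOBEL_Y) - brute_sobel(b, SOBEL_Y)).mean()
        assert gradient_loss(a, b) == pytest.approx(expected, abs=1e-9)


class TestPixelLosses:
    def test_identical(self, phantom64):
        assert l1_loss(phantom64, phantom64) == 0.0
        assert l2_loss(phantom64, phantom64) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.full((10, 10), 0.4)
        assert l1_loss(a, a + 0.1) == pytest.approx(0.1)
        assert l2_loss(a, a + 0.1) == pytest.approx(0.01)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_l2_below_l1_for_unit_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert l2_loss(a, b) <= l1_loss(a, b) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((4, 4)), np.zeros((5, 4)))


class TestSSIM:
    def test_self_similarity(self, phantom64):
        assert ssim(phantom64, phantom64) == pytest.approx(1.0)
        assert ssim_loss(phantom64, phantom64) == pytest.approx(0.0)

    def test_contrast_inversion_below_one(self, phantom64):
        assert ssim(phantom64, 1.0 - phantom64) < 1.0

    def test_matches_reference_implementation(self):
        """Cross-implementation oracle: scikit-image with the Gaussian
        window settings that reproduce the classic formulation."""
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(5)
        a = rng.random((32, 32))
        b = np.clip(a + 0.08 * rng.standard_normal((32, 32)), 0, 1)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False, data_range=1.0
        )
        assert ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((10, 10)), np.zeros((10, 10)))


class TestTotalLoss:
    def test_identical_images_zero(self, phantom64):
        assert total_loss(phantom64, phantom64, LossWeights()) == pytest.approx(0.0)

    def test_reduces_to_l1(self):
        a = np.full((16, 16), 0.2)
        b = np.full((16, 16), 0.5)
        w = LossWeights(1.0, 0.0, 0.0, 0.0)
        assert total_loss(a, b, w) == pytest.approx(l1_loss(a, b))

    def test_composition_identity(self):
        """Weighted sum of independently computed components to 1e-9."""
        rng = np.random.default_rng(6)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        w = LossWeights()
        expected = (
            w.lambda1 * l1_loss(a, b)
            + w.lambda2 * l2_loss(a, b)
            + w.lambda3 * ssim_loss(a, b)
            + w.lambdag * gradient_loss(a, b)
        )
        assert total_loss(a, b, w) == pytest.approx(expected, abs=1e-9)

    def test_all_terms_non_negative(self):
        rng = np.random.default_rng(7)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert l1_loss(a, b) >= 0
        assert l2_loss(a, b) >= 0
        assert gradient_loss(a, b) >= 0
        assert ssim_loss(a, b) >= 0

    def test_zero_iff_identical_with_positive_l1(self):
        rng = np.random.default_rng(8)
        a = rng.random((16, 16))
        b = a.copy()
        b[3, 3] += 0.05
        assert total_loss(a, b, LossWeights()) > 0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-0.1)

    def test_ablation_presets_cover_study_variants(self):
        assert set(ABLATION_PRESETS) == {"l1", "l2", "l1_ssim", "l1_l2_ssim", "l1_l2_ssim_grad"}
        assert ABLATION_PRESETS["l1"].lambda2 == 0.0
        assert ABLATION_PRESETS["l1_l2_ssim_grad"] == LossWeights()


class TestAnalyticGradients:
    """Every loss term's analytic gradient agrees with central finite
    differences (away from the measure-zero kinks of |·|)."""

    @pytest.mark.parametrize(
        "fn,size",
        [
            (l1_loss_and_grad, 8),
            (l2_loss_and_grad, 8),
            (gradient_loss_and_grad, 8),
            (ssim_loss_and_grad, 16),
            (lambda a, b: total_loss_and_grad(a, b, LossWeights()), 16),
        ],
        ids=["l1", "l2", "grad", "ssim", "total"],
    )
    def test_finite_difference_agreement(self, fn, size):
        rng = np.random.default_rng(9)
        x = rng.random((size, size))
        t = rng.random((size, size))
        _, ana = fn(x, t)
        num = _fd_grad(fn, x, t)
        assert np.abs(num - ana).max() / np.abs(num).max() < 1e-3
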