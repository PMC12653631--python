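"""Loss-term oracles: grayscale, LBP (hard vs brute force), soft LBP,
Grad-CAM vs manual chain rule, cross-entropy, and the composed objective."""

import numpy as np
import pytest

from latatk import _autodiff as ad
from latatk import losses
from latatk._autodiff import Tensor


def brute_force_lbp(gray: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit loop over the 8 documented neighbour
    positions (clockwise from top-left, bit q weighted 2^q)."""
    H, W = gray.shape
    out = np.zeros((H - 2, W - 2), dtype=np.int64)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    for i in range(1, H - 1):
        for j in range(1, W - 1):
            code = 0
            for q, (dy, dx) in enumerate(offsets):
                if gray[i + dy, j + dx] - gray[i, j] >= 0:
                    code += 2 ** q
            out[i - 1, j - 1] = code
    return out


class TestGrayscale:
    def test_neutral_red_and_mixed_pixels(self):
        gray = np.full((4, 4, 3), 0.7)
        np.testing.assert_allclose(losses.to_grayscale(gray), 0.7)
        red = np.zeros((2, 2, 3))
        red[..., 0] = 1.0
        np.testing.assert_allclose(losses.to_grayscale(red), 0.299)
        px = np.array([[[0.2, 0.4, 0.6]]])
        np.testing.assert_allclose(losses.to_grayscale(px),
                                   [[0.299 * 0.2 + 0.587 * 0.4 + 0.114 * 0.6]])

    def test_tensor_route_matches_numpy_route(self, rng):
        img = rng.random((2, 8, 8, 3))
        nchw = Tensor(img.transpose(0, 3, 1, 2))
        np.testing.assert_allclose(losses.to_grayscale(nchw).data,
                                   losses.to_grayscale(img), atol=1e-6)


class TestHardLBP:
    def test_matches_brute_force_oracle_on_random_images(self, rng):
        for _ in range(20):
            g = rng.random((8, 8))
            np.testing.assert_array_equal(losses.lbp_codes(g), brute_force_lbp(g))

    def test_constant_image_gives_all_255(self):
        assert (losses.lbp_codes(np.full((5, 7), 0.4)) == 255).all()

    def test_grayscale_shift_invariance_is_exact(self, rng):
        g = rng.random((10, 10)) * 0.8
        np.testing.assert_array_equal(losses.lbp_codes(g),
                                      losses.lbp_codes(g + 0.1))

    def test_documented_single_patch_code(self):
        patch = np.array([[1, 2, 3], [9, 5, 4], [8, 7, 6]], dtype=float)
        assert losses.lbp_codes(patch)[0, 0] == 240

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            losses.lbp_codes(np.ones((2, 5)))


class TestSoftLBP:
    def test_flat_patch_gives_127_5(self):
        val = losses.soft_lbp(np.full((3, 3), 0.5))
        assert val.shape == (1, 1)
        assert val[0, 0] == pytest.approx(255 / 2)

    def test_low_temperature_recovers_hard_codes(self, rng):
        # all-distinct values: every neighbour-centre difference is at
        # least 1/35, so the logistic saturates at temperature 1e-4
        g = rng.permutation(np.linspace(0.0, 1.0, 36)).reshape(6, 6)
        soft = losses.soft_lbp(g, losses.SoftLBPConfig(temperature=1e-4))
        np.testing.assert_allclose(soft, losses.lbp_codes(g), atol=1e-3)

    def test_bounded_in_code_range(self, rng):
        soft = losses.soft_lbp(rng.random((12, 12)))
        assert soft.min() >= 0.0 and soft.max() <= 255.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            losses.SoftLBPConfig(temperature=0.0)


class TestLBPLoss:
    def test_identity_and_shift_invariance_are_zero(self, rng):
        g = rng.random((8, 8))
        assert losses.lbp_loss(g, g, mode="hard") == 0.0
        assert losses.lbp_loss(np.full((6, 6), 0.8), np.full((6, 6), 0.2),
                               mode="hard") == 0.0

    def test_mean_square_on_images_with_known_uniform_codes(self):
        # constant image -> every code 255; strict left-to-right gradient
        # -> N,NE,E,SE,S neighbours are >= centre, W,NW,SW are below, so
        # every code is 2+4+8+16+32 = 62; the loss is (255-62)^2 everywhere
        const = np.full((6, 6), 0.5)
        grad_img = np.tile(np.linspace(0.1, 0.6, 6), (6, 1))
        assert (losses.lbp_codes(grad_img) == 62).all()
        assert losses.lbp_loss(grad_img, const, mode="hard") == pytest.approx(193.0 ** 2)
        assert losses.lbp_loss(grad_img, const, mode="hard",
                               reduction="sum") == pytest.approx(193.0 ** 2 * 16)

    def test_soft_mode_is_differentiable_and_zero_at_identity(self, rng):
        g = Tensor(rng.random((1, 8, 8)))
        loss = losses.lbp_loss(g, g, mode="soft")
        assert loss.item() == 0.0
        (grad_g,) = ad.grad(loss, [g])
        assert grad_g.shape == g.shape

    def test_ste_mode_forwards_hard_values_with_soft_gradient(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        ste_val = losses.lbp_loss(Tensor(a), Tensor(b), mode="ste")
        hard_val = losses.lbp_loss(a, b, mode="hard")
        assert ste_val.item() == pytest.approx(hard_val, rel=1e-4)
        t = Tensor(a)
        (grad_a,) = ad.grad(losses.lbp_loss(t, Tensor(b), mode="ste"), [t])
        assert np.abs(grad_a.data).sum() > 0


class _ToyCam(ad.Module):
    """One 2x2 feature map A = x, logit_c = w_c * (spatial sum of A):
    the chain rule gives a^c = w_c and CAM = relu(w_y * A)."""

    def __init__(self, w=(1.5, -0.7)):
        self.w = np.array(w)
        self.activations = {}

    def __call__(self, x):
        x = ad.as_tensor(x)
        self.activations = {"feat": x}
        pooled = ad.sum_op(x, axis=(1, 2, 3))          # (N,)
        return ad.matmul(ad.reshape(pooled, (x.shape[0], 1)),
                         Tensor(self.w.reshape(1, -1)))


class TestGradCAM:
    def test_toy_model_matches_manual_chain_rule(self):
        with ad.use_dtype(np.float64):
            model = _ToyCam(w=(1.5, -0.7))
            A = np.array([[[[0.3, -0.2], [0.5, 0.1]]]])   # (1,1,2,2)
            for label, w in ((0, 1.5), (1, -0.7)):
                cam = losses.gradcam(model, Tensor(A), [label], "feat")
                expected = np.maximum(w * A[:, 0], 0.0)
                np.testing.assert_allclose(cam.data, expected, atol=1e-6)

    def test_constant_logit_model_gives_zero_cam(self):
        model = _ToyCam(w=(0.0, 0.0))
        cam = losses.gradcam(model, Tensor(np.ones((1, 1, 2, 2))), [0], "feat")
        np.testing.assert_array_equal(cam.data, 0.0)

    def test_cam_nonnegative_on_classifier(self, quick_classifier, small_data):
        from latatk import fixtures as fx
        images, _, labels = small_data
        x = fx.to_nchw(images[:4])
        cam = losses.gradcam(quick_classifier, Tensor(x), labels[:4],
                             quick_classifier.last_conv_layer)
        assert cam.data.min() >= 0.0

    def test_unknown_layer_and_bad_label_rejected(self, quick_classifier, small_data):
        from latatk import fixtures as fx
        images, _, _ = small_data
        x = Tensor(fx.to_nchw(images[:1]))
        with pytest.raises(KeyError):
            losses.gradcam(quick_classifier, x, [0], "conv99")
        with pytest.raises(ValueError, match="label"):
            losses.gradcam(quick_classifier, x, [7], quick_classifier.last_conv_layer)


class TestCamLoss:
    def test_identity_is_zero_and_constant_offset_squared(self):
        model = _ToyCam(w=(1.0, 2.0))
        A = np.abs(np.random.default_rng(0).normal(size=(1, 1, 2, 2)))
        assert losses.cam_loss(model, Tensor(A), Tensor(A), [0], "feat").item() == 0.0
        # CAMs differing by a constant d on every cell -> mean square d^2
        d = 0.25
        loss = losses.cam_loss(model, Tensor(A), Tensor(A + d), [0], "feat")
        assert loss.item() == pytest.approx(d ** 2, rel=1e-5)

    def test_nonnegative(self, rng):
        model = _ToyCam()
        a = Tensor(rng.normal(size=(1, 1, 2, 2)))
        b = Tensor(rng.normal(size=(1, 1, 2, 2)))
        assert losses.cam_loss(model, a, b, [0], "feat").item() >= 0.0


class TestAdvAndTotalLoss:
    def test_adv_loss_closed_forms(self):
        class Uniform(ad.Module):
            def __call__(self, x):
                return Tensor(np.zeros((1, 2)))

        assert losses.adv_loss(Uniform(), Tensor(np.zeros((1, 3, 4, 4))),
                               [0]).item() == pytest.approx(np.log(2))

        class NinetyTen(ad.Module):
            def __call__(self, x):
                return Tensor(np.log(np.array([[0.9, 0.1]])))

        assert losses.adv_loss(NinetyTen(), Tensor(np.zeros((1, 3, 4, 4))),
                               [0]).item() == pytest.approx(-np.log(0.9), rel=1e-5)

    def test_total_loss_sign_structure(self, rng):
        w = losses.LossWeights()  # λ = (1, 0.5)
        assert losses.total_loss(0.0, 0.0, 0.0, w) == 0.0
        assert losses.total_loss(2.0, 3.0, 4.0, w) == pytest.approx(-3.0)
        for _ in range(10):
            la, lc, ll = rng.random(3) * 5
            expected = -la - w.lambda_cam * lc + w.lambda_lbp * ll
            assert losses.total_loss(la, lc, ll, w) == pytest.approx(
                expected, rel=1e-5)
        # raising the texture term strictly raises the total
        assert losses.total_loss(1, 1, 2.0, w) > losses.total_loss(1, 1, 1.0, w)
        # raising the adversarial or CAM terms lowers it
        assert losses.total_loss(2, 1, 1, w) < losses.total_loss(1, 1, 1, w)
        assert losses.total_loss(1, 2, 1, w) < losses.total_loss(1, 1, 1, w)

    def test_nan_component_raises(self):
        with pytest.raises(FloatingPointError):
            losses.total_loss(float("nan"), 0.0, 0.0)
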