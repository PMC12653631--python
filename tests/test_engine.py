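"""Attack assembly contracts (ε-ball, mask preservation, normalisation)
and the training loop (ablations, determinism, frozen surrogate)."""

import numpy as np
import pytest

from latatk import engine
from latatk import fixtures as fx
from latatk._autodiff import Tensor
from latatk.generator import GeneratorConfig, build_generator
from latatk.losses import LossWeights


class TestClipToBall:
    def test_identity_and_clamp_arithmetic(self):
        src = np.full((2, 2, 3), 0.5)
        np.testing.assert_array_equal(engine.clip_to_ball(src, src, 0.1), src)
        out = engine.clip_to_ball(np.full((1, 1, 3), 0.9),
                                  np.full((1, 1, 3), 0.5), 0.1)
        np.testing.assert_allclose(out, 0.6)
        # valid-range floor binds before the ball bound
        out = engine.clip_to_ball(np.full((1, 1, 3), -0.2),
                                  np.full((1, 1, 3), 0.005), 0.01)
        np.testing.assert_allclose(out, 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            engine.clip_to_ball(np.zeros((2, 2, 3)), np.zeros((3, 3, 3)), 0.1)


class TestComposeAdversarial:
    def test_zero_mask_returns_source_exactly(self, rng):
        x = rng.random((8, 8, 3))
        pert = rng.uniform(-1, 1, size=(8, 8, 3))
        cfg = engine.AttackConfig(epsilon=0.1)
        adv = engine.compose_adversarial(x, pert, np.zeros((8, 8)), cfg)
        np.testing.assert_array_equal(adv.image, x)

    def test_saturated_perturbation_with_full_mask(self):
        cfg = engine.AttackConfig(epsilon=0.05)
        x = np.full((4, 4, 3), 0.5)
        adv = engine.compose_adversarial(x, np.ones((4, 4, 3)),
                                         np.ones((4, 4)), cfg)
        np.testing.assert_allclose(adv.image, 0.55)

    @pytest.mark.parametrize("epsilon", [0.01, 0.1])
    def test_mixed_mask_contract_over_random_triples(self, rng, epsilon):
        cfg = engine.AttackConfig(epsilon=epsilon)
        for _ in range(20):
            x = rng.random((12, 12, 3))
            pert = rng.uniform(-1, 1, size=(12, 12, 3))
            mask = (rng.random((12, 12)) > 0.5).astype(float)
            adv = engine.compose_adversarial(x, pert, mask, cfg)
            off = mask == 0
            assert np.array_equal(adv.image[off], x[off])
            assert np.abs(adv.image - x).max() <= epsilon + 1e-12
            assert adv.image.min() >= 0.0 and adv.image.max() <= 1.0

    def test_use_mask_off_perturbs_everywhere(self, rng):
        cfg = engine.AttackConfig(epsilon=0.1, use_mask=False)
        x = np.full((6, 6, 3), 0.5)
        adv = engine.compose_adversarial(x, np.ones((6, 6, 3)),
                                         np.zeros((6, 6)), cfg)
        np.testing.assert_allclose(adv.image, 0.6)
        assert adv.applied_mask.all()


class TestPerChannelNormalize:
    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=(16, 16, 3))
        x = (x - x.mean(axis=(0, 1))) / x.std(axis=(0, 1))
        np.testing.assert_allclose(engine.per_channel_normalize(x), x, atol=1e-5)

    def test_constant_channel_maps_to_zeros(self):
        x = np.full((8, 8, 3), 0.7)
        np.testing.assert_allclose(engine.per_channel_normalize(x), 0.0,
                                   atol=1e-3)

    def test_binary_channel_standardizes_to_unit_values(self):
        x = np.zeros((2, 4, 3))
        x[:, ::2] = 1.0  # half zeros, half ones: mean .5, sd .5
        np.testing.assert_allclose(np.abs(engine.per_channel_normalize(x)),
                                   1.0, atol=1e-6)

    def test_tensor_route_matches_numpy_route(self, rng):
        imgs = rng.random((2, 8, 8, 3))
        t = engine.per_channel_normalize(Tensor(fx.to_nchw(imgs)))
        np.testing.assert_allclose(fx.to_nhwc(t.data),
                                   engine.per_channel_normalize(imgs),
                                   atol=1e-5)


@pytest.fixture(scope="module")
def tiny_setup(small_data):
    model = fx.build_tiny_classifier("A", 2, seed=0)
    model, _ = fx.train_classifier(model, small_data, epochs=2, seed=0)
    return model


class TestTrainAttack:
    def _cfg(self, **kw):
        base = dict(epsilon=0.1, epochs=2, learning_rate=1e-3, batch_size=16,
                    seed=0)
        base.update(kw)
        return engine.AttackConfig(**base)

    def test_adv_only_ablation_history_columns(self, tiny_setup, small_data):
        G = build_generator(GeneratorConfig(seed=0, base_channels=2))
        cfg = self._cfg(use_cam=False, use_lbp=False, epochs=1)
        G, hist = engine.train_attack(G, tiny_setup, None, small_data, cfg)
        assert {"step", "epoch", "l_adv", "total"} <= set(hist.columns)
        assert "l_cam" not in hist.columns and "l_lbp" not in hist.columns
        np.testing.assert_allclose(hist["total"], -hist["l_adv"], atol=1e-6)

    def test_training_is_deterministic_and_surrogate_frozen(self, tiny_setup,
                                                            small_data):
        before = {k: v.copy() for k, v in tiny_setup.state_dict().items()}
        states = []
        for _ in range(2):
            G = build_generator(GeneratorConfig(seed=0, base_channels=2))
            G, _ = engine.train_attack(G, tiny_setup, None, small_data,
                                       self._cfg())
            states.append(G.state_dict())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])
        after = tiny_setup.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_adversarial_loss_ascends_under_training(self, tiny_setup,
                                                     small_data):
        G = build_generator(GeneratorConfig(seed=0))
        cfg = self._cfg(epochs=4, learning_rate=3e-3, use_cam=False,
                        use_lbp=False)
        G, hist = engine.train_attack(G, tiny_setup, None, small_data, cfg)
        first = hist[hist.epoch == 0]["l_adv"].mean()
        last = hist[hist.epoch == hist.epoch.max()]["l_adv"].mean()
        assert last > first

    def test_empty_manifest_rejected(self, tiny_setup):
        G = build_generator(GeneratorConfig(seed=0))
        empty = (np.zeros((0, 32, 32, 3)), np.zeros((0, 32, 32)),
                 np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            engine.train_attack(G, tiny_setup, None, empty, self._cfg())


class TestCraft:
    def test_samples_satisfy_invariants_and_png_round_trip(self, tmp_path,
                                                           small_data, rng):
        images, masks, labels = small_data
        sub = (images[:4], masks[:4], labels[:4])
        G = build_generator(GeneratorConfig(seed=1, base_channels=2))
        G.head.w.data = rng.normal(0, 0.5, size=G.head.w.shape).astype(
            G.head.w.data.dtype)
        cfg = engine.AttackConfig(epsilon=0.1, batch_size=2)
        samples = engine.craft(G, None, sub, cfg, out_dir=tmp_path)
        assert len(samples) == 4
        for s, img, m in zip(samples, images[:4], masks[:4]):
            off = s.applied_mask == 0
            assert np.array_equal(s.image[off], img[off])
            assert np.abs(s.image - img).max() <= cfg.epsilon + 1e-12
            reloaded = fx.load_image(tmp_path / f"adv_{s.source_index:05d}.png")
            assert np.abs(reloaded - s.image).max() <= 0.5 / 255 + 1e-9
        assert (tmp_path / "attack.json").exists()

    def test_degenerate_epsilon_keeps_inputs(self, small_data):
        images, masks, labels = small_data
        sub = (images[:2], masks[:2], labels[:2])
        G = build_generator(GeneratorConfig(seed=1, base_channels=2))
        cfg = engine.AttackConfig(epsilon=1e-9)
        for s, img in zip(engine.craft(G, None, sub, cfg), images):
            np.testing.assert_allclose(s.image, img, atol=1e-9)


def test_masked_noise_baseline_respects_same_contract(small_data):
    images, masks, _ = small_data
    cfg = engine.AttackConfig(epsilon=0.1)
    for s, img, m in zip(
            engine.masked_uniform_noise_attack(images[:4], masks[:4], cfg),
            images, masks):
        assert np.array_equal(s.image[m == 0], img[m == 0])
        assert np.abs(s.image - img).max() <= 0.1 + 1e-12
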