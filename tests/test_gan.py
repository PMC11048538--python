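"""WGAN-GP components: losses, penalty oracle, networks, training loop."""

import numpy as np
import pytest

from eegaug import autodiff as ad
from eegaug.autodiff import Tensor, grad
from eegaug.gan import (DiscriminatorSpec, GANTrainConfig, GeneratorSpec,
                        build_critic, build_generator, discriminator_loss,
                        generate_samples, generator_loss, gradient_penalty,
                        interpolate, sample_latent, train_dcgan_gp)
from eegaug.preprocess import ImageSet, SpectrogramImage


class LinearCritic:
    """D(x) = <w, x> — gradient norm is ||w|| everywhere (analytic oracle)."""

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=float).reshape(1, -1),
                        requires_grad=True)

    def __call__(self, images, labels=None):
        x = ad.as_tensor(images)
        flat = x.reshape((x.shape[0], -1))
        return (flat @ ad.transpose(self.w, (1, 0))).reshape((x.shape[0],))


def _images(n=4, seed=0, size=32):
    return np.random.default_rng(seed).normal(size=(n, 1, size, size))


class TestLatentAndInterpolation:
    def test_latent_labels_and_determinism(self):
        rng = np.random.default_rng(0)
        lat = sample_latent(4, ["left", "left", "right", "right"], rng)
        assert lat.z.shape == (4, 100)
        np.testing.assert_array_equal(lat.labels, [0, 0, 1, 1])
        np.testing.assert_array_equal(lat.onehot.sum(axis=1), 1.0)
        lat2 = sample_latent(4, [0, 0, 1, 1], np.random.default_rng(0))
        np.testing.assert_array_equal(lat.z, lat2.z)
        with pytest.raises(ValueError):
            sample_latent(0, [], rng)

    def test_latent_is_standard_normal(self):
        lat = sample_latent(100_000, np.zeros(100_000, dtype=int),
                            np.random.default_rng(1), latent_dim=8)
        assert np.max(np.abs(lat.z.mean(axis=0))) < 0.02

    def test_interpolation_lies_on_segment(self):
        rng = np.random.default_rng(2)
        real, fake = _images(8, 1), _images(8, 2)
        batch = interpolate(real, fake, rng)
        assert np.all((batch.eps >= 0) & (batch.eps <= 1))
        eps = batch.eps.reshape(-1, 1, 1, 1)
        np.testing.assert_allclose(batch.images, eps * real + (1 - eps) * fake,
                                   rtol=1e-12)
        ones, zeros = np.ones((3, 1, 4, 4)), np.zeros((3, 1, 4, 4))
        mid = interpolate(ones, zeros, np.random.default_rng(3))
        np.testing.assert_allclose(mid.images,
                                   mid.eps.reshape(-1, 1, 1, 1) * ones)
        with pytest.raises(ValueError, match="mismatch"):
            interpolate(np.zeros((2, 1, 4, 4)), np.zeros((3, 1, 4, 4)), rng)


class TestLosses:
    def test_generator_loss_values(self):
        assert generator_loss(np.array([2.0, 4.0])).item() == pytest.approx(-3.0)
        assert generator_loss(np.array([0.0, 0.0, 0.0])).item() == 0.0
        assert generator_loss(np.full(7, 1.25)).item() == pytest.approx(-1.25)
        with pytest.raises(ValueError):
            generator_loss(np.array([]))

    def test_discriminator_loss_convention(self):
        """Minimisation form: mean(fake) - mean(real) + penalty."""
        assert discriminator_loss(np.array([1.0, 1.0]),
                                  np.array([0.0, 0.0]), 0.0).item() == -1.0
        assert discriminator_loss(np.full(5, 2.2), np.full(5, 2.2), 0.0).item() == 0.0
        assert discriminator_loss(np.array([0.0]), np.array([0.0]),
                                  3.7).item() == pytest.approx(3.7)
        with pytest.raises(ValueError):
            discriminator_loss(np.array([]), np.array([1.0]))


class TestGradientPenalty:
    def test_unit_norm_linear_critic_gives_zero(self):
        w = np.zeros(32 * 32)
        w[0] = 1.0  # unit 2-norm
        gp = gradient_penalty(LinearCritic(w), _images(6, 3), gp_weight=10.0)
        assert abs(gp.item()) < 1e-10

    def test_linear_critic_matches_closed_form(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=32 * 32)
        lam = 10.0
        gp = gradient_penalty(LinearCritic(w), _images(5, 5), gp_weight=lam)
        expected = lam * (np.linalg.norm(w) - 1.0) ** 2
        assert gp.item() == pytest.approx(expected, abs=1e-8)

    def test_matches_finite_difference_norm_oracle(self):
        """Penalty equals lam*mean((||grad_x D||-1)^2) with the gradient taken
        by central differences, for 10 random small critics."""
        lam = 10.0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            critic = build_critic(DiscriminatorSpec(conv_channels=(4, 8, 8),
                                                    conditional=False,
                                                    input_shape=(8, 8)),
                                  seed=trial)
            for t in critic.param_tensors():
                t.data = t.data.astype(np.float64)
            x = rng.normal(size=(2, 1, 8, 8))
            gp = gradient_penalty(critic, x, gp_weight=lam).item()

            eps = 1e-5
            norms = []
            for i in range(x.shape[0]):
                g = np.zeros(64)
                for j in range(64):
                    pert = np.zeros_like(x)
                    pert[i].flat[j] = eps
                    with ad.no_grad():
                        fp = critic(x + pert).data[i]
                        fm = critic(x - pert).data[i]
                    g[j] = (fp - fm) / (2 * eps)
                norms.append(np.linalg.norm(g))
            oracle = lam * np.mean((np.array(norms) - 1.0) ** 2)
            assert gp == pytest.approx(oracle, rel=1e-3)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            gradient_penalty(LinearCritic(np.ones(1024)), _images(2), gp_weight=-1.0)


class TestNetworks:
    def test_generator_output_shape_range_determinism(self):
        gen = build_generator(GeneratorSpec(), seed=1)
        lat = sample_latent(8, np.array([0, 1] * 4), np.random.default_rng(0))
        out = gen(lat.z, lat.onehot)
        assert out.shape == (8, 1, 32, 32)
        assert out.data.min() >= -1.0 and out.data.max() <= 1.0
        out2 = gen(lat.z, lat.onehot)
        np.testing.assert_array_equal(out.data, out2.data)
        with pytest.raises(ValueError, match="latent"):
            gen(np.zeros((2, 64), dtype=np.float32), np.eye(2, dtype=np.float32))

    def test_critic_scores_and_head(self):
        critic = build_critic(DiscriminatorSpec(), seed=2)
        labels = np.array([0, 1] * 4)
        s = critic(_images(8, 7).astype(np.float32), labels)
        assert s.shape == (8,)
        assert np.all(np.isfinite(s.data))
        critic.head.w.data[...] = 0.0
        critic.head.b.data[...] = 0.0
        np.testing.assert_array_equal(
            critic(_images(8, 7).astype(np.float32), labels).data, 0.0)
        with pytest.raises(ValueError, match="critic expects"):
            critic(np.zeros((2, 1, 16, 16), dtype=np.float32), labels[:2])

    def test_critic_is_differentiable_wrt_input(self):
        critic = build_critic(DiscriminatorSpec(), seed=3)
        x = Tensor(_images(2, 8).astype(np.float32), requires_grad=True)
        g = grad(critic(x, np.array([0, 1])).sum(), x)
        assert g.shape == x.shape and np.all(np.isfinite(g.data))


def _tiny_imageset(n_per_class=8, seed=0):
    rng = np.random.default_rng(seed)
    images = []
    for ci, lab in enumerate(("left", "right")):
        for i in range(n_per_class):
            images.append(SpectrogramImage(pixels=rng.random((32, 32)),
                                           label=lab, source_id=f"{lab}{i}"))
    return ImageSet(images)


class TestTrainingLoop:
    def test_update_schedule_accounting(self):
        cfg = GANTrainConfig(iterations=3, n_critic=5, batch_size=8, seed=0)
        _, _, hist = train_dcgan_gp(_tiny_imageset(), cfg=cfg)
        assert hist.critic_updates == 15
        assert hist.generator_updates == 3
        assert hist.critic_updates == cfg.n_critic * hist.generator_updates
        assert len(hist.grad_penalty) == 15 and len(hist.wasserstein) == 15

    def test_training_is_reproducible(self):
        cfg = GANTrainConfig(iterations=2, n_critic=2, batch_size=8, seed=5)
        g1, c1, h1 = train_dcgan_gp(_tiny_imageset(), cfg=cfg)
        g2, c2, h2 = train_dcgan_gp(_tiny_imageset(), cfg=cfg)
        assert g1.checksum() == g2.checksum()
        assert c1.checksum() == c2.checksum()
        assert h1.critic_loss == h2.critic_loss

    def test_single_class_data_rejected(self):
        rng = np.random.default_rng(0)
        one_class = ImageSet([SpectrogramImage(pixels=rng.random((32, 32)),
                                               label="left", source_id=str(i))
                              for i in range(8)])
        with pytest.raises(ValueError, match="both classes"):
            train_dcgan_gp(one_class, cfg=GANTrainConfig(iterations=1, batch_size=4))

    def test_generate_samples_balanced_and_deterministic(self):
        gen = build_generator(GeneratorSpec(), seed=4)
        out = generate_samples(gen, 5, seed=5)
        assert len(out) == 10
        assert out.class_counts() == {"left": 5, "right": 5}
        assert all(im.kind == "generated" for im in out)
        pix = out.pixel_array()
        assert pix.min() >= 0.0 and pix.max() <= 1.0
        out2 = generate_samples(gen, 5, seed=5)
        np.testing.assert_array_equal(pix, out2.pixel_array())
        with pytest.raises(ValueError):
            generate_samples(gen, 0, seed=1)
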