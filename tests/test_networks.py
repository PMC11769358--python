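"""Architecture contracts: shapes, determinism, SPADE semantics, gradients."""

import numpy as np
import pytest

from eegtranslate._autograd import Tensor
from eegtranslate.networks import (
    ArchitectureConfig,
    Discriminator,
    Encoder,
    Generator,
    SpadeBlock,
    SpadeResNet,
    reparameterize,
    sample_unit_norm_latent,
    spade_modulate,
)

from .oracles import spade_modulate_loop

RNG = np.random.default_rng(0)


def tiny_arch(**kw):
    return ArchitectureConfig.tiny(**kw)


class TestEncoder:
    def test_default_latent_dimensions(self):
        enc = Encoder(ArchitectureConfig(), np.random.default_rng(1))
        mu, sigma = enc.encode(RNG.uniform(-1, 1, (64, 20)))
        assert mu.shape == (256,) and sigma.shape == (256,)
        assert np.all(sigma > 0)

    def test_forward_determinism(self):
        enc = Encoder(tiny_arch(), np.random.default_rng(2))
        x = RNG.uniform(-1, 1, (64, 8))
        np.testing.assert_array_equal(enc.encode(x)[0], enc.encode(x)[0])

    def test_input_sensitivity(self):
        enc = Encoder(tiny_arch(), np.random.default_rng(3))
        mu0, _ = enc.encode(np.zeros((64, 8)))
        mu1, _ = enc.encode(np.ones((64, 8)) * 0.5)
        assert np.abs(mu0 - mu1).max() > 1e-8

    def test_shape_mismatch_reported(self):
        enc = Encoder(tiny_arch(), np.random.default_rng(4))
        with pytest.raises(ValueError, match=r"\(64, 8\)"):
            enc.encode(RNG.uniform(-1, 1, (64, 20)))

    @pytest.mark.parametrize("L,layers", [(64, 4), (64, 3), (32, 3), (128, 5)])
    def test_temporal_halving_shape_algebra(self, L, layers):
        arch = ArchitectureConfig(L=L, M=4, M_bar=2, latent_dim=8, encoder_layers=layers,
                                  encoder_base_filters=2, generator_stages=2,
                                  generator_base_filters=4, lstm_hidden=4,
                                  discriminator_layers=3, discriminator_base_filters=2,
                                  spade_embed_filters=2)
        enc = Encoder(arch, np.random.default_rng(5))
        h = enc.encode(RNG.uniform(-1, 1, (L, 4)))
        assert h[0].shape == (8,)


class TestReparameterize:
    def test_epsilon_zero_returns_mu(self):
        mu = RNG.normal(size=6)
        np.testing.assert_array_equal(reparameterize(mu, np.ones(6), np.zeros(6)), mu)

    def test_standard_posterior_returns_epsilon(self):
        eps = RNG.normal(size=6)
        np.testing.assert_array_equal(reparameterize(np.zeros(6), np.ones(6), eps), eps)

    def test_hand_computed_value(self):
        z = reparameterize(np.array([1.0, 2.0]), np.array([0.5, 2.0]), np.array([2.0, -1.0]))
        np.testing.assert_allclose(z, [2.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            reparameterize(np.zeros(3), np.ones(2), np.zeros(3))


class TestSpade:
    def test_modulate_matches_elementwise_loop(self):
        g, b, a = (RNG.normal(size=(2, 3, 4, 2)) for _ in range(3))
        np.testing.assert_allclose(spade_modulate(g, b, a), spade_modulate_loop(g, b, a),
                                   rtol=1e-12)

    def test_identity_modulation_returns_normalized_activation(self):
        arch = tiny_arch()
        rng = np.random.default_rng(6)
        block = SpadeBlock(3, arch, rng)
        # force gamma = 1, beta = 0
        block.to_gamma.w.data[:] = 0.0
        block.to_gamma.b.data[:] = 1.0
        block.to_beta.w.data[:] = 0.0
        block.to_beta.b.data[:] = 0.0
        act = Tensor(RNG.normal(size=(4, 3, 16, arch.M_bar)))
        cond = Tensor(RNG.uniform(-1, 1, (4, 1, 64, arch.M)))
        out = block(act, cond).data
        # output equals the sensor-wise normalized activation...
        assert np.abs(out.mean(axis=(0, 2))).max() < 1e-10
        assert np.abs(out.std(axis=(0, 2)) - 1.0).max() < 1e-4
        from eegtranslate._modules import sensor_norm
        np.testing.assert_allclose(out, sensor_norm(act).data, atol=1e-12)

    def test_resnet_residual_identity_when_main_path_zeroed(self):
        arch = tiny_arch()
        rng = np.random.default_rng(7)
        block = SpadeResNet(3, 3, arch, rng)
        block.conv2.w.data[:] = 0.0
        block.conv2.b.data[:] = 0.0
        x = Tensor(RNG.normal(size=(2, 3, 16, arch.M_bar)))
        cond = Tensor(RNG.uniform(-1, 1, (2, 1, 64, arch.M)))
        np.testing.assert_allclose(block(x, cond).data, x.data)
        assert block.conv_skip is None  # equal channel counts: identity skip

    def test_resnet_channel_projection(self):
        arch = tiny_arch()
        block = SpadeResNet(3, 5, arch, np.random.default_rng(8))
        assert block.conv_skip is not None
        x = Tensor(RNG.normal(size=(2, 3, 16, arch.M_bar)))
        cond = Tensor(RNG.uniform(-1, 1, (2, 1, 64, arch.M)))
        assert block(x, cond).shape == (2, 5, 16, arch.M_bar)


class TestGenerator:
    def test_default_output_shape_and_bound(self):
        gen = Generator(ArchitectureConfig(), np.random.default_rng(9))
        out = gen.generate(RNG.uniform(-1, 1, (64, 20)), RNG.standard_normal(256))
        assert out.shape == (64, 12)
        assert np.abs(out).max() < 1.0

    def test_ablation_keeps_output_shape(self):
        arch = tiny_arch(ablation="no_spade_resnet")
        gen = Generator(arch, np.random.default_rng(10))
        out = gen.generate(RNG.uniform(-1, 1, (64, 8)), RNG.standard_normal(16))
        assert out.shape == (64, 4)

    @pytest.mark.parametrize("L,stages", [(64, 4), (64, 2), (32, 3)])
    def test_temporal_doubling_shape_algebra(self, L, stages):
        arch = ArchitectureConfig(L=L, M=4, M_bar=2, latent_dim=8, encoder_layers=2,
                                  encoder_base_filters=2, generator_stages=stages,
                                  generator_base_filters=4, lstm_hidden=4,
                                  discriminator_layers=3, discriminator_base_filters=2,
                                  spade_embed_filters=2)
        gen = Generator(arch, np.random.default_rng(11))
        out = gen.generate(RNG.uniform(-1, 1, (L, 4)), RNG.standard_normal(8))
        assert out.shape == (L, 2)

    def test_latent_validation(self):
        gen = Generator(tiny_arch(), np.random.default_rng(12))
        with pytest.raises(ValueError, match="latent"):
            gen.generate(RNG.uniform(-1, 1, (64, 8)), RNG.standard_normal(5))

    def test_unit_norm_latent_sampler(self):
        z = sample_unit_norm_latent(np.random.default_rng(13), 7, 16)
        np.testing.assert_allclose(np.linalg.norm(z, axis=1), 1.0)


class TestDiscriminator:
    def test_patch_shape_default(self):
        disc = Discriminator(ArchitectureConfig(), np.random.default_rng(14))
        ps = disc.discriminate(RNG.uniform(-1, 1, (64, 12)))
        assert ps.scores.shape == (1, 12)
        assert len(ps.feature_maps) == 4  # one per configured layer

    def test_forward_determinism_and_unbounded_scores(self):
        disc = Discriminator(tiny_arch(), np.random.default_rng(15))
        y = RNG.uniform(-1, 1, (64, 4))
        a, b = disc.discriminate(y), disc.discriminate(y)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_shape_mismatch(self):
        disc = Discriminator(tiny_arch(), np.random.default_rng(16))
        with pytest.raises(ValueError, match=r"\(64, 4\)"):
            disc.discriminate(RNG.uniform(-1, 1, (64, 12)))


class TestGradientFlow:
    def test_loss_on_generator_output_reaches_all_networks(self):
        """A scalar loss assembled from the full forward graph produces nonzero
        gradients in encoder, generator and discriminator parameters, and the
        encoder gradient agrees with a finite-difference probe."""
        from eegtranslate.objectives import hinge_g_loss, l1_loss

        arch = ArchitectureConfig(L=16, M=3, M_bar=2, latent_dim=4, encoder_layers=2,
                                  encoder_base_filters=2, generator_stages=2,
                                  generator_base_filters=2, lstm_hidden=4,
                                  discriminator_layers=2, discriminator_base_filters=2,
                                  spade_embed_filters=2)
        rng = np.random.default_rng(17)
        enc, gen, disc = Encoder(arch, rng), Generator(arch, rng), Discriminator(arch, rng)
        x = RNG.uniform(-1, 1, (2, 16, 3))
        eps = RNG.standard_normal((2, 4))
        target = RNG.uniform(-1, 1, (2, 16, 2))

        def loss_value():
            mu, sigma = enc(x)
            y = gen(x, reparameterize(mu, sigma, Tensor(eps)))
            scores, _ = disc(y.data)
            return l1_loss(Tensor(target), y) + hinge_g_loss(scores), y

        mu, sigma = enc(x)
        y = gen(x, reparameterize(mu, sigma, Tensor(eps)))
        scores, _ = disc(y)
        total = l1_loss(Tensor(target), y) + hinge_g_loss(scores)
        total.backward()
        for net in (enc, gen, disc):
            grads = [p.grad for p in net.parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in grads)

        # finite-difference spot check on one encoder weight
        p = enc.fc_mu.w
        idx = (0, 0)
        analytic = p.grad[idx]
        h = 1e-5
        orig = p.data[idx]
        p.data[idx] = orig + h
        up, _ = loss_value()
        p.data[idx] = orig - h
        dn, _ = loss_value()
        p.data[idx] = orig
        fd = (up.item() - dn.item()) / (2 * h)
        assert analytic == pytest.approx(fd, rel=1e-4, abs=1e-7)
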