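"""Training loop contracts: smoke, determinism, update isolation, checkpoints."""

import numpy as np
import pytest

from eegtranslate.networks import ArchitectureConfig
from eegtranslate.segment_store import ScalpSegment
from eegtranslate.synthetic import SimulationConfig, default_forward_model, simulate_subject
from eegtranslate.trainer import (
    TrainingConfig,
    TrainingDivergedError,
    build_model,
    load_model,
    save_model,
    train_cohort,
    train_subject,
    translate,
)
from eegtranslate.trainer import _d_step, _g_step, _stack_segments
from eegtranslate._autograd import Adam


def micro_arch(**kw):
    base = dict(L=64, M=4, M_bar=2, latent_dim=8, encoder_layers=2,
                encoder_base_filters=2, generator_stages=2, generator_base_filters=4,
                lstm_hidden=8, discriminator_layers=3, discriminator_base_filters=4,
                spade_embed_filters=2)
    base.update(kw)
    return ArchitectureConfig(**base)


def micro_segments(n=32, seed=0):
    cfg = SimulationConfig(n_subjects=1, segments_per_subject=n, M=4, M_bar=2,
                           snr_db=12.0, target_visible_fraction=None)
    fwd = default_forward_model(cfg, np.random.default_rng(0), attenuation=1.0,
                                attenuation_spread=0.0)
    return simulate_subject(cfg, fwd, subject_seed=seed).segments


TINY_TRAIN = TrainingConfig(epochs=2, batch_size=8, seed=0)


class TestTrainSubject:
    def test_smoke_all_losses_finite(self):
        segs = micro_segments()
        model, hist = train_subject(segs, micro_arch(), TINY_TRAIN)
        assert hist.n_epochs == 2
        for name in ("d_loss", "g_hinge", "kl", "l1", "fm", "g_total"):
            vals = getattr(hist, name)
            assert len(vals) == 2 and all(np.isfinite(v) for v in vals)

    def test_seed_determinism(self):
        segs = micro_segments()
        _, h1 = train_subject(segs, micro_arch(), TINY_TRAIN)
        _, h2 = train_subject(segs, micro_arch(), TINY_TRAIN)
        assert h1.g_total == h2.g_total  # bit-identical numpy trajectory

    def test_empty_and_mismatched_segments_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_subject([], micro_arch(), TINY_TRAIN)
        with pytest.raises(ValueError, match="architecture"):
            _stack_segments(micro_segments(), micro_arch(M=20))

    def test_divergence_reported_with_context(self):
        segs = micro_segments(n=8)
        bad = TrainingConfig(epochs=1, batch_size=8, seed=0, learning_rate_g=1e12,
                             learning_rate_d=1e12)
        with pytest.raises(TrainingDivergedError, match="epoch"):
            # absurd learning rate drives parameters (and losses) non-finite
            train_subject(segs * 4, micro_arch(), bad)


class TestUpdateIsolation:
    def test_d_step_leaves_generator_untouched_and_vice_versa(self):
        segs = micro_segments(n=16)
        arch = micro_arch()
        model = build_model(arch, seed=1)
        xs, ys = _stack_segments(segs, arch)
        rng = np.random.default_rng(0)
        params_g = model.generator.parameters() + model.encoder.parameters()
        opt_g = Adam(params_g, lr=1e-3)
        opt_d = Adam(model.discriminator.parameters(), lr=1e-3)

        snap_g = [p.data.copy() for p in params_g]
        snap_d = [p.data.copy() for p in model.discriminator.parameters()]
        _d_step(model, opt_d, xs[:8], ys[:8], rng)
        assert all(np.array_equal(a, p.data) for a, p in zip(snap_g, params_g))
        assert any(not np.array_equal(a, p.data)
                   for a, p in zip(snap_d, model.discriminator.parameters()))

        snap_d2 = [p.data.copy() for p in model.discriminator.parameters()]
        from eegtranslate.objectives import LossWeights

        _g_step(model, opt_g, xs[:8], ys[:8], rng, LossWeights())
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(snap_d2, model.discriminator.parameters()))
        assert any(not np.array_equal(a, p.data) for a, p in zip(snap_g, params_g))


class TestTranslate:
    def test_mean_mode_deterministic(self):
        model = build_model(micro_arch(), seed=2)
        x = np.random.default_rng(1).uniform(-1, 1, (64, 4))
        np.testing.assert_array_equal(translate(model, x), translate(model, x))

    def test_sample_mode_varies_with_rng(self):
        model = build_model(micro_arch(), seed=2)
        x = np.random.default_rng(1).uniform(-1, 1, (64, 4))
        a = translate(model, x, mode="sample", rng=np.random.default_rng(0))
        b = translate(model, x, mode="sample", rng=np.random.default_rng(1))
        assert not np.array_equal(a, b)

    def test_segment_api_returns_estimated_provenance(self):
        model = build_model(micro_arch(), seed=2)
        seg = ScalpSegment(np.random.default_rng(1).uniform(-1, 1, (64, 4)))
        out = translate(model, seg)
        assert out.provenance == "estimated"
        assert out.samples.shape == (64, 2)

    def test_no_encoder_ablation_ignores_encoder(self):
        model = build_model(micro_arch(ablation="no_encoder"), seed=3)
        assert model.encoder is None
        x = np.random.default_rng(2).uniform(-1, 1, (64, 4))
        a, b = translate(model, x), translate(model, x)
        np.testing.assert_array_equal(a, b)  # seeded default noise: repeatable
        assert a.shape == (64, 2)

    def test_default_output_geometry(self):
        model = build_model(ArchitectureConfig(), seed=0)
        out = translate(model, np.random.default_rng(0).uniform(-1, 1, (64, 20)))
        assert out.shape == (64, 12)


class TestCohortAndCheckpoint:
    def test_train_cohort_distinct_models_and_determinism(self):
        from eegtranslate.segment_store import SubjectCohort, SubjectRecord

        records = []
        for i in range(3):
            segs = micro_segments(n=16, seed=i)
            for s in segs:
                s.subject_id = f"S{i + 1}"
            records.append(SubjectRecord(f"S{i + 1}", segs, n_ied_total=8))
        cohort = SubjectCohort(records)
        cfg = TrainingConfig(epochs=1, batch_size=8, seed=5)
        models, hists = train_cohort(cohort, micro_arch(), cfg)
        assert set(models) == {"S1", "S2", "S3"}
        w = [models[s].generator.head.w.data for s in ("S1", "S2", "S3")]
        assert not np.array_equal(w[0], w[1]) and not np.array_equal(w[1], w[2])
        assert hists["S1"].g_total != hists["S2"].g_total
        models2, _ = train_cohort(cohort, micro_arch(), cfg)
        np.testing.assert_array_equal(models["S1"].generator.head.w.data,
                                      models2["S1"].generator.head.w.data)

    def test_checkpoint_roundtrip(self, tmp_path):
        segs = micro_segments(n=16)
        model, _ = train_subject(segs, micro_arch(), TINY_TRAIN)
        path = save_model(model, tmp_path / "model.npz")
        back = load_model(path)
        x = np.random.default_rng(3).uniform(-1, 1, (5, 64, 4))
        np.testing.assert_array_equal(translate(model, x), translate(back, x))

    def test_checkpoint_roundtrip_no_encoder(self, tmp_path):
        model = build_model(micro_arch(ablation="no_encoder"), seed=4)
        back = load_model(save_model(model, tmp_path / "m.npz"))
        assert back.encoder is None
        x = np.random.default_rng(3).uniform(-1, 1, (2, 64, 4))
        np.testing.assert_array_equal(translate(model, x), translate(back, x))
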