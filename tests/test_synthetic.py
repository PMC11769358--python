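"""Synthetic cohort generator: waveform morphology, forward model, visibility."""

from dataclasses import replace

import numpy as np
import pytest

from eegtranslate.synthetic import (
    ForwardModel,
    IedTemplate,
    OSC_AMPLITUDE_RATIO,
    SimulationConfig,
    calibrate_attenuation,
    default_forward_model,
    default_templates,
    measure_visible_fraction,
    oscillation_envelope,
    render_ied_template,
    simulate_cohort,
    simulate_continuous,
    simulate_subject,
)


def small_cfg(**kw) -> SimulationConfig:
    base = dict(n_subjects=1, segments_per_subject=40, target_visible_fraction=None)
    base.update(kw)
    return SimulationConfig(**base)


class TestTemplate:
    def test_zero_amplitude_is_zero_waveform(self):
        t = IedTemplate(spike_amplitude=0.0)
        assert np.all(render_ied_template(t, 64, 200, 32) == 0)

    def test_peak_at_onset_sample(self):
        w = render_ied_template(IedTemplate(), 64, 200.0, 32)
        assert abs(int(np.argmax(np.abs(w))) - 32) <= 1
        assert np.abs(w).max() == pytest.approx(IedTemplate().spike_amplitude)

    def test_oscillation_matches_closed_form(self):
        """Beyond the spike support the waveform is the damped sinusoid
        a*exp(-t/tau)*sin(2*pi*f*t), with the closed-form envelope at t=k*tau
        equal to a*e^-k."""
        t = IedTemplate()
        L, rate, onset = 128, 200.0, 32
        w = render_ied_template(t, L, rate, onset)
        sigma = t.spike_width / 4.0
        t0 = 2.0 * sigma
        time = (np.arange(L) - onset) / rate
        shifted = time - t0
        amp = OSC_AMPLITUDE_RATIO * t.spike_amplitude
        expected = np.where(
            shifted >= 0,
            amp * np.exp(-shifted / t.oscillation_decay)
            * np.sin(2 * np.pi * t.oscillation_frequency * shifted),
            0.0,
        )
        beyond_spike = time > t0 + 9 * sigma
        assert np.abs(w[beyond_spike] - expected[beyond_spike]).max() < 0.02 * amp
        # envelope at t0 + k*tau decays as e^-k
        for k in (1, 2):
            ts = k * t.oscillation_decay
            assert oscillation_envelope(t, ts) == pytest.approx(amp * np.exp(-k))
        # and bounds the rendered oscillation
        env = oscillation_envelope(t, shifted[beyond_spike])
        assert np.all(np.abs(w[beyond_spike]) <= env + 1e-12)

    def test_polarity_flips_waveform(self):
        up = render_ied_template(IedTemplate(polarity=1), 64, 200, 32)
        down = render_ied_template(IedTemplate(polarity=-1), 64, 200, 32)
        np.testing.assert_allclose(up, -down)

    def test_template_wider_than_segment_rejected(self):
        with pytest.raises(ValueError, match="support"):
            render_ied_template(IedTemplate(oscillation_decay=2.0), 64, 200, 32)
        with pytest.raises(ValueError, match="onset"):
            render_ied_template(IedTemplate(), 64, 200, 70)


class TestSimulateSubject:
    def test_identity_forward_model_gives_equal_streams(self):
        cfg = small_cfg(M=4, M_bar=4, segments_per_subject=10)
        fwd = ForwardModel(mixing_matrix=np.eye(4), noise_sd=0.0, attenuation=1.0,
                           attenuation_spread=0.0)
        rec = simulate_subject(cfg, fwd, subject_seed=3)
        for seg in rec.segments:
            np.testing.assert_array_equal(seg.scalp.samples, seg.intracranial.samples)

    def test_linear_projection_exact(self):
        """Without saturation/noise the scalp is exactly attenuation * Y @ mix^T
        (brute-force matrix-product oracle)."""
        cfg = small_cfg(M=6, M_bar=3, segments_per_subject=8)
        rng = np.random.default_rng(5)
        mix = rng.uniform(0, 1, (6, 3))
        mix /= mix.sum(axis=1, keepdims=True)  # keep the projection inside [-1, 1]
        fwd = ForwardModel(mixing_matrix=mix, noise_sd=0.0, attenuation=0.7,
                           attenuation_spread=0.0)
        rec = simulate_subject(cfg, fwd, subject_seed=4)
        for seg in rec.segments:
            y = seg.intracranial.samples
            expected = 0.7 * np.array(
                [[sum(y[l, k] * mix[m, k] for k in range(3)) for m in range(6)]
                 for l in range(y.shape[0])]
            )
            np.testing.assert_allclose(seg.scalp.samples, expected, atol=1e-12)

    def test_default_geometry_and_exact_label_balance(self):
        cfg = SimulationConfig(n_subjects=1, segments_per_subject=20,
                               target_visible_fraction=None)
        rec = simulate_subject(cfg, subject_seed=1)
        labels = [s.label for s in rec.segments]
        assert labels.count("IED") == labels.count("nonIED") == 10
        for seg in rec.segments:
            assert seg.scalp.samples.shape == (64, 20)
            assert seg.intracranial.samples.shape == (64, 12)
            assert np.abs(seg.scalp.samples).max() <= 1.0
        ied = [s for s in rec.segments if s.label == "IED"]
        assert all(s.scalp.onset_index == 32 for s in ied)

    def test_determinism(self):
        cfg = small_cfg(segments_per_subject=12)
        a = simulate_subject(cfg, subject_seed=9)
        b = simulate_subject(cfg, subject_seed=9)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.scalp.samples, sb.scalp.samples)
            np.testing.assert_array_equal(sa.intracranial.samples, sb.intracranial.samples)

    def test_realized_snr_matches_config_at_unit_attenuation(self):
        for seed, snr in ((0, 5.0), (1, 12.0)):
            cfg = small_cfg(segments_per_subject=100, snr_db=snr)
            fwd = default_forward_model(cfg, np.random.default_rng(0), attenuation=1.0)
            _, diag = simulate_subject(cfg, fwd, subject_seed=seed, return_diagnostics=True)
            assert diag["snr_db_estimate"] == pytest.approx(snr, abs=0.5)


class TestVisibility:
    def test_vanishing_attenuation_hides_all_ieds(self):
        cfg = small_cfg(segments_per_subject=100)
        fwd = default_forward_model(cfg, np.random.default_rng(0), attenuation=1e-4)
        frac = measure_visible_fraction(simulate_subject(cfg, fwd, subject_seed=2))
        assert frac <= 0.05

    def test_clean_unit_attenuation_shows_all_ieds(self):
        cfg = small_cfg(segments_per_subject=60)
        fwd = default_forward_model(cfg, np.random.default_rng(0), noise_sd=0.0,
                                    attenuation=1.0, attenuation_spread=0.0)
        assert measure_visible_fraction(simulate_subject(cfg, fwd, subject_seed=2)) == 1.0

    def test_requires_ied_segments(self):
        cfg = small_cfg(segments_per_subject=8, ied_fraction=1.0)
        rec = simulate_subject(cfg, subject_seed=1)
        rec.segments = [s for s in rec.segments if s.label == "nonIED"]
        with pytest.raises(ValueError, match="IED"):
            measure_visible_fraction(rec)

    def test_calibrated_cohort_reproduces_target_fraction(self):
        """Over >=500 IED segments the measured scalp-visible fraction lies
        within 3 binomial standard errors of the 18.8% reference value."""
        target = 0.188
        cfg = SimulationConfig(n_subjects=1, segments_per_subject=200,
                               target_visible_fraction=None)
        fwd = default_forward_model(cfg, np.random.default_rng(0))
        att = calibrate_attenuation(cfg, fwd, default_templates(), target, seed=5)
        n_ied, hits = 0, 0
        for seed in range(6):
            rec = simulate_subject(cfg, replace(fwd, attenuation=att), subject_seed=seed + 10)
            n_ied += rec.n_ied_total
            hits += rec.n_ied_visible
        assert n_ied >= 500
        se = np.sqrt(target * (1 - target) / n_ied)
        assert abs(hits / n_ied - target) <= 3 * se


class TestCohortAndContinuous:
    def test_cohort_structure_and_determinism(self):
        cfg = SimulationConfig(n_subjects=3, segments_per_subject=8,
                               target_visible_fraction=None)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.subject_ids == ["S1", "S2", "S3"]
        for ra, rb in zip(a.subjects, b.subjects):
            for sa, sb in zip(ra.segments, rb.segments):
                np.testing.assert_array_equal(sa.scalp.samples, sb.scalp.samples)
        # different subjects get different data
        assert not np.array_equal(a.subjects[0].segments[0].scalp.samples,
                                  a.subjects[1].segments[0].scalp.samples)

    def test_continuous_mode_shapes_and_onsets(self):
        cfg = small_cfg()
        x, y, rate, onsets = simulate_continuous(cfg, duration_s=20.0, n_ieds=5, seed=3)
        assert x.shape == (4000, 20) and y.shape == (4000, 12)
        assert rate == 200.0 and len(onsets) == 5
        assert np.all(np.diff(onsets) >= cfg.L)
        # the intracranial trace actually carries a transient at each onset
        for onset in onsets:
            win = np.abs(y[onset - 4:onset + 8]).max()
            assert win > 3 * np.sqrt(np.mean(y[onset + 40:onset + 60] ** 2))
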