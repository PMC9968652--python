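"""Spectrogram computation and the template-correlation detector."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bluecall.spectro import (
    SONG_THRESHOLD,
    SONG_WINDOW_SAMPLES,
    compute_spectrogram,
    correlate_template,
    cut_template,
    detect_calls,
)
from bluecall.synth import synth_clip
from bluecall.templates import detector_spectrogram
from bluecall.types import AudioClip, Template


class TestComputeSpectrogram:
    def test_freq_step_is_rate_over_fft_size(self, noise_clip):
        spec = compute_spectrogram(noise_clip, window_samples=3000, fft_size=3072)
        assert spec.freq_step_hz == pytest.approx(2000 / 3072)
        assert np.allclose(np.diff(spec.freqs), 2000 / 3072)

    def test_frame_count_formula(self, noise_clip):
        n = noise_clip.samples.size
        for window, overlap in [(2048, 0.5), (3000, 0.5), (1000, 0.75)]:
            spec = compute_spectrogram(noise_clip, window_samples=window, overlap_frac=overlap)
            hop = int(round(window * (1 - overlap)))
            assert spec.times.size == (n - window) // hop + 1

    def test_pure_tone_localized_to_nearest_bin(self):
        sr = 2000
        t = np.arange(60 * sr) / sr
        clip = AudioClip(samples=np.sin(2 * np.pi * 23.5 * t), sample_rate=sr)
        spec = compute_spectrogram(clip, window_samples=3000)
        target = np.argmin(np.abs(spec.freqs - 23.5))
        assert np.all(np.argmax(spec.power, axis=0) == target)

    def test_constant_zero_clip_uniform_floor(self):
        clip = AudioClip(samples=np.zeros(8000), sample_rate=2000)
        spec = compute_spectrogram(clip, window_samples=2048)
        assert np.allclose(spec.power, spec.power.flat[0])

    def test_too_short_clip_raises(self):
        clip = AudioClip(samples=np.zeros(1000), sample_rate=2000)
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(clip, window_samples=2048)

    def test_fft_smaller_than_window_rejected(self, noise_clip):
        with pytest.raises(ValueError):
            compute_spectrogram(noise_clip, window_samples=3000, fft_size=2048)


class TestCorrelateTemplate:
    def test_self_correlation_peaks_at_one(self, single_song_spec, single_song_clip):
        _, anns = single_song_clip
        tmpl = cut_template(single_song_spec, anns.entries[0], "self")
        scores = correlate_template(single_song_spec, tmpl)
        assert scores.max() == pytest.approx(1.0, abs=1e-6)

    def test_score_series_valid_mode_length(self, single_song_spec, song_template):
        scores = correlate_template(single_song_spec, song_template)
        assert scores.size == single_song_spec.times.size - song_template.n_frames + 1

    def test_scores_bounded(self, single_song_spec, song_template):
        scores = correlate_template(single_song_spec, song_template)
        assert np.all(scores >= -1.0) and np.all(scores <= 1.0)

    @given(gain_db=st.floats(min_value=-40, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_gain_invariance(self, gain_db):
        # adding a constant (dB) to the spectrogram leaves scores unchanged
        clip, anns = synth_clip(60.0, "song", [20.0], snr_db=15, seed=9)
        spec = compute_spectrogram(clip, window_samples=SONG_WINDOW_SAMPLES)
        tmpl = cut_template(spec, anns.entries[0], "g")
        base = correlate_template(spec, tmpl)
        spec.power = spec.power + gain_db
        shifted = correlate_template(spec, tmpl)
        assert np.allclose(base, shifted, atol=1e-8)

    def test_white_noise_rarely_scores_high(self):
        # Monte Carlo null: a 2-s template almost never reaches 0.5
        # against white-noise spectrograms
        tclip, tanns = synth_clip(60.0, "dcall", [20.0], snr_db=30, seed=999)
        tspec = compute_spectrogram(tclip)
        full = cut_template(tspec, tanns.entries[0], "null")
        m2 = int(round(2.0 / tspec.time_step_s))
        short = Template(
            patch=full.patch[:, :m2],
            call_type="dcall",
            band=full.band,
            duration_s=2.0,
            template_id="null2s",
        )
        n_high = 0
        trials = 200
        for s in range(trials):
            clip, _ = synth_clip(30.0, "dcall", [], noise_slope_db_per_octave=0.0, seed=1000 + s)
            spec = compute_spectrogram(clip)
            if correlate_template(spec, short).max() >= 0.5:
                n_high += 1
        assert n_high / trials <= 0.01 + 1e-9

    def test_zero_variance_window_scores_zero(self, song_template):
        clip = AudioClip(samples=np.zeros(30 * 2000), sample_rate=2000)
        spec = compute_spectrogram(clip, window_samples=SONG_WINDOW_SAMPLES)
        scores = correlate_template(spec, song_template)
        assert np.allclose(scores, 0.0)


class TestDetectCalls:
    def test_threshold_is_inclusive_boundary(self, song_bank):
        clip, _ = synth_clip(200.0, "song", [60.0, 140.0], snr_db=10, seed=13)
        spec = detector_spectrogram(clip, "song")
        dets = detect_calls(spec, song_bank, threshold=SONG_THRESHOLD)
        peak = max(d.score for d in dets)
        # exactly at threshold -> detected; just above it -> not
        at = detect_calls(spec, song_bank, threshold=peak)
        above = detect_calls(spec, song_bank, threshold=min(peak + 1e-6, 1.0))
        assert any(d.score == peak for d in at)
        assert all(d.score < peak + 1e-6 for d in above)

    def test_arbitration_keeps_highest_scoring_template(self, song_bank):
        clip, _ = synth_clip(120.0, "song", [50.0], snr_db=18, seed=14)
        spec = detector_spectrogram(clip, "song")
        dets = detect_calls(spec, song_bank, threshold=0.5)
        best = max(dets, key=lambda d: d.score)
        scores = {
            t.template_id: correlate_template(spec, t)[
                int(round(best.start_s / spec.time_step_s))
            ]
            for t in song_bank
        }
        assert best.template_id == max(scores, key=scores.get)

    def test_empty_template_list_rejected(self, single_song_spec):
        with pytest.raises(ValueError, match="empty"):
            detect_calls(single_song_spec, [], threshold=0.75)

    def test_mixed_call_types_rejected(self, song_bank, dcall_bank, single_song_spec):
        with pytest.raises(ValueError, match="call_type"):
            detect_calls(single_song_spec, [song_bank[0], dcall_bank[0]], threshold=0.75)

    def test_min_gap_merging_keeps_higher_score(self, song_bank):
        clip, _ = synth_clip(120.0, "song", [50.0], snr_db=18, seed=15)
        spec = detector_spectrogram(clip, "song")
        loose = detect_calls(spec, song_bank, threshold=0.3, min_gap_s=0.0)
        merged = detect_calls(spec, song_bank, threshold=0.3, min_gap_s=30.0)
        assert len(merged) <= len(loose)
        assert max(d.score for d in merged) == max(d.score for d in loose)

    def test_planted_signal_recovery_at_10db(self, song_bank):
        # >= 95% of 50 planted events detected within one template
        # duration of truth at 10 dB band SNR
        rng = np.random.default_rng(77)
        times = np.sort(rng.choice(np.arange(20, 3560, 15), 50, replace=False)).astype(float)
        times += rng.uniform(0, 0.7, 50)
        clip, anns = synth_clip(3600.0, "song", times, snr_db=10.0, seed=78)
        spec = detector_spectrogram(clip, "song")
        dets = detect_calls(spec, song_bank, threshold=SONG_THRESHOLD)
        tol = max(t.duration_s for t in song_bank)
        hit = sum(
            any(abs(d.start_s - a.start_s) <= tol for d in dets) for a in anns
        )
        assert hit / len(anns) >= 0.95
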