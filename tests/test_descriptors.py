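"""Descriptor extraction: envelope, attack, ERB spectrogram, frame-level
spectral descriptors and their summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timbreaffect as ta
from timbreaffect import descriptors as desc
from timbreaffect.descriptors import DescriptorError
from timbreaffect.synth import AudioClip

SR = 44100


def _clip(samples):
    return AudioClip(samples=np.asarray(samples, dtype=float), sample_rate=SR)


def _env(values, sr=1000):
    values = np.asarray(values, dtype=float)
    return desc.TemporalEnvelope(times=np.arange(len(values)) / sr,
                                 values=values, sample_rate=sr)


class TestTemporalEnvelope:
    def test_sinusoid_plateau_matches_amplitude(self):
        t = np.arange(SR) / SR
        env = ta.temporal_envelope(_clip(0.7 * np.sin(2 * np.pi * 440 * t)))
        mid = env.values[SR // 4: 3 * SR // 4]
        assert np.all(np.abs(mid - 0.7) < 0.02 * 0.7)

    def test_linearity_under_scaling(self):
        t = np.arange(SR // 2) / SR
        x = np.sin(2 * np.pi * 300 * t) * np.exp(-2 * t)
        e1 = ta.temporal_envelope(_clip(x)).values
        e2 = ta.temporal_envelope(_clip(0.5 * x)).values
        assert np.allclose(e2, 0.5 * e1, atol=1e-12)

    def test_beat_envelope_oscillates_at_beat_rate(self):
        t = np.arange(2 * SR) / SR
        x = np.sin(2 * np.pi * 440 * t) + np.sin(2 * np.pi * 441 * t)
        env = ta.temporal_envelope(_clip(x))
        centred = env.values - env.values.mean()
        spec = np.abs(np.fft.rfft(centred))
        freqs = np.fft.rfftfreq(len(centred), 1 / SR)
        assert freqs[np.argmax(spec)] == pytest.approx(1.0, abs=0.3)

    def test_all_zero_signal_gives_zero_envelope(self):
        env = ta.temporal_envelope(_clip(np.zeros(SR // 4)))
        assert np.all(env.values == 0)


class TestDetectAttack:
    def test_linear_ramp_spans_10_to_90_percent(self):
        sr = 1000
        values = np.concatenate([np.linspace(0, 1, 100), np.ones(400)])
        seg = ta.detect_attack(_env(values, sr))
        assert seg.t_end - seg.t_start == pytest.approx(0.08, abs=0.005)

    def test_instantaneous_step_has_tiny_attack(self):
        sr = 1000
        values = np.concatenate([[0.0], np.ones(499)])
        seg = ta.detect_attack(_env(values, sr))
        assert seg.t_end - seg.t_start <= 2 / sr

    def test_two_stage_ramp_matches_crossing_oracle(self):
        # slow rise to 0.5 then fast rise to 1: enumerate crossings directly
        sr = 1000
        values = np.concatenate([np.linspace(0, 0.5, 400),
                                 np.linspace(0.5, 1.0, 20), np.ones(80)])
        env = _env(values, sr)
        seg = ta.detect_attack(env)
        thresholds = desc.ATTACK_THRESHOLDS
        crossings = np.array([np.argmax(values >= th * values.max())
                              for th in thresholds])
        efforts = np.diff(crossings).astype(float)
        valid = np.where(efforts <= 3.0 * efforts.mean())[0]
        expected_start = crossings[valid[0]] / sr
        expected_end = crossings[valid[-1] + 1] / sr
        assert seg.t_start == pytest.approx(expected_start)
        assert seg.t_end == pytest.approx(expected_end)

    def test_zero_envelope_rejected(self):
        with pytest.raises(DescriptorError):
            ta.detect_attack(_env(np.zeros(100)))


class TestTemporalScalars:
    def test_log_attack_time_of_100ms(self):
        sr = 1000
        values = np.concatenate([np.linspace(0, 1, 100), np.ones(400)])
        seg = desc.AttackSegment(t_start=0.0, t_end=0.1)
        lat, _, _ = ta.temporal_scalars(_env(values, sr), seg)
        assert lat == pytest.approx(-1.0, abs=1e-6)

    def test_linear_ramp_attack_slope(self):
        sr = 1000
        values = np.concatenate([np.linspace(0, 1, 101), np.ones(399)])
        seg = desc.AttackSegment(t_start=0.0, t_end=0.1)
        _, slope, _ = ta.temporal_scalars(_env(values, sr), seg)
        assert slope == pytest.approx(10.0, rel=1e-6)

    def test_rectangular_envelope_centroid_at_midpoint(self):
        sr = 1000
        env = _env(np.ones(500), sr)
        seg = desc.AttackSegment(t_start=0.0, t_end=0.01)
        _, _, centroid = ta.temporal_scalars(env, seg)
        # mean of times 0 .. 0.499 s
        assert centroid == pytest.approx(np.mean(env.times), rel=1e-9)

    def test_linear_decay_centroid_at_one_third(self):
        sr = 10000
        T = 0.5
        values = 1.0 - np.arange(int(T * sr)) / (T * sr)
        seg = desc.AttackSegment(t_start=0.0, t_end=0.01)
        _, _, centroid = ta.temporal_scalars(_env(values, sr), seg)
        assert centroid == pytest.approx(T / 3, rel=0.01)


class TestErbRate:
    def test_zero_maps_to_zero(self):
        assert ta.erb_rate(0.0) == 0.0

    def test_1khz_value(self):
        assert ta.erb_rate(1000.0) == pytest.approx(21.4 * np.log10(5.37), abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=20000.0),
           st.floats(min_value=0.01, max_value=2000.0))
    def test_strictly_increasing(self, f, delta):
        assert ta.erb_rate(f + delta) > ta.erb_rate(f)

    def test_negative_frequency_rejected(self):
        with pytest.raises(DescriptorError):
            ta.erb_rate(-1.0)


class TestErbSpectrogram:
    def test_frame_count_for_500ms_clip(self):
        spec = ta.erb_spectrogram(_clip(np.random.default_rng(0).normal(size=22050)))
        assert spec.magnitudes.shape[0] == 1 + (22050 - 1024) // 256  # 83

    def test_pure_tone_peak_bin(self):
        t = np.arange(22050) / SR
        f = 1000.0
        spec = ta.erb_spectrogram(_clip(np.sin(2 * np.pi * f * t)))
        for frame in spec.magnitudes[5:-5]:
            peak_hz = spec.bin_freqs_hz[np.argmax(frame)]
            assert abs(peak_hz - f) <= SR / 1024  # within one bin

    def test_silence_flagged(self):
        spec = ta.erb_spectrogram(_clip(np.zeros(22050)))
        assert spec.silent.all()

    def test_short_clip_rejected(self):
        with pytest.raises(DescriptorError):
            ta.erb_spectrogram(_clip(np.ones(512)))


class TestSpectralMoments:
    def test_point_mass(self):
        mu, sd, sk, ku = ta.spectral_moments(np.array([0, 1.0, 0]),
                                             np.array([5.0, 12.0, 20.0]))
        assert (mu, sd, sk, ku) == (12.0, 0.0, 0.0, 0.0)

    def test_two_point_symmetric_mass(self):
        mu, sd, sk, ku = ta.spectral_moments(np.array([1.0, 1.0]),
                                             np.array([10.0, 20.0]))
        assert mu == 15.0 and sd == 5.0
        assert sk == pytest.approx(0.0) and ku == pytest.approx(1.0)

    def test_weighted_mean(self):
        mu, *_ = ta.spectral_moments(np.array([1.0, 3.0]), np.array([10.0, 20.0]))
        assert mu == pytest.approx(17.5)

    def test_gain_invariance(self, rng):
        mags = rng.uniform(0, 1, 16)
        freqs = np.sort(rng.uniform(1, 30, 16))
        a = ta.spectral_moments(mags, freqs)
        b = ta.spectral_moments(3.7 * mags, freqs)
        assert np.allclose(a, b, rtol=1e-12)

    def test_mirrored_spectrum_flips_skewness(self, rng):
        mags = rng.uniform(0, 1, 16)
        freqs = np.linspace(2, 32, 16)
        mu, sd, sk, ku = ta.spectral_moments(mags, freqs)
        mu2, sd2, sk2, ku2 = ta.spectral_moments(mags[::-1], freqs)
        assert sd2 == pytest.approx(sd)
        assert sk2 == pytest.approx(-sk)
        assert ku2 == pytest.approx(ku)


class TestSpectralShape:
    def test_flat_frame(self):
        mags = np.ones(8)
        freqs = np.linspace(1, 8, 8)
        slope, decrease, _, flatness, crest = ta.spectral_shape(mags, freqs)
        assert slope == pytest.approx(0.0)
        assert flatness == pytest.approx(1.0)
        assert crest == pytest.approx(1.0)

    def test_single_spike_among_k_bins(self):
        K = 10
        mags = np.zeros(K)
        mags[3] = 2.0
        freqs = np.linspace(1, K, K)
        *_, flatness, crest = ta.spectral_shape(mags, freqs)
        assert flatness == 0.0
        assert crest == pytest.approx(K)

    def test_decrease_hand_value(self):
        mags = np.array([1.0, 0.5, 0.25])
        freqs = np.array([1.0, 2.0, 3.0])
        _, decrease, *_ = ta.spectral_shape(mags, freqs)
        expected = ((0.5 - 1) / 1 + (0.25 - 1) / 2) / 0.75
        assert decrease == pytest.approx(expected)  # ~ -1.1667

    def test_rolloff_cumulative_energy_oracle(self, rng):
        for _ in range(50):
            mags = rng.uniform(0, 1, 16)
            freqs = np.sort(rng.uniform(1, 40, 16))
            rolloff = ta.spectral_shape(mags, freqs)[2]
            cum = np.cumsum(mags**2)
            idx = next(i for i in range(16) if cum[i] >= 0.95 * cum[-1])
            assert rolloff == freqs[idx]


class TestSpectralVariation:
    def test_identical_frames(self):
        f = np.array([1.0, 2.0, 3.0])
        assert ta.spectral_variation(f, f) == pytest.approx(0.0)

    def test_scaled_frames(self):
        f = np.array([1.0, 2.0, 3.0])
        assert ta.spectral_variation(f, 5 * f) == pytest.approx(0.0)

    def test_disjoint_support(self):
        assert ta.spectral_variation(np.array([1.0, 0.0]),
                                     np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_silent_frame_rejected(self):
        with pytest.raises(DescriptorError):
            ta.spectral_variation(np.zeros(3), np.ones(3))


class TestSummarizeSeries:
    def test_constant_series(self):
        assert ta.summarize_series([4.2] * 7) == (4.2, 0.0)

    def test_median_of_five(self):
        med, _ = ta.summarize_series([1, 2, 3, 4, 5])
        assert med == 3.0

    def test_iqr_matches_sort_interpolation_oracle(self, rng):
        def interp_percentile(sorted_vals, q):
            # linear interpolation between order statistics
            pos = q / 100 * (len(sorted_vals) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            frac = pos - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        for n in (5, 8, 13):
            vals = rng.uniform(0, 10, n)
            _, iqr = ta.summarize_series(vals)
            s = np.sort(vals)
            expected = interp_percentile(s, 75) - interp_percentile(s, 25)
            assert iqr == pytest.approx(expected, rel=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(DescriptorError):
            ta.summarize_series([])


class TestExtractAll:
    def test_full_vector_schema(self, stimulus_set):
        clips, _ = stimulus_set
        vec = ta.extract_all(clips[0])
        assert list(vec) == desc.CANONICAL_DESCRIPTORS
        assert all(np.isfinite(v) for v in vec.values())

    def test_steady_tone_is_stationary_and_tonal(self):
        t = np.arange(22050) / SR
        x = 0.8 * np.sin(2 * np.pi * 500 * t)
        n_fade = round(0.05 * SR)
        x[-n_fade:] *= 0.5 * (1 + np.cos(np.pi * np.arange(n_fade) / (n_fade - 1)))
        vec = ta.extract_all(_clip(x))
        assert vec["spec_variation_med"] < 0.01
        # windowing leakage leaves a small floor; tonal flatness stays well
        # below the ~0.5+ of broadband noise
        assert vec["spec_flatness_med"] < 0.2

    def test_noise_flatter_than_tone(self, rng):
        t = np.arange(22050) / SR
        tone = ta.extract_all(_clip(0.8 * np.sin(2 * np.pi * 500 * t)))
        noise = ta.extract_all(_clip(0.8 * rng.standard_normal(22050)))
        assert noise["spec_flatness_med"] > tone["spec_flatness_med"]

    def test_silent_clip_rejected(self):
        with pytest.raises(DescriptorError):
            ta.extract_all(_clip(np.zeros(22050)))

    def test_gain_invariance_of_spectral_descriptors(self, stimulus_set):
        clips, _ = stimulus_set
        clip = clips[10]
        half = AudioClip(samples=0.5 * clip.samples, sample_rate=clip.sample_rate)
        a = ta.extract_all(clip)
        b = ta.extract_all(half)
        # slope scales with gain; attack slope halves; everything else on the
        # spectral side is gain-invariant, temporal centroid/attack unchanged
        gain_dependent = {"spec_slope_med", "spec_slope_iqr", "attack_slope"}
        for name in desc.CANONICAL_DESCRIPTORS:
            if name in gain_dependent:
                continue
            assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9), name
        assert b["attack_slope"] == pytest.approx(0.5 * a["attack_slope"], rel=1e-6)
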