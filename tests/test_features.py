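"""Acoustic feature operators against hand-computed and simulated oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocalence import features
from vocalence.features import (
    AverageSpectrum, FeatureConfig, IntensityContour, amplitude_features,
    average_spectrum, classify_call_type, duration, harmonicity,
    intensity_contour, spectral_features,
)
from vocalence.synth import CallRecording


def _call(wave, sr=44100):
    return CallRecording(call_id="t", waveform=np.asarray(wave, float), sample_rate=sr,
                         pig_id="p", team_id="t", age_days=10, age_class=1,
                         context="Isolation", valence="negative")


def _tone(freq, dur=0.5, sr=44100, amp=0.5):
    t = np.arange(int(dur * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


class TestDuration:
    def test_samples_over_rate(self):
        assert duration(_call(np.ones(22050))) == 0.5
        assert duration(_call(np.ones(1))) == 1 / 44100

    def test_empty_errors(self):
        call = _call([1.0])
        call.waveform = np.array([])
        with pytest.raises(ValueError):
            duration(call)


class TestIntensityContour:
    def test_flat_for_constant_sine(self):
        c = intensity_contour(_call(_tone(1000, dur=0.3)))
        inner = c.levels[20:-20]
        assert inner.max() - inner.min() < 0.5

    def test_silence_floored(self):
        c = intensity_contour(_call(np.zeros(4410)))
        assert np.all(c.levels == -70.0)
        assert np.all(np.isfinite(c.levels))

    def test_am_oscillation_at_10hz(self):
        sr = 44100
        t = np.arange(sr) / sr
        wave = (1 + 0.5 * np.sin(2 * np.pi * 10 * t)) * _tone(1000, dur=1.0)
        c = intensity_contour(_call(wave))
        d = c.levels - c.levels.mean()
        freqs = np.fft.rfftfreq(d.size, c.frame_step)
        spec = np.abs(np.fft.rfft(d * np.hanning(d.size)))
        assert abs(freqs[np.argmax(spec)] - 10.0) < 1.5

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            intensity_contour(_call(np.ones(100)))


class TestAmplitudeFeatures:
    def test_flat_contour_no_cycles(self):
        c = IntensityContour(times=np.linspace(0, 1, 11),
                             levels=np.full(11, -20.0), frame_step=0.1)
        amp_var, rate, extent = amplitude_features(c, 1.0)
        assert amp_var == pytest.approx(0.0)
        assert np.isnan(rate) and np.isnan(extent)

    def test_hand_contour_oracle(self):
        # cumulative variation 24 dB over 1 s; two 6 dB cycles
        c = IntensityContour(times=np.linspace(0, 1, 5),
                             levels=np.array([0.0, 6.0, 0.0, 6.0, 0.0]),
                             frame_step=0.25)
        amp_var, rate, extent = amplitude_features(c, 1.0)
        assert amp_var == pytest.approx(24.0)
        assert rate == pytest.approx(2.0)
        assert extent == pytest.approx(6.0)

    def test_fewer_than_two_frames_errors(self):
        c = IntensityContour(times=np.array([0.0]), levels=np.array([-10.0]),
                             frame_step=0.01)
        with pytest.raises(ValueError):
            amplitude_features(c, 1.0)


class TestAverageSpectrum:
    def test_tone_concentrates_at_bin(self):
        s = average_spectrum(_call(_tone(1000, dur=1.0)))
        assert abs(s.freqs[np.argmax(s.power)] - 1000) < 30

    def test_two_tones_two_dominant_bins(self):
        s = average_spectrum(_call(_tone(500, 1.0) + _tone(3000, 1.0)))
        order = np.argsort(s.power)[::-1]
        top = sorted(s.freqs[order[:6]])
        assert any(abs(f - 500) < 50 for f in top)
        assert any(abs(f - 3000) < 50 for f in top)

    def test_white_noise_no_dominant_bin(self):
        rng = np.random.default_rng(0)
        s = average_spectrum(_call(rng.standard_normal(2 * 44100)))
        assert s.power.max() < 5 * np.median(s.power)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            average_spectrum(_call(np.zeros(1000)))


class TestSpectralFeatures:
    def test_flat_spectrum(self):
        spec = AverageSpectrum(freqs=np.arange(1.0, 1001.0), power=np.ones(1000))
        q25, q50, q75, fpeak, ent = spectral_features(spec)
        assert (q25, q50, q75) == (250.0, 500.0, 750.0)
        assert ent == 0.0

    def test_two_equal_bins_q50_at_first(self):
        spec = AverageSpectrum(freqs=np.array([100.0, 900.0]), power=np.array([1.0, 1.0]))
        _, q50, _, _, _ = spectral_features(spec)
        assert q50 == 100.0

    def test_two_bin_entropy_hand_value(self):
        spec = AverageSpectrum(freqs=np.array([100.0, 200.0]), power=np.array([1.0, 4.0]))
        *_, ent = spectral_features(spec)
        assert ent == pytest.approx(np.log(0.8), abs=1e-12)

    def test_zero_power_errors(self):
        with pytest.raises(ValueError):
            spectral_features(AverageSpectrum(freqs=np.array([1.0]), power=np.array([0.0])))

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=8)
           .filter(lambda p: sum(p) > 0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_small_spectra_match_brute_force(self, power):
        power = np.asarray(power)
        freqs = np.arange(1.0, power.size + 1)
        q25, q50, q75, fpeak, ent = spectral_features(
            AverageSpectrum(freqs=freqs, power=power))
        # brute-force cumulative scan
        cum = 0.0
        total = power.sum()
        expected = {}
        for frac, name in [(0.25, "q25"), (0.5, "q50"), (0.75, "q75")]:
            cum = 0.0
            for f, p in zip(freqs, power):
                cum += p
                if cum >= frac * total - 1e-9 * total:
                    expected[name] = f
                    break
        assert (q25, q50, q75) == (expected["q25"], expected["q50"], expected["q75"])
        assert q25 <= q50 <= q75
        assert ent <= 0.0
        pf = np.maximum(power, 1e-12 * power.max())
        assert ent == pytest.approx(min(0.0, np.mean(np.log(pf)) - np.log(np.mean(pf))), abs=1e-9)


class TestHarmonicity:
    def test_pure_sine_near_ceiling(self):
        assert harmonicity(_call(_tone(200, dur=0.5))) >= 30.0

    def test_white_noise_low(self):
        rng = np.random.default_rng(1)
        assert harmonicity(_call(rng.standard_normal(22050))) <= 5.0

    def test_mix_between(self):
        rng = np.random.default_rng(2)
        tone = _tone(200, dur=0.5)
        noise = rng.standard_normal(tone.size) * np.sqrt(np.mean(tone**2))
        hnr_mix = harmonicity(_call(tone + noise))
        assert harmonicity(_call(noise)) < hnr_mix < harmonicity(_call(tone))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            harmonicity(_call(np.ones(100)))


class TestCallTyping:
    @pytest.mark.parametrize("q50,age,expected", [
        (3000.0, 1, "HF"),   # above the 2414 Hz youngest-class cutoff
        (896.0, 3, "LF"),    # exactly at the oldest-class cutoff -> LF
        (2200.0, 2, "HF"),   # above the 2153 Hz cutoff
        (2414.0, 1, "LF"),   # boundary assigned to LF
        (100.0, 3, "LF"),
    ])
    def test_cutoffs(self, q50, age, expected):
        assert classify_call_type(q50, age) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_call_type(-5.0, 1)
        with pytest.raises(ValueError, match="age_class"):
            classify_call_type(1000.0, 7)


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.25, 4.0])
    def test_ratio_features_unchanged_under_gain(self, scale):
        rng = np.random.default_rng(3)
        t = np.arange(22050) / 44100
        wave = (1 + 0.4 * np.sin(2 * np.pi * 8 * t)) * (
            np.sin(2 * np.pi * 300 * t) + 0.2 * rng.standard_normal(t.size))
        a = features.extract_features(_call(wave))
        b = features.extract_features(_call(scale * wave))
        for name in ("Q25", "Q50", "Q75", "FPeak", "WienEntropy",
                     "AmpModRate", "AmpModExtent", "AmpVar"):
            assert a[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name


def test_extract_table_columns_and_rows(mixed_dataset):
    _, _, table = mixed_dataset
    assert list(table.columns) == features.FEATURE_COLUMNS
    assert table["Q25"].le(table["Q50"]).all() and table["Q50"].le(table["Q75"]).all()
    assert (table["WienEntropy"] <= 0).all()
    assert (table["Dur"] > 0).all()
    assert set(table["call_type"]) <= {"LF", "HF"}
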