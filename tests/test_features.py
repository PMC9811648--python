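import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from vocaldistress.audio_io import AudioRecording, SegmentAnnotation, frame_signal
from vocaldistress.features import (
    FEATURE_NAMES,
    FrameSpectrum,
    amplitude_rms_db,
    extract_feature_table,
    formants_lpc,
    frame_spectrum,
    harmonicity,
    loudness_sone,
    sequence_features,
    spectral_shape,
)

RATE = 8000


def tone(freq, n=320, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / RATE)


class TestFrameSpectrum:
    def test_zero_frame_all_zero_power(self):
        assert np.all(frame_spectrum(np.zeros(320), RATE).power == 0.0)

    def test_parseval(self, rng):
        fr = rng.normal(size=320) * np.blackman(320)
        spec = frame_spectrum(fr, RATE)
        assert spec.power.sum() == pytest.approx(np.sum(fr**2), rel=1e-6)

    def test_sine_dominant_lobe(self):
        spec = frame_spectrum(tone(1000) * np.blackman(320), RATE)
        assert abs(spec.freqs[np.argmax(spec.power)] - 1000) <= spec.freqs[1]

    def test_nfft_too_small(self):
        with pytest.raises(ValueError):
            frame_spectrum(np.ones(320), RATE, nfft=256)

    def test_white_noise_flat_on_average(self, rng):
        acc = np.zeros(257)
        for _ in range(300):
            acc += frame_spectrum(rng.normal(size=320), RATE).power
        acc /= acc.mean()
        assert np.all(np.abs(acc[1:-1] - 1.0) < 0.35)


class TestAmplitudeRms:
    def test_full_scale_square_wave(self):
        sq = np.sign(tone(250, 640))
        assert amplitude_rms_db(sq) == pytest.approx(0.0, abs=0.05)

    def test_sine_minus_3db(self):
        assert amplitude_rms_db(tone(500, 8000)) == pytest.approx(-3.0103, abs=0.01)

    def test_halving_is_6db(self, rng):
        x = rng.normal(size=320)
        assert amplitude_rms_db(x) - amplitude_rms_db(0.5 * x) == pytest.approx(
            20 * np.log10(2), abs=1e-9
        )

    def test_zero_frame_sentinel(self):
        assert amplitude_rms_db(np.zeros(10)) == -np.inf


class TestSpectralShape:
    def test_pure_tone_identities(self):
        spec = frame_spectrum(tone(1000) * np.blackman(320), RATE, nfft=512)
        ss = spectral_shape(spec)
        binw = spec.freqs[1]
        for key in ("spectral_centroid", "peak_freq", "dominant_freq", "q50_freq"):
            assert abs(ss[key] - 1000) <= binw + 1e-9, key
        assert ss["entropy"] < 1e-3

    def test_flat_spectrum_identities(self):
        freqs = np.linspace(0, RATE / 2, 257)
        ss = spectral_shape(FrameSpectrum(freqs=freqs, power=np.ones(257), rate=RATE))
        assert ss["entropy"] == pytest.approx(1.0)
        assert ss["spectral_centroid"] == pytest.approx(RATE / 4, rel=1e-6)
        for q, frac in (("q25_freq", 0.25), ("q50_freq", 0.5), ("q75_freq", 0.75)):
            assert ss[q] == pytest.approx(frac * RATE / 2, abs=freqs[1] + 1e-9)

    def test_two_equal_tones_centroid(self):
        fr = (tone(500) + tone(1500)) * np.blackman(320)
        ss = spectral_shape(frame_spectrum(fr, RATE))
        assert abs(ss["spectral_centroid"] - 1000) <= RATE / 512 + 1

    def test_zero_spectrum_rejected(self):
        spec = FrameSpectrum(freqs=np.linspace(0, 4000, 10), power=np.zeros(10), rate=RATE)
        with pytest.raises(ValueError):
            spectral_shape(spec)

    def test_quantile_ordering_and_entropy_range(self, rng):
        for _ in range(50):
            ss = spectral_shape(frame_spectrum(rng.normal(size=320), RATE))
            assert ss["q25_freq"] <= ss["q50_freq"] <= ss["q75_freq"]
            assert 0.0 <= ss["entropy"] <= 1.0


def synth_resonated_noise(rng, formants_bws, n=16000, preemph=True):
    x = rng.standard_normal(n)
    for fc, bw in formants_bws:
        r = np.exp(-np.pi * bw / RATE)
        th = 2 * np.pi * fc / RATE
        x = sps.lfilter([1 - r], [1, -2 * r * np.cos(th), r**2], x)
    if preemph:
        x = np.append(x[0], x[1:] - 0.97 * x[:-1])
    return x


class TestFormants:
    def test_single_resonator_recovery(self, rng):
        x = synth_resonated_noise(rng, [(500, 80)])
        fs = frame_signal(AudioRecording(samples=x / np.abs(x).max(), rate=RATE))
        f1 = [
            formants_lpc(fs.frames[i], RATE)["f1_freq"]
            for i in range(fs.n_frames)
        ]
        f1 = [v for v in f1 if np.isfinite(v)]
        assert abs(np.mean(f1) - 500) < 25

    def test_three_resonator_vowel_recovery(self, rng):
        x = synth_resonated_noise(rng, [(500, 80), (1500, 110), (2500, 150)])
        fs = frame_signal(AudioRecording(samples=x / np.abs(x).max(), rate=RATE))
        got = {"f1_freq": [], "f2_freq": [], "f3_freq": []}
        for i in range(fs.n_frames):
            d = formants_lpc(fs.frames[i], RATE)
            for k in got:
                if np.isfinite(d[k]):
                    got[k].append(d[k])
        for k, target in (("f1_freq", 500), ("f2_freq", 1500), ("f3_freq", 2500)):
            assert abs(np.mean(got[k]) - target) < 50, k

    def test_pure_sine_missing_upper_formants(self):
        d = formants_lpc(tone(800) * np.blackman(320), RATE)
        assert abs(d["f1_freq"] - 800) < 40
        assert np.isnan(d["f3_freq"])

    def test_order_precondition(self):
        with pytest.raises(ValueError):
            formants_lpc(tone(500), RATE, order=6)


class TestHarmonicity:
    def test_noiseless_pulse_train_low_nhr(self):
        pulse = np.zeros(320)
        pulse[::64] = 1.0  # f0 = 125 Hz, inside the 75-300 band
        assert harmonicity(pulse, RATE)["noise_to_harmonics"] < 0.05

    def test_white_noise_high_nhr(self, rng):
        vals = [
            harmonicity(rng.standard_normal(320), RATE)["noise_to_harmonics"]
            for _ in range(20)
        ]
        assert np.mean(vals) > 2.0

    def test_subharmonic_depth_increases_with_period_doubling(self):
        depths = []
        for alt in (0.0, 0.2, 0.4, 0.6):
            x = np.zeros(320)
            for k, i in enumerate(range(0, 320, 64)):
                x[i] = 1.0 - alt * (k % 2)
            depths.append(harmonicity(x, RATE)["subharmonic_depth"])
        assert depths[0] == 0.0
        assert all(b > a for a, b in zip(depths, depths[1:]))

    def test_silent_frame_flagged(self):
        out = harmonicity(np.zeros(320), RATE)
        assert np.isnan(out["noise_to_harmonics"])


class TestLoudness:
    def test_zero_spectrum(self):
        assert loudness_sone(frame_spectrum(np.zeros(320), RATE)) == 0.0

    def test_stevens_homogeneity(self):
        spec = frame_spectrum(tone(700) * np.blackman(320), RATE)
        double = FrameSpectrum(freqs=spec.freqs, power=2 * spec.power, rate=RATE)
        assert loudness_sone(double) / loudness_sone(spec) == pytest.approx(2**0.3)

    def test_band_weighting_bounded(self):
        lo = loudness_sone(frame_spectrum(tone(1000) * np.blackman(320), RATE))
        hi = loudness_sone(frame_spectrum(tone(3000) * np.blackman(320), RATE))
        assert lo > 0 and hi > 0
        assert 0.5 < lo / hi < 2.0


class TestSequenceFeatures:
    def make_spectra(self, frames):
        return np.stack([frame_spectrum(f, RATE).power for f in frames])

    def test_identical_frames_no_change(self):
        fr = np.tile(tone(500), (8, 1))
        out = sequence_features(self.make_spectra(fr), fr, RATE)
        assert np.allclose(out["spectral_flux"], 0.0)
        assert np.all(out["spectral_novelty"] < 1e-9)

    def test_novelty_peaks_at_tone_switch(self):
        fr = np.concatenate([np.tile(tone(500), (6, 1)), np.tile(tone(2000), (6, 1))])
        out = sequence_features(self.make_spectra(fr), fr, RATE)
        peak = out["spectral_novelty"].to_numpy().argmax()
        assert peak in (5, 6)

    def test_am_tone_rougher_than_pure(self):
        n = 320 * 4
        t = np.arange(n) / RATE
        carrier = np.sin(2 * np.pi * 1000 * t)
        am = (1 + 0.9 * np.sin(2 * np.pi * 100 * t)) * carrier
        def rough(sig):
            fr = sig.reshape(-1, 320)
            return sequence_features(self.make_spectra(fr), fr, RATE)["roughness"].mean()
        assert rough(am) > rough(carrier) + 0.05

    def test_single_frame_zeros(self):
        fr = tone(500)[None, :]
        out = sequence_features(self.make_spectra(fr), fr, RATE)
        assert out.iloc[0].tolist() == [0.0, 0.0, 0.0]


class TestInvariances:
    def test_polarity_invariance(self, rng):
        fr = rng.normal(size=320)
        a = spectral_shape(frame_spectrum(fr, RATE))
        b = spectral_shape(frame_spectrum(-fr, RATE))
        for k in a:
            assert a[k] == pytest.approx(b[k])
        assert amplitude_rms_db(fr) == amplitude_rms_db(-fr)

    def test_gain_invariance_split(self, rng):
        fr = rng.normal(size=320)
        for g in (0.1, 3.0):
            a = spectral_shape(frame_spectrum(fr, RATE))
            b = spectral_shape(frame_spectrum(g * fr, RATE))
            for k in a:  # spectral shape ignores gain
                assert a[k] == pytest.approx(b[k], rel=1e-9), k
            # rms and loudness follow gain
            assert amplitude_rms_db(g * fr) != pytest.approx(amplitude_rms_db(fr))
            assert loudness_sone(frame_spectrum(g * fr, RATE)) != pytest.approx(
                loudness_sone(frame_spectrum(fr, RATE))
            )


class TestExtractFeatureTable:
    def make_call(self, dur_s=1.0, silent=False):
        n = int(dur_s * RATE)
        x = np.zeros(n) if silent else 0.3 * np.sin(2 * np.pi * 220 * np.arange(n) / RATE)
        rec = AudioRecording(samples=x, rate=RATE, call_id="c1", caller_id="p1", sex="female")
        ann = SegmentAnnotation(
            segment_id="s1", call_id="c1", start_s=0.0, end_s=dur_s,
            distress_rating=7, distress_label="high",
        )
        return rec, ann

    def test_framing_arithmetic_and_label_broadcast(self):
        rec, ann = self.make_call()
        tab = extract_feature_table([rec], [ann])
        assert len(tab) == 49
        assert (tab["label"] == 1).all()
        assert (tab["caller_id"] == "p1").all() and (tab["sex"] == "female").all()
        assert set(FEATURE_NAMES) <= set(tab.columns)

    def test_fully_silent_segment_yields_no_rows(self):
        rec, ann = self.make_call(silent=True)
        with pytest.warns(UserWarning, match="silent"):
            tab = extract_feature_table([rec], [ann])
        assert len(tab) == 0

    def test_out_of_bounds_annotation_rejected(self):
        rec, ann = self.make_call()
        bad = SegmentAnnotation(
            segment_id="s9", call_id="c1", start_s=0.5, end_s=5.0,
            distress_rating=2, distress_label="low",
        )
        with pytest.raises(ValueError, match="s9"):
            extract_feature_table([rec], [ann, bad])
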