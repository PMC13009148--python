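"""Harmonization contracts: channel selection, anti-aliased resampling,
band-pass response, average reference, segmentation arithmetic, artifact
handling and normalization."""

import numpy as np
import pytest

from eegmark.channels import CANONICAL_CHANNELS
from eegmark.preprocess import (NormStats, PreprocessConfig, SegmentSet,
                                average_reference, bandpass_filter,
                                correct_eye_artifacts, count_eye_events,
                                normalize_amplitude, preprocess_subject,
                                reject_bad_segments, resample_to_target,
                                segment, select_common_channels)
from eegmark.synthetic import EffectSpec, SiteProfile, SubjectRecord, generate_subject

CFG = PreprocessConfig()


def make_record(signal, fs=250.0, channels=CANONICAL_CHANNELS, group="HC",
                responder="NA"):
    return SubjectRecord("s0", "site", group, responder, 8,
                         np.asarray(signal, float), fs, tuple(channels))


def sinusoid_record(freq, fs, duration=20.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return make_record(np.tile(sig, (10, 1)), fs=fs)


def amplitude_at(x, fs, freq):
    """Oracle: amplitude of one frequency via the Fourier coefficient."""
    t = np.arange(len(x)) / fs
    return 2 * abs(np.mean(x * np.exp(-2j * np.pi * freq * t)))


class TestChannelSelection:
    def test_superset_reduced_and_reordered(self):
        extra = ["Fp1", "Fp2", "Fz", "Cz", "Pz", "T3", "T4"]
        names = list(CANONICAL_CHANNELS[::-1]) + extra  # scrambled order
        sig = np.arange(len(names))[:, None] * np.ones((1, 500))
        rec = make_record(sig, channels=names)
        out = select_common_channels(rec)
        assert out.channel_names == CANONICAL_CHANNELS
        # rows follow the canonical order, not the input order
        for i, c in enumerate(CANONICAL_CHANNELS):
            assert out.signal[i, 0] == names.index(c)

    def test_identity_on_canonical_input(self):
        rec = make_record(np.random.default_rng(0).normal(size=(10, 500)))
        out = select_common_channels(rec)
        assert np.array_equal(out.signal, rec.signal)

    def test_missing_channel_named_in_error(self):
        names = [c for c in CANONICAL_CHANNELS if c != "P3"] + ["Cz"]
        rec = make_record(np.zeros((10, 100)), channels=names)
        with pytest.raises(ValueError, match="P3"):
            select_common_channels(rec)

    def test_vendor_labels_accepted(self):
        names = [f"EEG {c}-REF" for c in CANONICAL_CHANNELS]
        rec = make_record(np.zeros((10, 500)), channels=names)
        assert select_common_channels(rec).channel_names == CANONICAL_CHANNELS


class TestResampling:
    def test_sample_count_1000hz(self):
        rec = make_record(np.zeros((10, 75000)), fs=1000.0)
        out = resample_to_target(rec, CFG)
        assert out.sampling_rate == 250.0
        assert out.signal.shape[1] == 18750

    def test_passband_tone_survives_512hz(self):
        """10 Hz sinusoid at 512 Hz keeps its amplitude within 1%."""
        rec = sinusoid_record(10.0, 512.0)
        out = resample_to_target(rec, CFG)
        amp = amplitude_at(out.signal[0], 250.0, 10.0)
        assert abs(amp - 1.0) < 0.01

    def test_aliasing_band_attenuated(self):
        """A 120 Hz tone (above the new Nyquist) drops by >= 20 dB."""
        rec = sinusoid_record(120.0, 1000.0)
        out = resample_to_target(rec, CFG)
        residual = np.sqrt(2) * out.signal[0].std()
        assert residual < 10 ** (-20 / 20)

    def test_upsampling_rejected(self):
        rec = make_record(np.zeros((10, 1000)), fs=200.0)
        with pytest.raises(ValueError):
            resample_to_target(rec, CFG)


class TestBandpass:
    def test_dc_removed(self):
        rec = make_record(np.full((10, 5000), 50.0))
        out = bandpass_filter(rec, CFG)
        assert np.abs(out.signal.mean()) < 50.0 * 1e-3

    @pytest.mark.parametrize("freq,min_db,max_db", [
        (10.0, -1.0, 1.0),       # passband: < 1 dB loss
        (60.0, -np.inf, -20.0),  # stopband: >= 20 dB attenuation
    ])
    def test_filter_response(self, freq, min_db, max_db):
        rec = sinusoid_record(freq, 250.0, duration=40.0)
        out = bandpass_filter(rec, CFG)
        amp = amplitude_at(out.signal[0][2000:-2000], 250.0, freq)
        db = 20 * np.log10(max(amp, 1e-12))
        assert min_db <= db <= max_db


class TestAverageReference:
    def test_channel_mean_zeroed(self):
        rng = np.random.default_rng(1)
        rec = make_record(rng.normal(scale=30.0, size=(10, 1000)))
        out = average_reference(rec)
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-9 * 30.0

    def test_idempotent(self):
        rec = make_record(np.random.default_rng(2).normal(size=(10, 500)))
        once = average_reference(rec)
        twice = average_reference(once)
        assert np.allclose(once.signal, twice.signal)

    def test_single_active_channel_closed_form(self):
        sig = np.zeros((10, 100))
        sig[3] = 10.0
        out = average_reference(make_record(sig))
        assert np.allclose(out.signal[3], 9.0)
        assert np.allclose(out.signal[0], -1.0)

    def test_commutes_with_bandpass(self):
        """Both operations are linear, so their order cannot matter."""
        rec = make_record(
            np.random.default_rng(3).normal(scale=20.0, size=(10, 5000)))
        a = average_reference(bandpass_filter(rec, CFG))
        b = bandpass_filter(average_reference(rec), CFG)
        scale = np.abs(a.signal).max()
        assert np.abs(a.signal - b.signal).max() < 1e-6 * scale


class TestSegmentation:
    @pytest.mark.parametrize("duration,expected", [
        (906.0, 453), (900.0, 450), (72.0, 36), (3.9, 1),
    ])
    def test_segment_counts(self, duration, expected):
        rec = make_record(np.zeros((10, int(duration * 250))))
        assert len(segment(rec, CFG)) == expected

    def test_too_short_warns_and_returns_empty(self):
        rec = make_record(np.zeros((10, 400)))
        with pytest.warns(UserWarning):
            assert len(segment(rec, CFG)) == 0

    def test_segments_tile_the_recording(self):
        sig = np.arange(10)[:, None] + np.arange(1500)[None, :] * 1.0
        segs = segment(make_record(sig), CFG)
        assert segs.data.shape == (3, 10, 500)
        assert np.array_equal(segs.data[1, 0], sig[0, 500:1000])


class TestEyeArtifacts:
    @staticmethod
    def blinky_record(n_blinks=12, duration=60.0, background=0.0, seed=0):
        """Noise-free record with evenly spaced slow biphasic ocular pulses
        (320 ms, energy below the 5 Hz surrogate low-pass)."""
        eff = EffectSpec(blink_rate=0.0, emg_burst_rate=0.0,
                         background_rms=background, alpha_amp=0.0)
        site = SiteProfile("b", 250.0, duration, 1, 0, 0.5, 8)
        rec = generate_subject(site, eff, "HC", "NA", seed=seed)
        from eegmark.synthetic import _BLINK_WEIGHTS
        w = np.array([_BLINK_WEIGHTS[c] for c in rec.channel_names])[:, None]
        n = rec.signal.shape[1]
        sig = rec.signal.copy()
        m = 100  # 400 ms at 250 Hz, monophasic lid-closure deflection
        tpl = np.hanning(m)
        for k in range(n_blinks):
            start = int((k + 0.5) * n / n_blinks)
            stop = min(start + m, n)
            sig[:, start:stop] += 80.0 * w * tpl[: stop - start]
        return make_record(sig)

    def test_blink_amplitude_reduced(self):
        rec = self.blinky_record()
        out = correct_eye_artifacts(rec)
        f7 = list(rec.channel_names).index("F7")
        assert np.abs(out.signal[f7]).max() < 0.1 * np.abs(rec.signal[f7]).max()

    def test_blink_free_record_almost_unchanged(self):
        """Regression on a near-orthogonal EOG (independent noise) is a no-op."""
        eff = EffectSpec(blink_rate=0.0, emg_burst_rate=0.0)
        site = SiteProfile("c", 250.0, 60.0, 1, 0, 0.5, 8)
        rec = generate_subject(site, eff, "HC", "NA", seed=4)
        eog = np.random.default_rng(9).normal(
            scale=50.0, size=rec.signal.shape[1])
        out = correct_eye_artifacts(rec, eog=eog)
        rel = np.linalg.norm(out.signal - rec.signal) / np.linalg.norm(rec.signal)
        assert rel < 0.05

    def test_flat_record_noop_with_warning(self):
        rec = make_record(np.zeros((10, 1000)))
        with pytest.warns(UserWarning):
            out = correct_eye_artifacts(rec)
        assert np.array_equal(out.signal, rec.signal)

    def test_event_counter_recovers_planted_rate(self):
        rec = self.blinky_record(n_blinks=12, duration=60.0)
        report = count_eye_events(rec)
        assert report.events_per_minute == pytest.approx(12, abs=2)

    def test_event_counter_linearity(self):
        r1 = count_eye_events(self.blinky_record(n_blinks=10)).events_per_minute
        r2 = count_eye_events(self.blinky_record(n_blinks=20)).events_per_minute
        assert r2 == pytest.approx(2 * r1, rel=0.2)

    def test_blink_free_record_zero_events(self):
        sig = np.tile(np.sin(2 * np.pi * 1.0 *
                             np.arange(15000) / 250.0), (10, 1))
        rec = make_record(sig)  # identical channels: flat surrogate
        assert count_eye_events(rec).events_per_minute == 0.0


class TestRejection:
    @staticmethod
    def seg_set(n=10, spike_in=(1, 4, 7)):
        rng = np.random.default_rng(0)
        data = rng.normal(scale=20.0, size=(n, 10, 500)).clip(-99, 99)
        for i in spike_in:
            data[i, 2, 100] = 150.0
        return SegmentSet(data, np.array([f"s{i % 2}" for i in range(n)],
                                         dtype=object))

    def test_exactly_spiked_segments_removed(self):
        segs = self.seg_set()
        kept = reject_bad_segments(segs, CFG)
        assert len(kept) == 7

    def test_within_threshold_kept(self):
        data = np.full((3, 10, 500), 99.0)
        segs = SegmentSet(data, np.array(["a", "a", "a"], dtype=object))
        assert len(reject_bad_segments(segs, CFG)) == 3

    def test_subject_losing_all_segments_warns(self):
        data = np.zeros((2, 10, 500))
        data[0, 0, 0] = 200.0
        segs = SegmentSet(data, np.array(["gone", "stays"], dtype=object))
        with pytest.warns(UserWarning, match="gone"):
            kept = reject_bad_segments(segs, CFG)
        assert list(kept.subject_ids) == ["stays"]


class TestNormalization:
    def test_training_role_standardizes(self):
        rng = np.random.default_rng(5)
        segs = SegmentSet(rng.normal(3.0, 7.0, size=(20, 10, 500)),
                          np.array(["a"] * 20, dtype=object))
        out, stats = normalize_amplitude(segs)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1.0) < 1e-6

    def test_test_role_uses_training_stats(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 10, 500))
        train = SegmentSet(data, np.array(["a"] * 10, dtype=object))
        _, stats = normalize_amplitude(train)
        shifted = SegmentSet(data + 5.0, np.array(["b"] * 10, dtype=object))
        out, _ = normalize_amplitude(shifted, stats)
        assert out.data.mean() == pytest.approx(5.0 / stats.std, rel=1e-6)

    def test_zero_variance_rejected(self):
        segs = SegmentSet(np.ones((2, 10, 500)),
                          np.array(["a", "a"], dtype=object))
        with pytest.raises(ValueError):
            normalize_amplitude(segs)

    def test_degenerate_stats_rejected(self):
        with pytest.raises(ValueError):
            NormStats(0.0, 0.0)


class TestFullPipeline:
    def test_segment_count_conservation(self):
        """Sum of per-subject counts equals sum of floor(duration/2)."""
        site = SiteProfile("p", 512.0, 21.0, 2, 2, 0.5, 8)
        from eegmark.synthetic import generate_cohort
        cohort = generate_cohort([site], EffectSpec(), seed=1)
        total = sum(len(preprocess_subject(r)) for r in cohort)
        assert total == sum(int(r.duration // 2) for r in cohort)

    def test_pipeline_deterministic(self):
        site = SiteProfile("p", 512.0, 11.0, 1, 0, 0.5, 8)
        rec = generate_subject(site, EffectSpec(), "HC", "NA", seed=2)
        a = preprocess_subject(rec)
        b = preprocess_subject(rec)
        assert np.array_equal(a.data, b.data)
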