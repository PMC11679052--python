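import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegauth import (Recording, average_reference, bandpass_filter,
                     reject_artifacts_ica, segment)

FS = 256.0


def _sine_recording(freq, n=2048, n_ch=2):
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (n_ch, 1)), FS, [f"c{i}" for i in range(n_ch)], 1, 1)


def _dft_peak_amplitude(x):
    """Oracle: amplitude of the dominant sinusoid via Hann-windowed DFT peak."""
    w = np.hanning(x.size)
    return np.abs(np.fft.rfft(x * w)).max() / (w.sum() / 2)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rec = _sine_recording(10.0)
        out = bandpass_filter(rec).data[0]
        central = slice(512, 1536)
        a_out = _dft_peak_amplitude(out[central])
        a_in = _dft_peak_amplitude(rec.data[0][central])
        assert abs(a_out / a_in - 1) < 0.05

    def test_stopband_attenuated(self):
        rec = _sine_recording(60.0)
        out = bandpass_filter(rec).data[0]
        central = slice(512, 1536)
        rms_out = np.sqrt(np.mean(out[central] ** 2))
        rms_in = np.sqrt(np.mean(rec.data[0][central] ** 2))
        assert rms_out <= 0.1 * rms_in

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((2, 1024)), FS, ["a", "b"], 1, 1)
        np.testing.assert_allclose(bandpass_filter(rec).data, 0.0, atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, 1.0, 130.0)


class TestAverageReference:
    def test_antisymmetric_pair_unchanged(self):
        t = np.arange(512) / FS
        a = np.sin(2 * np.pi * 7 * t)
        rec = Recording(np.vstack([a, -a]), FS, ["a", "b"], 1, 1)
        np.testing.assert_allclose(average_reference(rec).data, rec.data,
                                   atol=1e-12)

    def test_common_offset_removed(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 256))
        rec = Recording(base, FS, list("abcd"), 1, 1)
        shifted = Recording(base + 3.7, FS, list("abcd"), 1, 1)
        np.testing.assert_allclose(average_reference(shifted).data,
                                   average_reference(rec).data, atol=1e-12)

    def test_per_sample_channel_mean_vanishes(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.standard_normal((8, 1000)), FS,
                        [f"c{i}" for i in range(8)], 1, 1)
        out = average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_single_channel_rejected(self):
        rec = Recording(np.zeros((1, 256)), FS, ["a"], 1, 1)
        with pytest.raises(ValueError, match="single channel"):
            average_reference(rec)

    def test_commutes_with_bandpass(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.standard_normal((4, 2048)), FS, list("abcd"), 1, 1)
        out = average_reference(bandpass_filter(rec))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        out2 = bandpass_filter(average_reference(rec))
        assert np.abs(out2.data.mean(axis=0)).max() < 1e-9


class TestIca:
    def _band_noise_recording(self, seed=0, n=8192):
        rng = np.random.default_rng(seed)
        mixing = rng.standard_normal((8, 8))
        sources = rng.standard_normal((8, n))
        return Recording(mixing @ sources, FS, [f"c{i}" for i in range(8)], 1, 1)

    def test_clean_recording_roundtrips(self):
        rec = self._band_noise_recording()
        out, rejected = reject_artifacts_ica(rec, n_components=6)
        assert rejected == []
        rel = np.sqrt(np.mean((out.data - rec.data) ** 2) / np.mean(rec.data ** 2))
        assert rel < 1e-6

    def test_spike_component_rejected_and_attenuated(self):
        rec = self._band_noise_recording(seed=3)
        data = rec.data.copy()
        spikes = np.zeros(data.shape[1])
        spikes[::500] = 60.0  # sparse, huge-kurtosis spike train
        data[2] += spikes
        noisy = rec.copy_with(data)
        out, rejected = reject_artifacts_ica(noisy, n_components=6)
        assert len(rejected) >= 1
        before = np.abs(noisy.data[2, ::500]).max()
        after = np.abs(out.data[2, ::500]).max()
        assert after <= 0.5 * before

    def test_too_many_components_rejected(self):
        rec = self._band_noise_recording()
        with pytest.raises(ValueError, match="n_components"):
            reject_artifacts_ica(rec, n_components=9)


class TestSegment:
    def _rec(self, s, user=1, run=1):
        return Recording(np.zeros((2, s)), FS, ["a", "b"], user, run)

    @pytest.mark.parametrize("s,window,stride,expected", [
        (1280, 512, 256, 4),
        (512, 512, 256, 1),
        (2048, 512, 512, 4),
        (2047, 512, 512, 3),
    ])
    def test_segment_count_examples(self, s, window, stride, expected):
        out = segment([self._rec(s)], window=window, stride=stride)
        assert out.n_segments == expected
        starts = out.origin_starts.tolist()
        assert starts == [k * stride for k in range(expected)]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(s=st.integers(64, 3000), window=st.integers(16, 512),
           data=st.data())
    def test_count_formula_matches_enumeration(self, s, window, data):
        stride = data.draw(st.integers(1, window))
        if s < window:
            with pytest.warns(UserWarning):
                with pytest.raises(ValueError):
                    segment([self._rec(s)], window=window, stride=stride)
            return
        out = segment([self._rec(s)], window=window, stride=stride)
        brute = sum(1 for start in range(0, s, stride) if start + window <= s)
        assert out.n_segments == (s - window) // stride + 1 == brute

    def test_no_window_crosses_run_boundary_and_labels_consistent(self):
        recs = [self._rec(1280, user=1, run=1), self._rec(800, user=2, run=1)]
        out = segment(recs, window=512, stride=256)
        # per-recording counts: 4 and 2; every window inside its run
        assert out.labels.tolist() == [1, 1, 1, 1, 2, 2]
        for start in out.origin_starts[out.origin_user_ids == 2]:
            assert start + 512 <= 800

    def test_short_recording_skipped_with_warning(self):
        recs = [self._rec(1280), self._rec(100, user=2)]
        with pytest.warns(UserWarning, match="skipped"):
            out = segment(recs)
        assert set(out.labels.tolist()) == {1}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no recordings"):
            segment([])
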