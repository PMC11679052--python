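"""Recording cleanup and segmentation.

The standard chain is: zero-phase FIR band-pass (1-50 Hz), common-average
re-reference, optional automated ICA artifact rejection, then overlapped
windowing into fixed-length segments (512 samples with 50% overlap at
256 Hz, i.e. 2 s windows stepped by 1 s). Windows never cross a run
boundary; trailing samples shorter than one window are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps


@dataclass
class SegmentSet:
    """Windowed segments with per-segment provenance."""

    segments: np.ndarray            # (n_segments, n_channels, window)
    labels: np.ndarray              # (n_segments,) user labels
    fs: float
    origin_user_ids: np.ndarray
    origin_run_indices: np.ndarray
    origin_starts: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_segments, channels, window)")
        n = self.segments.shape[0]
        for name in ("labels", "origin_user_ids", "origin_run_indices",
                     "origin_starts"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length must equal segment count")
            setattr(self, name, arr)
        if not np.array_equal(self.labels, self.origin_user_ids):
            raise ValueError("labels must match origin user ids")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@lru_cache(maxsize=32)
def _design_bandpass(fs: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Hamming-window FIR band-pass with an automatic length rule.

    Transition width = min(low_hz, 0.25*low_hz + 2 Hz); taps from the Hamming
    approximation 3.3 / (transition / fs), forced odd (linear phase, type I).
    Cutoffs are widened by half the transition width so the nominal band
    edges sit at full (not -6 dB) gain.
    """
    trans = min(low_hz, 0.25 * low_hz + 2.0)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2
    lo = max(low_hz - trans / 2.0, trans / 4.0)
    hi = min(high_hz + trans / 2.0, fs / 2.0 * 0.999)
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def _apply_bandpass(data: np.ndarray, fs: float, low_hz: float,
                    high_hz: float) -> np.ndarray:
    """Forward-backward (zero net phase) FIR filtering along the last axis."""
    taps = _design_bandpass(float(fs), float(low_hz), float(high_hz))
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    return sps.filtfilt(taps, 1.0, data, axis=-1, padlen=padlen)


def bandpass_filter(rec, low_hz: float = 1.0, high_hz: float = 50.0):
    """Zero-phase FIR band-pass of a Recording (default 1-50 Hz)."""
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= rec.fs / 2:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{rec.fs / 2:.1f} Hz")
    return rec.copy_with(_apply_bandpass(rec.data, rec.fs, low_hz, high_hz))


def average_reference(rec):
    """Re-reference to the common average: subtract the instantaneous mean
    across channels, leaving zero channel-mean at every sample."""
    if rec.n_channels < 2:
        raise ValueError("average reference is undefined for a single channel")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def reject_artifacts_ica(rec, n_components: int = 6,
                         kurtosis_threshold: float = 8.0, seed: int = 0):
    """Automated ICA artifact rejection.

    FastICA decomposes the recording into ``n_components`` sources; sources
    whose excess kurtosis exceeds ``kurtosis_threshold`` (spiky, artifact
    like) have their contribution subtracted from the data. This is an
    automated surrogate for manual component inspection and makes no claim
    of equivalence to a human review. When nothing exceeds the threshold the
    recording is returned unchanged.

    Returns (cleaned Recording, list of rejected component indices).
    """
    from scipy.stats import kurtosis
    from sklearn.decomposition import FastICA

    if n_components > rec.n_channels:
        raise ValueError(
            f"n_components={n_components} exceeds channel count {rec.n_channels}")
    recommended = 10 * rec.n_channels * n_components
    if rec.n_samples < recommended:
        warnings.warn(
            f"recording has {rec.n_samples} samples; >= {recommended} are "
            "recommended for a stable unmixing estimate", stacklevel=2)
    x = rec.data.T  # (samples, channels)
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000)
    try:
        sources = ica.fit_transform(x)
    except Exception as exc:  # pragma: no cover - rank-deficiency path
        raise RuntimeError(f"ICA decomposition failed: {exc}") from exc
    if not np.all(np.isfinite(sources)):
        raise RuntimeError("ICA decomposition failed: non-finite sources")
    k = kurtosis(sources, axis=0, fisher=True, bias=True)
    rejected = [int(i) for i in np.flatnonzero(k > kurtosis_threshold)]
    if not rejected:
        return rec.copy_with(rec.data.copy()), []
    contribution = sources[:, rejected] @ ica.mixing_[:, rejected].T
    cleaned = (x - contribution).T
    return rec.copy_with(cleaned), rejected


def segment(recs: list, window: int = 512, stride: int = 256) -> SegmentSet:
    """Overlapped windowing of a list of recordings into a SegmentSet.

    Per recording, windows start at 0, stride, 2*stride, ... giving
    floor((S - window)/stride) + 1 segments; no window spans a recording
    (run) boundary. Recordings shorter than one window are skipped with a
    warning.
    """
    if not recs:
        raise ValueError("no recordings to segment")
    if window < 1 or not (1 <= stride <= window):
        raise ValueError("need window >= 1 and 1 <= stride <= window")
    fs = recs[0].fs
    n_ch = recs[0].n_channels
    segments, labels, users, runs, starts = [], [], [], [], []
    for rec in recs:
        if rec.fs != fs or rec.n_channels != n_ch:
            raise ValueError("all recordings must share fs and channel count")
        s = rec.n_samples
        if s < window:
            warnings.warn(
                f"recording (user {rec.user_id}, run {rec.run_index}) has "
                f"{s} < {window} samples and is skipped", stacklevel=2)
            continue
        count = (s - window) // stride + 1
        for k in range(count):
            start = k * stride
            segments.append(rec.data[:, start:start + window])
            labels.append(rec.user_id)
            users.append(rec.user_id)
            runs.append(rec.run_index)
            starts.append(start)
    if not segments:
        raise ValueError("every recording was shorter than one window")
    return SegmentSet(
        segments=np.stack(segments),
        labels=np.asarray(labels, dtype=int),
        fs=fs,
        origin_user_ids=np.asarray(users, dtype=int),
        origin_run_indices=np.asarray(runs, dtype=int),
        origin_starts=np.asarray(starts, dtype=int),
    )


def preprocess_recording(rec, low_hz: float = 1.0, high_hz: float = 50.0,
                         use_ica: bool = False, ica_components: int = 6,
                         kurtosis_threshold: float = 8.0):
    """Standard per-recording chain: band-pass, average reference, optional
    automated ICA rejection."""
    out = average_reference(bandpass_filter(rec, low_hz, high_hz))
    if use_ica:
        out, _ = reject_artifacts_ica(out, n_components=ica_components,
                                      kurtosis_threshold=kurtosis_threshold)
    return out
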