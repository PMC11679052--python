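"""Band-power feature extraction.

Each 2 s EEG segment is reduced, per channel, to five canonical band powers
(delta, theta, alpha, beta, gamma) computed from a single Hann-tapered
periodogram of the segment — no Welch sub-averaging. With M channels this
yields a P = 5*M dimensional feature vector per segment.

Absolute PSD scale follows scipy's one-sided density convention (so the PSD
integrates to the signal variance); everything downstream (MI ranking,
standardised classifier inputs) depends only on relative values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import SegmentSet

#: Canonical EEG bands, ordered. Edges are half-open [low, high) except gamma,
#: which closes at 50 Hz inclusive.
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
BAND_EDGES = ((1.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 30.0), (30.0, 50.0))


@dataclass
class PsdSpectrum:
    """One-sided periodogram of a single-channel segment."""

    freqs: np.ndarray
    power: np.ndarray
    nfft: int


@dataclass
class FeatureMatrix:
    """Segments x band-power features with (channel, band) column provenance.

    ``origin`` (optional) is a record array / dict-of-arrays with per-row
    user_id, run_index, start_sample — carried through so chronological
    splits and per-run authentication attempts can be formed downstream.
    """

    values: np.ndarray              # (n_segments, P)
    columns: list[str]              # "ch<i>_<band>" descriptors, unique
    labels: np.ndarray              # (n_segments,) integer user labels
    origin: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column descriptors must match value columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column descriptors must be unique")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        origin = None
        if self.origin is not None:
            origin = {k: v[idx] for k, v in self.origin.items()}
        return FeatureMatrix(self.values[idx], list(self.columns),
                             self.labels[idx], origin)

    def take_columns(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[:, idx],
                             [self.columns[i] for i in idx],
                             self.labels, self.origin)


@dataclass
class ScalerStats:
    """Per-column standardisation statistics, fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray               # sd with ddof=1; 1.0 for flagged columns
    constant_columns: np.ndarray    # boolean mask of zero-variance columns


def periodogram_psd(channel_signal: np.ndarray, fs: float) -> PsdSpectrum:
    """Hann-windowed periodogram PSD of one channel segment.

    One FFT of the full segment (nfft = T), one-sided density scaling with
    interior bins doubled, so that sum(power) * df approximates the signal
    variance.
    """
    x = np.asarray(channel_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel_signal must be 1-D")
    if x.size < 8:
        raise ValueError("segment too short for a PSD estimate (need >= 8)")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel signal contains NaN or Inf")
    freqs, power = sps.periodogram(x, fs=fs, window="hann", nfft=x.size,
                                   scaling="density")
    return PsdSpectrum(freqs=freqs, power=power, nfft=x.size)


def band_powers(spec: PsdSpectrum) -> np.ndarray:
    """Sum PSD values inside each canonical band (delta..gamma order).

    Bands are half-open [low, high); gamma includes its 50 Hz upper edge.
    """
    if spec.freqs[-1] < BAND_EDGES[-1][1]:
        raise ValueError(
            f"spectrum reaches only {spec.freqs[-1]:.1f} Hz; the gamma band "
            f"requires content up to {BAND_EDGES[-1][1]:.0f} Hz (fs too low)"
        )
    out = np.empty(len(BAND_EDGES))
    for i, (low, high) in enumerate(BAND_EDGES):
        if i == len(BAND_EDGES) - 1:
            mask = (spec.freqs >= low) & (spec.freqs <= high)
        else:
            mask = (spec.freqs >= low) & (spec.freqs < high)
        out[i] = spec.power[mask].sum()
    return out


def extract_features(segs: "SegmentSet") -> FeatureMatrix:
    """Band-power features for every segment: row = concat over channels of
    band_powers(periodogram(channel))."""
    data = segs.segments
    n_seg, n_ch, n_t = data.shape
    # vectorised periodogram across (segment, channel)
    freqs, power = sps.periodogram(data, fs=segs.fs, window="hann", nfft=n_t,
                                   scaling="density", axis=-1)
    if freqs[-1] < BAND_EDGES[-1][1]:
        raise ValueError("sampling rate too low for the gamma band")
    bp = np.empty((n_seg, n_ch, len(BAND_EDGES)))
    for i, (low, high) in enumerate(BAND_EDGES):
        if i == len(BAND_EDGES) - 1:
            mask = (freqs >= low) & (freqs <= high)
        else:
            mask = (freqs >= low) & (freqs < high)
        bp[:, :, i] = power[:, :, mask].sum(axis=-1)
    values = bp.reshape(n_seg, n_ch * len(BAND_EDGES))
    columns = [f"ch{c}_{band}" for c in range(n_ch) for band in BAND_NAMES]
    origin = {
        "user_id": segs.origin_user_ids.copy(),
        "run_index": segs.origin_run_indices.copy(),
        "start_sample": segs.origin_starts.copy(),
    }
    return FeatureMatrix(values=values, columns=columns,
                         labels=segs.labels.copy(), origin=origin)


def fit_scaler(train: FeatureMatrix | np.ndarray) -> ScalerStats:
    """Column-wise z-score statistics on training rows (sd denominator n-1).

    Zero-variance columns are flagged and later only centred, with a warning.
    """
    x = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature column(s); "
            "these are centred but not scaled", stacklevel=2)
    scale = np.where(constant, 1.0, sd)
    return ScalerStats(mean=mean, scale=scale, constant_columns=constant)


def apply_scaler(rows: FeatureMatrix | np.ndarray, stats: ScalerStats) -> np.ndarray:
    x = rows.values if isinstance(rows, FeatureMatrix) else np.asarray(rows, float)
    if x.shape[1] != stats.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match scaler "
            f"({stats.mean.shape[0]})")
    return (x - stats.mean) / stats.scale
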