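"""Synthetic multi-user EEG generator.

Emulates the structure of an 8-user, 8-channel, 256 Hz P300-speller style
recording campaign: each user contributes ``n_runs`` continuous runs, with a
chronological train/test split (runs 1..3 train, the rest test). Every user
carries a fixed *band-power signature* — a per-(channel, band) amplitude —
that is the ground truth the downstream identification pipeline should
recover. Signals are a mixture of band-limited Gaussian noise (one process
per canonical EEG band, scaled by the signature), 1/f pink background noise,
and optional P300-like positive transients.

All randomness is driven by a single integer seed fanned out through
``numpy.random.SeedSequence`` spawn keys, so generating more runs or users
never perturbs previously generated ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache as _lru_cache

import numpy as np

from .features import BAND_EDGES, BAND_NAMES

#: Electrode names used for the default 8-channel montage (10-10 system,
#: centro-parietal heavy, matching a typical P300 speller setup).
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

#: Relative P300 transient amplitude per default channel (largest over
#: centro-parietal sites).
_ERP_TOPOGRAPHY = {
    "Fz": 0.4, "Cz": 0.9, "Pz": 1.0, "Oz": 0.5,
    "P3": 0.8, "P4": 0.8, "PO7": 0.6, "PO8": 0.6,
}


@dataclass(frozen=True)
class UserSignature:
    """Per-user ground-truth band-power structure.

    ``band_amplitudes`` is an (n_channels, 5) nonnegative array; columns are
    ordered delta, theta, alpha, beta, gamma.
    """

    user_id: int
    band_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.band_amplitudes, dtype=float)
        if amps.ndim != 2 or amps.shape[1] != len(BAND_NAMES):
            raise ValueError(
                f"band_amplitudes must be (n_channels, {len(BAND_NAMES)}), "
                f"got {amps.shape}"
            )
        if np.any(amps < 0):
            raise ValueError("band amplitudes must be nonnegative")
        object.__setattr__(self, "band_amplitudes", amps)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults mirror the validation campaign
    (8 users, 8 channels, 256 Hz, 7 runs of 60 s, runs 1-3 for training)."""

    n_users: int = 8
    n_channels: int = 8
    fs: float = 256.0
    n_runs: int = 7
    n_train_runs: int = 3
    run_duration: float = 60.0
    separation: float = 0.5
    noise_sd: float = 1.0
    erp_enabled: bool = False
    erp_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 2:
            raise ValueError(
                "n_users must be >= 2: authentication needs at least two "
                "identities to distinguish"
            )
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 2 * 50:
            raise ValueError(
                f"fs must exceed 100 Hz so that activity up to 50 Hz is "
                f"representable; got {self.fs}"
            )
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (1 <= self.n_train_runs < self.n_runs):
            raise ValueError("need 1 <= n_train_runs < n_runs")

    @property
    def n_samples(self) -> int:
        return int(round(self.run_duration * self.fs))

    def channel_names(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS[: self.n_channels])
        extra = [f"EEG{i}" for i in range(len(DEFAULT_CHANNELS), self.n_channels)]
        return list(DEFAULT_CHANNELS) + extra


@dataclass
class Recording:
    """One user's continuous multichannel EEG run."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    user_id: int
    run_index: int
    event_times: list[int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf")
        if self.run_index < 1:
            raise ValueError("run_index starts at 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))


@dataclass
class SynthDataset:
    """All recordings of a campaign plus the generating ground truth."""

    recordings: list[Recording]
    signatures: list[UserSignature]
    config: SimConfig

    def train_recordings(self) -> list[Recording]:
        return [r for r in self.recordings if r.run_index <= self.config.n_train_runs]

    def test_recordings(self) -> list[Recording]:
        return [r for r in self.recordings if r.run_index > self.config.n_train_runs]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Fixed fan-out rule: one global seed, per-purpose spawn keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def sample_user_signatures(config: SimConfig, rng_seed: int | None = None) -> list[UserSignature]:
    """Draw the N user signatures.

    A single log-normal baseline amplitude is drawn per (channel, band) and
    shared by all users; each user multiplies it by ``exp(separation * z)``
    with z standard normal, so ``separation`` is exactly the log-scale spread
    between users and ``separation == 0`` collapses all users onto the
    baseline.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = _rng(seed, 0)
    m, b = config.n_channels, len(BAND_NAMES)
    baseline = np.exp(rng.normal(loc=0.0, scale=0.3, size=(m, b)))
    sigs = []
    for user in range(1, config.n_users + 1):
        z = rng.standard_normal((m, b))
        amps = baseline * np.exp(config.separation * z)
        sigs.append(UserSignature(user_id=user, band_amplitudes=amps))
    return sigs


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


@_lru_cache(maxsize=64)
def _band_response(n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Squared magnitude response of a narrow-transition firwin band-pass on
    the length-n rFFT grid (zero-phase, filtfilt-equivalent attenuation).

    The transition is kept narrow (<= 0.5 Hz and <= 1/8 of the band width) so
    that ground-truth band power stays essentially inside the nominal edges.
    """
    from scipy import signal as sps

    trans = min(0.5, (high - low) / 8.0, low / 2.0)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2
    # cutoffs pulled inward by trans/2 so the transition tails stay inside
    # the nominal band edges (ground-truth band purity)
    taps = sps.firwin(numtaps, [low + trans / 2.0, high - trans / 2.0],
                      pass_zero=False, window="hamming", fs=fs)
    h = np.fft.rfft(taps, n)
    return np.abs(h) ** 2


def _band_noise(n: int, fs: float, low: float, high: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz.

    White noise is shaped in the frequency domain by the squared magnitude of
    a firwin/Hamming band-pass (the same design family as the preprocessing
    filter, applied zero-phase).
    """
    white = rng.standard_normal(n)
    x = np.fft.irfft(np.fft.rfft(white) * _band_response(n, fs, low, high), n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _erp_kernel(fs: float) -> np.ndarray:
    """Positive half-sine transient, ~200 ms wide (P300-like)."""
    width = int(round(0.2 * fs))
    return np.sin(np.linspace(0.0, np.pi, width))


def generate_recording(signature: UserSignature, run_index: int, config: SimConfig,
                       rng_seed: int | None = None) -> Recording:
    """Synthesize one run for one user.

    data = sum over bands of (band-limited noise * signature amplitude)
         + pink noise (sd = noise_sd)
         + optional P300-like transients at Poisson-scheduled event times.
    """
    if signature.band_amplitudes.shape[0] != config.n_channels:
        raise ValueError("signature channel count does not match config")
    n = config.n_samples
    if n < 512:
        raise ValueError(
            f"run_duration gives {n} samples; at least 512 (one analysis "
            f"window, {512 / config.fs:.2f} s at fs={config.fs}) are required"
        )
    seed = config.seed if rng_seed is None else rng_seed
    rng = _rng(seed, 1, signature.user_id, run_index)

    data = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        for b, (low, high) in enumerate(BAND_EDGES):
            amp = signature.band_amplitudes[ch, b]
            if amp > 0:
                data[ch] += amp * _band_noise(n, config.fs, low, high, rng)
        if config.noise_sd > 0:
            data[ch] += config.noise_sd * _pink_noise(n, rng)

    event_times: list[int] | None = None
    if config.erp_enabled:
        names = config.channel_names()
        kernel = _erp_kernel(config.fs)
        latency = int(round(0.3 * config.fs))
        n_events = rng.poisson(config.erp_rate * config.run_duration)
        starts = np.sort(rng.integers(0, n, size=n_events))
        event_times = [int(s) for s in starts]
        amp = 2.0 * max(config.noise_sd, 1e-12)
        for s in starts:
            lo = s + latency
            hi = min(lo + kernel.size, n)
            if lo >= n:
                continue
            seg = kernel[: hi - lo]
            for ch, name in enumerate(names):
                data[ch, lo:hi] += amp * _ERP_TOPOGRAPHY.get(name, 0.5) * seg

    return Recording(
        data=data,
        fs=config.fs,
        channel_names=config.channel_names(),
        user_id=signature.user_id,
        run_index=run_index,
        event_times=event_times,
    )


def generate_dataset(config: SimConfig) -> SynthDataset:
    """Generate the full campaign: every (user, run) pair exactly once.

    Runs 1..n_train_runs are the chronological training portion (3 of 7 by
    default, i.e. the "40%" train share of the emulated campaign); the rest
    are test runs.
    """
    signatures = sample_user_signatures(config)
    recordings = [
        generate_recording(sig, run, config)
        for sig in signatures
        for run in range(1, config.n_runs + 1)
    ]
    return SynthDataset(recordings=recordings, signatures=signatures, config=config)
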