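"""Synthetic surrogates for licensed long-term scalp-EEG monitoring data.

The real study population (presurgical temporal-lobe-epilepsy monitoring,
256 Hz, 19 channels, >=4 lead seizures separated by >=4.5 h) is available
only under license, so this module generates stand-ins with the statistical
structure the downstream analysis assumes, at two levels:

:func:`generate_recording`
    a signal-level recording: per-channel colored (pink by default) noise
    with additive band-limited oscillations, a preictal window before each
    onset in which selected band oscillations are multiplicatively boosted
    so that the named relative-band-power features shift by approximately
    ``effect_size`` interictal standard deviations, and short high-variance
    ictal segments;

:func:`generate_feature_dataset`
    a feature-level fast path that draws per-window feature vectors directly
    from diagonal-covariance normal distributions, with the preictal mean of
    the signature features shifted by ``effect_size`` (features have unit
    variance, so the configured shift IS the standardized effect).

Both are fully deterministic given ``SynthConfig.seed``.  Neither pretends
to be physiologically realistic EEG: there are no artifacts, no circadian
structure and no autocorrelation between windows at the feature level; the
preictal signature is a modeling stand-in, not a claim about real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import (
    BANDS,
    FEATURE_NAMES,
    FeatureMatrix,
    WINDOW_S,
    _spectral_block,
    column_names,
)

_BAND_NAMES = tuple(b[0] for b in BANDS)


@dataclass(frozen=True)
class SeizureEvent:
    """A seizure: onset (and optional offset) in seconds from recording start."""

    onset: float
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.offset is not None and self.offset <= self.onset:
            raise ValueError("seizure offset must be greater than onset")

    def offset_or_default(self, ictal_duration_s: float = 60.0) -> float:
        return self.offset if self.offset is not None else self.onset + ictal_duration_s


@dataclass
class Recording:
    """A continuous multichannel signal with seizure annotations."""

    signal: np.ndarray  # (n_channels, n_samples), microvolt-like amplitudes
    fs: float
    channel_names: list[str]
    seizures: list[SeizureEvent] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        onsets = [s.onset for s in self.seizures]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")
        dur = self.duration
        if any(not (self.start_time <= o < self.start_time + dur) for o in onsets):
            raise ValueError("seizure onsets must lie inside the recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s.onset for s in self.seizures], dtype=float)


class PlacementError(ValueError):
    """Raised when seizures cannot be placed under the configured constraints."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults mirror the emulated study conditions.

    ``effect_size`` is the standardized preictal mean shift d of the
    ``signature_features``; ``preictal_minutes`` is the span of that
    signature before each onset (40 min = the default 30-min seizure
    occurrence period plus the 10-min intervention horizon).
    """

    n_seizures: int = 4
    interictal_gap_hours: float = 4.5
    fs: float = 256.0
    n_channels: int = 19
    preictal_minutes: float = 40.0
    effect_size: float = 0.0
    signature_features: tuple[str, ...] | None = None
    noise_spectrum: str = "pink"  # "pink" | "white"
    seed: int = 0
    # timeline shaping
    duration_hours: float | None = None  # only used when n_seizures == 0
    lead_in_hours: float = 1.0
    tail_hours: float = 0.5
    onset_jitter_hours: float = 0.25
    ictal_duration_s: float = 60.0
    # feature-level fast path only
    n_features: int = 59

    def __post_init__(self) -> None:
        if self.n_seizures < 0:
            raise ValueError("n_seizures must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.interictal_gap_hours <= 0:
            raise ValueError("interictal_gap_hours must be positive")
        if self.noise_spectrum not in ("pink", "white"):
            raise ValueError("noise_spectrum must be 'pink' or 'white'")

    def replace(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _onset_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Seizure onsets: >= the configured gap apart, with deterministic jitter."""
    if cfg.n_seizures == 0:
        return np.empty(0)
    gaps = cfg.interictal_gap_hours + rng.uniform(0, cfg.onset_jitter_hours, cfg.n_seizures - 1)
    onsets = cfg.lead_in_hours + np.concatenate([[0.0], np.cumsum(gaps)])
    return onsets * 3600.0


def _total_duration_s(cfg: SynthConfig, onsets: np.ndarray) -> float:
    if cfg.n_seizures == 0:
        hours = cfg.duration_hours if cfg.duration_hours is not None else 1.0
        return hours * 3600.0
    return float(onsets[-1] + cfg.ictal_duration_s + cfg.tail_hours * 3600.0)


def _check_placement(cfg: SynthConfig, onsets: np.ndarray, duration_s: float) -> None:
    if cfg.n_seizures == 0:
        return
    if cfg.duration_hours is not None and duration_s > cfg.duration_hours * 3600.0:
        raise PlacementError(
            f"cannot place {cfg.n_seizures} seizures with {cfg.interictal_gap_hours} h "
            f"gaps inside {cfg.duration_hours} h"
        )
    if onsets[0] < cfg.preictal_minutes * 60.0:
        raise PlacementError("lead-in too short for a full preictal before the first seizure")


# ---------------------------------------------------------------------------
# feature-level fast path
# ---------------------------------------------------------------------------

#: Default signature at the feature level: five of the 59 features carry the
#: preictal shift.  The names are only labels here (every feature is a unit
#: normal), chosen to span the three feature domains.
DEFAULT_FEATURE_SIGNATURE = (
    "Ch1:rel_power_alpha",
    "Ch1:rel_power_beta",
    "Ch1:hjorth_mobility",
    "Ch1:sef50",
    "Ch1:wavelet_d3_energy",
)


def _resolve_columns(names: Sequence[str], wanted: Sequence[str]) -> np.ndarray:
    idx = []
    for w in wanted:
        if w not in names:
            raise ValueError(f"signature feature {w!r} not among generated columns")
        idx.append(names.index(w))
    return np.asarray(idx, dtype=int)


def generate_feature_dataset(cfg: SynthConfig) -> tuple[FeatureMatrix, list[SeizureEvent]]:
    """Draw per-window feature vectors directly (no signal synthesis).

    Window cadence is one vector per 5 s.  Interictal windows are N(0, I);
    windows whose start falls in the ``preictal_minutes`` before an onset
    have the signature features' mean shifted by ``effect_size``.  The
    preictal:interictal row ratio therefore follows directly from the
    configured seizure spacing.
    """
    rng = np.random.default_rng(cfg.seed)
    onsets = _onset_times(cfg, rng)
    duration_s = _total_duration_s(cfg, onsets)
    _check_placement(cfg, onsets, duration_s)

    n_windows = int(duration_s // WINDOW_S)
    t = np.arange(n_windows) * WINDOW_S
    values = rng.standard_normal((n_windows, cfg.n_features))

    names = column_names(1, FEATURE_NAMES)[: cfg.n_features]
    if cfg.n_features > 59:
        names = [f"Ch1:f{i}" if i >= 59 else names[i] for i in range(cfg.n_features)]
    signature = cfg.signature_features or DEFAULT_FEATURE_SIGNATURE
    sig_idx = _resolve_columns(names, signature)

    if cfg.effect_size > 0:
        pre = np.zeros(n_windows, dtype=bool)
        for onset in onsets:
            pre |= (t >= onset - cfg.preictal_minutes * 60.0) & (t < onset)
        values[np.ix_(pre, sig_idx)] += cfg.effect_size

    seizures = [SeizureEvent(o, o + cfg.ictal_duration_s) for o in onsets]
    return FeatureMatrix(values, t, names), seizures


# ---------------------------------------------------------------------------
# signal-level generator
# ---------------------------------------------------------------------------

#: Default signature at the signal level: boost the alpha-band oscillation.
DEFAULT_SIGNAL_SIGNATURE = ("rel_power_alpha",)

#: Interictal RMS amplitude (microvolt-like) of each band-limited oscillation.
_BAND_RMS = {
    "delta": 3.0,
    "theta": 2.0,
    "alpha": 4.0,
    "beta": 2.0,
    "gamma1": 1.0,
    "gamma2": 0.8,
    "gamma3": 0.6,
    "gamma4": 0.5,
}
_PINK_RMS = 10.0
_ICTAL_GAIN = 6.0


def _signature_bands(signature: Sequence[str]) -> list[str]:
    bands = []
    for name in signature:
        base = name.split(":", 1)[-1]
        if not base.startswith("rel_power_"):
            raise ValueError(
                "signal-level signatures are expressed as relative band powers "
                f"(rel_power_<band>); got {name!r}"
            )
        band = base[len("rel_power_") :]
        if band not in _BAND_NAMES:
            raise ValueError(f"unknown band {band!r}")
        bands.append(band)
    return bands


def _colored_noise(rng: np.random.Generator, shape, fs: float, spectrum: str) -> np.ndarray:
    """Unit-RMS noise with a flat ('white') or 1/f ('pink') power spectrum."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if spectrum == "white":
        return white
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * shaping, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / rms


def _band_noise(rng: np.random.Generator, shape, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz via spectral masking."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= min(hi, fs / 2))
    if not mask.any():
        return np.zeros(shape)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * mask, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _synth_windows(
    rng: np.random.Generator,
    n_windows: int,
    fs: float,
    spectrum: str,
    gains: dict[str, float],
) -> np.ndarray:
    """Stationary background windows with per-band oscillation gains applied."""
    step = int(round(fs * WINDOW_S))
    shape = (n_windows, step)
    flat = (1, n_windows * step)
    x = _PINK_RMS * _colored_noise(rng, flat, fs, spectrum).reshape(shape)
    for band, lo, hi in BANDS:
        amp = _BAND_RMS[band] * gains.get(band, 1.0)
        if amp > 0 and lo < fs / 2:
            x += amp * _band_noise(rng, flat, fs, lo, hi).reshape(shape)
    return x


def _calibrate_band_gains(cfg: SynthConfig, bands: list[str]) -> dict[str, float]:
    """Solve, per signature band, the oscillation gain moving that band's
    relative power by ``effect_size`` interictal standard deviations.

    Uses bisection on short deterministic calibration stretches (120 windows)
    sharing the recording's spectral parameters.  Bands are calibrated
    one at a time with the others at baseline; when several bands are
    boosted jointly the realized shifts are approximate (relative powers
    are coupled through the total power).
    """
    if cfg.effect_size == 0:
        return {}
    n_cal = 120
    feat_idx = {b: i for i, b in enumerate(_BAND_NAMES)}
    gains: dict[str, float] = {}
    for band in bands:
        col = feat_idx[band]

        def rel_power_mean_sd(gain: float, sub_seed: int) -> tuple[float, float]:
            rng = np.random.default_rng((cfg.seed, 0xCA1, sub_seed))
            w = _synth_windows(rng, n_cal, cfg.fs, cfg.noise_spectrum, {band: gain})
            rel = _spectral_block(w, cfg.fs)[:, col]
            return float(rel.mean()), float(rel.std(ddof=1))

        mu0, sd0 = rel_power_mean_sd(1.0, 0)
        target = mu0 + cfg.effect_size * sd0
        lo, hi = 1.0, 2.0
        while rel_power_mean_sd(hi, 1)[0] < target:
            hi *= 2.0
            if hi > 1e3:  # relative power saturates below the target
                break
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if rel_power_mean_sd(mid, 1)[0] < target:
                lo = mid
            else:
                hi = mid
        gains[band] = 0.5 * (lo + hi)
    return gains


def generate_recording(cfg: SynthConfig) -> Recording:
    """Synthesize a continuous multichannel recording.

    Interictal background is stationary colored noise plus band-limited
    oscillations per channel; during the ``preictal_minutes`` before each
    onset the signature bands' oscillations are boosted by a calibrated
    gain (ramped over 60 s) so the corresponding relative-power features
    shift by about ``effect_size`` standard deviations; ictal segments are
    ``ictal_duration_s`` of high-variance activity.
    """
    rng = np.random.default_rng(cfg.seed)
    onsets = _onset_times(cfg, rng)
    duration_s = _total_duration_s(cfg, onsets)
    _check_placement(cfg, onsets, duration_s)

    n_samples = int(round(duration_s * cfg.fs))
    t = np.arange(n_samples) / cfg.fs

    bands = _signature_bands(cfg.signature_features or DEFAULT_SIGNAL_SIGNATURE)
    gains = _calibrate_band_gains(cfg, bands)

    # smooth preictal gain envelope per signature band: 1 interictally,
    # the calibrated gain inside the signature window (60-s cosine ramp)
    ramp_s = 60.0
    envelopes: dict[str, np.ndarray] = {}
    for band, gain in gains.items():
        env = np.ones(n_samples)
        for onset in onsets:
            t0 = onset - cfg.preictal_minutes * 60.0
            in_pre = (t >= t0) & (t < onset)
            smooth = 0.5 - 0.5 * np.cos(np.pi * np.clip((t - t0) / ramp_s, 0, 1))
            env = np.where(in_pre, 1.0 + (gain - 1.0) * smooth, env)
        envelopes[band] = env

    signal = np.empty((cfg.n_channels, n_samples))
    for c in range(cfg.n_channels):
        ch_rng = np.random.default_rng((cfg.seed, 0x5EED, c))
        x = _PINK_RMS * _colored_noise(ch_rng, (1, n_samples), cfg.fs, cfg.noise_spectrum)[0]
        for band, lo, hi in BANDS:
            if _BAND_RMS[band] <= 0 or lo >= cfg.fs / 2:
                continue
            comp = _BAND_RMS[band] * _band_noise(ch_rng, (1, n_samples), cfg.fs, lo, hi)[0]
            if band in envelopes:
                comp *= envelopes[band]
            x += comp
        signal[c] = x

    # ictal segments: high-amplitude activity
    for onset in onsets:
        a = int(round(onset * cfg.fs))
        b = min(int(round((onset + cfg.ictal_duration_s) * cfg.fs)), n_samples)
        signal[:, a:b] *= _ICTAL_GAIN

    seizures = [SeizureEvent(o, min(o + cfg.ictal_duration_s, duration_s)) for o in onsets]
    ch_names = [f"EEG{i + 1:02d}" for i in range(cfg.n_channels)]
    return Recording(signal=signal, fs=cfg.fs, channel_names=ch_names, seizures=seizures)
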