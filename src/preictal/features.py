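"""Univariate linear EEG features on non-overlapping 5-second windows.

Each analysis window of a multichannel scalp-EEG recording is reduced to 59
features per channel, split across three domains:

frequency (46)
    relative spectral power of 8 bands (delta, theta, alpha, beta and four
    gamma sub-bands), absolute power of the same bands, the 28 unordered
    pairwise band-power ratios (lower-frequency band in the numerator), the
    spectral edge frequency at 50% (SEF50) and the cumulative power at that
    frequency (SEP50);
time (8)
    mean, variance, skewness, kurtosis (non-excess; a Gaussian scores 3),
    the Hjorth parameters (activity, mobility, complexity) and the
    decorrelation time (first zero crossing of the sample autocorrelation);
time-frequency (5)
    energies of the detail coefficients D1..D5 of a 5-level discrete wavelet
    transform with the db4 mother wavelet.

Power spectra are Hamming-windowed periodograms of the full 5-s window (too
short for multi-segment Welch averaging).  The 47-53 and 97-103 Hz power-line
notch gaps are excluded from every band and from the total power.

Degenerate windows (all-zero or constant signal) yield NaN sentinels for the
features that are undefined there; downstream code masks such windows out
instead of silently zero-filling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pywt
from scipy.signal import periodogram

if TYPE_CHECKING:  # pragma: no cover
    from .synth import Recording

logger = logging.getLogger(__name__)

#: Non-overlapping analysis window length in seconds.
WINDOW_S = 5.0

#: Frequency bands (name, low Hz, high Hz).  The gap between gamma1 and
#: gamma2 (47-53 Hz) and between gamma3 and gamma4 (97-103 Hz) is the
#: power-line notch and is excluded from the total power as well.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma1", 30.0, 47.0),
    ("gamma2", 53.0, 75.0),
    ("gamma3", 75.0, 97.0),
    ("gamma4", 103.0, 128.0),
)

_WAVELET = "db4"
_DWT_LEVELS = 5


@dataclass(frozen=True)
class FeatureSpec:
    """One registry entry: a named feature and the domain it belongs to."""

    name: str
    domain: str  # "frequency" | "time" | "time-frequency"


def _build_registry() -> tuple[FeatureSpec, ...]:
    specs: list[FeatureSpec] = []
    names = [b[0] for b in BANDS]
    for b in names:
        specs.append(FeatureSpec(f"rel_power_{b}", "frequency"))
    for b in names:
        specs.append(FeatureSpec(f"abs_power_{b}", "frequency"))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            # lower-frequency band in the numerator
            specs.append(FeatureSpec(f"power_ratio_{names[i]}_{names[j]}", "frequency"))
    specs.append(FeatureSpec("sef50", "frequency"))
    specs.append(FeatureSpec("sep50", "frequency"))
    for name in (
        "mean",
        "variance",
        "skewness",
        "kurtosis",
        "hjorth_activity",
        "hjorth_mobility",
        "hjorth_complexity",
        "decorrelation_time",
    ):
        specs.append(FeatureSpec(name, "time"))
    for level in range(1, _DWT_LEVELS + 1):
        specs.append(FeatureSpec(f"wavelet_d{level}_energy", "time-frequency"))
    return tuple(specs)


#: Ordered registry of the 59 per-channel features.
FEATURE_REGISTRY: tuple[FeatureSpec, ...] = _build_registry()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in FEATURE_REGISTRY)
N_FEATURES = len(FEATURE_REGISTRY)
assert N_FEATURES == 59

_N_SPECTRAL = 46
_N_TIME = 8
_N_WAVELET = 5


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with their window start times.

    ``values`` has one row per 5-s window and ``n_channels * 59`` columns,
    ordered channel-major (all 59 features of channel 1, then channel 2, ...).
    Column names follow the ``Ch{index}:{feature_name}`` convention with
    1-based channel indices.
    """

    values: np.ndarray
    window_start: np.ndarray  # seconds, strictly increasing, 5-s stride
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_start = np.asarray(self.window_start, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (windows x columns)")
        if self.values.shape[0] != self.window_start.shape[0]:
            raise ValueError("values and window_start row counts differ")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match column count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "window_start_s", self.window_start)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        t = df.pop("window_start_s").to_numpy()
        return cls(df.to_numpy(dtype=float), t, list(df.columns))


def column_names(channel_names_or_count, feature_names: Sequence[str] = FEATURE_NAMES) -> list[str]:
    """``Ch{i}:{feature}`` column labels for a channel count or name list."""
    if isinstance(channel_names_or_count, int):
        n = channel_names_or_count
    else:
        n = len(channel_names_or_count)
    return [f"Ch{c + 1}:{name}" for c in range(n) for name in feature_names]


def segment(recording: "Recording", window_s: float = WINDOW_S) -> list[tuple[int, int]]:
    """Half-open sample index ranges of the non-overlapping analysis windows.

    The trailing partial window is dropped; an empty recording yields an
    empty list.  ``fs * window_s`` must be integral.
    """
    n_win_samples = recording.fs * window_s
    if abs(n_win_samples - round(n_win_samples)) > 1e-9:
        raise ValueError(f"fs * window_s = {n_win_samples} is not integral")
    step = int(round(n_win_samples))
    n_samples = recording.signal.shape[1]
    n_windows = n_samples // step
    return [(i * step, (i + 1) * step) for i in range(n_windows)]


# ---------------------------------------------------------------------------
# vectorized feature kernels; ``x`` is (..., n_samples)
# ---------------------------------------------------------------------------


def _band_masks(freqs: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    band_masks = [(freqs >= lo) & (freqs <= hi) for _, lo, hi in BANDS]
    total_mask = np.zeros_like(freqs, dtype=bool)
    for m in band_masks:
        total_mask |= m
    return band_masks, total_mask


def _trapz_bands(pxx: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoid-integrated absolute band powers and the total analyzed power."""
    band_masks, _ = _band_masks(freqs)
    powers = np.stack(
        [np.trapezoid(pxx[..., m], freqs[m], axis=-1) for m in band_masks], axis=-1
    )
    # the analyzed region is exactly the union of the (gapless-within) bands;
    # adjacent bands share their edge bin so trapezoid integrals are additive
    total = powers.sum(axis=-1)
    return powers, total


def _spectral_block(x: np.ndarray, fs: float) -> np.ndarray:
    """46 frequency-domain features for each window in ``x``."""
    freqs, pxx = periodogram(x, fs=fs, window="hamming", detrend="constant", axis=-1)
    powers, total = _trapz_bands(pxx, freqs)

    out = np.full(x.shape[:-1] + (_N_SPECTRAL,), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = powers / total[..., None]
        out[..., 0:8] = rel
        out[..., 8:16] = powers
        k = 16
        for i in range(8):
            for j in range(i + 1, 8):
                out[..., k] = powers[..., i] / powers[..., j]
                k += 1
    # SEF50 / SEP50 over the analyzed (notch-free) region
    _, total_mask = _band_masks(freqs)
    f_an = freqs[total_mask]
    p_an = pxx[..., total_mask]
    df = np.diff(f_an)
    seg = 0.5 * (p_an[..., 1:] + p_an[..., :-1]) * df
    cum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(seg, axis=-1)], axis=-1)
    tot = cum[..., -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = cum / tot[..., None]
    idx = np.argmax(frac >= 0.5, axis=-1)
    out[..., 44] = f_an[idx]
    out[..., 45] = np.take_along_axis(cum, idx[..., None], axis=-1)[..., 0]
    degenerate = ~(tot > 0)
    if np.any(degenerate):
        out[degenerate, :] = np.nan
        out[degenerate, 8:16] = 0.0  # absolute powers of a null signal are 0
    return out


def _time_block(x: np.ndarray, fs: float) -> np.ndarray:
    """8 time-domain features for each window in ``x``."""
    n = x.shape[-1]
    mean = x.mean(axis=-1)
    xc = x - mean[..., None]
    var = np.mean(xc**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(var)
        skew = np.mean(xc**3, axis=-1) / sd**3
        kurt = np.mean(xc**4, axis=-1) / var**2  # non-excess: Gaussian -> 3
        d1 = np.diff(x, axis=-1)
        var_d1 = d1.var(axis=-1)
        mobility = np.sqrt(var_d1 / var)
        d2 = np.diff(d1, axis=-1)
        var_d2 = d2.var(axis=-1)
        mobility_d1 = np.sqrt(var_d2 / var_d1)
        complexity = mobility_d1 / mobility

        # decorrelation time: first zero crossing of the sample autocorrelation
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        fx = np.fft.rfft(xc, n=nfft, axis=-1)
        acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=-1)[..., :n]
        acf0 = acf[..., :1]
        acf = np.divide(acf, acf0, out=np.full_like(acf, np.nan), where=acf0 != 0)
    nonpos = acf <= 0
    nonpos[..., 0] = False
    has_cross = nonpos.any(axis=-1)
    first = np.argmax(nonpos, axis=-1)
    decorr = np.where(has_cross, first / fs, np.nan)

    out = np.stack(
        [mean, var, skew, kurt, var, mobility, complexity, decorr], axis=-1
    )
    return out


def _wavelet_block(x: np.ndarray) -> np.ndarray:
    """Energies of detail levels D1..D5 of the db4 DWT, for each window."""
    min_len = pywt.Wavelet(_WAVELET).dec_len * 2**_DWT_LEVELS  # generous bound
    if x.shape[-1] < 2**_DWT_LEVELS:
        raise ValueError(
            f"window of {x.shape[-1]} samples too short for a "
            f"{_DWT_LEVELS}-level {_WAVELET} decomposition (needs >= {min_len})"
        )
    coeffs = pywt.wavedec(x, _WAVELET, level=_DWT_LEVELS, axis=-1)
    # wavedec order: [cA5, cD5, cD4, cD3, cD2, cD1] -> report D1..D5
    details = coeffs[:0:-1]
    return np.stack([np.sum(c**2, axis=-1) for c in details], axis=-1)


# ---------------------------------------------------------------------------
# single-window public API
# ---------------------------------------------------------------------------


def spectral_features(x: np.ndarray, fs: float) -> np.ndarray:
    """46 frequency-domain features of one single-channel window.

    Registry order: 8 relative band powers, 8 absolute band powers, 28
    pairwise ratios, SEF50, SEP50.  An all-zero window has no defined
    relative powers or ratios and returns NaN sentinels there.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D window")
    out = _spectral_block(x[None, :], fs)[0]
    if np.isnan(out).any():
        logger.warning("degenerate window: spectral features flagged NaN")
    return out


def time_features(x: np.ndarray, fs: float) -> np.ndarray:
    """Mean, variance, skewness, kurtosis, Hjorth parameters, decorrelation time."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("expected a 1-D window of at least 3 samples")
    out = _time_block(x[None, :], fs)[0]
    if np.isnan(out).any():
        logger.warning("degenerate window: time features flagged NaN")
    return out


def wavelet_features(x: np.ndarray) -> np.ndarray:
    """Energies of the db4 detail coefficients D1..D5."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D window")
    return _wavelet_block(x[None, :])[0]


def window_features(x: np.ndarray, fs: float) -> np.ndarray:
    """All 59 features of one single-channel window, in registry order."""
    return np.concatenate([spectral_features(x, fs), time_features(x, fs), wavelet_features(x)])


def extract(recording: "Recording", window_s: float = WINDOW_S) -> FeatureMatrix:
    """Feature matrix of a recording: one row per window, 59 columns per channel.

    Columns are channel-major in registry order; a 19-channel recording yields
    1121 columns.  Windows where a feature is undefined carry NaN sentinels
    that downstream labeling converts into an invalid-window mask.
    """
    ranges = segment(recording, window_s)
    n_channels = recording.signal.shape[0]
    names = column_names(recording.channel_names or n_channels)
    if not ranges:
        return FeatureMatrix(np.empty((0, n_channels * N_FEATURES)), np.empty(0), names)
    step = ranges[0][1] - ranges[0][0]
    n_windows = len(ranges)
    # (n_windows, n_channels, step) view of the contiguous windows
    windows = (
        recording.signal[:, : n_windows * step]
        .reshape(n_channels, n_windows, step)
        .transpose(1, 0, 2)
    )
    blocks = np.concatenate(
        [
            _spectral_block(windows, recording.fs),
            _time_block(windows, recording.fs),
            _wavelet_block(windows),
        ],
        axis=-1,
    )  # (n_windows, n_channels, 59)
    values = blocks.reshape(n_windows, n_channels * N_FEATURES)
    n_bad = int(np.isnan(values).any(axis=1).sum())
    if n_bad:
        logger.warning("%d of %d windows contain NaN feature sentinels", n_bad, n_windows)
    t = np.arange(n_windows) * window_s + recording.start_time
    return FeatureMatrix(values, t, names)
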