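"""Firing Power smoothing and its two output modes: alarms and risk states.

The Firing Power is a causal moving average of the classifier's binary
per-window outputs: fp[n] is the fraction of the last tau windows classified
preictal, so it lies in [0, 1] and rises smoothly as preictal evidence
accumulates.  tau defaults to the preictal duration (SOP + SPH) expressed in
5-s windows, i.e. a full preictal of unanimous outputs is exactly what is
needed to saturate the filter.  Before tau windows of history exist, the
missing history counts as 0 (cold start), and the history is cleared across
recording gaps longer than one window so discontinuous data cannot bleed
through the filter.

Prediction branch: an alarm fires the first time fp strictly exceeds the
threshold (0.7) outside a refractory interval; each alarm opens a refractory
interval equal to the preictal duration, during which no further alarm may
fire.

Forecasting branch: each window is assigned a risk state instead — high if
fp > 0.7, moderate if 0.3 < fp <= 0.7, low if fp <= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .features import WINDOW_S

ALARM_THRESHOLD = 0.7
LOW_RISK_THRESHOLD = 0.3
HIGH_RISK_THRESHOLD = 0.7


class RiskState(IntEnum):
    LOW = 0
    MODERATE = 1
    HIGH = 2


@dataclass
class FiringPowerSeries:
    """Smoothed preictal evidence per window, in [0, 1]."""

    fp: np.ndarray
    window_start: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        self.fp = np.asarray(self.fp, dtype=float)
        self.window_start = np.asarray(self.window_start, dtype=float)
        if self.fp.shape != self.window_start.shape:
            raise ValueError("fp and window_start must have equal length")
        if self.fp.size and (self.fp.min() < -1e-12 or self.fp.max() > 1 + 1e-12):
            raise ValueError("firing power values must lie in [0, 1]")


@dataclass
class AlarmList:
    """Alarm times (window starts, seconds) under a refractory discipline."""

    times: np.ndarray
    threshold: float
    refractory_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) < self.refractory_s - 1e-9):
            raise ValueError("alarms closer than the refractory period")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RiskSeries:
    """Per-window risk state (low / moderate / high)."""

    states: np.ndarray  # RiskState values
    window_start: np.ndarray

    @property
    def high_times(self) -> np.ndarray:
        return self.window_start[self.states == RiskState.HIGH]


def preictal_tau(sop_minutes: float, sph_minutes: float, window_s: float = WINDOW_S) -> int:
    """Smoothing length: the preictal duration (SOP+SPH) in windows."""
    return max(1, int(round((sop_minutes + sph_minutes) * 60.0 / window_s)))


def firing_power(
    outputs: np.ndarray,
    tau: int,
    window_start: np.ndarray | None = None,
    window_s: float = WINDOW_S,
) -> FiringPowerSeries:
    """Causal moving average of binary outputs over the last ``tau`` windows.

    ``window_start`` is optional; when given, gaps longer than one window
    reset the filter history (each contiguous segment gets its own cold
    start).
    """
    outputs = np.asarray(outputs)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if not np.isin(outputs, (0, 1)).all():
        raise ValueError("firing power input must be binary")
    if window_start is None:
        window_start = np.arange(outputs.size) * window_s
    window_start = np.asarray(window_start, dtype=float)

    fp = np.empty(outputs.size, dtype=float)
    gap_after = np.flatnonzero(np.diff(window_start) > window_s * 1.5) + 1
    bounds = [0, *gap_after.tolist(), outputs.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = outputs[a:b].astype(float)
        c = np.concatenate([[0.0], np.cumsum(seg)])
        lo = np.maximum(np.arange(1, seg.size + 1) - tau, 0)
        fp[a:b] = (c[1:] - c[lo]) / tau  # cold start: missing history counts as 0
    return FiringPowerSeries(fp=fp, window_start=window_start, tau=tau)


def alarms(
    fps: FiringPowerSeries,
    threshold: float = ALARM_THRESHOLD,
    refractory_s: float | None = None,
) -> AlarmList:
    """Alarm times: first window with fp > threshold outside any refractory
    interval; each alarm opens a refractory interval of ``refractory_s``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if refractory_s is None:
        refractory_s = fps.tau * WINDOW_S
    above = np.flatnonzero(fps.fp > threshold)
    times = []
    last = -np.inf
    for i in above:
        t = fps.window_start[i]
        if t >= last + refractory_s:
            times.append(t)
            last = t
    return AlarmList(times=np.array(times), threshold=threshold, refractory_s=refractory_s)


def risk_states(
    fps: FiringPowerSeries,
    low_thr: float = LOW_RISK_THRESHOLD,
    high_thr: float = HIGH_RISK_THRESHOLD,
) -> RiskSeries:
    """Map fp to risk states: high > 0.7, moderate > 0.3, low otherwise."""
    if not (0 < low_thr < high_thr < 1):
        raise ValueError("thresholds must satisfy 0 < low < high < 1")
    states = np.full(fps.fp.size, RiskState.LOW, dtype=int)
    states[fps.fp > low_thr] = RiskState.MODERATE
    states[fps.fp > high_thr] = RiskState.HIGH
    return RiskSeries(states=states, window_start=fps.window_start)


def plot_firing_power(
    fps: FiringPowerSeries,
    seizure_onsets=(),
    alarm_list: AlarmList | None = None,
    sop_minutes: float | None = None,
    sph_minutes: float = 10.0,
    ax=None,
):
    """Firing Power curve with SOP band, alarm markers and risk coloring."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = fps.window_start / 3600.0
    ax.plot(t, fps.fp, color="k", lw=0.8, label="Firing Power")
    ax.axhspan(0, LOW_RISK_THRESHOLD, color="green", alpha=0.08)
    ax.axhspan(LOW_RISK_THRESHOLD, HIGH_RISK_THRESHOLD, color="gold", alpha=0.08)
    ax.axhspan(HIGH_RISK_THRESHOLD, 1, color="red", alpha=0.08)
    for onset in np.atleast_1d(np.asarray(seizure_onsets, dtype=float)):
        if sop_minutes is not None:
            ax.axvspan(
                (onset - (sop_minutes + sph_minutes) * 60) / 3600.0,
                (onset - sph_minutes * 60) / 3600.0,
                color="tan",
                alpha=0.4,
            )
        ax.axvline(onset / 3600.0, color="b", lw=1.0)
    if alarm_list is not None and len(alarm_list):
        ax.plot(
            alarm_list.times / 3600.0,
            np.full(len(alarm_list), alarm_list.threshold),
            "rv",
            ms=8,
            label="alarm",
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("Firing Power")
    ax.set_ylim(0, 1.02)
    return ax
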