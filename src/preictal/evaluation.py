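"""Prediction and forecasting metrics with surrogate statistical validation.

Prediction metrics
    Seizure sensitivity (SS): a seizure counts as predicted iff some alarm
    at time t satisfies onset in (t+SPH, t+SPH+SOP] — i.e. the seizure falls
    inside the occurrence period the alarm announced.  FPR/h divides the
    false alarms by the alarm-capable interictal time (interictal hours
    minus the refractory time consumed by the false alarms themselves).

Forecasting metrics
    SS: a seizure counts as forecast iff at least one high-risk window
    starts inside its occurrence period [onset-(SOP+SPH), onset-SPH).
    Time in warning (TiW): fraction of windows in the high-risk state.
    Brier score (BS): mean squared error between the Firing Power and the
    binary preictal observation.  Brier skill score (BSS): 1 - BS/BS_ref,
    where BS_ref is the mean BS of randomly shuffled forecasts.

Statistical validation
    Surrogate seizure times: the original onsets are re-placed uniformly in
    the interictal period (full preictal fitting, surrogate preictals
    non-overlapping) and the frozen alarm/risk series is re-scored; repeated
    30 times, and the achieved SS is compared to the surrogate sample with a
    one-sided one-sample t-test at alpha = 0.05.  Surrogate forecasts: the
    achieved BS is compared the same way against the BS of shuffled Firing
    Power series (lower BS = better; the test direction follows the metric).
    The improvement-over-chance (IoC) of a cohort is the fraction of
    patients validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .features import WINDOW_S
from .postprocess import AlarmList, FiringPowerSeries, RiskSeries

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
N_SS_SURROGATES = 30
N_BS_SURROGATES = 1000


# ---------------------------------------------------------------------------
# prediction metrics
# ---------------------------------------------------------------------------


def _predicted_mask(alarm_times: np.ndarray, onsets: np.ndarray, sop_minutes, sph_minutes):
    sph = sph_minutes * 60.0
    sop = sop_minutes * 60.0
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    alarm_times = np.asarray(alarm_times, dtype=float)
    out = np.zeros(onsets.size, dtype=bool)
    for i, onset in enumerate(onsets):
        lead = onset - alarm_times
        out[i] = bool(np.any((lead > sph) & (lead <= sph + sop)))
    return out


def prediction_ss(
    alarm_list: AlarmList | np.ndarray, onsets, sop_minutes: float, sph_minutes: float
) -> float:
    """Fraction of seizures with an alarm whose occurrence period they hit."""
    times = alarm_list.times if isinstance(alarm_list, AlarmList) else np.asarray(alarm_list)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("prediction SS undefined without seizures")
    return float(_predicted_mask(times, onsets, sop_minutes, sph_minutes).mean())


def false_alarms(
    alarm_list: AlarmList | np.ndarray, onsets, sop_minutes: float, sph_minutes: float
) -> np.ndarray:
    """Alarm times not matching any seizure under the prediction-SS rule."""
    times = alarm_list.times if isinstance(alarm_list, AlarmList) else np.asarray(alarm_list)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    sph = sph_minutes * 60.0
    sop = sop_minutes * 60.0
    is_true = np.zeros(times.size, dtype=bool)
    for onset in onsets:
        lead = onset - times
        is_true |= (lead > sph) & (lead <= sph + sop)
    return times[~is_true]


def fpr_per_hour(
    alarm_list: AlarmList | np.ndarray,
    onsets,
    interictal_hours: float,
    refractory_hours: float,
    sop_minutes: float,
    sph_minutes: float,
) -> float:
    """False alarms per alarm-capable interictal hour."""
    fa = false_alarms(alarm_list, onsets, sop_minutes, sph_minutes)
    denom = interictal_hours - fa.size * refractory_hours
    if denom <= 0:
        raise ValueError("non-positive alarm-capable interictal duration")
    return float(fa.size / denom)


# ---------------------------------------------------------------------------
# forecasting metrics
# ---------------------------------------------------------------------------


def _forecast_mask(high_times: np.ndarray, onsets: np.ndarray, sop_minutes, sph_minutes):
    sph = sph_minutes * 60.0
    pre = (sop_minutes + sph_minutes) * 60.0
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    out = np.zeros(onsets.size, dtype=bool)
    for i, onset in enumerate(onsets):
        out[i] = bool(np.any((high_times >= onset - pre) & (high_times < onset - sph)))
    return out


def forecast_ss(
    risk: RiskSeries | np.ndarray, onsets, sop_minutes: float, sph_minutes: float
) -> float:
    """Fraction of seizures with a high-risk window inside their SOP."""
    high_times = risk.high_times if isinstance(risk, RiskSeries) else np.asarray(risk)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("forecast SS undefined without seizures")
    return float(_forecast_mask(high_times, onsets, sop_minutes, sph_minutes).mean())


def time_in_warning(risk: RiskSeries) -> float:
    """Fraction of windows spent in the high-risk state."""
    if risk.states.size == 0:
        raise ValueError("time in warning undefined for an empty series")
    from .postprocess import RiskState

    return float(np.mean(risk.states == RiskState.HIGH))


def brier(fp: np.ndarray, obs: np.ndarray) -> float:
    """Mean squared error between forecast probabilities and observations."""
    fp = np.asarray(fp, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if fp.shape != obs.shape:
        raise ValueError("forecast and observation lengths differ")
    return float(np.mean((fp - obs) ** 2))


def _surrogate_bs_sample(fp: np.ndarray, obs: np.ndarray, n: int, seed: int) -> np.ndarray:
    """BS of n randomly shuffled forecasts against the fixed observations."""
    rng = np.random.default_rng(seed)
    fp = np.asarray(fp, dtype=float)
    obs = np.asarray(obs, dtype=float)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.mean((rng.permutation(fp) - obs) ** 2)
    return out


def brier_skill(
    fp: np.ndarray, obs: np.ndarray, n_surrogates: int = N_BS_SURROGATES, seed: int = 0
) -> tuple[float, float]:
    """(BSS, BS_ref): skill of the forecast over shuffled-forecast references."""
    bs = brier(fp, obs)
    bs_ref = float(_surrogate_bs_sample(fp, obs, n_surrogates, seed).mean())
    if bs_ref == 0:
        raise ValueError("degenerate forecast/observation pair: BS_ref is zero")
    return 1.0 - bs / bs_ref, bs_ref


# ---------------------------------------------------------------------------
# surrogate statistical validation
# ---------------------------------------------------------------------------


class SurrogatePlacementError(ValueError):
    """Interictal period too short to place surrogate seizure times."""


def _one_sided_better(surrogate: np.ndarray, achieved: float, alpha: float, larger_is_better: bool):
    """One-sample t-test of the surrogate sample against the achieved value.

    Returns True when the achieved value beats the surrogate sample in the
    stated direction with significance alpha.  A zero-variance surrogate
    sample degenerates to a direct comparison of means.
    """
    surrogate = np.asarray(surrogate, dtype=float)
    if np.ptp(surrogate) == 0:
        better = achieved > surrogate[0] if larger_is_better else achieved < surrogate[0]
        return bool(better)
    alternative = "less" if larger_is_better else "greater"
    res = sp_stats.ttest_1samp(surrogate, popmean=achieved, alternative=alternative)
    return bool(res.pvalue < alpha)


def place_surrogate_onsets(
    rng: np.random.Generator,
    window_start: np.ndarray,
    allowed: np.ndarray,
    n_seizures: int,
    preictal_s: float,
    max_tries: int = 100,
) -> np.ndarray:
    """Uniformly re-place seizure onsets within the interictal period.

    A candidate onset is a window start whose full preceding preictal
    (``preictal_s`` seconds) lies in contiguous allowed (valid interictal)
    windows; chosen onsets keep their preictal regions non-overlapping.
    """
    window_start = np.asarray(window_start, dtype=float)
    allowed = np.asarray(allowed, dtype=bool)
    w = max(1, int(round(preictal_s / WINDOW_S)))
    n = allowed.size
    if n < w:
        raise SurrogatePlacementError("test segment shorter than one preictal")
    contiguous = np.concatenate([[True], np.diff(window_start) < WINDOW_S * 1.5])
    ok_win = allowed & contiguous
    c = np.concatenate([[0], np.cumsum(ok_win)])
    # candidate onset index i: preictal windows [i-w, i) all allowed/contiguous
    idx = np.arange(w, n + 1)
    full = (c[idx] - c[idx - w]) == w
    cand = idx[full]  # onset sits at window_start of index i (or segment end)
    if cand.size == 0:
        raise SurrogatePlacementError("no interictal stretch fits a full preictal")
    onset_times = np.where(
        cand < n, window_start[np.minimum(cand, n - 1)], window_start[-1] + WINDOW_S
    )
    for _ in range(max_tries):
        order = rng.permutation(cand.size)
        chosen: list[float] = []
        for j in order:
            t = onset_times[j]
            if all(abs(t - u) >= preictal_s for u in chosen):
                chosen.append(t)
                if len(chosen) == n_seizures:
                    return np.sort(np.asarray(chosen))
    raise SurrogatePlacementError(
        f"could not place {n_seizures} non-overlapping surrogate preictals"
    )


def surrogate_ss_test(
    event_times: np.ndarray,
    onsets,
    window_start: np.ndarray,
    allowed: np.ndarray,
    sop_minutes: float,
    sph_minutes: float,
    mode: str,
    n: int = N_SS_SURROGATES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[bool, float]:
    """Surrogate-seizure-time validation of the achieved seizure sensitivity.

    ``event_times`` is the frozen alarm list (mode="prediction") or the
    frozen high-risk window starts (mode="forecasting"); the classifier is
    not re-run.  Returns (validated, surrogate mean SS).
    """
    if mode not in ("prediction", "forecasting"):
        raise ValueError("mode must be 'prediction' or 'forecasting'")
    score = prediction_ss if mode == "prediction" else forecast_ss
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    achieved = score(np.asarray(event_times, dtype=float), onsets, sop_minutes, sph_minutes)
    rng = np.random.default_rng(seed)
    preictal_s = (sop_minutes + sph_minutes) * 60.0
    surrogate = np.empty(n)
    for i in range(n):
        surr_onsets = place_surrogate_onsets(
            rng, window_start, allowed, onsets.size, preictal_s
        )
        surrogate[i] = score(
            np.asarray(event_times, dtype=float), surr_onsets, sop_minutes, sph_minutes
        )
    validated = _one_sided_better(surrogate, achieved, alpha, larger_is_better=True)
    return validated, float(surrogate.mean())


def surrogate_bs_test(
    fp: np.ndarray,
    obs: np.ndarray,
    n: int = N_BS_SURROGATES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> bool:
    """Shuffled-forecast validation of the achieved Brier score.

    Validated iff the achieved BS is significantly LOWER than the surrogate
    BS sample (lower BS = better forecast; the test direction follows the
    metric).
    """
    achieved = brier(fp, obs)
    surrogate = _surrogate_bs_sample(fp, obs, n, seed)
    return _one_sided_better(surrogate, achieved, alpha, larger_is_better=False)


def ioc(flags) -> float:
    """Improvement over chance: fraction of validated patients."""
    flags = list(flags)
    if not flags:
        raise ValueError("IoC undefined for an empty cohort")
    return float(np.mean([bool(f) for f in flags]))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class PredictionMetrics:
    ss: float
    fpr_per_hour: float
    ss_validated: bool
    surrogate_ss_mean: float


@dataclass
class ForecastingMetrics:
    ss: float
    tiw: float
    bs: float
    bss: float
    bs_ref: float
    ss_validated: bool
    surrogate_ss_mean: float
    bs_validated: bool


@dataclass
class PatientReport:
    """Per-patient outcome of both pipeline branches from one trained model."""

    patient_id: str
    backend: str
    prediction: PredictionMetrics
    forecasting: ForecastingMetrics
    hyperparameters: dict
    n_test_seizures: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "backend": self.backend,
            "prediction": vars(self.prediction).copy(),
            "forecasting": vars(self.forecasting).copy(),
            "hyperparameters": dict(self.hyperparameters),
            "n_test_seizures": self.n_test_seizures,
            "seed": self.seed,
        }


@dataclass
class CohortReport:
    """Cohort mean +/- sd per metric and IoC per surrogate test."""

    n_patients: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    ioc_prediction_ss: float = 0.0
    ioc_forecasting_ss: float = 0.0
    ioc_forecasting_bs: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "means": dict(self.means),
            "sds": dict(self.sds),
            "ioc_prediction_ss": self.ioc_prediction_ss,
            "ioc_forecasting_ss": self.ioc_forecasting_ss,
            "ioc_forecasting_bs": self.ioc_forecasting_bs,
        }

    def to_markdown(self) -> str:
        m, s = self.means, self.sds
        lines = [
            "| branch | metric | mean ± sd |",
            "|---|---|---|",
        ]
        for branch, keys in (
            ("prediction", ("ss", "fpr_per_hour")),
            ("forecasting", ("ss", "tiw", "bs", "bss")),
        ):
            for key in keys:
                name = f"{branch}.{key}"
                lines.append(f"| {branch} | {key} | {m[name]:.3f} ± {s[name]:.3f} |")
        lines.append(
            f"| prediction | IoC (SS) | {100 * self.ioc_prediction_ss:.1f}% |"
        )
        lines.append(
            f"| forecasting | IoC (SS) | {100 * self.ioc_forecasting_ss:.1f}% |"
        )
        lines.append(
            f"| forecasting | IoC (BS) | {100 * self.ioc_forecasting_bs:.1f}% |"
        )
        return "\n".join(lines)


def cohort_report(patients: list[PatientReport]) -> CohortReport:
    """Aggregate patient reports: mean ± sample sd, and the IoC fractions."""
    if not patients:
        raise ValueError("cohort report needs at least one patient")
    metric_values: dict[str, list[float]] = {}
    for p in patients:
        for branch, obj in (("prediction", p.prediction), ("forecasting", p.forecasting)):
            for key, value in vars(obj).items():
                if isinstance(value, (int, float)) and not isinstance(value, bool):
                    metric_values.setdefault(f"{branch}.{key}", []).append(float(value))
    means = {k: float(np.mean(v)) for k, v in metric_values.items()}
    sds = {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in metric_values.items()
    }
    return CohortReport(
        n_patients=len(patients),
        means=means,
        sds=sds,
        ioc_prediction_ss=ioc([p.prediction.ss_validated for p in patients]),
        ioc_forecasting_ss=ioc([p.forecasting.ss_validated for p in patients]),
        ioc_forecasting_bs=ioc([p.forecasting.bs_validated for p in patients]),
    )
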