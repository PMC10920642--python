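"""Window labeling, train/test splitting, normalization and class balancing.

Labeling follows the standard seizure-prediction convention: the preictal
class of each seizure spans SOP + SPH minutes before its onset (the SPH is
the intervention horizon immediately before the seizure; the SOP is the
occurrence period before that).  Windows overlapping the ictal segment or a
postictal buffer are masked invalid rather than assigned to either class,
and so are windows carrying NaN feature sentinels.

The training set holds everything up to the end of the third seizure's
postictal buffer; the remaining seizures form the test set.  Patients with
fewer than four seizures are ineligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

from .features import FeatureMatrix, WINDOW_S
from .synth import SeizureEvent

logger = logging.getLogger(__name__)

DEFAULT_SPH_MINUTES = 10.0
DEFAULT_POSTICTAL_BUFFER_MINUTES = 30.0


class IneligiblePatientError(ValueError):
    """Patient does not meet the >=4 seizure eligibility rule."""


@dataclass
class NormStats:
    """Per-column z-score statistics fitted on training data.

    Zero-variance columns cannot be standardized; they are dropped on apply
    and recorded in ``dropped``.
    """

    mean: np.ndarray
    std: np.ndarray
    kept: np.ndarray  # column indices retained (std > 0)
    dropped: np.ndarray  # column indices removed


@dataclass
class LabeledDataset:
    """A feature matrix with per-window class labels and a validity mask."""

    features: FeatureMatrix
    labels: np.ndarray  # 0 interictal, 1 preictal
    valid_mask: np.ndarray
    seizure_id: np.ndarray  # index of the seizure each window precedes
    seizures: list[SeizureEvent] = field(default_factory=list)
    sop_minutes: float = 30.0
    sph_minutes: float = DEFAULT_SPH_MINUTES
    postictal_buffer_minutes: float = DEFAULT_POSTICTAL_BUFFER_MINUTES

    @property
    def window_start(self) -> np.ndarray:
        return self.features.window_start

    @property
    def n_windows(self) -> int:
        return self.features.n_windows

    def valid_interictal_hours(self) -> float:
        n = int(np.sum(self.valid_mask & (self.labels == 0)))
        return n * WINDOW_S / 3600.0

    def to_csv(self, path) -> None:
        """Write windows (features + label/valid/seizure_id columns) as CSV
        with a JSON sidecar (same path + '.json') for labeling metadata."""
        import json
        from pathlib import Path

        df = self.features.to_frame()
        df["label"] = self.labels
        df["valid"] = self.valid_mask.astype(int)
        df["seizure_id"] = self.seizure_id
        df.to_csv(path, index=False)
        meta = {
            "sop_minutes": self.sop_minutes,
            "sph_minutes": self.sph_minutes,
            "postictal_buffer_minutes": self.postictal_buffer_minutes,
            "seizures": [
                {"onset": s.onset, "offset": s.offset} for s in self.seizures
            ],
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        import json
        from pathlib import Path

        import pandas as pd

        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int)
        valid = df.pop("valid").to_numpy(dtype=int).astype(bool)
        sid = df.pop("seizure_id").to_numpy(dtype=int)
        t = df.pop("window_start_s").to_numpy(dtype=float)
        meta = json.loads(Path(str(path) + ".json").read_text())
        fm = FeatureMatrix(df.to_numpy(dtype=float), t, list(df.columns))
        return cls(
            features=fm,
            labels=labels,
            valid_mask=valid,
            seizure_id=sid,
            seizures=[SeizureEvent(s["onset"], s["offset"]) for s in meta["seizures"]],
            sop_minutes=meta["sop_minutes"],
            sph_minutes=meta["sph_minutes"],
            postictal_buffer_minutes=meta["postictal_buffer_minutes"],
        )


def label_windows(
    fm: FeatureMatrix,
    seizures: list[SeizureEvent],
    sop_minutes: float,
    sph_minutes: float = DEFAULT_SPH_MINUTES,
    postictal_buffer_minutes: float = DEFAULT_POSTICTAL_BUFFER_MINUTES,
) -> LabeledDataset:
    """Label windows preictal/interictal for a given SOP and SPH.

    A window is preictal iff its start lies in ``[onset - (SOP+SPH), onset)``
    (in seconds).  Windows overlapping an ictal segment or the postictal
    buffer, and windows with NaN features, are masked invalid.
    """
    t = fm.window_start
    labels = np.zeros(fm.n_windows, dtype=int)
    valid = np.isfinite(fm.values).all(axis=1)
    preictal_s = (sop_minutes + sph_minutes) * 60.0

    onsets = np.array([s.onset for s in seizures])
    for s in seizures:
        lo = s.onset - preictal_s
        if t.size and lo < t[0] - 1e-9:
            logger.warning(
                "preictal of seizure at %.0f s truncated by recording start", s.onset
            )
        prev = onsets[onsets < s.onset]
        if prev.size and lo < prev.max():
            logger.warning(
                "preictal of seizure at %.0f s truncated by the previous seizure", s.onset
            )
        labels[(t >= lo) & (t < s.onset)] = 1
        # ictal + postictal exclusion: any window overlapping
        # [onset, offset + buffer) is unusable for either class
        hi = s.offset_or_default() + postictal_buffer_minutes * 60.0
        valid &= ~((t + WINDOW_S > s.onset) & (t < hi))

    seizure_id = np.searchsorted(onsets, t, side="right") if onsets.size else np.zeros(
        fm.n_windows, dtype=int
    )
    return LabeledDataset(
        features=fm,
        labels=labels,
        valid_mask=valid,
        seizure_id=seizure_id,
        seizures=list(seizures),
        sop_minutes=sop_minutes,
        sph_minutes=sph_minutes,
        postictal_buffer_minutes=postictal_buffer_minutes,
    )


def _slice(ds: LabeledDataset, row_mask: np.ndarray, seizures: list[SeizureEvent]) -> LabeledDataset:
    fm = FeatureMatrix(
        ds.features.values[row_mask],
        ds.features.window_start[row_mask],
        ds.features.column_names,
    )
    onsets = np.array([s.onset for s in seizures])
    sid = (
        np.searchsorted(onsets, fm.window_start, side="right")
        if onsets.size
        else np.zeros(fm.n_windows, dtype=int)
    )
    return LabeledDataset(
        features=fm,
        labels=ds.labels[row_mask],
        valid_mask=ds.valid_mask[row_mask],
        seizure_id=sid,
        seizures=seizures,
        sop_minutes=ds.sop_minutes,
        sph_minutes=ds.sph_minutes,
        postictal_buffer_minutes=ds.postictal_buffer_minutes,
    )


def split_train_test(
    ds: LabeledDataset, n_train_seizures: int = 3
) -> tuple[LabeledDataset, LabeledDataset]:
    """First-three-seizures split: train up to the end of the 3rd seizure's
    postictal buffer, test on the remainder.  Requires >= 4 seizures."""
    if len(ds.seizures) < n_train_seizures + 1:
        raise IneligiblePatientError(
            f"patient has {len(ds.seizures)} seizures; needs >= {n_train_seizures + 1}"
        )
    last_train = ds.seizures[n_train_seizures - 1]
    boundary = last_train.offset_or_default() + ds.postictal_buffer_minutes * 60.0
    t = ds.window_start
    train = _slice(ds, t < boundary, ds.seizures[:n_train_seizures])
    test = _slice(ds, t >= boundary, ds.seizures[n_train_seizures:])
    return train, test


def zscore_fit(X: np.ndarray) -> NormStats:
    """Column means/SDs of the training matrix; zero-variance columns recorded."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two training windows to fit z-score stats")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # constant columns can carry O(eps) round-off variance; treat as zero
    tiny = 1e-10 * np.maximum(1.0, np.abs(mean))
    kept = np.flatnonzero(std > tiny)
    dropped = np.flatnonzero(std <= tiny)
    if dropped.size:
        logger.warning("dropping %d zero-variance columns: %s", dropped.size, dropped[:10])
    return NormStats(mean=mean, std=std, kept=kept, dropped=dropped)


def zscore_apply(stats: NormStats, X: np.ndarray) -> np.ndarray:
    """Standardize with training statistics only; dropped columns are removed."""
    X = np.asarray(X, dtype=float)
    k = stats.kept
    return (X[:, k] - stats.mean[k]) / stats.std[k]


def class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights w_i = N_total / (2 N_i)."""
    labels = np.asarray(labels)
    n = labels.size
    n1 = int(np.sum(labels == 1))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    return n / (2.0 * n0), n / (2.0 * n1)


def systematic_undersample(labels: np.ndarray, seed: int) -> np.ndarray:
    """Class-balance by systematic random undersampling of the interictal class.

    The time-ordered interictal rows are divided into n contiguous groups
    (n = number of preictal rows; sizes differ by at most one, earliest
    groups larger) and one row is drawn uniformly from each group.  Every
    preictal row is kept.  Returns sorted row indices.
    """
    labels = np.asarray(labels)
    pre_idx = np.flatnonzero(labels == 1)
    inter_idx = np.flatnonzero(labels == 0)
    n = pre_idx.size
    if n == 0:
        raise ValueError("no preictal rows to balance against")
    if inter_idx.size < n:
        logger.warning(
            "fewer interictal (%d) than preictal (%d) rows; keeping all interictal",
            inter_idx.size,
            n,
        )
        return np.sort(np.concatenate([pre_idx, inter_idx]))
    rng = np.random.default_rng(seed)
    picks = [grp[rng.integers(grp.size)] for grp in np.array_split(inter_idx, n)]
    return np.sort(np.concatenate([pre_idx, np.asarray(picks, dtype=int)]))


def _ranked(scores: np.ndarray) -> np.ndarray:
    """Column order by descending score; ties broken by lower column index."""
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    return np.argsort(-scores, kind="stable")


def anova_select(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Top-k columns by the one-way ANOVA F statistic between classes."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} columns")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_scores, _ = f_classif(X, y)
    return _ranked(f_scores)[:k]


def rf_select(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Top-k columns by impurity-based Random-Forest importance (100 trees)."""
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} columns")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    forest = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return _ranked(forest.feature_importances_)[:k]
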