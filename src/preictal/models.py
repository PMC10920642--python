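"""Classifier backends, hyperparameter grid search and the fitted pipeline.

Three patient-specific backends detect the preictal class from z-scored
window features:

``logreg``
    a single class-weighted logistic regression (weights w_i = N/(2 N_i));
``svm15``
    a majority-voting ensemble of 15 linear SVMs, each trained on its own
    systematic-undersample realization of the interictal class, with the
    cost C searched over 2^-10 .. 2^8;
``snn15``
    a majority-voting ensemble of 15 shallow dropout networks (no feature
    selection: the network weighs features itself).

Hyperparameters (the SOP duration for every backend, the number k of
selected features for logreg/svm15, C for svm15) are chosen by grid search
with leave-one-seizure-out cross-validation on the three training seizures:
for every grid point the windows are relabeled at that SOP, each fold trains
on two seizures' windows and validates on the third's, the three validation
confusion matrices are pooled, and the grid point maximizing the geometric
mean of pooled sample sensitivity and specificity wins (ties prefer the
smaller SOP, then k, then C).  Normalization and feature selection are
re-fitted inside each fold on fold-training data only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .dataset import (
    LabeledDataset,
    NormStats,
    anova_select,
    class_weights,
    label_windows,
    rf_select,
    systematic_undersample,
    zscore_apply,
    zscore_fit,
)
from .snn import ShallowNet

logger = logging.getLogger(__name__)

#: Printed hyperparameter grids.
SOP_GRID_MINUTES: tuple[float, ...] = (20, 25, 30, 35, 40, 45, 50)
K_GRID: tuple[int, ...] = (3, 5, 7, 10, 15, 20, 30)
C_GRID: tuple[float, ...] = tuple(2.0**e for e in (-10, -8, -6, -4, -2, 0, 2, 4, 6, 8))

N_ENSEMBLE_MEMBERS = 15

BACKENDS = ("logreg", "svm15", "snn15")


@dataclass(frozen=True)
class Hyperparameters:
    """A point of the printed grids; ``k``/``C`` apply per backend."""

    sop_minutes: float
    k: int | None = None
    C: float | None = None


def geometric_mean(ss_sample: float, sp_sample: float) -> float:
    """sqrt(SS_sample * SP_sample): the grid-search selection criterion."""
    if not (0 <= ss_sample <= 1 and 0 <= sp_sample <= 1):
        raise ValueError("sample sensitivity/specificity must lie in [0, 1]")
    return float(np.sqrt(ss_sample * sp_sample))


def majority_vote(member_outputs: np.ndarray) -> np.ndarray:
    """Per-window majority class over an odd number of member outputs."""
    member_outputs = np.asarray(member_outputs)
    n_members = member_outputs.shape[0]
    if n_members % 2 == 0:
        raise ValueError("majority voting requires an odd member count")
    return (member_outputs.sum(axis=0) * 2 > n_members).astype(int)


def fit_logreg(X: np.ndarray, y: np.ndarray, weights: tuple[float, float]) -> LogisticRegression:
    """Class-weighted binary logistic regression."""
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in training features")
    model = LogisticRegression(
        solver="lbfgs", class_weight={0: weights[0], 1: weights[1]}, max_iter=1000
    )
    model.fit(X, y)
    return model


def _member_subsets(y: np.ndarray, seed: int, n_members: int) -> list[np.ndarray]:
    """One systematic-undersample realization per ensemble member."""
    return [systematic_undersample(y, seed + m) for m in range(n_members)]


def fit_svm_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    seed: int,
    n_members: int = N_ENSEMBLE_MEMBERS,
    subsets: list[np.ndarray] | None = None,
) -> list[LinearSVC]:
    """15 linear SVMs, each on its own class-balanced undersample."""
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in training features")
    if subsets is None:
        subsets = _member_subsets(y, seed, n_members)
    members = []
    for rows in subsets:
        svm = LinearSVC(C=C, dual=False, max_iter=5000)
        svm.fit(X[rows], y[rows])
        members.append(svm)
    return members


def fit_snn_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_members: int = N_ENSEMBLE_MEMBERS,
    hidden_units: int = 32,
    subsets: list[np.ndarray] | None = None,
) -> list[ShallowNet]:
    """15 shallow dropout networks, each on its own balanced undersample."""
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in training features")
    if subsets is None:
        subsets = _member_subsets(y, seed, n_members)
    members = []
    for m, rows in enumerate(subsets):
        net = ShallowNet(hidden_units=hidden_units, seed=seed + m)
        net.fit(X[rows], y[rows])
        members.append(net)
    return members


def _predict_members(members, X: np.ndarray) -> np.ndarray:
    return majority_vote(np.stack([np.asarray(m.predict(X)) for m in members]))


@dataclass
class FittedPipeline:
    """A trained per-patient model: normalization statistics, selected
    feature columns, classifier members and the winning hyperparameters."""

    backend: str
    norm: NormStats
    selected: np.ndarray | None
    members: list
    hyperparameters: Hyperparameters
    sph_minutes: float
    seed: int
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 1 if self.backend == "logreg" else N_ENSEMBLE_MEMBERS
        if len(self.members) != expected:
            raise ValueError(
                f"{self.backend} pipeline must hold {expected} member(s), "
                f"got {len(self.members)}"
            )

    def predict_windows(self, values: np.ndarray) -> np.ndarray:
        """Binary preictal output per window.  Windows with non-finite
        features produce output 0 (they are masked out of metrics anyway)."""
        values = np.asarray(values, dtype=float)
        out = np.zeros(values.shape[0], dtype=int)
        finite = np.isfinite(values).all(axis=1)
        if finite.any():
            X = zscore_apply(self.norm, values[finite])
            if self.selected is not None:
                X = X[:, self.selected]
            if self.backend == "logreg":
                out[finite] = self.members[0].predict(X)
            else:
                out[finite] = _predict_members(self.members, X)
        return out

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "backend": self.backend,
            "hyperparameters": {
                "sop_minutes": self.hyperparameters.sop_minutes,
                "k": self.hyperparameters.k,
                "C": self.hyperparameters.C,
            },
            "sph_minutes": self.sph_minutes,
            "seed": self.seed,
            "training_log": self.training_log,
        }
        (directory / "pipeline.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self, directory / "pipeline.joblib")

    @classmethod
    def load(cls, directory) -> "FittedPipeline":
        return joblib.load(Path(directory) / "pipeline.joblib")


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def _pooled_rates(cm: np.ndarray) -> tuple[float, float]:
    tn, fp, fn, tp = cm
    ss = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    sp = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return ss, sp


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return np.array([tn, fp, fn, tp])


def _grid_points(backend: str, sop_grid, k_grid, c_grid) -> list[Hyperparameters]:
    pts = []
    for sop in sop_grid:
        if backend == "snn15":
            pts.append(Hyperparameters(sop))
        elif backend == "logreg":
            pts.extend(Hyperparameters(sop, k=k) for k in k_grid)
        elif backend == "svm15":
            pts.extend(Hyperparameters(sop, k=k, C=C) for k in k_grid for C in c_grid)
        else:
            raise ValueError(f"unknown backend {backend!r}")
    return pts


def grid_search(
    train: LabeledDataset,
    backend: str,
    seed: int,
    sop_grid=SOP_GRID_MINUTES,
    k_grid=K_GRID,
    c_grid=C_GRID,
    n_members: int = N_ENSEMBLE_MEMBERS,
    hidden_units: int = 32,
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Leave-one-seizure-out grid search on the training seizures.

    Returns the winning grid point and a trace with one row per grid point
    (sop, k, C, pooled sample SS/SP and geometric mean).
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    n_seiz = len(train.seizures)
    if n_seiz < 2:
        raise ValueError("grid search needs at least two training seizures")

    confusions: dict[Hyperparameters, np.ndarray] = {
        hp: np.zeros(4, dtype=int) for hp in _grid_points(backend, sop_grid, k_grid, c_grid)
    }

    for sop_idx, sop in enumerate(sop_grid):
        ds = label_windows(
            train.features,
            train.seizures,
            sop_minutes=sop,
            sph_minutes=train.sph_minutes,
            postictal_buffer_minutes=train.postictal_buffer_minutes,
        )
        sid = np.minimum(ds.seizure_id, n_seiz - 1)
        for fold in range(n_seiz):
            val_rows = ds.valid_mask & (sid == fold)
            tr_rows = ds.valid_mask & (sid != fold)
            y_val = ds.labels[val_rows]
            y_tr = ds.labels[tr_rows]
            if y_val.sum() == 0 or y_tr.sum() == 0 or (y_tr == 0).sum() == 0:
                logger.warning(
                    "fold %d at SOP=%g min lacks preictal windows; skipped", fold, sop
                )
                continue
            norm = zscore_fit(ds.features.values[tr_rows])
            X_tr = zscore_apply(norm, ds.features.values[tr_rows])
            X_val = zscore_apply(norm, ds.features.values[val_rows])
            fold_seed = seed + 7919 * (sop_idx * n_seiz + fold + 1)

            if backend == "logreg":
                ranking = anova_select(X_tr, y_tr, X_tr.shape[1])
                w = class_weights(y_tr)
                for k in k_grid:
                    cols = ranking[: min(k, X_tr.shape[1])]
                    model = fit_logreg(X_tr[:, cols], y_tr, w)
                    cm = _confusion(y_val, model.predict(X_val[:, cols]))
                    confusions[Hyperparameters(sop, k=k)] += cm
            elif backend == "svm15":
                subsets = _member_subsets(y_tr, fold_seed, n_members)
                ranking = rf_select(
                    X_tr[subsets[0]], y_tr[subsets[0]], X_tr.shape[1], fold_seed
                )
                for k in k_grid:
                    cols = ranking[: min(k, X_tr.shape[1])]
                    for C in c_grid:
                        members = fit_svm_ensemble(
                            X_tr[:, cols], y_tr, C, fold_seed, n_members, subsets=subsets
                        )
                        cm = _confusion(y_val, _predict_members(members, X_val[:, cols]))
                        confusions[Hyperparameters(sop, k=k, C=C)] += cm
            else:  # snn15
                members = fit_snn_ensemble(
                    X_tr, y_tr, fold_seed, n_members, hidden_units=hidden_units
                )
                cm = _confusion(y_val, _predict_members(members, X_val))
                confusions[Hyperparameters(sop)] += cm

    rows = []
    best_hp, best_gm = None, -1.0
    for hp, cm in confusions.items():  # insertion order = sorted grid order
        ss, sp = _pooled_rates(cm)
        gm = geometric_mean(ss, sp)
        rows.append(
            {
                "sop_minutes": hp.sop_minutes,
                "k": hp.k,
                "C": hp.C,
                "ss_sample": ss,
                "sp_sample": sp,
                "geometric_mean": gm,
            }
        )
        if gm > best_gm + 1e-12:  # ties keep the earlier (smaller) grid point
            best_hp, best_gm = hp, gm
    trace = pd.DataFrame(rows)
    return best_hp, trace


def final_fit(
    train: LabeledDataset,
    backend: str,
    hp: Hyperparameters,
    seed: int,
    n_members: int = N_ENSEMBLE_MEMBERS,
    hidden_units: int = 32,
) -> FittedPipeline:
    """Refit on all training seizures with the winning hyperparameters."""
    ds = label_windows(
        train.features,
        train.seizures,
        sop_minutes=hp.sop_minutes,
        sph_minutes=train.sph_minutes,
        postictal_buffer_minutes=train.postictal_buffer_minutes,
    )
    rows = ds.valid_mask
    y = ds.labels[rows]
    norm = zscore_fit(ds.features.values[rows])
    X = zscore_apply(norm, ds.features.values[rows])

    selected = None
    log: dict = {}
    if backend == "logreg":
        if hp.k is not None:
            selected = anova_select(X, y, min(hp.k, X.shape[1]))
            X = X[:, selected]
        members = [fit_logreg(X, y, class_weights(y))]
    elif backend == "svm15":
        subsets = _member_subsets(y, seed, n_members)
        if hp.k is not None:
            selected = rf_select(X[subsets[0]], y[subsets[0]], min(hp.k, X.shape[1]), seed)
            X = X[:, selected]
        members = fit_svm_ensemble(X, y, hp.C, seed, n_members, subsets=subsets)
    elif backend == "snn15":
        members = fit_snn_ensemble(X, y, seed, n_members, hidden_units=hidden_units)
        log["epochs"] = [m.n_epochs_ for m in members]
    else:
        raise ValueError(f"unknown backend {backend!r}")

    log["n_train_windows"] = int(rows.sum())
    log["n_preictal"] = int(y.sum())
    return FittedPipeline(
        backend=backend,
        norm=norm,
        selected=selected,
        members=members,
        hyperparameters=hp,
        sph_minutes=train.sph_minutes,
        seed=seed,
        training_log=log,
    )
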