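"""Classifier backends, voting, and grid-search behavior."""

import numpy as np
import pytest

from preictal import (
    C_GRID,
    K_GRID,
    SOP_GRID_MINUTES,
    SynthConfig,
    generate_feature_dataset,
    geometric_mean,
    grid_search,
    label_windows,
    majority_vote,
    split_train_test,
)
from preictal.models import (
    Hyperparameters,
    final_fit,
    fit_logreg,
    fit_snn_ensemble,
    fit_svm_ensemble,
)
from preictal.snn import ShallowNet


def _separable(n=200, seed=0):
    """Linearly separable with margin 2 along the first coordinate."""
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.standard_normal((n, 3))
    X[:, 0] = (2 * y - 1) * 2.0 + rng.uniform(-1, 1, n)
    return X, y


class TestVotingAndGmean:
    def test_majority_count(self):
        votes = np.array([[1] * 8 + [0] * 7]).T.reshape(15, 1)
        assert majority_vote(votes)[0] == 1

    def test_unanimous_and_complement_symmetry(self, rng):
        v = (rng.random((15, 30)) < 0.5).astype(int)
        assert np.array_equal(majority_vote(1 - v), 1 - majority_vote(v))
        assert majority_vote(np.ones((15, 4), dtype=int)).tolist() == [1, 1, 1, 1]

    def test_even_member_count_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros((14, 3), dtype=int))

    def test_geometric_mean_values(self):
        assert geometric_mean(1.0, 1.0) == 1.0
        assert geometric_mean(0.0, 0.73) == 0.0
        assert geometric_mean(0.8, 0.5) == pytest.approx(0.6325, abs=1e-4)
        with pytest.raises(ValueError):
            geometric_mean(1.2, 0.5)


class TestLogreg:
    def test_separable_data_fits_perfectly(self):
        X, y = _separable()
        model = fit_logreg(X, y, (1.0, 1.0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_weight_scale_invariance(self):
        X, y = _separable(seed=3)
        m1 = fit_logreg(X, y, (0.6, 4.0))
        m2 = fit_logreg(X, y, (1.2, 8.0))
        # doubling both weights scales the loss only; same decision boundary
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_label_permutation_gives_chance_accuracy(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 3))
            y = rng.permutation(np.array([0, 1] * 100))
            model = fit_logreg(X[:150], y[:150], (1.0, 1.0))
            accs.append((model.predict(X[150:]) == y[150:]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_non_finite_inputs_rejected(self):
        X, y = _separable()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_logreg(X, y, (1.0, 1.0))


class TestSvmEnsemble:
    def test_fifteen_members_each_balanced_and_agreeing_when_separable(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 300 + [1] * 30)
        X = rng.standard_normal((330, 4))
        X[:, 1] = (2 * y - 1) * 2.0 + rng.uniform(-1, 1, 330)
        members = fit_svm_ensemble(X, y, C=1.0, seed=0)
        assert len(members) == 15
        for m in members:
            assert (m.predict(X) == y).mean() == 1.0

    def test_ensemble_decisions_are_seed_deterministic(self):
        rng = np.random.default_rng(2)
        y = (rng.random(200) < 0.3).astype(int)
        X = rng.standard_normal((200, 5)) + y[:, None]
        d1 = [m.decision_function(X) for m in fit_svm_ensemble(X, y, 0.5, seed=4)]
        d2 = [m.decision_function(X) for m in fit_svm_ensemble(X, y, 0.5, seed=4)]
        assert all(np.array_equal(a, b) for a, b in zip(d1, d2))


class TestSnn:
    def test_training_halts_within_epoch_budget_and_separates(self):
        X, y = _separable(n=120, seed=5)
        net = ShallowNet(seed=0).fit(X, y)
        assert net.n_epochs_ <= 500
        assert (net.predict(X[: int(0.8 * len(X))]) == y[: int(0.8 * len(X))]).mean() > 0.95

    def test_early_stopping_triggers_on_unlearnable_validation(self):
        # trailing validation rows carry random labels: validation loss cannot
        # keep improving, so patience must end training before the budget
        rng = np.random.default_rng(7)
        X, y = _separable(n=200, seed=7)
        y_noise = y.copy()
        y_noise[-40:] = rng.integers(0, 2, 40)
        net = ShallowNet(seed=1).fit(X, y_noise)
        assert net.n_epochs_ < 500

    def test_fit_is_deterministic_given_seed(self):
        X, y = _separable(n=80, seed=9)
        p1 = ShallowNet(seed=3).fit(X, y).predict_proba(X)
        p2 = ShallowNet(seed=3).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_ensemble_has_15_members(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 100 + [1] * 20)
        X = rng.standard_normal((120, 4)) + 2 * y[:, None]
        members = fit_snn_ensemble(X, y, seed=0)
        assert len(members) == 15
        assert all(m.n_epochs_ <= 500 for m in members)


@pytest.fixture(scope="module")
def small_train():
    cfg = SynthConfig(
        interictal_gap_hours=1.2,
        lead_in_hours=1.0,
        tail_hours=0.25,
        effect_size=2.0,
        n_features=12,
        signature_features=("Ch1:rel_power_alpha", "Ch1:rel_power_beta"),
        seed=3,
    )
    fm, seizures = generate_feature_dataset(cfg)
    base = label_windows(fm, seizures, sop_minutes=20)
    train, _ = split_train_test(base)
    return train


class TestGridSearch:
    def test_grid_sizes_per_backend(self, small_train):
        assert len(SOP_GRID_MINUTES) == 7 and len(K_GRID) == 7 and len(C_GRID) == 10
        hp, trace = grid_search(small_train, "logreg", seed=0)
        assert len(trace) == 49
        assert hp.sop_minutes in SOP_GRID_MINUTES and hp.k in K_GRID and hp.C is None

    def test_snn_grid_is_sop_only(self, small_train):
        hp, trace = grid_search(
            small_train, "snn15", seed=0, sop_grid=(20, 30), hidden_units=8
        )
        assert len(trace) == 2
        assert hp.k is None and hp.C is None

    def test_selected_point_maximizes_trace_gmean_with_tie_rule(self, small_train):
        hp, trace = grid_search(small_train, "logreg", seed=1)
        best = trace["geometric_mean"].max()
        winners = trace[np.isclose(trace["geometric_mean"], best)]
        assert hp.sop_minutes == winners["sop_minutes"].min()

    def test_fold_validation_never_leaks_into_training(self, small_train):
        # fold partition by following-seizure id: indices must be disjoint
        sid = np.minimum(small_train.seizure_id, len(small_train.seizures) - 1)
        for fold in range(3):
            val = np.flatnonzero(small_train.valid_mask & (sid == fold))
            tr = np.flatnonzero(small_train.valid_mask & (sid != fold))
            assert len(np.intersect1d(val, tr)) == 0

    def test_final_fit_shapes_and_determinism(self, small_train):
        hp = Hyperparameters(30.0, k=5, C=1.0)
        pipe = final_fit(small_train, "svm15", hp, seed=2)
        assert len(pipe.members) == 15
        assert pipe.selected is not None and pipe.selected.size == 5
        out1 = pipe.predict_windows(small_train.features.values)
        out2 = final_fit(small_train, "svm15", hp, seed=2).predict_windows(
            small_train.features.values
        )
        assert np.array_equal(out1, out2)
        assert set(np.unique(out1)) <= {0, 1}

    def test_null_data_gives_chance_level_sample_performance(self):
        """Without a preictal signature the trained classifier's sample
        sensitivity/specificity geometric mean sits at chance level."""
        fm, seizures = generate_feature_dataset(
            SynthConfig(effect_size=0.0, interictal_gap_hours=1.5, seed=123)
        )
        base = label_windows(fm, seizures, sop_minutes=30)
        train, test = split_train_test(base)
        pipe = final_fit(train, "logreg", Hyperparameters(30.0, k=10), seed=0)
        test_ds = label_windows(test.features, test.seizures, sop_minutes=30)
        out = pipe.predict_windows(test_ds.features.values)
        v = test_ds.valid_mask
        y, o = test_ds.labels[v], out[v]
        ss = (o[y == 1] == 1).mean()
        sp = (o[y == 0] == 0).mean()
        assert 0.35 <= geometric_mean(ss, sp) <= 0.65

    def test_pipeline_round_trips_through_disk(self, small_train, tmp_path):
        from preictal import FittedPipeline

        hp = Hyperparameters(25.0, k=3)
        pipe = final_fit(small_train, "logreg", hp, seed=0)
        pipe.save(tmp_path / "model")
        back = FittedPipeline.load(tmp_path / "model")
        X = small_train.features.values
        assert np.array_equal(back.predict_windows(X), pipe.predict_windows(X))
        assert (tmp_path / "model" / "pipeline.json").exists()
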