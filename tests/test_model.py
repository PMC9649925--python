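"""Split construction, weighted loss, GRU classifier, logistic baseline."""

import numpy as np
import pandas as pd
import pytest

from strokerad import evaluation, model
from strokerad.errors import DataError, ShapeError


class TestBuildSplit:
    def test_undersampling_arithmetic(self):
        labels = np.array([1] * 85 + [0] * 918)
        plan = model.build_split(labels, 57, 100, seed=0)
        assert len(plan.train_idx) == 157
        assert len(plan.test_idx) == 846
        assert plan.n_pos_test == 28 and plan.n_neg_test == 818
        assert np.intersect1d(plan.train_idx, plan.test_idx).size == 0

    def test_empty_train_request(self):
        labels = np.array([1, 0, 0, 1])
        plan = model.build_split(labels, 0, 0, seed=0)
        assert len(plan.train_idx) == 0 and len(plan.test_idx) == 4

    def test_determinism_and_seed_sensitivity(self):
        labels = (np.random.default_rng(0).random(300) < 0.3).astype(int)
        a = model.build_split(labels, 20, 50, seed=5)
        b = model.build_split(labels, 20, 50, seed=5)
        c = model.build_split(labels, 20, 50, seed=6)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)
        assert len(c.train_idx) == 70

    def test_shortfall_reported(self):
        labels = np.array([1] * 10 + [0] * 10)
        with pytest.raises(DataError, match="positives"):
            model.build_split(labels, 11, 5, seed=0)
        with pytest.raises(DataError, match="negatives"):
            model.build_split(labels, 5, 11, seed=0)


class TestWeightedCrossEntropy:
    def test_half_probabilities_give_ln2(self):
        loss = model.weighted_cross_entropy(np.full(8, 0.5), np.array([0, 1] * 4))
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_perfect_predictions_approach_zero(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([1e-9, 1 - 1e-9, 1 - 1e-9, 1e-9])
        assert model.weighted_cross_entropy(p, y) < 1e-6

    def test_positive_weight_scales_positive_contribution(self):
        # 2-sample batch: one positive at p=0.6, one negative at p=0.3
        p = np.array([0.6, 0.3])
        y = np.array([1, 0])
        base_pos = -np.log(0.6) / 2
        base_neg = -np.log(0.7) / 2
        assert model.weighted_cross_entropy(p, y, (1.0, 1.0)) == pytest.approx(base_pos + base_neg)
        assert model.weighted_cross_entropy(p, y, (1.0, 2.0)) == pytest.approx(2 * base_pos + base_neg)

    def test_extreme_probabilities_clamped(self):
        loss = model.weighted_cross_entropy(np.array([0.0, 1.0]), np.array([1, 1]))
        assert np.isfinite(loss)


class TestSequenceLayout:
    def test_radiomic_only_layout(self):
        X = np.arange(2 * 513, dtype=float).reshape(2, 513)
        seq = model.to_sequence(X)
        assert seq.shape == (2, 9, 57)
        np.testing.assert_array_equal(seq[0, 0], X[0, :57])

    def test_combined_layout_pads_clinical_step(self):
        X = np.ones((3, 519))
        seq = model.to_sequence(X)
        assert seq.shape == (3, 10, 57)
        assert seq[0, 9, :6].sum() == 6 and seq[0, 9, 6:].sum() == 0

    def test_bad_width_rejected(self):
        with pytest.raises(ShapeError):
            model.to_sequence(np.ones((2, 100)))


@pytest.fixture(scope="module")
def factor_cohort():
    """Separable cohort with a latent factor expressed in many features,
    the structure phantom radiomics actually has."""
    rng = np.random.default_rng(0)
    n, p = 400, 513
    f = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    loading = np.zeros(p)
    idx = rng.choice(p, 60, replace=False)
    loading[idx] = rng.uniform(0.5, 1.0, 60)
    X = X + np.outer(f, loading)
    y = (f > 0.7).astype(int)
    return X, y


class TestTrainRNN:
    def test_high_snr_cohort_reaches_good_auc(self, factor_cohort):
        X, y = factor_cohort
        tr, te = np.arange(300), np.arange(300, 400)
        cfg = model.RNNConfig(epochs=50, learning_rate=1e-3, seed=0)
        clf = model.train_rnn(X[tr], y[tr], cfg)
        auc = evaluation.auc_mann_whitney(clf.predict(X[te]), y[te])
        assert auc > 0.9

    def test_loss_decreases(self, factor_cohort):
        X, y = factor_cohort
        cfg = model.RNNConfig(epochs=10, learning_rate=1e-3, seed=0)
        clf = model.train_rnn(X[:200], y[:200], cfg)
        h = clf.history["train_loss"]
        assert h[-1] < h[0]

    def test_seed_reproducibility(self, factor_cohort):
        X, y = factor_cohort
        cfg = model.RNNConfig(epochs=5, learning_rate=1e-3, seed=3)
        a = model.train_rnn(X[:150], y[:150], cfg)
        b = model.train_rnn(X[:150], y[:150], cfg)
        np.testing.assert_allclose(a.predict(X[150:200]), b.predict(X[150:200]), atol=1e-12)

    def test_prediction_contracts(self, factor_cohort):
        X, y = factor_cohort
        cfg = model.RNNConfig(epochs=3, learning_rate=1e-3, seed=0)
        clf = model.train_rnn(X[:150], y[:150], cfg)
        p1 = clf.predict(X[150:200])
        assert np.all((p1 >= 0) & (p1 <= 1))
        perm = np.random.default_rng(0).permutation(50)
        np.testing.assert_allclose(clf.predict(X[150:200][perm]), p1[perm], atol=1e-12)
        np.testing.assert_array_equal(clf.predict(X[150:200]), p1)

    def test_imbalance_weighting_beats_constant_predictor(self):
        """With inverse-frequency weights a constant predictor is not
        loss-optimal on imbalanced labels."""
        y = np.array([1] * 10 + [0] * 90)
        cw = (100 / (2 * 90), 100 / (2 * 10))
        const = model.weighted_cross_entropy(np.full(100, 0.1), y, cw)
        informed = model.weighted_cross_entropy(np.where(y == 1, 0.6, 0.2), y, cw)
        assert informed < const


class TestClinicalLogistic:
    def test_odds_ratio_matches_contingency_table(self):
        # single binary covariate, 2x2 counts: (exposed, outcome)
        counts = {(0, 0): 200, (0, 1): 20, (1, 0): 100, (1, 1): 30}
        rows, labels = [], []
        for (x, y), c in counts.items():
            rows += [x] * c
            labels += [y] * c
        X = np.array(rows, dtype=float)[:, None]
        y = np.array(labels)
        clf = model.train_clinical_logistic(X, y, C=1e8)
        fitted_or = np.exp(clf.coef_[0])
        emp_or = (30 / 100) / (20 / 200)
        assert fitted_or == pytest.approx(emp_or, abs=1e-3)

    def test_zero_signal_gives_chance_auc(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((600, 4))
        y = (rng.random(600) < 0.3).astype(int)
        clf = model.train_clinical_logistic(X[:400], y[:400])
        auc = evaluation.auc_mann_whitney(clf.predict(X[400:]), y[400:])
        assert abs(auc - 0.5) < 0.12

    def test_constant_column_does_not_change_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < 0.4).astype(int)
        a = model.train_clinical_logistic(X, y).predict(X)
        Xc = np.hstack([X, np.ones((200, 1))])
        b = model.train_clinical_logistic(Xc, y).predict(Xc)
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(DataError):
            model.train_clinical_logistic(X, np.array([0, 1]))
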