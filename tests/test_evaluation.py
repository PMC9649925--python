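"""ROC/AUC, DeLong test, threshold metrics, decision curves."""

import numpy as np
import pytest

from strokerad import evaluation
from strokerad.errors import DataError, ParameterError


def auc_pair_counting(scores, labels):
    """Independent oracle: explicit double loop over pos-neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestROCAUC:
    def test_worked_example(self):
        assert evaluation.auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_ranking(self):
        r = evaluation.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_label_complement_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        assert evaluation.auc_mann_whitney(s, 1 - y) == pytest.approx(
            1 - evaluation.auc_mann_whitney(s, y))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        s = np.round(rng.random(30), 1)  # rounding forces ties
        y = np.array([0] * 15 + [1] * 15)
        assert evaluation.auc_mann_whitney(s, y) == pytest.approx(
            auc_pair_counting(s, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.random(50)
        y = (rng.random(50) < 0.3).astype(int)
        a = evaluation.auc_mann_whitney(s, y)
        b = evaluation.auc_mann_whitney(np.exp(3 * s), y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_ordering_and_bounds(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 20)])
        y = np.array([0] * 50 + [1] * 20)
        r = evaluation.roc_auc(s, y)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            evaluation.roc_auc([0.1, 0.2], [1, 1])

    def test_delong_se_close_to_hanley_mcneil(self):
        """DeLong variance within 20% of the Hanley-McNeil closed form on
        balanced normal scores."""
        rng = np.random.default_rng(3)
        n = 200
        s = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        y = np.array([0] * n + [1] * n)
        r = evaluation.roc_auc(s, y)
        a = r.auc
        q1 = a / (2 - a)
        q2 = 2 * a ** 2 / (1 + a)
        hm_var = (a * (1 - a) + (n - 1) * (q1 - a ** 2) + (n - 1) * (q2 - a ** 2)) / (n * n)
        x = s[y == 1]; yn = s[y == 0]
        v10, v01 = evaluation._placements(x, yn)
        dl_var = v10.var(ddof=1) / n + v01.var(ddof=1) / n
        assert dl_var == pytest.approx(hm_var, rel=0.2)


class TestDeLongTest:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        p, diff = evaluation.delong_test(s, s, y)
        assert p == 1.0 and diff == 0.0

    def test_agrees_with_bootstrap_oracle(self):
        """Two-sided DeLong p vs a 10,000-draw bootstrap of the AUC
        difference on an n=30 instance, within Monte-Carlo error."""
        rng = np.random.default_rng(4)
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        latent = np.where(y == 1, 1.2, 0.0)
        a = latent + rng.normal(0, 1, n)
        b = 0.3 * latent + rng.normal(0, 1, n)
        p_delong, _ = evaluation.delong_test(a, b, y)
        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.sum() in (0, n):
                continue
            diffs.append(evaluation.auc_mann_whitney(a[idx], yy)
                         - evaluation.auc_mann_whitney(b[idx], yy))
        diffs = np.asarray(diffs)
        observed = (evaluation.auc_mann_whitney(a, y)
                    - evaluation.auc_mann_whitney(b, y))
        # bootstrap normal-approximation p for H0: diff = 0
        from scipy import stats
        z = observed / diffs.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        assert p_delong == pytest.approx(p_boot, abs=0.1)

    def test_separation_increase_lowers_p(self):
        """Raising model A's separation at fixed B decreases the DeLong p
        on average over replicates."""
        rng = np.random.default_rng(5)
        n = 200
        y = np.array([0] * 150 + [1] * 50)
        mean_p = []
        for sep in (0.3, 1.5):
            ps = []
            for _ in range(10):
                a = sep * y + rng.normal(0, 1, n)
                b = 0.3 * y + rng.normal(0, 1, n)
                ps.append(evaluation.delong_test(a, b, y)[0])
            mean_p.append(np.mean(ps))
        assert mean_p[1] < mean_p[0]


class TestConfusionMetrics:
    def test_hand_examples(self):
        # scores (0.2, 0.6, 0.7), labels (0, 0, 1): at t = 0.65 only the true
        # positive crosses the threshold
        m = evaluation.confusion_metrics([0.2, 0.6, 0.7], [0, 0, 1], 0.65)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        # at t = 0.5 the 0.6-scoring negative becomes a false positive
        m = evaluation.confusion_metrics([0.2, 0.6, 0.7], [0, 0, 1], 0.5)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5
        assert m["accuracy"] == pytest.approx(2 / 3)

    def test_threshold_extremes(self):
        s = np.array([0.2, 0.4, 0.9])
        y = np.array([0, 1, 1])
        assert evaluation.confusion_metrics(s, y, 0.0)["sensitivity"] == 1.0
        assert evaluation.confusion_metrics(s, y, 1.1)["specificity"] == 1.0

    def test_youden_threshold_maximizes_j(self):
        rng = np.random.default_rng(0)
        s = np.concatenate([rng.normal(0, 1, 100), rng.normal(1.5, 1, 40)])
        y = np.array([0] * 100 + [1] * 40)
        t = evaluation.youden_threshold(s, y)
        m = evaluation.confusion_metrics(s, y, t)
        j_star = m["sensitivity"] + m["specificity"] - 1
        for tt in np.unique(s):
            mm = evaluation.confusion_metrics(s, y, tt)
            assert j_star >= mm["sensitivity"] + mm["specificity"] - 1 - 1e-12


class TestDecisionCurve:
    def _cohort(self, prevalence=0.085, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < prevalence).astype(int)
        return y

    def test_treat_none_is_zero(self):
        y = self._cohort()
        grid = np.arange(0.05, 0.5, 0.05)
        c = evaluation.decision_curve(np.random.default_rng(1).random(len(y)), y, grid)
        assert np.all(c.nb_treat_none == 0)

    def test_treat_all_vanishes_at_prevalence_threshold(self):
        # exactly pi positives out of N: treat-all NB at t = pi is 0
        n, k = 1000, 85
        y = np.array([1] * k + [0] * (n - k))
        pi = k / n
        c = evaluation.decision_curve(np.zeros(n), y, np.array([pi]))
        assert c.nb_treat_all[0] == pytest.approx(pi - (1 - pi) * pi / (1 - pi), abs=1e-12)
        assert abs(c.nb_treat_all[0]) < 1e-12

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.array([1] * 85 + [0] * 915)
        scores = y.astype(float)
        grid = np.arange(0.1, 0.9, 0.1)
        c = evaluation.decision_curve(scores, y, grid)
        np.testing.assert_allclose(c.nb_model, 0.085, atol=1e-12)

    def test_model_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(2)
        y = self._cohort(seed=3)
        c = evaluation.decision_curve(rng.random(len(y)), y, np.arange(0.01, 0.99, 0.01))
        assert (c.nb_model <= y.mean() + 1e-12).all()

    def test_grid_validation(self):
        y = np.array([0, 1])
        with pytest.raises(ParameterError):
            evaluation.decision_curve([0.1, 0.9], y, np.array([0.5, 1.0]))
        with pytest.raises(ParameterError):
            evaluation.decision_curve([0.1, 0.9], y, np.array([0.0, 0.5]))
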