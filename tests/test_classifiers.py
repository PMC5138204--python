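"""MDM and SWLDA classifiers and K-command selection."""

import numpy as np
import pytest
from scipy import stats

from riemerp.classifiers import (
    MDM,
    SWLDA,
    command_select,
    decimate_epochs,
    mdm_fit,
    mdm_predict,
    swlda_command_select,
    swlda_fit,
    swlda_predict,
)
from riemerp.geometry import riemannian_distance
from riemerp.preprocessing import NONTARGET, TARGET

from conftest import random_spd


def cluster_covs(rng, center, n, jitter=0.01, d=4):
    """SPD cluster: small symmetric perturbations around a center."""
    out = []
    for _ in range(n):
        e = jitter * rng.standard_normal((d, d))
        out.append(center + 0.5 * (e + e.T) + jitter * d * np.eye(d))
    return out


class TestMDM:
    def test_singleton_class_means_equal_inputs(self, rng):
        a, b = random_spd(rng, 3), random_spd(rng, 3)
        model = mdm_fit([a, b], [TARGET, NONTARGET])
        np.testing.assert_allclose(model.covmeans_[0], a, rtol=1e-8)
        np.testing.assert_allclose(model.covmeans_[1], b, rtol=1e-8)
        assert list(model.counts_) == [1, 1]

    def test_duplicated_training_set_same_means(self, rng):
        covs = [random_spd(rng, 3) for _ in range(4)]
        labels = [TARGET, TARGET, NONTARGET, NONTARGET]
        m1 = mdm_fit(covs, labels)
        m2 = mdm_fit(covs + covs, labels + labels)
        np.testing.assert_allclose(m1.covmeans_, m2.covmeans_, rtol=1e-6)

    def test_separable_clusters_perfect_training_accuracy(self, rng):
        c1, c2 = np.eye(4), 100.0 * np.eye(4)  # far apart under delta_R
        covs = cluster_covs(rng, c1, 10) + cluster_covs(rng, c2, 10)
        labels = [TARGET] * 10 + [NONTARGET] * 10
        model = MDM().fit(np.stack(covs), labels)
        assert np.array_equal(model.predict(np.stack(covs)), labels)

    def test_predict_mean_itself(self, rng):
        model = mdm_fit([random_spd(rng, 3), random_spd(rng, 3)], [TARGET, NONTARGET])
        assert mdm_predict(model.covmeans_[0], model) == TARGET

    def test_tie_goes_to_smaller_label(self, rng):
        a = np.eye(3)
        model = mdm_fit([a, a], [TARGET, NONTARGET])  # both means identical
        assert mdm_predict(random_spd(rng, 3), model) == TARGET

    def test_agrees_with_bruteforce_enumeration(self, rng):
        covs = [random_spd(rng, 3) for _ in range(6)]
        labels = [TARGET, NONTARGET, TARGET, NONTARGET, TARGET, NONTARGET]
        model = mdm_fit(covs, labels)
        for _ in range(50):
            c = random_spd(rng, 3)
            dists = [riemannian_distance(m, c) for m in model.covmeans_]
            expected = model.classes_[int(np.argmin(dists))]
            assert mdm_predict(c, model) == expected

    def test_decision_congruence_invariant(self, rng):
        covs = np.stack([random_spd(rng, 3) for _ in range(8)])
        labels = np.array([TARGET, NONTARGET] * 4)
        tests = np.stack([random_spd(rng, 3) for _ in range(10)])
        base = MDM().fit(covs, labels).predict(tests)
        w = rng.standard_normal((3, 3)) + np.eye(3)
        congr = lambda arr: np.einsum("ij,njk,kl->nil", w.T, arr, w)
        moved = MDM().fit(congr(covs), labels).predict(congr(tests))
        np.testing.assert_array_equal(base, moved)

    def test_dimension_mismatch_errors(self, rng):
        model = mdm_fit([random_spd(rng, 3), random_spd(rng, 3)], [TARGET, NONTARGET])
        with pytest.raises(ValueError, match="dimension mismatch"):
            model.predict(np.stack([np.eye(4)]))

    def test_missing_class_errors(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            MDM().fit(np.stack([random_spd(rng, 3)] * 3), [TARGET] * 3)


class TestCommandSelect:
    def _model(self, rng, d=3):
        c_t, c_nt = np.eye(d), 50.0 * np.eye(d)
        covs = cluster_covs(rng, c_t, 5, d=d) + cluster_covs(rng, c_nt, 5, d=d)
        return mdm_fit(covs, [TARGET] * 5 + [NONTARGET] * 5), c_t, c_nt

    def test_attended_code_decided(self, rng):
        model, c_t, c_nt = self._model(rng)
        for attended in range(1, 6):
            trial_covs = {
                c: (c_t if c == attended else c_nt) + 0.01 * np.eye(3) for c in range(1, 6)
            }
            decision = command_select(trial_covs, model)
            assert decision.decided_command == attended
            assert decision.scores[attended - 1] == decision.scores.max()

    def test_all_identical_ties_to_code_one(self, rng):
        model, c_t, _ = self._model(rng)
        decision = command_select({c: c_t for c in range(1, 6)}, model)
        assert decision.decided_command == 1

    def test_code_set_mismatch_errors(self, rng):
        model, c_t, _ = self._model(rng)
        with pytest.raises(ValueError, match="one covariance per code"):
            command_select({1: c_t, 3: c_t}, model)


class TestSWLDA:
    def _noise_problem(self, rng, n=60, f=20, effect=6.0):
        x = rng.standard_normal((n, f))
        y = np.where(rng.random(n) < 0.5, TARGET, NONTARGET)
        x[:, 7] += effect * np.where(y == TARGET, 1.0, -1.0)
        return x, y

    def test_separating_feature_selected_first(self, rng):
        x, y = self._noise_problem(rng)
        model = swlda_fit(x, y)
        assert model.selected_features_[0] == 7

    def test_null_features_enter_at_p_enter_rate(self, rng):
        # step-1 candidate test: on pure noise the fraction of features with
        # partial-F p < p_enter should approximate p_enter; checked against an
        # independent Pearson-correlation oracle over many label permutations
        n, f = 40, 30
        counts = []
        for _ in range(200):
            x = rng.standard_normal((n, f))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            p = np.array([stats.pearsonr(x[:, j], y).pvalue for j in range(f)])
            counts.append(np.sum(p < 0.10))
        mean_entering = np.mean(counts)
        assert 0.5 * 0.10 * f <= mean_entering <= 1.5 * 0.10 * f
        # and SWLDA's own entry decision agrees with the oracle's minimum:
        x = rng.standard_normal((n, f))
        y_lab = np.where(rng.random(n) < 0.5, TARGET, NONTARGET)
        z = np.where(y_lab == TARGET, 1.0, -1.0)
        p = np.array([stats.pearsonr(x[:, j], z).pvalue for j in range(f)])
        model = SWLDA(max_features=1).fit(x, y_lab)
        if p.min() < 0.10:
            assert list(model.selected_features_) == [int(np.argmin(p))]
        else:
            assert len(model.selected_features_) == 0

    def test_empty_selection_majority_fallback(self, rng):
        # constant features cannot enter; model falls back to majority class
        x = np.ones((20, 5))
        y = np.array([TARGET] * 5 + [NONTARGET] * 15)
        model = swlda_fit(x, y)
        assert len(model.selected_features_) == 0
        assert np.all(swlda_predict(x, model) == NONTARGET)

    def test_zero_score_is_nontarget(self):
        model = SWLDA()
        model.selected_features_ = np.array([0])
        model.weights_ = np.array([1.0])
        model.intercept_ = 0.0
        model.n_features_in_ = 1
        model.classes_ = np.array([TARGET, NONTARGET])
        assert swlda_predict(np.array([[0.0]]), model)[0] == NONTARGET

    def test_training_rescore_deterministic(self, rng):
        x, y = self._noise_problem(rng)
        model = swlda_fit(x, y)
        first = swlda_predict(x, model)
        second = swlda_predict(x, model)
        np.testing.assert_array_equal(first, second)

    def test_decision_function_matches_matrix_oracle(self, rng):
        x, y = self._noise_problem(rng)
        model = swlda_fit(x, y)
        scores = model.decision_function(x)
        oracle = x[:, model.selected_features_] @ model.weights_ + model.intercept_
        np.testing.assert_allclose(scores, oracle, atol=1e-12)

    def test_max_features_respected(self, rng):
        x = rng.standard_normal((100, 50))
        y = np.where(rng.random(100) < 0.5, TARGET, NONTARGET)
        model = SWLDA(p_enter=0.9, p_remove=0.95, max_features=5).fit(x, y)
        assert len(model.selected_features_) <= 5
        assert len(np.unique(model.selected_features_)) == len(model.selected_features_)

    def test_feature_length_mismatch_errors(self, rng):
        x, y = self._noise_problem(rng)
        model = swlda_fit(x, y)
        with pytest.raises(ValueError, match="feature length"):
            model.decision_function(np.zeros((2, x.shape[1] + 1)))

    def test_command_selection_argmax(self, rng):
        x, y = self._noise_problem(rng)
        model = swlda_fit(x, y)
        feats = {c: x[c] for c in range(1, 6)}
        decision = swlda_command_select(feats, model)
        scores = model.decision_function(np.stack([x[c] for c in range(1, 6)]))
        assert decision.decided_command == int(np.argmax(scores)) + 1


class TestDecimate:
    def test_bin_means_and_shape(self):
        fs = 256.0  # 20 ms bins -> 5 samples per bin, 51 bins of 256
        epochs = np.arange(2 * 256, dtype=float).reshape(1, 2, 256)
        out = decimate_epochs(epochs, fs)
        assert out.shape == (1, 2 * 51)
        assert out[0, 0] == pytest.approx(np.mean(np.arange(5)))

    def test_single_epoch_vector(self):
        out = decimate_epochs(np.zeros((2, 256)), 256.0)
        assert out.shape == (2 * 51,)
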