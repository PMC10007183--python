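"""RFE, SVM cross-validation, permutation testing and condition contrast."""

import numpy as np
import pandas as pd
import pytest

from fatiguefc.bands import BETA
from fatiguefc.classify import (
    FatigueClassifier,
    LabeledFeatures,
    condition_contrast,
    feature_count_sweep,
    grid_search_svm,
    permutation_pvalue,
    permutation_test,
    repeated_twofold_cv,
    rfe_select,
)
from fatiguefc.connectivity import ConnectivityMatrix
from fatiguefc.parcellation import Atlas


def _paired(X, n_subjects):
    y = np.tile([0, 1], n_subjects)
    sid = np.repeat([f"S{i:02d}" for i in range(n_subjects)], 2)
    return LabeledFeatures(X, y, sid)


@pytest.fixture()
def null_features(rng):
    return _paired(rng.standard_normal((48, 30)), 24)


@pytest.fixture()
def separable_features(rng):
    X = rng.standard_normal((48, 10))
    y = np.tile([0, 1], 24)
    X[:, 7] += 6.0 * y  # one feature carries the class cleanly
    return _paired(X, 24)


class TestLabeledFeatures:
    def test_from_dataframe(self):
        df = pd.DataFrame({
            "subject_id": ["S1", "S1", "S2", "S2"],
            "condition": ["alert", "fatigue", "alert", "fatigue"],
            "f1": [0.0, 1.0, 0.1, 0.9],
        })
        lf = LabeledFeatures.from_dataframe(df)
        assert lf.n_samples == 4 and lf.n_features == 1
        np.testing.assert_array_equal(lf.y, [0, 1, 0, 1])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            LabeledFeatures(np.array([[np.nan]]), [1], ["S1"])


class TestRFE:
    def test_keep_13pct_of_2278_is_296(self, rng):
        data = _paired(rng.standard_normal((96, 2278)), 48)
        selected, ranking = rfe_select(data, keep_fraction=0.13,
                                       step_fraction=0.05)
        assert selected.size == 296
        assert ranking.shape == (2278,)
        assert np.all(ranking[selected] == 1)

    def test_keep_all_is_identity(self, null_features):
        selected, _ = rfe_select(null_features, keep_fraction=1.0)
        np.testing.assert_array_equal(selected, np.arange(30))

    def test_separating_feature_survives_aggressive_selection(self, rng):
        kept = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((48, 50))
            y = np.tile([0, 1], 24)
            X[:, 13] = 4.0 * y + 0.1 * r.standard_normal(48)
            data = _paired(X, 24)
            sel, _ = rfe_select(data, keep_fraction=0.02)
            kept += 13 in sel
        assert kept >= 19

    def test_zero_keep_rejected(self, null_features):
        with pytest.raises(ValueError):
            rfe_select(null_features, keep_fraction=1e-9)


class TestGridSearch:
    def test_singleton_grid_chosen(self, separable_features):
        clf, params = grid_search_svm(separable_features.X, separable_features.y,
                                      grid={"kernel": ["linear"], "C": [2.0]})
        assert params == {"kernel": "linear", "C": 2.0}

    def test_separable_data_perfect_training_fit(self, separable_features):
        clf, _ = grid_search_svm(separable_features.X, separable_features.y,
                                 grid={"kernel": ["linear"], "C": [1.0, 10.0]})
        assert clf.score(separable_features.X, separable_features.y) == 1.0

    def test_tie_broken_by_grid_order(self, separable_features):
        # identical entries must tie; the first wins
        clf, params = grid_search_svm(
            separable_features.X, separable_features.y,
            grid=[{"kernel": ["linear"], "C": [3.0]},
                  {"kernel": ["linear"], "C": [3.0]}])
        assert params["C"] == 3.0

    def test_empty_grid_rejected(self, separable_features):
        with pytest.raises(ValueError, match="empty"):
            grid_search_svm(separable_features.X, separable_features.y, grid=[])


class TestRepeatedCV:
    def test_metric_identities_per_repetition(self, separable_features):
        res = repeated_twofold_cv(separable_features, n_reps=10, seed=0)
        # accuracy = (sens * P + spec * N) / (P + N) with balanced classes
        np.testing.assert_allclose(
            res.accuracy, 0.5 * (res.sensitivity + res.specificity), atol=1e-12)

    def test_separable_data_high_accuracy(self, separable_features):
        res = repeated_twofold_cv(separable_features, n_reps=10, seed=0)
        assert res.accuracy_mean > 0.95

    def test_null_features_near_chance(self, rng):
        data = _paired(rng.standard_normal((96, 30)), 48)
        res = repeated_twofold_cv(data, n_reps=50, seed=1,
                                  svm_params={"kernel": "linear", "C": 1.0})
        se = np.sqrt(0.25 / 96)
        assert abs(res.accuracy_mean - 0.5) < 3 * se

    def test_subject_pairs_never_split(self, separable_features):
        from fatiguefc.classify import _subject_twofold_split

        rng_local = np.random.default_rng(0)
        for _ in range(50):
            a, b = _subject_twofold_split(separable_features, rng_local, True)
            sa = set(separable_features.subject_ids[a])
            sb = set(separable_features.subject_ids[b])
            assert not (sa & sb)

    def test_confusion_metric_formulas(self):
        """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
        (TP+TN)/total, via a degenerate always-fatigue predictor."""
        X = np.zeros((48, 3))  # featureless: the SVM predicts one constant class
        data = _paired(X, 24)
        res = repeated_twofold_cv(data, n_reps=5, seed=0,
                                  svm_params={"kernel": "linear", "C": 1.0})
        # degenerate constant predictions give sens + spec = 1 on balanced data
        np.testing.assert_allclose(res.sensitivity + res.specificity, 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(res.accuracy, 0.5, atol=1e-12)

    def test_summary_mentions_metrics(self, separable_features):
        res = repeated_twofold_cv(separable_features, n_reps=3, seed=0)
        text = res.summary()
        for word in ("sensitivity", "specificity", "accuracy"):
            assert word in text


class TestModelInterface:
    def test_fit_returns_results_with_model_backref(self, separable_features):
        model = FatigueClassifier(separable_features,
                                  svm_params={"kernel": "linear", "C": 1.0})
        res = model.fit(n_reps=5, seed=0)
        assert res.model is model
        assert res.n_repetitions == 5

    def test_from_dataframe_roundtrip(self, rng):
        df = pd.DataFrame(rng.standard_normal((8, 2)), columns=["a", "b"])
        df.insert(0, "subject_id", np.repeat(["S1", "S2", "S3", "S4"], 2))
        df.insert(1, "condition", np.tile(["alert", "fatigue"], 4))
        model = FatigueClassifier.from_dataframe(df)
        assert model.features.n_features == 2


class TestPermutation:
    def test_pvalue_definition(self):
        assert permutation_pvalue(0.9, np.array([0.5, 0.6, 0.95, 0.7])) == 0.25
        assert permutation_pvalue(1.0, np.zeros(10)) == 0.0
        assert permutation_pvalue(0.0, np.ones(10)) == 1.0

    def test_strong_signal_small_p(self, separable_features):
        res = permutation_test(separable_features, n_perm=49, n_reps=3, seed=0,
                               svm_params={"kernel": "linear", "C": 1.0})
        assert res.p_value < 0.05
        assert res.observed > 0.9
        assert res.p_smoothed == pytest.approx(
            (np.sum(res.null_distribution > res.observed) + 1) / 50)

    def test_permutations_respect_pairing(self, separable_features):
        # permuted label vectors always keep one alert + one fatigue per subject
        data = separable_features
        rng_local = np.random.default_rng(0)
        subjects = np.unique(data.subject_ids)
        for _ in range(20):
            flip = subjects[rng_local.random(subjects.size) < 0.5]
            y_perm = np.where(np.isin(data.subject_ids, flip), 1 - data.y, data.y)
            for s in subjects:
                assert set(y_perm[data.subject_ids == s]) == {0, 1}


class TestFeatureSweep:
    def test_sweep_finds_informative_fraction(self, rng):
        X = rng.standard_normal((48, 100))
        y = np.tile([0, 1], 24)
        X[:, 3] += 4.0 * y
        data = _paired(X, 24)
        table = feature_count_sweep(data, [1, 50], n_reps=5, seed=0)
        assert table.loc[1, "accuracy"] > 0.9
        assert list(table.index) == [1, 50]
        assert table.loc[1, "n_features"] == 1

    def test_invalid_percentage_rejected(self, null_features):
        with pytest.raises(ValueError):
            feature_count_sweep(null_features, [0])


def _matrices(values_list):
    names = ["roi1", "roi2", "roi3"]
    out = []
    for v in values_list:
        m = np.zeros((3, 3))
        m[1, 0] = m[0, 1] = v[0]
        m[2, 0] = m[0, 2] = v[1]
        m[2, 1] = m[1, 2] = v[2]
        out.append(ConnectivityMatrix(m, BETA, "source", names))
    return out


class TestConditionContrast:
    def _atlas(self):
        return Atlas(["roi1", "roi2", "roi3"], np.array([0, 1, 2]),
                     {"roi1": "frontal", "roi2": "frontal", "roi3": "parietal"})

    def test_identical_conditions_all_zero(self):
        ms = _matrices([[0.2, 0.3, 0.4]] * 2)
        rep = condition_contrast(ms, ms, [0, 1, 2], self._atlas())
        assert rep.n_increased == rep.n_decreased == 0
        assert rep.n_zero == 3

    def test_uniform_increase_counted(self):
        alert = _matrices([[0.2, 0.3, 0.4]] * 2)
        fatigue = _matrices([[0.3, 0.4, 0.5]] * 2)
        rep = condition_contrast(alert, fatigue, [0, 1, 2], self._atlas())
        assert rep.n_increased == 3 and rep.n_decreased == 0
        np.testing.assert_allclose(rep.differences, 0.1)

    def test_lobe_shares_and_intra_inter(self):
        alert = _matrices([[0.2, 0.3, 0.4]])
        fatigue = _matrices([[0.1, 0.4, 0.5]])
        rep = condition_contrast(alert, fatigue, [0, 1, 2], self._atlas())
        # pairs: (roi2,roi1) frontal-frontal; (roi3,roi1), (roi3,roi2) parietal-frontal
        assert rep.n_intra == 1 and rep.n_inter == 2
        assert rep.intra_by_lobe == {"frontal": 1}
        assert rep.lobe_shares["frontal"] == pytest.approx(4 / 6)
        assert rep.lobe_shares["parietal"] == pytest.approx(2 / 6)
        assert sum(rep.lobe_shares.values()) == pytest.approx(1.0)
        df = rep.to_dataframe()
        assert set(df.columns) == {"roi_a", "roi_b", "lobe_a", "lobe_b",
                                   "difference", "direction"}

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            condition_contrast(_matrices([[0.1, 0.1, 0.1]]), [], [0], self._atlas())
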