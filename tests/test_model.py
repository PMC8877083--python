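import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from deltarad import model as M
from deltarad.errors import ParameterError, SchemaError


class TestSplits:
    def test_stratified_sizes_50_patients(self):
        y = np.array([1] * 25 + [0] * 25)
        splits = M.make_splits(y, seed=0, n_reps=10)
        for tr, va, te in splits.repetitions:
            assert len(te) == 10 and y[te].sum() == 5
            assert len(tr) == 28 and y[tr].sum() == 14
            assert len(va) == 12 and y[va].sum() == 6

    def test_partition_contract(self):
        y = np.array([1] * 13 + [0] * 17)
        splits = M.make_splits(y, seed=3, n_reps=5)
        for tr, va, te in splits.repetitions:
            allidx = np.concatenate([tr, va, te])
            assert len(allidx) == 30
            assert len(np.unique(allidx)) == 30

    def test_same_seed_identical(self):
        y = np.array([1] * 10 + [0] * 10)
        s1 = M.make_splits(y, seed=42, n_reps=4)
        s2 = M.make_splits(y, seed=42, n_reps=4)
        for a, b in zip(s1.repetitions, s2.repetitions):
            for u, v in zip(a, b):
                np.testing.assert_array_equal(u, v)

    def test_tiny_class_rejected(self):
        with pytest.raises(ParameterError):
            M.make_splits(np.array([1, 0, 0, 0]), seed=0)


class TestZscore:
    def test_hand_arithmetic(self):
        mean, sd = M.zscore_fit(np.array([[1.0], [2.0], [3.0]]))
        z = M.zscore_apply(np.array([[1.0], [2.0], [3.0]]), mean, sd)
        np.testing.assert_allclose(z.ravel(), [-1.2247448, 0.0, 1.2247448], rtol=1e-6)

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        mean, sd = M.zscore_fit(X)
        z = M.zscore_apply(X, mean, sd)
        assert (z[:, 0] == 0).all()

    def test_test_set_mean_not_zero(self):
        train = np.array([[0.0], [1.0], [2.0]])
        mean, sd = M.zscore_fit(train)
        z = M.zscore_apply(np.array([[10.0], [11.0]]), mean, sd)
        assert abs(z.mean()) > 1


class TestWhitelist:
    def test_subset_in_whitelist_order(self):
        t = pd.DataFrame(np.arange(6).reshape(2, 3), columns=["a", "b", "c"])
        out = M.apply_stability_whitelist(t, ["c", "a"])
        assert list(out.columns) == ["c", "a"]

    def test_none_is_identity(self):
        t = pd.DataFrame(np.zeros((2, 3)), columns=list("abc"))
        assert M.apply_stability_whitelist(t, None) is t

    @pytest.mark.parametrize("wl", [["a", "a"], ["nope"]])
    def test_bad_whitelists_rejected(self, wl):
        t = pd.DataFrame(np.zeros((2, 3)), columns=list("abc"))
        with pytest.raises(SchemaError):
            M.apply_stability_whitelist(t, wl)


class TestWilcoxonPreselect:
    def test_identical_feature_excluded_separated_included(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 10 + [0] * 10)
        X = np.column_stack(
            [
                np.ones(20),                       # identical in both classes
                np.concatenate([np.arange(10) + 100, np.arange(10)]),  # separated
                rng.normal(size=20),               # noise
            ]
        )
        keep = M.wilcoxon_preselect(X, y)
        assert 1 in keep and 0 not in keep

    def test_type_one_error_rate(self):
        """Null features are selected at roughly the nominal alpha."""
        rng = np.random.default_rng(5)
        y = np.array([1] * 13 + [0] * 13)
        hits, total = 0, 0
        for _ in range(20):
            X = rng.normal(size=(26, 200))
            keep = M.wilcoxon_preselect(X, y)
            hits += len(keep)
            total += 200
        assert 0.02 < hits / total < 0.09

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            M.wilcoxon_preselect(np.zeros((4, 2)), np.ones(4))


class TestPca:
    def test_two_uncorrelated_unit_features_need_both(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        pca = M.pca_fit(X, var_threshold=0.97)
        assert pca.k97 == 2

    def test_rank_one_data_single_component(self):
        t = np.linspace(0, 1, 30).reshape(-1, 1)
        X = t @ np.array([[1.0, 2.0, -1.0]])
        pca = M.pca_fit(X)
        assert pca.k97 == 1

    def test_orthonormal_loadings_and_threshold(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10)) * np.linspace(3, 0.1, 10)
        pca = M.pca_fit(X, var_threshold=0.97)
        G = pca.components @ pca.components.T
        np.testing.assert_allclose(G, np.eye(pca.k97), atol=1e-10)
        cum = pca.explained_variance_ratio.sum()
        assert cum >= 0.97
        assert cum - pca.explained_variance_ratio[-1] < 0.97


def _toy_components(rng, n_comp, beta_scale=0.8, ntr=20, nva=12):
    ytr = np.array([0, 1] * (ntr // 2))
    yva = np.array([0, 1] * (nva // 2))
    beta = rng.normal(0, 1, n_comp) * (rng.random(n_comp) < 0.6)
    Ztr = rng.normal(0, 1, (ntr, n_comp)) + beta_scale * np.outer(ytr, beta)
    Zva = rng.normal(0, 1, (nva, n_comp)) + beta_scale * np.outer(yva, beta)
    return Ztr, Zva, ytr, yva


class TestSffs:
    def test_single_informative_component_found_first(self):
        rng = np.random.default_rng(3)
        ytr = np.array([0, 1] * 15)
        yva = np.array([0, 1] * 8)
        Ztr = rng.normal(0, 1, (30, 6)) * 0.2
        Zva = rng.normal(0, 1, (16, 6)) * 0.2
        Ztr[:, 4] += 3.0 * ytr
        Zva[:, 4] += 3.0 * yva
        sel = M.sffs_select(Ztr, Zva, ytr, yva)
        assert sel[0] == 4

    def test_matches_exhaustive_optimum_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_comp = int(rng.integers(2, 6))
            Ztr, Zva, ytr, yva = _toy_components(rng, n_comp)
            sel = M.sffs_select(Ztr, Zva, ytr, yva)

            def acc(sub):
                svm = SVC(kernel="linear", C=1.0).fit(Ztr[:, list(sub)], ytr)
                return (svm.predict(Zva[:, list(sub)]) == yva).mean()

            best = max(acc(c) for c in itertools.combinations(range(n_comp), len(sel)))
            assert acc(sel) == pytest.approx(best)

    def test_all_noise_small_selection(self):
        rng = np.random.default_rng(9)
        Ztr, Zva, ytr, yva = _toy_components(rng, 5, beta_scale=0.0)
        sel = M.sffs_select(Ztr, Zva, ytr, yva)
        assert 1 <= len(sel) <= 5


class TestSvm:
    def test_linearly_separable_training_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [6, 5]])
        y = np.array([0, 0, 1, 1])
        svm = M.train_svm(X, y)
        assert (svm.predict(X) == y).all()
        assert (M.score(svm, X) > 0).tolist() == [False, False, True, True]

    def test_hard_margin_decision_values(self):
        """Against the closed-form max-margin separator on 6 points."""
        X = np.array([[-2.0, 0], [-3, 1], [-2.5, -1], [2.0, 0], [3, 1], [2.5, -1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        svm = M.train_svm(X, y, C=1e6)
        # optimal separator is x1 = 0 with margin 2 -> |f| >= 1 on all points
        s = M.score(svm, X)
        assert (np.abs(s) >= 1 - 1e-6).all()
        np.testing.assert_allclose(s[3], 1.0, atol=1e-3)  # support vector at margin

    def test_one_class_rejected(self):
        with pytest.raises(ParameterError):
            M.train_svm(np.zeros((3, 2)), np.zeros(3))


class TestPipeline:
    def test_informative_cohort_recovers_signal(self, feature_cohort):
        _, tables, labels, _ = feature_cohort
        tab = tables["adc"]
        y = labels.loc[tab.index].to_numpy()
        splits = M.make_splits(y, seed=2, n_reps=8)
        rec, met, models = M.run_modality_pipeline(tab, labels, splits, modality="adc")
        assert met[met.role == "test"].auc.mean() > 0.8
        for m in models:
            assert set(m.sffs_components) <= set(range(m.pca.k97))

    def test_determinism(self, feature_cohort):
        _, tables, labels, _ = feature_cohort
        tab = tables["t1w"].iloc[:, :60]
        splits = M.make_splits(labels.to_numpy(), seed=5, n_reps=3)
        r1, m1, _ = M.run_modality_pipeline(tab, labels, splits, modality="x")
        r2, m2, _ = M.run_modality_pipeline(tab, labels, splits, modality="x")
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_one_test_record_per_patient_repetition(self, feature_cohort):
        _, tables, labels, _ = feature_cohort
        tab = tables["t2w"].iloc[:, :40]
        splits = M.make_splits(labels.to_numpy(), seed=8, n_reps=4)
        rec, _, _ = M.run_modality_pipeline(tab, labels, splits, modality="t2w")
        test = rec[rec.role == "test"]
        assert not test.duplicated(["patient_id", "repetition"]).any()
        for rep, (_, _, te) in enumerate(splits.repetitions):
            got = set(test[test.repetition == rep].patient_id)
            assert got == set(tab.index[te])

    def test_no_leakage_from_test_rows(self, feature_cohort):
        """Perturbing test rows must not change any train-fitted parameter."""
        _, tables, labels, _ = feature_cohort
        tab = tables["t2w"].iloc[:, :100]
        y = labels.to_numpy()
        X = tab.to_numpy()
        splits = M.make_splits(y, seed=11, n_reps=3)
        for tr, va, te in splits.repetitions:
            m1 = M.fit_one_repetition(X, y, tr, va)
            X2 = X.copy()
            X2[te] += np.random.default_rng(0).normal(0, 100, size=X2[te].shape)
            m2 = M.fit_one_repetition(X2, y, tr, va)
            np.testing.assert_array_equal(m1.zscore_mean, m2.zscore_mean)
            np.testing.assert_array_equal(m1.zscore_sd, m2.zscore_sd)
            np.testing.assert_array_equal(m1.preselected, m2.preselected)
            np.testing.assert_array_equal(m1.pca.components, m2.pca.components)
            assert m1.sffs_components == m2.sffs_components
            np.testing.assert_array_equal(m1.svm_coef, m2.svm_coef)
            assert m1.svm_intercept == m2.svm_intercept
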