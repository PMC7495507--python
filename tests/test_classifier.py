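"""SAE feature pool, Fisher selection, linear SVM and double cross-validation."""

import numpy as np
import pytest

from conftest import roc_auc_bruteforce
from neuromse.classifier import (CVConfig, SAEParams, SparseAutoencoder,
                                 apply_selector, build_feature_pool, double_cv,
                                 fisher_score, fit_outer_fold, roc_auc,
                                 select_features, stratified_folds,
                                 train_linear_svm, train_sae)


def gaussian_cohort(n_per_group=15, n_regions=4, shift=0.0, seed=0,
                    temporal=(0, 1)):
    """Feature-level cohort: (subjects, regions, 60) with an optional
    group shift planted in the temporal regions."""
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((2 * n_per_group, n_regions, 60))
    for r in temporal:
        F[n_per_group:, r, :15] += shift
    y = np.array(["HC"] * n_per_group + ["AD"] * n_per_group)
    return F, y


class TestFisherScore:
    def test_hand_computed_example(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_score(X, y)[0] == pytest.approx(4.0)

    def test_equal_class_means_score_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        assert fisher_score(X, np.array([0, 0, 1, 1]))[0] == 0.0

    def test_label_indicator_dominates_pool(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 30))
        X[:, 7] = y
        scores = fisher_score(X, y)
        assert np.argmax(scores) == 7

    def test_zero_variance_feature_scores_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        scores = fisher_score(X, np.repeat([0, 1], 4))
        assert scores[0] == 0.0


class TestRocAuc:
    def test_perfectly_ordered_and_inverted(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_enumerated_example(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels) == 0.75

    def test_matches_bruteforce_and_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.standard_normal(30), 1)  # induce ties
            mine = roc_auc(s, y)
            assert mine == pytest.approx(roc_auc_bruteforce(s, y))
            assert mine == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestSparseAutoencoder:
    def test_overcomplete_linear_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 60))
        sae = SparseAutoencoder(n_hidden=60, l1_coeff=0.0, epochs=400,
                                learning_rate=0.02, activation="linear",
                                seed=1).fit(X)
        mse = np.mean((sae.reconstruct(X) - X) ** 2)
        assert mse < 0.01 * X.var()

    def test_sparsity_penalty_shrinks_activations(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 20))
        grid = [0.0, 0.1, 1.0, 10.0]
        medians = []
        for l1 in grid:
            acts = []
            for seed in range(5):
                sae = SparseAutoencoder(n_hidden=10, l1_coeff=l1, epochs=150,
                                        learning_rate=0.02, seed=seed).fit(X)
                acts.append(np.mean(np.abs(sae.encode(X))))
            medians.append(np.median(acts))
        assert all(b <= a + 1e-6 for a, b in zip(medians, medians[1:]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 10))
        a = SparseAutoencoder(n_hidden=5, epochs=50, seed=9).fit(X)
        b = SparseAutoencoder(n_hidden=5, epochs=50, seed=9).fit(X)
        assert np.array_equal(a.encode(X), b.encode(X))

    def test_default_geometry_matches_architecture(self):
        params = SAEParams()
        assert params.n_autoencoders == 300
        assert params.n_hidden == 70

    def test_nonfinite_input_rejected(self):
        X = np.full((20, 5), np.nan)
        with pytest.raises(ValueError):
            train_sae(X, SAEParams(n_hidden=3, epochs=5))


class TestFeaturePool:
    def test_dimensional_bookkeeping(self):
        rng = np.random.default_rng(5)
        F = rng.standard_normal((6, 4, 60))
        params = SAEParams(n_autoencoders=2, n_hidden=3, epochs=20)
        pool, bank = build_feature_pool(F, params)
        assert pool.shape == (6, 4, 6)  # 2 SAEs x 3 nodes per (subject, region)
        assert len(bank) == 2

    def test_same_seed_identical_pool(self):
        rng = np.random.default_rng(6)
        F = rng.standard_normal((5, 3, 60))
        params = SAEParams(n_autoencoders=2, n_hidden=4, epochs=20, seed=3)
        a, _ = build_feature_pool(F, params)
        b, _ = build_feature_pool(F, params)
        assert np.array_equal(a, b)


class TestSelectFeatures:
    def test_identity_selection_at_full_k(self):
        rng = np.random.default_rng(7)
        pool = rng.standard_normal((20, 3, 5))
        y = np.repeat([0, 1], 10)
        selector, _ = select_features(pool, y, k=15, region_subset=[0, 1, 2])
        assert selector.shape == (15, 2)
        pairs = {tuple(p) for p in selector.tolist()}
        assert len(pairs) == 15

    def test_planted_feature_always_ranked_first(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pool = rng.standard_normal((30, 2, 10))
            y = np.repeat([0, 1], 15)
            pool[:, 1, 4] = y * 10.0 + rng.standard_normal(30) * 0.01
            selector, _ = select_features(pool, y, k=3, region_subset=[0, 1])
            assert tuple(selector[0]) == (1, 4)

    def test_k_capped_to_available(self):
        rng = np.random.default_rng(8)
        pool = rng.standard_normal((10, 2, 3))
        y = np.repeat([0, 1], 5)
        selector, _ = select_features(pool, y, k=100, region_subset=[0])
        assert selector.shape[0] == 3

    def test_selection_restricted_to_region_subset(self):
        rng = np.random.default_rng(9)
        pool = rng.standard_normal((20, 3, 4))
        y = np.repeat([0, 1], 10)
        pool[:, 2, 0] = y * 100.0  # huge effect OUTSIDE the subset
        selector, _ = select_features(pool, y, k=8, region_subset=[0, 1])
        assert set(selector[:, 0].tolist()) <= {0, 1}


class TestLinearSvm:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(-3, 0.3, (20, 5)),
                       rng.normal(3, 0.3, (20, 5))])
        y = np.repeat([0, 1], 20)
        clf = train_linear_svm(X, y, C=1.0)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_margin_violations_nonincreasing_in_c(self):
        medians = []
        for C in (1e-3, 1e-2, 1e-1, 1.0):
            counts = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                X = np.vstack([rng.normal(-0.5, 1, (25, 4)),
                               rng.normal(0.5, 1, (25, 4))])
                y = np.repeat([0, 1], 25)
                clf = train_linear_svm(X, y, C=C)
                margin = clf.decision_function(X) * (2 * y - 1)
                counts.append(int((margin < 1).sum()))
            medians.append(np.median(counts))
        assert all(b <= a for a, b in zip(medians, medians[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.eye(4), np.zeros(4), C=0.1)

    def test_default_search_ranges(self):
        cfg = CVConfig()
        assert cfg.k_range == (100, 10000)
        assert cfg.c_range == (1e-3, 1.0)
        assert cfg.n_folds == 5
        assert cfg.n_repeats == 300


def small_cv(n_repeats=4, seed=0):
    return CVConfig(n_repeats=n_repeats, search_budget=5, seed=seed,
                    k_range=(10, 120),
                    sae=SAEParams(n_autoencoders=3, n_hidden=6, epochs=60))


class TestDoubleCv:
    def test_separated_cohort_classified(self):
        F, y = gaussian_cohort(shift=2.0, seed=11)
        rep = double_cv(F, y, temporal_regions=[0, 1], config=small_cv(),
                        architecture="sae_fs_svm")
        assert rep.summary()["auc"]["mean"] > 0.9

    def test_metrics_bounded_and_accuracy_identity(self):
        F, y = gaussian_cohort(shift=1.0, seed=12)
        rep = double_cv(F, y, temporal_regions=[0, 1], config=small_cv(),
                        architecture="fs_svm")
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = getattr(rep, name)
            assert np.all(vals[np.isfinite(vals)] >= 0)
            assert np.all(vals[np.isfinite(vals)] <= 1)

    def test_fold_assignment_stratified(self):
        rng = np.random.default_rng(13)
        y = np.repeat([0, 1], 20)
        folds = stratified_folds(y, 5, rng)
        for f in range(5):
            sel = folds == f
            assert (y[sel] == 1).sum() == (y[sel] == 0).sum() == 4

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(14)
        F, y = gaussian_cohort(shift=2.0, seed=15)
        y_perm = rng.permutation(y)
        rep = double_cv(F, y_perm, temporal_regions=[0, 1],
                        config=small_cv(n_repeats=6, seed=1),
                        architecture="fs_svm")
        aucs = rep.auc[np.isfinite(rep.auc)]
        sd = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * max(sd, 0.05)

    def test_no_leakage_from_test_fold(self):
        """Poisoning subjects outside train/validation leaves the fitted
        model and the chosen hyperparameters unchanged."""
        F, y = gaussian_cohort(shift=1.0, seed=16)
        labels01 = (y == "AD").astype(int)
        train_idx = np.arange(0, 18)
        val_idx = np.arange(18, 24)
        test_idx = np.arange(24, 30)
        cfg = small_cv()
        bundle_clean = fit_outer_fold(F, labels01, train_idx, val_idx,
                                      [0, 1], "sae_fs_svm", cfg,
                                      np.random.default_rng(7))
        F_poisoned = F.copy()
        F_poisoned[test_idx] = 1e6
        bundle_poisoned = fit_outer_fold(F_poisoned, labels01, train_idx,
                                         val_idx, [0, 1], "sae_fs_svm", cfg,
                                         np.random.default_rng(7))
        assert bundle_clean["hyperparams"] == bundle_poisoned["hyperparams"]
        assert np.array_equal(bundle_clean["model"]["clf"].coef_,
                              bundle_poisoned["model"]["clf"].coef_)
        dec_clean, _ = bundle_clean["predict"](train_idx)
        dec_poisoned, _ = bundle_poisoned["predict"](train_idx)
        assert np.array_equal(dec_clean, dec_poisoned)

    def test_architectures_share_folds_when_given(self):
        F, y = gaussian_cohort(shift=1.5, seed=17)
        labels01 = (y == "AD").astype(int)
        rng = np.random.default_rng(3)
        folds = np.stack([stratified_folds(labels01, 5, rng)
                          for _ in range(2)])
        cfg = small_cv(n_repeats=2)
        reps = {arch: double_cv(F, y, [0, 1], config=cfg, architecture=arch,
                                fold_assignments=folds)
                for arch in ("svm", "fs_svm")}
        assert reps["svm"].auc.shape == reps["fs_svm"].auc.shape

    def test_too_few_subjects_rejected(self):
        F, y = gaussian_cohort(n_per_group=2, seed=18)
        with pytest.raises(ValueError):
            double_cv(F, y, [0], config=small_cv())

    def test_undefined_cells_imputed_from_training_fold(self):
        F, y = gaussian_cohort(shift=2.0, seed=19)
        F[5, 0, 3] = np.nan
        rep = double_cv(F, y, temporal_regions=[0, 1],
                        config=small_cv(n_repeats=2), architecture="fs_svm")
        assert np.isfinite(rep.auc).any()
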