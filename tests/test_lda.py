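import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from flyvep.exceptions import (
    DegenerateClassError,
    InvalidInputError,
    NoFeaturesRetainedError,
    SingularCovarianceError,
)
from flyvep.lda import (
    ShrinkageLDA,
    fit_lda,
    kfold_loss,
    loo_accuracy,
    optimize_regularization,
    predict,
    stratified_group_folds,
)

from conftest import gaussian_two_class


class TestFitPredict:
    def test_midpoint_hyperplane_geometry(self):
        # two spherical classes, means at 0 and (2,0,...): the boundary is
        # the mid-hyperplane, so x1=0.9 belongs to the first class
        rng = np.random.default_rng(0)
        n, p = 200, 6
        X = rng.normal(size=(2 * n, p))
        X[n:, 0] += 2.0
        y = np.array([0] * n + [1] * n)
        clf = ShrinkageLDA(gamma=0.0, delta=0.0).fit(X, y)
        x = np.zeros(p)
        x[0] = 0.9
        assert predict(clf, x) == 0
        x[0] = 1.2
        assert predict(clf, x) == 1

    def test_class_mean_classified_to_own_class(self, two_class_separable):
        X, y = two_class_separable
        clf = fit_lda(X, y, gamma=0.1)
        assert predict(clf, X[y == "a"].mean(axis=0)) == "a"
        assert predict(clf, X[y == "b"].mean(axis=0)) == "b"

    def test_equidistant_point_breaks_tie_to_first_label(self):
        # antisymmetric construction: negating both coordinates swaps the
        # classes, so the origin scores identically for both; the first
        # label in sorted order wins
        X = np.array([[-3.0, 1], [-1, -1], [1, 1], [3, -1]])
        y = np.array(["a", "a", "b", "b"])
        clf = ShrinkageLDA(gamma=0.5, delta=0.0).fit(X, y)
        scores = clf.decision_function(np.zeros((1, 2)))
        assert np.allclose(scores[0, 0], scores[0, 1])
        assert clf.predict(np.zeros((1, 2)))[0] == "a"

    def test_training_accuracy_on_well_separated_clusters(self):
        # well-separated 2-d clusters embedded in 64-d
        rng = np.random.default_rng(4)
        n = 25
        X = rng.normal(size=(2 * n, 64)) * 0.3
        X[:n, :2] += [0, 0]
        X[n:, :2] += [5, 5]
        y = np.array(["A"] * n + ["B"] * n)
        clf = ShrinkageLDA(gamma=0.5, delta=0.0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_singular_covariance_raises_without_shrinkage(self):
        X, y = gaussian_two_class(seed=1, n_per=20, p=64)
        with pytest.raises(SingularCovarianceError):
            ShrinkageLDA(gamma=0.0, delta=0.0).fit(X, y)

    def test_pinv_mode_fits_singular_raw_data_with_rank_warning(self):
        X, y = gaussian_two_class(seed=1, n_per=20, p=64)
        with pytest.warns(RuntimeWarning, match="rank"):
            clf = ShrinkageLDA(gamma=0.0, delta=0.0, singular="pinv").fit(X, y)
        assert clf.rank_ <= 38
        assert len(clf.predict(X)) == 40

    def test_any_positive_gamma_regularizes_singular_covariance(self):
        X, y = gaussian_two_class(seed=2, n_per=20, p=64)
        clf = ShrinkageLDA(gamma=0.1, delta=0.0).fit(X, y)
        assert clf.rank_ == 64

    def test_delta_above_all_coefficients_is_an_error(self, two_class_separable):
        X, y = two_class_separable
        with pytest.raises(NoFeaturesRetainedError):
            ShrinkageLDA(gamma=0.5, delta=1e9).fit(X, y)

    def test_delta_prunes_features_and_reports_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 20))
        y = np.array(["a", "b"] * 30)
        X[y == "b", 0] += 4.0  # single informative feature
        clf = ShrinkageLDA(gamma=0.3, delta=0.0).fit(X, y)
        big = ShrinkageLDA(gamma=0.3,
                           delta=0.5 * clf.coef_magnitudes_.max()).fit(X, y)
        assert big.n_components_ < 20
        assert big.retained_mask_[0]

    def test_degenerate_class_rejected(self):
        X = np.zeros((3, 4))
        y = np.array(["a", "a", "b"])
        with pytest.raises(DegenerateClassError):
            ShrinkageLDA().fit(X, y)

    def test_non_finite_input_rejected(self, two_class_separable):
        X, y = two_class_separable
        clf = ShrinkageLDA(gamma=0.2).fit(X, y)
        bad = X[0].copy()
        bad[3] = np.nan
        with pytest.raises(InvalidInputError):
            predict(clf, bad)

    def test_sklearn_params_round_trip(self):
        clf = ShrinkageLDA(gamma=0.25, delta=0.5)
        params = clf.get_params()
        assert params["gamma"] == 0.25 and params["delta"] == 0.5
        clf.set_params(gamma=0.75)
        assert clf.gamma == 0.75

    def test_retained_count_bounds(self, two_class_separable):
        X, y = two_class_separable
        clf = ShrinkageLDA(gamma=0.4, delta=0.0).fit(X, y)
        assert 1 <= clf.n_components_ <= X.shape[1]


class TestOracleEquivalence:
    def test_matches_closed_form_fisher_rule_on_random_instances(self):
        # gamma=0, delta=0 with nonsingular covariance must reproduce the
        # classical pooled-covariance discriminant exactly
        rng = np.random.default_rng(42)
        agree = total = 0
        for _ in range(100):
            n_per, p = 15, 5
            X = rng.normal(size=(2 * n_per, p))
            X[n_per:] += rng.normal(0, 0.6, size=p)
            y = np.array([0] * n_per + [1] * n_per)
            ours = ShrinkageLDA(gamma=0.0, delta=0.0).fit(X, y)
            ref = LinearDiscriminantAnalysis().fit(X, y)
            Xt = rng.normal(size=(30, p))
            agree += int(np.sum(ours.predict(Xt) == ref.predict(Xt)))
            total += 30
        assert agree == total


class TestCrossValidation:
    def test_loo_is_perfect_on_separated_clusters(self, two_class_separable):
        X, y = two_class_separable
        assert loo_accuracy(X, y, gamma=0.2) == 1.0

    def test_permutation_null_is_near_chance(self):
        # permuting labels on separable low-dimensional data: mean LOO
        # accuracy over permutations sits near 0.5
        rng = np.random.default_rng(0)
        X, y = gaussian_two_class(seed=10, n_per=30, p=2, shift=4.0)
        accs = []
        for _ in range(150):
            yp = rng.permutation(y)
            try:
                accs.append(loo_accuracy(X, yp, gamma=0.5))
            except DegenerateClassError:
                continue
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_loo_fold_failure_names_the_fold(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["a", "a", "b", "b", "b"])
        # leaving out either 'a' row empties the class below 2 members
        with pytest.raises(DegenerateClassError, match="fold"):
            loo_accuracy(X, y, gamma=1.0)

    def test_kfold_loss_bounds(self, two_class_separable):
        X, y = two_class_separable
        loss = kfold_loss(X, y, gamma=0.3, k_folds=5)
        assert 0.0 <= loss <= 1.0

    def test_stratified_folds_hold_out_one_fly_per_class(self):
        y_idx = np.array([0] * 6 + [1] * 6)
        groups = np.array([0, 0, 1, 1, 2, 2, 10, 10, 11, 11, 12, 12])
        folds = stratified_group_folds(y_idx, groups, None)
        assert len(folds) == 3
        for f in folds:
            held = set(f)
            assert len(held & {0, 1, 2}) == 1
            assert len(held & {10, 11, 12}) == 1


class TestOptimizeRegularization:
    def test_recovers_informative_features(self):
        # 5 informative features among 64 noise features at n=40: the
        # selected model keeps all 5 and prunes the rest
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 64))
            y = np.array(["a"] * 20 + ["b"] * 20)
            X[20:, :5] += 2.0
            gamma, delta, n_comp, _ = optimize_regularization(X, y, seed=seed)
            clf = ShrinkageLDA(gamma=gamma, delta=delta).fit(X, y)
            retained = set(np.flatnonzero(clf.retained_mask_))
            if n_comp < 64 and {0, 1, 2, 3, 4} <= retained:
                hits += 1
        assert hits >= 4

    def test_diagonal_limit_matches_independent_feature_rule(self):
        # gamma=1, delta=0: the classifier must equal the closed-form
        # diagonal (independent-feature) discriminant
        X, y = gaussian_two_class(seed=5, n_per=20, p=6, shift=1.0)
        clf = ShrinkageLDA(gamma=1.0, delta=0.0).fit(X, y)
        mu0, mu1 = X[:20].mean(0), X[20:].mean(0)
        var = (np.vstack([X[:20] - mu0, X[20:] - mu1]) ** 2).sum(0) / (40 - 2)
        scores = np.stack([
            X @ (mu0 / var) - 0.5 * mu0 @ (mu0 / var) + np.log(0.5),
            X @ (mu1 / var) - 0.5 * mu1 @ (mu1 / var) + np.log(0.5),
        ], axis=1)
        expected = np.array(["a", "b"])[scores.argmax(axis=1)]
        np.testing.assert_array_equal(clf.predict(X), expected)

    def test_cv_loss_is_a_valid_rate(self, two_class_separable):
        X, y = two_class_separable
        *_, loss = optimize_regularization(
            X, y, gamma_grid=[0.2, 0.8], n_delta=4, k_folds=5, seed=0
        )
        assert 0.0 <= loss <= 1.0
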