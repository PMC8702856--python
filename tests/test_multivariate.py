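"""Sparse PLS-DA, keepX tuning and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cazytyping import multivariate as mv


def dense_pls2_nipals(x, y_dummy, n_components, max_iter=5000, tol=1e-13):
    """Independent dense PLS2 oracle (NIPALS iteration, regression deflation)."""
    x = x.copy()
    y = y_dummy.copy()
    weights, scores = [], []
    for _ in range(n_components):
        u = y[:, 0].copy()
        w_prev = None
        for _ in range(max_iter):
            w = x.T @ u
            w /= np.linalg.norm(w)
            t = x @ w
            c = y.T @ t / (t @ t)
            u = y @ c / (c @ c)
            if w_prev is not None and np.linalg.norm(w - w_prev) < tol:
                break
            w_prev = w
        t = x @ w
        p = x.T @ t / (t @ t)
        c = y.T @ t / (t @ t)
        x = x - np.outer(t, p)
        y = y - np.outer(t, c)
        weights.append(w)
        scores.append(t)
    return np.array(weights).T, np.array(scores).T


def standardized(rng, n, p):
    x = rng.normal(size=(n, p))
    return (x - x.mean(0)) / x.std(0, ddof=1)


def two_class_labels(n):
    return np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))


class TestFitSplsda:
    def test_dense_limit_equals_nipals_oracle(self):
        """With keepX = all features, sparse PLS-DA reduces to dense PLS-DA."""
        for seed, (n, p) in [(0, (10, 6)), (1, (20, 10))]:
            rng = np.random.default_rng(seed)
            x = standardized(rng, n, p)
            y = two_class_labels(n)
            model = mv.fit_splsda(x, y, keepx=p, n_components=3)
            y_dummy = mv._dummy_matrix(y, model.classes)
            w_oracle, t_oracle = dense_pls2_nipals(x, y_dummy, 3)
            for h in range(3):
                sign = np.sign(model.x_weights[:, h] @ w_oracle[:, h])
                np.testing.assert_allclose(
                    model.x_weights[:, h], sign * w_oracle[:, h], atol=1e-8
                )
                np.testing.assert_allclose(
                    model.scores[:, h], sign * t_oracle[:, h], atol=1e-8
                )

    def test_keepx_one_selects_the_informative_feature(self):
        """Exhaustive check: the sole non-zero loading is the feature whose
        class-mean separation dominates all others."""
        rng = np.random.default_rng(12)
        n, p = 20, 5
        y = two_class_labels(n)
        x = rng.normal(size=(n, p))
        x[y == "b", 2] += 4.0  # single informative feature
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        model = mv.fit_splsda(x, y, keepx=1, n_components=1)
        nonzero = np.flatnonzero(model.x_weights[:, 0])
        y_dummy = mv._dummy_matrix(y, model.classes)
        cross = np.linalg.norm(x.T @ y_dummy, axis=1)
        assert list(nonzero) == [int(np.argmax(cross))] == [2]

    def test_keepx_bounds_respected(self):
        rng = np.random.default_rng(3)
        x = standardized(rng, 16, 8)
        y = two_class_labels(16)
        model = mv.fit_splsda(x, y, keepx=[3, 5], n_components=2)
        assert (np.count_nonzero(model.x_weights[:, 0])) <= 3
        assert (np.count_nonzero(model.x_weights[:, 1])) <= 5
        np.testing.assert_allclose(np.linalg.norm(model.x_weights, axis=0), 1.0)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        x = standardized(rng, 14, 6)
        model = mv.fit_splsda(x, two_class_labels(14), keepx=6, n_components=2)
        for h in range(2):
            w = model.x_weights[:, h]
            assert w[np.argmax(np.abs(w))] > 0

    def test_whole_dataset_duplication_symmetry(self):
        """Duplicating every sample (and label) leaves loadings unchanged."""
        rng = np.random.default_rng(5)
        x = standardized(rng, 20, 10)
        y = two_class_labels(20)
        m1 = mv.fit_splsda(x, y, keepx=10, n_components=2)
        m2 = mv.fit_splsda(
            np.vstack([x, x]), np.concatenate([y, y]), keepx=10, n_components=2
        )
        for h in range(2):
            sign = np.sign(m1.x_weights[:, h] @ m2.x_weights[:, h])
            np.testing.assert_allclose(
                m1.x_weights[:, h], sign * m2.x_weights[:, h], atol=1e-8
            )

    def test_single_class_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="two classes"):
            mv.fit_splsda(standardized(rng, 8, 4), ["a"] * 8, keepx=2)

    def test_keepx_below_one_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="keepX"):
            mv.fit_splsda(standardized(rng, 8, 4), two_class_labels(8), keepx=0)


class TestPredictSplsda:
    def test_separable_training_error_zero(self):
        rng = np.random.default_rng(7)
        n = 16
        y = two_class_labels(n)
        x = rng.normal(size=(n, 4))
        x[y == "b", 0] += 8.0
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        model = mv.fit_splsda(x, y, keepx=4, n_components=2)
        for distance in ("max_dist", "centroids", "mahalanobis"):
            assert (mv.predict_splsda(model, x, distance) == y).all()

    def test_max_dist_matches_hand_dummy_thresholding(self):
        """On a 1-component model, max_dist is argmax of the predicted
        dummy columns; recompute them by hand for 4 points."""
        rng = np.random.default_rng(8)
        x = standardized(rng, 12, 3)
        y = two_class_labels(12)
        model = mv.fit_splsda(x, y, keepx=3, n_components=1)
        x_new = rng.normal(size=(4, 3))
        t_new = x_new @ model.rotation()
        y_hat = t_new @ model.y_loadings.T + model.y_mean
        expected = model.classes[np.argmax(y_hat, axis=1)]
        np.testing.assert_array_equal(
            mv.predict_splsda(model, x_new, "max_dist"), expected
        )

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(9)
        cols = [f"f{j}" for j in range(6)]
        x = pd.DataFrame(standardized(rng, 18, 6), columns=cols)
        y = two_class_labels(18)
        model = mv.fit_splsda(x, y, keepx=4, n_components=2)
        x_new = pd.DataFrame(rng.normal(size=(5, 6)), columns=cols)
        shuffled = x_new[["f3", "f0", "f5", "f1", "f4", "f2"]]
        np.testing.assert_array_equal(
            mv.predict_splsda(model, x_new), mv.predict_splsda(model, shuffled)
        )

    def test_unknown_distance_rejected(self):
        rng = np.random.default_rng(10)
        x = standardized(rng, 8, 3)
        model = mv.fit_splsda(x, two_class_labels(8), keepx=3, n_components=1)
        with pytest.raises(ValueError, match="distance"):
            mv.predict_splsda(model, x, "chebyshev")


class TestTuneKeepx:
    def test_pure_noise_error_near_half(self):
        rng = np.random.default_rng(20)
        x = standardized(rng, 40, 8)
        y = two_class_labels(40)
        res = mv.tune_keepx(x, y, [2, 8], n_components=1, repeats=5, seed=3)
        n_eff = res.folds * res.repeats
        mc_sd = 0.5 / np.sqrt(n_eff) * 2  # generous fold-size variation
        assert abs(res.mean_error.iloc[0, 0] - 0.5) < 3 * max(mc_sd, 0.05)

    def test_planted_three_feature_signal_recovered(self):
        """Chosen keepX lands in {2, 3, 4} in at least 80% of seeded runs."""
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            n, p = 40, 10
            y = two_class_labels(n)
            x = rng.normal(size=(n, p))
            x[y == "b", :3] += 2.5
            x = (x - x.mean(0)) / x.std(0, ddof=1)
            res = mv.tune_keepx(
                x, y, [1, 2, 3, 4, 5], n_components=1, repeats=2, seed=seed
            )
            if res.chosen_keepx[0] in (2, 3, 4):
                hits += 1
        assert hits >= 0.8 * runs

    def test_fold_determinism(self):
        rng = np.random.default_rng(21)
        x = standardized(rng, 30, 6)
        y = two_class_labels(30)
        a = mv.tune_keepx(x, y, [2, 4], n_components=1, repeats=2, seed=9)
        b = mv.tune_keepx(x, y, [2, 4], n_components=1, repeats=2, seed=9)
        pd.testing.assert_frame_equal(a.mean_error, b.mean_error)
        assert a.chosen_keepx == b.chosen_keepx

    def test_class_smaller_than_folds_advises(self):
        rng = np.random.default_rng(22)
        x = standardized(rng, 8, 4)
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="fewer folds"):
            mv.tune_keepx(x, y, [2], folds=5)


def block_distance():
    """6 points, two groups of 3: within-group distance 0, between 1."""
    d = np.ones((6, 6))
    d[:3, :3] = 0.0
    d[3:, 3:] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


class TestPermanova:
    def test_exhaustive_enumeration_oracle(self):
        """Sampled permutation p matches full enumeration over all 720
        labelings of the two-block configuration."""
        d = block_distance()
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        d2 = d**2

        def stat(labels):
            sst, ssw = mv._permanova_ss(d2, np.asarray(labels))
            return (sst - ssw) / 1 / (ssw / 4) if ssw > 0 else np.inf

        f_obs = stat(groups)
        exact = np.mean(
            [stat(list(perm)) >= f_obs for perm in itertools.permutations(groups)]
        )
        assert exact == pytest.approx(72 / 720)

        res = mv.permanova(d, groups, n_permutations=999, seed=4)
        assert res.pseudo_f == np.inf
        mc_sd = np.sqrt(exact * (1 - exact) / 999)
        assert abs(res.p_value - exact) < 3 * mc_sd + 1e-3

    def test_matches_scikit_bio(self):
        """Pseudo-F agrees with the independent scikit-bio implementation."""
        from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

        rng = np.random.default_rng(30)
        pts = rng.normal(size=(20, 4))
        pts[10:] += 0.8
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        groups = ["x"] * 10 + ["y"] * 10
        ours = mv.permanova(d, groups, n_permutations=999, seed=0)
        ids = [str(i) for i in range(20)]
        theirs = skbio_permanova(DistanceMatrix(d, ids), grouping=list(groups),
                                 permutations=999)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)
        assert abs(ours.p_value - theirs["p-value"]) < 0.05

    def test_null_pvalues_uniform(self):
        """Under a true null the permutation p-values are ~U(0,1)."""
        rng = np.random.default_rng(31)
        pvals = []
        for i in range(500):
            pts = rng.normal(size=(12, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            groups = rng.permutation(["a"] * 6 + ["b"] * 6)
            pvals.append(
                mv.permanova(d, groups, n_permutations=99, seed=i).p_value
            )
        ks = stats.kstest(pvals, "uniform").statistic
        # critical value at alpha=0.01 for n=500 (asymptotic 1.63/sqrt(n)),
        # widened for the discreteness of 99-permutation p-values
        assert ks < 1.63 / np.sqrt(500) + 0.01

    def test_r_squared_bounds_random_draws(self):
        rng = np.random.default_rng(32)
        for i in range(100):
            pts = rng.normal(size=(10, 2))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            groups = rng.permutation(["a"] * 5 + ["b"] * 5)
            res = mv.permanova(d, groups, n_permutations=9, seed=i)
            assert 0.0 <= res.r_squared <= 1.0
            assert 1 / 10 <= res.p_value <= 1.0

    def test_coincident_points_flagged_degenerate(self):
        d = np.zeros((6, 6))
        res = mv.permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.degenerate and np.isnan(res.pseudo_f)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            mv.permanova(block_distance(), ["g"] * 6)
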