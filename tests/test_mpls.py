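import numpy as np
import pytest

from nircal.mpls import (
    MPLSRegression,
    coefficient_extrema,
    cross_validate,
    fit_with_elimination,
    load_model,
    save_model,
)
from nircal.pretreat import parse_treatment


def nipals_pls1(X, y, k):
    """Independent textbook NIPALS PLS1 (deflation of X and y)."""
    X = X - X.mean(axis=0)
    y = y - y.mean()
    W, P, Q = [], [], []
    for _ in range(k):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        p = X.T @ t / tt
        q = y @ t / tt
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.inv(P.T @ W) @ Q


class TestPLS1Equivalence:
    def test_unit_scalings_match_nipals_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 50))
            y = rng.standard_normal(30)
            model = MPLSRegression(n_factors=5, scale_residuals=False).fit(X, y)
            beta = nipals_pls1(X.copy(), y.copy(), 5)
            np.testing.assert_allclose(model.coef_, beta, atol=1e-8 * np.abs(beta).max())
            fitted_oracle = (X - X.mean(0)) @ beta + y.mean()
            np.testing.assert_allclose(model.predict(X), fitted_oracle, atol=1e-8)

    def test_unit_scalings_match_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        ours = MPLSRegression(n_factors=6, scale_residuals=False).fit(X, y)
        ref = PLSRegression(n_components=6, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(ours.coef_, ref.coef_.ravel(), atol=1e-8)


class TestMPLSRegression:
    def test_recursion_equals_collapsed_linear_form(self, rng):
        X = rng.standard_normal((35, 80))
        y = rng.standard_normal(35)
        model = MPLSRegression(n_factors=7).fit(X, y)
        Xn = rng.standard_normal((10, 80))
        linear = Xn @ model.coef_ + model.intercept_
        np.testing.assert_allclose(model.predict(Xn), linear,
                                   atol=1e-8 * y.std())

    def test_zero_factors_predicts_training_mean(self, rng):
        X = rng.standard_normal((20, 30))
        y = rng.standard_normal(20) + 3.0
        model = MPLSRegression(n_factors=0).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_noiseless_single_band_fits_in_one_factor(self, rng):
        # spectra vary along a single band shape whose strength carries y
        band = np.exp(-0.5 * ((np.arange(40) - 13) / 3.0) ** 2)
        c = rng.standard_normal(25)
        X = np.outer(c, band) + 0.7
        y = 2.5 * c
        model = MPLSRegression(n_factors=1).fit(X, y)
        rmsec = np.sqrt(np.mean((y - model.predict(X)) ** 2))
        assert rmsec <= 1e-8 * y.std()

    def test_prediction_at_training_center_is_y_mean(self, rng):
        X = rng.standard_normal((20, 30))
        y = rng.standard_normal(20)
        model = MPLSRegression(n_factors=5).fit(X, y)
        assert model.predict(X.mean(axis=0)[None])[0] == pytest.approx(model.y_mean_)

    def test_rmsec_non_increasing_in_factor_count(self, rng):
        X = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        model = MPLSRegression(n_factors=10).fit(X, y)
        fits = model.predict_all_factors(X)
        rmsec = np.sqrt(((fits - y[:, None]) ** 2).mean(axis=0))
        assert np.all(np.diff(rmsec) <= 1e-10)

    def test_too_many_factors_rejected(self, rng):
        with pytest.raises(ValueError):
            MPLSRegression(n_factors=30).fit(rng.standard_normal((10, 50)),
                                             rng.standard_normal(10))

    def test_residual_scaling_changes_the_model(self, rng):
        X = rng.standard_normal((30, 50)) * np.linspace(0.1, 3.0, 50)
        y = rng.standard_normal(30)
        a = MPLSRegression(n_factors=4, scale_residuals=True).fit(X, y)
        b = MPLSRegression(n_factors=4, scale_residuals=False).fit(X, y)
        assert not np.allclose(a.coef_, b.coef_)


class TestCrossValidation:
    def test_group_sizes_for_71_samples(self, rng):
        X = rng.standard_normal((71, 40))
        y = rng.standard_normal(71)
        cv = cross_validate(X, y, max_factors=3, rng=rng)
        sizes = np.bincount(cv.groups)
        assert sorted(sizes) == [11, 12, 12, 12, 12, 12]

    def test_every_sample_predicted_exactly_once(self, rng):
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        cv = cross_validate(X, y, max_factors=3, rng=rng)
        assert cv.predictions.shape == (30,)
        assert np.bincount(cv.groups).sum() == 30

    def test_small_set_matches_manual_fold_loop(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 15))
        y = X[:, 2] + 0.1 * rng.standard_normal(12)
        cv = cross_validate(X, y, n_groups=6, max_factors=2,
                            rng=np.random.default_rng(9))
        # recompute with an explicit loop over the same partition
        errors = np.empty((12, 3))
        for g in range(6):
            train = cv.groups != g
            model = MPLSRegression(n_factors=2).fit(X[train], y[train])
            block = model.predict_all_factors(X[~train])
            errors[~train] = block - y[~train, None]
        np.testing.assert_allclose(cv.rmsecv_curve,
                                   np.sqrt((errors ** 2).mean(axis=0)))

    def test_noiseless_three_band_model_recovers_with_three_factors(self, rng):
        n, p = 48, 60
        scores = rng.standard_normal((n, 3))
        shapes = np.vstack([
            np.exp(-0.5 * ((np.arange(p) - c) / 4.0) ** 2) for c in (10, 30, 50)])
        X = scores @ shapes
        y = scores @ np.array([1.0, -2.0, 0.5])
        cv = cross_validate(X, y, max_factors=6, rng=rng)
        assert cv.rmsecv_curve[3] <= 0.01 * y.std()

    def test_fit_is_permutation_invariant(self, rng):
        X = rng.standard_normal((24, 30))
        y = rng.standard_normal(24)
        perm = rng.permutation(24)
        a = MPLSRegression(n_factors=4).fit(X, y)
        b = MPLSRegression(n_factors=4).fit(X[perm], y[perm])
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-10)
        np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-10)

    def test_shuffled_data_with_mapped_partition_gives_same_curve(self, rng):
        X = rng.standard_normal((24, 30))
        y = rng.standard_normal(24)
        cv = cross_validate(X, y, max_factors=4, rng=np.random.default_rng(5))
        perm = rng.permutation(24)
        # recompute the pooled curve on shuffled rows using the same
        # partition carried through the shuffle
        groups_shuffled = cv.groups[perm]
        errors = np.empty((24, 5))
        Xs, ys = X[perm], y[perm]
        for g in range(6):
            train = groups_shuffled != g
            model = MPLSRegression(n_factors=4).fit(Xs[train], ys[train])
            errors[~train] = model.predict_all_factors(Xs[~train]) - ys[~train, None]
        np.testing.assert_allclose(np.sqrt((errors ** 2).mean(axis=0)),
                                   cv.rmsecv_curve, atol=1e-10)


class TestEliminationLoop:
    def test_clean_synthetic_data_keeps_most_samples(self, rng):
        n, p = 71, 60
        X = rng.standard_normal((n, 5)) @ rng.standard_normal((5, p)) \
            + 0.05 * rng.standard_normal((n, p))
        y = X[:, 10] + 0.1 * rng.standard_normal(n)
        fc = fit_with_elimination(X, y, "None 0,0,1,1", rng=rng, max_factors=8)
        assert fc.summary.n >= n - 6
        assert fc.outliers.n_eliminated == n - fc.summary.n

    def test_eliminated_bookkeeping_consistent(self, rng):
        n = 50
        X = rng.standard_normal((n, 4)) @ rng.standard_normal((4, 30)) \
            + 0.05 * rng.standard_normal((n, 30))
        y = X[:, 3] + 0.2 * rng.standard_normal(n)
        fc = fit_with_elimination(X, y, "None 0,0,1,1", rng=rng, max_factors=6)
        n_h = len(fc.outliers.eliminated_ids("H"))
        n_t = len(fc.outliers.eliminated_ids("T"))
        assert n_h + n_t == fc.outliers.n_eliminated == n - fc.summary.n
        assert len(fc.ids) == fc.summary.n


class TestCoefficientExtrema:
    def test_single_spike_located(self):
        model = MPLSRegression(n_factors=1)
        model.x_mean_ = np.zeros(451)
        model.y_mean_ = 0.0
        model.n_factors_ = 1
        beta = np.zeros(451)
        beta[115] = 7.5  # channel 115 on the 1100..2000 nm grid -> 1330 nm
        model.coef_ = beta
        wl = 1100 + 2.0 * np.arange(451)
        assert coefficient_extrema(model, wl, top_k=1) == [(1330.0, 7.5)]

    def test_signed_values_reported(self, rng):
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        model = MPLSRegression(n_factors=3).fit(X, y)
        wl = np.arange(40.0)
        for w, b in coefficient_extrema(model, wl, top_k=2):
            assert model.coef_[int(w)] == b


class TestSerialization:
    def test_save_load_round_trip_predicts_identically(self, rng, tmp_path):
        n, p = 40, 60
        X = rng.standard_normal((n, p)) + 2.0
        y = X[:, 7] + 0.2 * rng.standard_normal(n)
        fc = fit_with_elimination(X, y, "Standard MSC 1,4,4,1", element="K",
                                  rng=rng, max_factors=5)
        path = tmp_path / "model.json"
        save_model(fc, path)
        back = load_model(path)
        X_new = rng.standard_normal((5, p)) + 2.0
        np.testing.assert_allclose(back.predict(X_new), fc.predict(X_new),
                                   rtol=1e-12)
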