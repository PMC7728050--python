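"""Global PLSR (one-sigma), memory-based learning and the plugin slot."""

import numpy as np
import pytest

from spectransfer.regression import (
    LoadedPLSR,
    MBLConfig,
    MemoryBasedLearner,
    ModelSpec,
    ModelTreeRegressor,
    PLSRegressionCV,
    fit_plsr,
    fit_plugin_model,
    mbl_predict,
    register_plugin,
    registered_plugins,
    weighted_average_pls,
)


def nipals_pls1_oracle(X, y, n_comp):
    """Independent NIPALS PLS1 implementation used only as a test oracle."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    E, f = X - x_mean, y - y_mean
    W, P, Q = [], [], []
    for _ in range(n_comp):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = f @ t / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return lambda Xn: y_mean + (np.atleast_2d(Xn) - x_mean) @ B


def _rank2_problem(n=40, p=15, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(n, 2))
    loads = rng.normal(size=(2, p))
    X = t @ loads
    y = 2.0 * t[:, 0] - 1.0 * t[:, 1]
    if noise:
        y = y + rng.normal(0, noise, n)
    return X, y


class TestPLSR:
    def test_noise_free_rank2_selects_two_components(self):
        X, y = _rank2_problem()
        res = fit_plsr(X, y, max_ncomp=8, seed=0)
        assert res.n_components == 2
        assert res.cv_curve["mean_rmse"].iloc[1] <= 1e-8

    def test_one_sigma_never_exceeds_argmin(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            X, y = _rank2_problem(noise=0.5, seed=seed)
            res = fit_plsr(X, y, max_ncomp=8, seed=int(rng.integers(1000)))
            assert res.n_components <= res.argmin_components

    def test_same_seed_reproduces_cv_curve(self):
        X, y = _rank2_problem(noise=0.3)
        a = fit_plsr(X, y, max_ncomp=6, seed=11)
        b = fit_plsr(X, y, max_ncomp=6, seed=11)
        assert np.array_equal(a.cv_curve["mean_rmse"], b.cv_curve["mean_rmse"])
        assert a.n_components == b.n_components

    def test_agreement_with_independent_nipals_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 30))
        y = rng.normal(size=10)
        from spectransfer.regression import _fit_pls

        for ncomp in (1, 3, 5):
            ours = _fit_pls(X, y, ncomp)
            oracle = nipals_pls1_oracle(X, y, ncomp)
            assert np.allclose(
                ours.predict(X).ravel(), oracle(X).ravel(), atol=1e-6
            )

    def test_full_rank_reproduces_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.1, 30)
        from spectransfer.regression import _fit_pls

        pls = _fit_pls(X, y, 6)
        A = np.column_stack([X, np.ones(30)])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(pls.predict(X).ravel(), A @ beta, atol=1e-6)

    def test_predicting_training_mean_gives_mean_response(self):
        X, y = _rank2_problem(noise=0.2)
        res = fit_plsr(X, y, max_ncomp=5, seed=0)
        pred = res.predict(X.mean(axis=0))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_out_of_sample_exact_on_noise_free_system(self):
        X, y = _rank2_problem(n=60)
        res = fit_plsr(X[:40], y[:40], max_ncomp=6, seed=0)
        assert np.abs(res.predict(X[40:]) - y[40:]).max() <= 1e-8

    def test_input_validation(self):
        X, y = _rank2_problem()
        with pytest.raises(ValueError, match="zero-variance"):
            PLSRegressionCV(X, np.ones(len(y)))
        with pytest.raises(ValueError, match="channels"):
            fit_plsr(X, y, max_ncomp=4, seed=0).predict(X[:, :5])
        with pytest.raises(ValueError, match="missing"):
            PLSRegressionCV(X, np.where(np.arange(len(y)) == 0, np.nan, y))

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _rank2_problem(noise=0.1)
        res = fit_plsr(X, y, max_ncomp=5, seed=0)
        path = tmp_path / "plsr.json"
        res.save(path)
        loaded = LoadedPLSR.load(path)
        assert np.allclose(loaded.predict(X), res.predict(X), atol=1e-10)

    def test_summary_mentions_selection(self):
        X, y = _rank2_problem(noise=0.2)
        s = fit_plsr(X, y, max_ncomp=5, seed=0).summary()
        assert "one-sigma" in s and "ncomp" in s


class TestMBL:
    @pytest.fixture(scope="class")
    @staticmethod
    def linear_cal():
        rng = np.random.default_rng(10)
        t = rng.normal(size=(400, 3))
        loads = rng.normal(size=(3, 60))
        X = t @ loads + rng.normal(0, 0.01, (400, 60))
        y = t @ [1.5, -0.7, 0.3] + rng.normal(0, 0.05, 400)
        return X, y

    def test_homogeneous_data_agrees_with_global_plsr(self, linear_cal):
        X, y = linear_cal
        Xc, yc, Xn, yn = X[:320], y[:320], X[320:360], y[320:360]
        cfg = MBLConfig(min_neighbors=100, max_neighbors=200, factor_range=(2, 8))
        res = mbl_predict(Xc, yc, Xn, config=cfg, seed=0)
        glob = fit_plsr(Xc, yc, max_ncomp=8, seed=0)
        cv_rmse = glob.cv_curve["mean_rmse"].iloc[glob.n_components - 1]
        err = np.sqrt(np.mean((res.predictions - yn) ** 2))
        assert err <= 2 * cv_rmse

    def test_neighborhood_clamped_to_min_and_max(self, linear_cal):
        X, y = linear_cal
        # tiny threshold -> fewer than min within distance -> expand to min
        cfg = MBLConfig(
            thresholds=np.array([1e-6]), min_neighbors=100, max_neighbors=200,
            factor_range=(2, 5),
        )
        res = mbl_predict(X, y, X[:2] + 1e-3, config=cfg, seed=0)
        assert np.all(res.neighborhood_size == 100)
        # huge threshold -> more than max within distance -> truncate to max
        cfg = MBLConfig(
            thresholds=np.array([1e6]), min_neighbors=100, max_neighbors=200,
            factor_range=(2, 5),
        )
        res = mbl_predict(X, y, X[:2] + 1e-3, config=cfg, seed=0)
        assert np.all(res.neighborhood_size == 200)

    def test_degenerates_to_global_wapls_with_infinite_threshold(self, linear_cal):
        X, y = linear_cal
        n = X.shape[0]
        cfg = MBLConfig(
            thresholds=np.array([np.inf]), min_neighbors=n, max_neighbors=n,
            factor_range=(2, 6),
        )
        res = mbl_predict(X, y, X[:5] + 1e-4, config=cfg, seed=0)
        direct = weighted_average_pls(X, y, X[:5] + 1e-4, factor_range=(2, 6))
        assert np.allclose(res.predictions, direct, atol=1e-10)

    def test_requires_min_neighbors_calibration_samples(self):
        X = np.random.default_rng(0).normal(size=(50, 10))
        y = X[:, 0]
        with pytest.raises(ValueError, match="min_neighbors"):
            MemoryBasedLearner(X, y, MBLConfig())

    def test_deterministic_given_seed(self, linear_cal):
        X, y = linear_cal
        cfg = MBLConfig(min_neighbors=100, max_neighbors=150, factor_range=(2, 6))
        a = mbl_predict(X[:300], y[:300], X[300:305], config=cfg, seed=5)
        b = mbl_predict(X[:300], y[:300], X[300:305], config=cfg, seed=5)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.chosen_threshold, b.chosen_threshold)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            MBLConfig(thresholds=np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="min_neighbors"):
            MBLConfig(min_neighbors=300, max_neighbors=200)


class TestPluginSlot:
    def test_model_tree_registered_by_default(self):
        assert "model_tree" in registered_plugins()

    def test_unregistered_plugin_raises_lookup(self):
        spec = ModelSpec(family="plugin", plugin_name="cubist")
        with pytest.raises(LookupError, match="cubist"):
            fit_plugin_model(np.ones((10, 3)), np.arange(10.0), spec)

    def test_capacity_defaults_honored(self):
        spec = ModelSpec(family="plugin")
        assert spec.hyperparameters["committees"] == 1
        assert spec.hyperparameters["max_rules"] == 100
        with pytest.raises(ValueError, match="committees"):
            ModelTreeRegressor(committees=3)

    def test_constant_response_gives_constant_predictor(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(80, 12))
        y = np.full(80, 3.5)
        model = ModelTreeRegressor().fit(X, y)
        assert np.allclose(model.predict(X), 3.5, atol=1e-9)

    def test_two_regime_data_beats_global_linear_fit(self):
        rng = np.random.default_rng(21)
        z = rng.uniform(-2, 2, 500)
        X = np.column_stack([z, rng.normal(size=(500, 4))])
        y = np.where(z > 0, 3.0 * z, -0.5 * z) + rng.normal(0, 0.05, 500)
        spec = ModelSpec(family="plugin", plugin_name="model_tree")
        tree = fit_plugin_model(X[:400], y[:400], spec)
        rmse_tree = np.sqrt(np.mean((tree.predict(X[400:]) - y[400:]) ** 2))
        A = np.column_stack([X[:400], np.ones(400)])
        beta = np.linalg.lstsq(A, y[:400], rcond=None)[0]
        lin = np.column_stack([X[400:], np.ones(100)]) @ beta
        rmse_lin = np.sqrt(np.mean((lin - y[400:]) ** 2))
        assert rmse_tree < rmse_lin


def test_wapls_weights_sum_to_one_and_prefer_better_factors():
    rng = np.random.default_rng(30)
    X, y = rng.normal(size=(50, 20)), rng.normal(size=50)
    from spectransfer.regression import _fit_pls, _wapls_weights

    pls = _fit_pls(X, y, 8)
    w = _wapls_weights(pls, X, y, np.arange(3, 9))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w > 0)
    # residual norms shrink with factors on training data -> weights increase
    assert w[-1] >= w[0]
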