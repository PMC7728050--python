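"""PCA scoring, Kennard–Stone selection and piecewise direct standardization."""

import numpy as np
import pytest

from spectransfer.spectra import PreprocessingState
from spectransfer.transfer import (
    PDSTransferResults,
    PiecewiseDirectStandardization,
    apply_pds,
    fit_pds,
    kennard_stone,
    pca_fit,
    pca_scores,
    select_transfer_indices,
)

from conftest import make_library


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 3))
        model = pca_fit(X, 3)
        # independent oracle: eigen-decompose the covariance directly
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(model.explained_variance, evals, atol=1e-8)
        s_model = pca_scores(model, X)
        s_oracle = Xc @ evecs
        for j in range(3):  # sign of each column is arbitrary
            assert np.allclose(s_model[:, j], s_oracle[:, j], atol=1e-8) or np.allclose(
                s_model[:, j], -s_oracle[:, j], atol=1e-8
            )

    def test_score_variance_equals_eigenvalue_and_orthonormal_loadings(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 12))
        model = pca_fit(X, 5)
        s = pca_scores(model, X)
        assert np.allclose(s.var(axis=0, ddof=1), model.explained_variance, atol=1e-8)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_rank_one_data_explained_by_pc1(self):
        base = np.linspace(0, 1, 20)
        X = np.outer([1.0, 2.0, 3.5, -0.5], base)
        model = pca_fit(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_mean_spectrum_scores_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 8))
        model = pca_fit(X, 3)
        assert np.allclose(pca_scores(model, X.mean(axis=0)[None, :]), 0.0, atol=1e-10)

    def test_n_pc_exceeding_rank_errors(self):
        with pytest.raises(ValueError, match="n_pc"):
            pca_fit(np.random.default_rng(3).normal(size=(4, 10)), 4)


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------


def brute_force_kennard_stone(scores, n_select):
    """Plain greedy max-min reference: O(n^2) recomputation each step."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores.reshape(-1, 1)
    n = scores.shape[0]
    dist = lambda i, j: float(np.linalg.norm(scores[i] - scores[j]))
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if dist(i, j) > best:
                best, pair = dist(i, j), (i, j)
    sel = list(pair)
    while len(sel) < n_select:
        best, pick = -1.0, None
        for c in range(n):
            if c in sel:
                continue
            d = min(dist(c, s) for s in sel)
            if d > best:
                best, pick = d, c
        sel.append(pick)
    return sel


class TestKennardStone:
    def test_hand_enumerated_1d_example(self):
        # greedy max-min on {0, 1, 2, 10}: extremes first, then 2
        idx = kennard_stone(np.array([0.0, 1.0, 2.0, 10.0]), 3)
        assert idx.tolist() == [0, 3, 2]

    def test_select_all_is_permutation(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(9, 2))
        idx = kennard_stone(scores, 9)
        assert sorted(idx.tolist()) == list(range(9))

    def test_duplicate_points_tie_break_lowest_index(self):
        idx = kennard_stone(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]), 2)
        assert idx.tolist() == [0, 2]

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(3, 21))
            d = int(rng.integers(1, 4))
            scores = rng.normal(size=(n, d))
            k = int(rng.integers(2, n + 1))
            assert kennard_stone(scores, k).tolist() == brute_force_kennard_stone(
                scores, k
            )

    def test_select_transfer_indices_is_deterministic(self, small_scenario):
        lib = small_scenario.calibration
        a = select_transfer_indices(lib, 10)
        b = select_transfer_indices(lib, 10)
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# PDS
# ---------------------------------------------------------------------------


def _rank1_pair(n=12, p=40, a=1.0, b=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = 0.5 + 0.4 * np.sin(np.linspace(0, 6, p)) ** 2
    c = rng.uniform(0.5, 3.0, n)
    primary = make_library(np.outer(c, base))
    secondary = primary.with_absorbance(a * primary.absorbance + b, instrument="secondary")
    return primary, secondary


class TestPDS:
    def test_identity_transfer_on_rank1_library(self):
        primary, secondary = _rank1_pair(a=1.0, b=0.0)
        model = fit_pds(primary, secondary)
        out = apply_pds(model, secondary)
        k = model.half_window
        assert np.allclose(out.absorbance, primary.absorbance[:, k:-k], atol=1e-10)

    def test_affine_distortion_recovered_exactly(self):
        primary, secondary = _rank1_pair(a=2.0, b=5.0)
        model = fit_pds(primary, secondary)
        out = model.transform(secondary)
        k = model.half_window
        assert np.allclose(out.absorbance, primary.absorbance[:, k:-k], atol=1e-10)
        assert out.instrument == "secondary_pds"

    def test_edge_trim_channel_count(self):
        primary, secondary = _rank1_pair(p=1687)
        model = fit_pds(primary, secondary, half_window=1)
        assert len(model.retained_grid) == 1685

    def test_k0_matches_per_channel_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        primary = make_library(rng.normal(size=(30, 10)))
        secondary = primary.with_absorbance(
            1.7 * primary.absorbance + rng.normal(0, 0.05, (30, 10)) + 0.3,
            instrument="secondary",
        )
        model = fit_pds(primary, secondary, half_window=0, n_pc=1)
        P, S = primary.absorbance, secondary.absorbance
        for j in range(10):
            # univariate least squares with intercept, channel by channel
            A = np.column_stack([S[:, j], np.ones(30)])
            beta, _, _, _ = np.linalg.lstsq(A, P[:, j], rcond=None)
            assert model.coeffs[j, 0] == pytest.approx(beta[0], abs=1e-8)
            assert model.intercepts[j] == pytest.approx(beta[1], abs=1e-8)

    def test_zero_variance_window_falls_back_to_mean(self):
        primary = make_library(np.tile([1.0, 2.0, 3.0, 4.0], (5, 1)))
        secondary = primary.with_absorbance(
            np.tile([2.0, 2.0, 2.0, 2.0], (5, 1)), instrument="secondary"
        )
        model = fit_pds(primary, secondary, half_window=1)
        assert np.all(model.coeffs == 0.0)
        assert np.allclose(model.intercepts, [2.0, 3.0])
        out = model.transform(secondary)
        assert np.allclose(out.absorbance, np.tile([2.0, 3.0], (5, 1)))

    def test_mismatched_inputs_rejected(self):
        primary, secondary = _rank1_pair()
        other = make_library(np.ones((12, 39)))
        with pytest.raises(ValueError, match="grids"):
            fit_pds(primary, other)
        shuffled = secondary.subset(list(range(11, -1, -1)))
        with pytest.raises(ValueError, match="sample order"):
            fit_pds(primary, shuffled)

    def test_determinism_bit_identical(self, small_scenario):
        sc = small_scenario
        m1 = fit_pds(sc.transfer_primary, sc.transfer_secondary)
        m2 = fit_pds(sc.transfer_primary, sc.transfer_secondary)
        assert np.array_equal(m1.coeffs, m2.coeffs)
        assert np.array_equal(m1.intercepts, m2.intercepts)

    def test_transfer_fidelity_on_held_out_samples(self, small_scenario):
        # PDS must bring secondary spectra closer to primary than they were
        sc = small_scenario
        model = fit_pds(sc.transfer_primary, sc.transfer_secondary)
        k = model.half_window
        out = model.transform(sc.prediction_secondary)
        P = sc.prediction_primary.absorbance[:, k:-k]
        S = sc.prediction_secondary.absorbance[:, k:-k]
        mse_pds = np.mean((out.absorbance - P) ** 2)
        mse_raw = np.mean((S - P) ** 2)
        assert mse_pds < mse_raw

    def test_json_roundtrip(self, tmp_path, small_scenario):
        sc = small_scenario
        model = fit_pds(sc.transfer_primary, sc.transfer_secondary)
        path = tmp_path / "pds.json"
        model.save(path)
        loaded = PDSTransferResults.load(path)
        assert np.allclose(loaded.coeffs, model.coeffs, atol=1e-15)
        assert np.allclose(loaded.intercepts, model.intercepts, atol=1e-15)
        assert loaded.input_state is model.input_state
        out_a = model.transform(sc.transfer_secondary).absorbance
        out_b = loaded.transform(sc.transfer_secondary).absorbance
        assert np.allclose(out_a, out_b, atol=1e-12)

    def test_state_mismatch_rejected_on_apply(self, small_scenario):
        sc = small_scenario
        model = fit_pds(sc.transfer_primary, sc.transfer_secondary)
        from spectransfer.preprocess import baseline_offset

        with pytest.raises(ValueError, match="fitted on"):
            model.transform(baseline_offset(sc.transfer_secondary))
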