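"""PCA selection, concatenation fusion, and canonical correlation."""

import numpy as np
import pytest
import scipy.optimize

import blinkfuse as bf
from _helpers import as_epochset, cca_oracle


def _whitened(rng, n, d):
    """Samples x d matrix whose sample covariance is exactly the identity."""
    Z = rng.standard_normal((n, d))
    Z -= Z.mean(axis=0)
    cov = Z.T @ Z / n
    return Z @ np.linalg.inv(np.linalg.cholesky(cov).T)


class TestPCASelect:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        w = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer(w, rng.standard_normal(2000))
        pcs = bf.fit_pca_select(as_epochset(X, n_epochs=20))
        assert pcs.k == 1
        assert pcs.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_cumulative_rule_on_constructed_spectrum(self):
        # sample eigen-spectrum exactly (0.60, 0.30, 0.05, 0.05):
        # cumulative 0.90 < 0.95 <= 0.95 selects k = 3
        rng = np.random.default_rng(1)
        Z = _whitened(rng, 4000, 4)
        X = (Z * np.sqrt([0.60, 0.30, 0.05, 0.05])).T
        pcs = bf.fit_pca_select(as_epochset(X, n_epochs=40))
        np.testing.assert_allclose(
            np.cumsum(pcs.explained_variance_ratio), [0.60, 0.90, 0.95],
            atol=1e-9)
        assert pcs.k == 3

    def test_variance_threshold_met_on_synthetic_epochs(self, noisy_epochs):
        epochs, _ = noisy_epochs
        pcs = bf.fit_pca_select(epochs)
        assert pcs.explained_variance_ratio.sum() >= 0.95
        if pcs.k > 1:
            assert pcs.explained_variance_ratio[:-1].sum() < 0.95

    def test_reconstruction_recovers_selected_variance(self, noisy_epochs):
        epochs, _ = noisy_epochs
        pcs = bf.fit_pca_select(epochs)
        centered = epochs.epochs - pcs.channel_mean[None, :, None]
        recon = np.einsum("ekt,ck->ect", pcs.pc_epochs, pcs.loadings)
        frac = 1.0 - np.sum((centered - recon) ** 2) / np.sum(centered ** 2)
        assert frac >= 0.95

    def test_loadings_orthonormal_and_sign_fixed(self, noisy_epochs):
        epochs, _ = noisy_epochs
        pcs = bf.fit_pca_select(epochs)
        np.testing.assert_allclose(pcs.loadings.T @ pcs.loadings,
                                   np.eye(pcs.k), atol=1e-10)
        peak = pcs.loadings[np.argmax(np.abs(pcs.loadings), axis=0),
                            np.arange(pcs.k)]
        assert np.all(peak > 0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            bf.fit_pca_select(as_epochset(np.zeros((4, 400)), n_epochs=4))


class TestFuseConcat:
    def test_epoch_mismatch_errors(self, noisy_epochs):
        epochs, _ = noisy_epochs
        pcs = bf.fit_pca_select(epochs)
        blink = bf.EpochSet(epochs=np.zeros((3, 1, epochs.n_times)),
                            time_ms=epochs.time_ms, fs=epochs.fs,
                            series_kind="blink")
        with pytest.raises(ValueError):
            bf.fuse_concat(pcs, blink)

    @pytest.mark.parametrize("k", range(1, 11))
    @pytest.mark.parametrize("w", [5, 13, 25])
    def test_flattened_length_is_k_plus_one_times_w(self, k, w):
        rng = np.random.default_rng(k * 100 + w)
        n_ep, n_t, fs = 12, 100, 250.0
        labels = np.asarray(["a", "b"] * 6, dtype=object)
        pcs = bf.PrincipalComponentSet(
            pc_epochs=rng.standard_normal((n_ep, k, n_t)),
            loadings=np.eye(max(k, 2))[:, :k],
            explained_variance_ratio=np.full(k, 1.0 / k), k=k,
            channel_mean=np.zeros(max(k, 2)),
            time_ms=np.arange(n_t) * 1000.0 / fs, fs=fs, labels=labels)
        blink = bf.EpochSet(epochs=rng.standard_normal((n_ep, 1, n_t)),
                            time_ms=pcs.time_ms, fs=fs, series_kind="blink",
                            labels=labels)
        fused = bf.fuse_concat(pcs, blink)
        assert fused.fused_epochs.shape[1] == k + 1
        window_ms = w * 1000.0 / fs - 1e-9  # w samples at fs
        fm = next(bf.slide_windows(fused, window_ms=window_ms))
        assert fm.n_features == (k + 1) * w


class TestCCA:
    def test_identical_signals_give_rho_one(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(2000)
        ex = as_epochset(s[None, :], n_epochs=10)
        eb = as_epochset(s[None, :], n_epochs=10)
        pairs = bf.fit_cca(ex, eb)
        assert pairs[0].rho == pytest.approx(1.0, abs=1e-6)
        ratio = pairs[0].u[0] / pairs[0].v[0]
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_gives_small_rho(self):
        rng = np.random.default_rng(3)
        ex = as_epochset(rng.standard_normal((1, 4000)), n_epochs=20)
        eb = as_epochset(rng.standard_normal((1, 4000)), n_epochs=20)
        assert bf.fit_cca(ex, eb)[0].rho < 0.1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_whitening_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((200, 4))
        B = rng.standard_normal((200, 3))
        B[:, 0] += 0.5 * X[:, 1]
        pairs = bf.fit_cca(as_epochset(X.T, n_epochs=2),
                           as_epochset(B.T, n_epochs=2), n_pairs=3)
        rhos, U, V = cca_oracle(X, B)
        for j, p in enumerate(pairs):
            assert abs(p.rho - rhos[j]) < 1e-8
            np.testing.assert_allclose(p.u, U[:, j], atol=1e-8)
            np.testing.assert_allclose(p.v, V[:, j], atol=1e-8)

    def test_invariant_to_invertible_remixing(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 5))
        B = rng.standard_normal((500, 3))
        B[:, 1] += X[:, 0]
        # ridge disabled: the regularization term is the one deliberate
        # departure from exact remixing invariance
        rho0 = bf.fit_cca(as_epochset(X.T, n_epochs=5),
                          as_epochset(B.T, n_epochs=5), ridge=0.0)[0].rho
        M = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        rho1 = bf.fit_cca(as_epochset((X @ M.T).T, n_epochs=5),
                          as_epochset(B.T, n_epochs=5), ridge=0.0)[0].rho
        assert abs(rho0 - rho1) < 1e-8

    def test_eigen_route_matches_direct_maximization_2x2(self):
        # gradient-free maximization of corr(uᵀX, vᵀB) over angles
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 2))
        B = rng.standard_normal((300, 2))
        B[:, 0] += 0.7 * X[:, 0]
        rho = bf.fit_cca(as_epochset(X.T, n_epochs=3),
                         as_epochset(B.T, n_epochs=3))[0].rho
        Xc, Bc = X - X.mean(0), B - B.mean(0)

        def neg_corr(angles):
            u = np.array([np.cos(angles[0]), np.sin(angles[0])])
            v = np.array([np.cos(angles[1]), np.sin(angles[1])])
            return -abs(np.corrcoef(Xc @ u, Bc @ v)[0, 1])

        best = min(
            scipy.optimize.minimize(neg_corr, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [(0.3, 0.3), (1.2, -0.5), (-1.0, 2.0)])
        assert abs(rho - (-best)) < 1e-6

    def test_singularity_message_names_ridge(self):
        X = np.zeros((2, 400))
        X[1] = X[0]
        with pytest.raises(Exception) as exc:
            bf.fit_cca(as_epochset(X, n_epochs=4),
                       as_epochset(X.copy(), n_epochs=4), ridge=0.0)
        assert "ridge" in str(exc.value).lower() or "regular" in str(exc.value).lower()


class TestFuseCCA:
    def test_one_pair_gives_two_series(self):
        rng = np.random.default_rng(6)
        ex = as_epochset(rng.standard_normal((3, 600)), n_epochs=6)
        eb = as_epochset(rng.standard_normal((2, 600)), n_epochs=6)
        fused = bf.fuse_cca(bf.fit_cca(ex, eb), ex)
        assert fused.fused_epochs.shape[1] == 2
        assert fused.provenance == "CCA"

    def test_empty_pairs_error(self):
        rng = np.random.default_rng(7)
        ex = as_epochset(rng.standard_normal((2, 100)), n_epochs=2)
        with pytest.raises(ValueError):
            bf.fuse_cca([], ex)

    def test_perfectly_correlated_pair_gives_equal_series(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((2, 1000))
        M = np.array([[1.0, 0.3], [0.2, 0.9]])
        ex = as_epochset(X, n_epochs=10)
        eb = as_epochset(M @ X, n_epochs=10)
        pairs = bf.fit_cca(ex, eb)
        assert pairs[0].rho > 1 - 1e-6
        x, b = pairs[0].x_variate.ravel(), pairs[0].b_variate.ravel()
        assert abs(np.corrcoef(x, b)[0, 1]) > 1 - 1e-8

    def test_first_variate_tracks_shared_source(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(4000)
        X = np.outer([1.0, -0.5, 0.3], s) + 0.3 * rng.standard_normal((3, 4000))
        B = np.outer([0.8, 0.6], s) + 0.3 * rng.standard_normal((2, 4000))
        pairs = bf.fit_cca(as_epochset(X, n_epochs=40),
                           as_epochset(B, n_epochs=40))
        r = np.corrcoef(pairs[0].x_variate.ravel(), s)[0, 1]
        assert abs(r) > 0.9
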