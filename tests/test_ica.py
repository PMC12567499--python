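import numpy as np
import pytest

from mtuforce import (
    IcaConfig,
    canonicalize,
    center,
    fit_separation,
    log_likelihood,
    recover_sources,
    whiten,
)
from conftest import match_abs_pcc


class TestCenter:
    def test_row_mean_removed(self):
        Xc, mu = center(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
        np.testing.assert_allclose(Xc[0], [-1, 0, 1])
        np.testing.assert_allclose(mu, [2.0, 4.0])
        assert np.all(np.abs(Xc.mean(axis=1)) < 1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 100))
        once, _ = center(X)
        twice, mu2 = center(once)
        np.testing.assert_allclose(once, twice, atol=1e-14)
        np.testing.assert_allclose(mu2, 0.0, atol=1e-14)

    def test_non_finite_rejected(self):
        X = np.ones((2, 10))
        X[0, 3] = np.nan
        with pytest.raises(ValueError):
            center(X)


class TestWhiten:
    def test_diagonal_covariance_closed_form(self):
        # 2 channels with sample covariance diag(4, 1): rows scale by 1/2 and 1
        rng = np.random.default_rng(1)
        base = rng.standard_normal((2, 100000))
        base -= base.mean(axis=1, keepdims=True)
        # orthogonalize and normalize rows exactly, then scale
        q, _ = np.linalg.qr(base.T)
        X = (q.T * np.sqrt(100000 - 1)) * np.array([[2.0], [1.0]])
        Z, res = whiten(X, 2)
        scales = np.sort(np.abs(res.whitening_matrix).max(axis=1))
        np.testing.assert_allclose(scales, [0.5, 1.0], rtol=1e-6)
        np.testing.assert_allclose(res.eig_values[:2], [4.0, 1.0], rtol=1e-6)

    def test_identity_covariance_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 20000))
        X, _ = center(X)
        Z, res = whiten(X, 4)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)

    def test_truncation_keeps_dominant_subspace(self, noiseless_mixture):
        rec, truth = noiseless_mixture
        Xc, _ = center(rec.samples)
        Z, res = whiten(Xc, 5)
        cov = Z @ Z.T / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(5), atol=1e-8)
        # 5 true sources: eigenvalues 6..64 are numerically zero
        assert res.eig_values[5] < 1e-10 * res.eig_values[0]

    def test_rank_deficiency_reported(self):
        X = np.vstack([np.ones((1, 50)), np.zeros((2, 50))])
        X[0] = np.sin(np.arange(50))
        X, _ = center(X)
        with pytest.raises(ValueError, match="rank"):
            whiten(X, 3)


class TestFitSeparation:
    def test_single_component_converges_to_scalar_fixed_point(self):
        # 1-D: ascent is stationary where E[y tanh y] = 1 under the sech prior
        rng = np.random.default_rng(3)
        z = rng.laplace(size=(1, 20000))
        z = (z - z.mean()) / z.std(ddof=1)
        res = fit_separation(z, IcaConfig(n_components=1, seed=0))
        assert res.converged
        y = res.sources[0]
        assert np.mean(y * np.tanh(y)) == pytest.approx(1.0, abs=0.02)

    def test_two_super_gaussian_sources_recovered(self):
        rng = np.random.default_rng(4)
        S = rng.laplace(size=(2, 20000))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        Xc, _ = center(A @ S)
        Z, white = whiten(Xc, 2)
        res = fit_separation(Z, IcaConfig(n_components=2, seed=0))
        matched = match_abs_pcc(res.sources, S)
        assert np.all(matched >= 0.99)

    def test_unwhitened_input_rejected(self):
        rng = np.random.default_rng(5)
        Z = 3.0 * rng.standard_normal((2, 5000))
        with pytest.raises(ValueError, match="whitened"):
            fit_separation(Z, IcaConfig(n_components=2))

    def test_loglik_increases_from_initial(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(-1, 1, size=(2, 10000))
        Xc, _ = center(np.array([[1.0, 0.5], [0.3, 1.0]]) @ S)
        Z, _ = whiten(Xc, 2)
        res = fit_separation(Z, IcaConfig(n_components=2, seed=1))
        assert res.loglik_trace[-1] >= res.loglik_trace[0]


class TestLogLikelihood:
    def test_closed_form_at_zero_data(self):
        T, n = 100, 3
        Z = np.zeros((n, T))
        expected = T * n * np.log(1 / np.pi)  # log p(0) for sech prior
        assert log_likelihood(np.eye(n), Z) == pytest.approx(expected)

    def test_singular_matrix_gives_minus_infinity(self):
        Z = np.zeros((2, 10))
        with pytest.warns(UserWarning, match="singular"):
            assert log_likelihood(np.zeros((2, 2)), Z) == -np.inf

    def test_shrinking_row_drives_likelihood_down(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((2, 1000))
        W = np.eye(2)
        lls = [log_likelihood(np.diag([1.0, eps]), Z) for eps in (1.0, 1e-3, 1e-8)]
        assert lls[0] > lls[1] > lls[2]


class TestRecoverSources:
    def test_identity_unmixing_returns_input(self):
        X = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(
            recover_sources(np.eye(3), X, np.zeros(3)), X
        )

    def test_zero_input_gives_zero_sources(self):
        out = recover_sources(np.ones((2, 3)), np.zeros((3, 5)), np.zeros(3))
        assert np.all(out == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recover_sources(np.eye(2), np.zeros((3, 5)), np.zeros(3))


class TestCanonicalize:
    def test_idempotent_and_reconstruction_invariant(self, fitted_ica):
        res, rec, truth = fitted_ica
        once = canonicalize(res)
        twice = canonicalize(once)
        np.testing.assert_allclose(once.sources, twice.sources, atol=1e-12)
        recon_before = res.mixing_estimate @ res.sources
        recon_after = once.mixing_estimate @ once.sources
        np.testing.assert_allclose(recon_before, recon_after, atol=1e-10)

    def test_components_ordered_by_contribution_variance(self, fitted_ica):
        res, _, _ = fitted_ica
        contrib = np.sum(res.mixing_estimate**2, axis=0) * res.sources.var(axis=1)
        assert np.all(np.diff(contrib) <= 1e-9)

    def test_peak_sample_positive(self, fitted_ica):
        res, _, _ = fitted_ica
        for row in res.sources:
            assert row[np.argmax(np.abs(row))] >= 0


class TestEndToEndSeparation:
    def test_noiseless_recovery_matches_ground_truth(self, fitted_ica):
        res, rec, truth = fitted_ica
        matched = match_abs_pcc(res.sources, truth.sources)
        assert np.all(matched >= 0.99)

    def test_global_matrix_is_permutation_scaling(self, fitted_ica):
        res, rec, truth = fitted_ica
        G = np.abs(res.unmixing_total @ truth.mixing)
        G = G / G.max(axis=1, keepdims=True)
        # exactly one dominant entry per row/column; others < 0.05
        assert np.sort(G.ravel())[::-1][G.shape[0]] < 0.05
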