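"""Whitening, constrained pair extraction, and model-level invariants."""

import numpy as np
import pytest

from rpcca.canonical import classical_cca, fit, refit_from, whiten
from rpcca.divergence import ProjectionScores, rp_normal, rp_value
from rpcca.errors import DomainError


def _unit(w):
    return w / np.linalg.norm(w)


class TestWhiten:
    def test_whitened_moments(self, rng):
        data = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        white, tr = whiten(data)
        assert tr.applied
        np.testing.assert_allclose(white.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.cov(white, rowvar=False, ddof=1), np.eye(5), atol=1e-8)
        np.testing.assert_allclose(tr.inv_sqrt @ tr.cov @ tr.inv_sqrt, np.eye(5), atol=1e-8)

    def test_identity_covariance_is_near_noop(self, rng):
        data = rng.standard_normal((5000, 3))
        white, tr = whiten(data)
        centered = data - data.mean(axis=0)
        # sample covariance is close to I, so whitening barely moves the data
        assert np.max(np.abs(white - centered)) < 0.2

    def test_rank_deficient_falls_back_to_centering(self, rng):
        base = rng.standard_normal((100, 2))
        data = np.column_stack([base, base[:, 0]])  # duplicated column
        white, tr = whiten(data)
        assert not tr.applied
        np.testing.assert_allclose(white, data - data.mean(axis=0), atol=1e-12)


class TestFit:
    def test_scalar_blocks(self, rng):
        x = rng.standard_normal(120)
        y = 0.8 * x + 0.6 * rng.standard_normal(120)
        model = fit(x, y, tau=0.3, n_pairs=1, restarts=3, seed=0)
        pair = model.pairs[0]
        # constraint set is {+-1}x{+-1} in whitened coordinates; the sign
        # convention forces +1, i.e. a = 1/sd(x) in original coordinates
        assert pair.a_white[0] == pytest.approx(1.0, abs=1e-8)
        assert pair.b_white[0] == pytest.approx(1.0, abs=1e-8)
        u = (x - x.mean()) / np.std(x, ddof=1)
        v = (y - y.mean()) / np.std(y, ddof=1)
        assert pair.divergence.value == pytest.approx(
            rp_value(ProjectionScores(u, v), 0.3).value, abs=1e-8
        )

    def test_constraint_satisfaction(self, benchmark_data):
        X, Y = benchmark_data
        model = fit(X, Y, tau=0.0, n_pairs=2, restarts=6, seed=1)
        Sx = np.cov(X, rowvar=False, ddof=1)
        Sy = np.cov(Y, rowvar=False, ddof=1)
        for pair in model.pairs:
            assert pair.a @ Sx @ pair.a == pytest.approx(1.0, abs=1e-6)
            assert pair.b @ Sy @ pair.b == pytest.approx(1.0, abs=1e-6)
        a1, a2 = model.pairs[0].a, model.pairs[1].a
        b1, b2 = model.pairs[0].b, model.pairs[1].b
        assert abs(_unit(a1) @ _unit(a2)) < 1e-6
        assert abs(_unit(b1) @ _unit(b2)) < 1e-6

    def test_divergence_non_increasing(self, benchmark_data):
        X, Y = benchmark_data
        model = fit(X, Y, tau=0.0, n_pairs=2, restarts=6, seed=1)
        assert model.pairs[1].divergence.value <= model.pairs[0].divergence.value + 1e-4

    def test_sign_convention(self, benchmark_data):
        X, Y = benchmark_data
        model = fit(X, Y, tau=0.3, n_pairs=1, restarts=4, seed=3)
        for pair in model.pairs:
            assert pair.a_white[np.argmax(np.abs(pair.a_white))] > 0
            assert pair.b_white[np.argmax(np.abs(pair.b_white))] > 0

    def test_matches_classical_cca_under_normality(self):
        # jointly normal blocks with leading canonical correlation 0.6: the
        # RP maximizer coincides with CCA and the achieved divergence
        # approaches the closed form at the canonical rho
        gen = np.random.default_rng(31)
        n = 2000
        X = gen.standard_normal((n, 3))
        Y = np.column_stack([
            0.6 * X[:, 0] + 0.8 * gen.standard_normal(n),
            gen.standard_normal(n),
        ])
        model = fit(X, Y, tau=0.3, n_pairs=1, restarts=4, seed=5)
        u, v = model.scores(X, Y, 1)
        rho_fit = abs(np.corrcoef(u, v)[0, 1])
        _, _, corr = classical_cca(X, Y, 1)
        assert rho_fit == pytest.approx(corr[0], abs=0.05)
        assert model.pairs[0].divergence.value == pytest.approx(
            rp_normal(corr[0], 0.3), abs=0.05
        )

    def test_classical_cca_against_sklearn(self, rng):
        sklearn_cca = pytest.importorskip("sklearn.cross_decomposition").CCA
        X = rng.standard_normal((300, 4))
        Y = 0.5 * X[:, :2] + rng.standard_normal((300, 2))
        A, B, corr = classical_cca(X, Y, 1)
        ref = sklearn_cca(n_components=1).fit(X, Y)
        xs, ys = ref.transform(X, Y)
        ref_corr = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert corr[0] == pytest.approx(ref_corr, abs=1e-6)
        # sklearn's iterative NIPALS direction agrees with the SVD solution
        # to ~1e-5 in angle
        assert abs(np.corrcoef(X @ A[:, 0], xs[:, 0])[0, 1]) == pytest.approx(1.0, abs=1e-3)

    def test_score_equivariance_under_invertible_map(self, benchmark_data):
        X, Y = benchmark_data
        gen = np.random.default_rng(17)
        T = gen.standard_normal((8, 8)) + 4 * np.eye(8)
        m1 = fit(X, Y, tau=0.0, n_pairs=1, restarts=6, seed=2)
        m2 = fit(X @ T.T, Y, tau=0.0, n_pairs=1, restarts=6, seed=2)
        u1, _ = m1.scores(X, Y, 1)
        u2, _ = m2.scores(X @ T.T, Y, 1)
        assert abs(np.corrcoef(u1, u2)[0, 1]) > 0.99

    def test_joint_row_permutation_leaves_model_unchanged(self, benchmark_data):
        X, Y = benchmark_data
        gen = np.random.default_rng(23)
        perm = gen.permutation(X.shape[0])
        m1 = fit(X, Y, tau=0.3, n_pairs=1, restarts=4, seed=4)
        m2 = fit(X[perm], Y[perm], tau=0.3, n_pairs=1, restarts=4, seed=4)
        assert m1.pairs[0].divergence.value == pytest.approx(
            m2.pairs[0].divergence.value, abs=1e-6
        )
        assert abs(_unit(m1.pairs[0].a) @ _unit(m2.pairs[0].a)) > 1 - 1e-6

    def test_restart_stability(self, benchmark_data):
        X, Y = benchmark_data
        values = [
            fit(X, Y, tau=0.0, n_pairs=1, restarts=6, seed=s).pairs[0].divergence.value
            for s in range(5)
        ]
        assert max(values) - min(values) < 1e-3

    def test_fallback_constraints_in_original_coordinates(self, rng):
        base = rng.standard_normal((80, 2))
        X = np.column_stack([base, base[:, 0]])  # singular covariance
        Y = 0.7 * base + rng.standard_normal((80, 2))
        model = fit(X, Y, tau=0.3, n_pairs=1, restarts=4, seed=6)
        assert not model.transform_x.applied
        Sx = np.cov(X, rowvar=False, ddof=1)
        assert model.pairs[0].a @ Sx @ model.pairs[0].a == pytest.approx(1.0, abs=1e-6)

    def test_refit_from_tracks_local_optimum(self, benchmark_data):
        # a tiny perturbation of the data should move the continuation
        # refit only slightly, and the refit must satisfy the constraints
        X, Y = benchmark_data
        model = fit(X, Y, tau=0.3, n_pairs=1, restarts=5, seed=8)
        gen = np.random.default_rng(8)
        Y_pert = Y + 1e-4 * Y.std(axis=0, ddof=1) * gen.standard_normal(Y.shape)
        refit = refit_from(model, X, Y_pert)
        assert abs(_unit(model.pairs[0].a) @ _unit(refit.pairs[0].a)) > 0.999
        Sy = np.cov(Y_pert, rowvar=False, ddof=1)
        assert refit.pairs[0].b @ Sy @ refit.pairs[0].b == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self, benchmark_data):
        X, Y = benchmark_data
        with pytest.raises(DomainError):
            fit(X, Y, tau=0.3, n_pairs=5)
        with pytest.raises(DomainError):
            fit(X, Y, tau=-0.1, n_pairs=1)
        with pytest.raises(DomainError):
            fit(X[:50], Y, tau=0.3, n_pairs=1)
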