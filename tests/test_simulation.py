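"""Data-generating processes, contamination, metrics, Monte Carlo driver."""

import numpy as np
import pandas as pd
import pytest

from rpcca.canonical import classical_cca
from rpcca.divergence import ProjectionScores, rp_kl_hat
from rpcca.errors import DomainError, InvalidInputError
from rpcca.simulation import (
    SimulationConfig,
    TRUE_STRUCTURE,
    abs_corr,
    contaminate,
    l2_dist,
    p2_dist,
    run_monte_carlo,
    simulate_linear_quadratic,
    simulate_hidden_quadratic,
)


class TestSection62:
    def test_clean_relations_hold_exactly(self):
        X, Y = simulate_linear_quadratic(200, 0.0, seed=1)
        np.testing.assert_array_equal(Y[:, 0], (2 * X[:, 0] + X[:, 1] + X[:, 2]) ** 2)
        np.testing.assert_array_equal(Y[:, 1], X[:, 1] - X[:, 2])

    def test_contamination_swaps_exact_count(self):
        X, Y = simulate_linear_quadratic(100, 0.2, seed=2)
        w = 2 * X[:, 0] + X[:, 1] + X[:, 2]
        violated = Y[:, 0] != w**2
        assert violated.sum() == 20
        assert np.all(Y[violated, 1] != (X[:, 1] - X[:, 2])[violated])

    def test_component_distributions(self):
        X, _ = simulate_linear_quadratic(100_000, 0.0, seed=3)
        assert X[:, 2].mean() == pytest.approx(7.0, abs=0.1)   # chi^2_7 mean
        assert X[:, 2].var() == pytest.approx(14.0, rel=0.05)  # chi^2_7 variance
        assert X[:, 0].std() == pytest.approx(1.0, abs=0.02)

    def test_true_vectors_euclidean_orthogonal(self):
        t = TRUE_STRUCTURE
        assert t.a1 @ t.a2 == 0
        assert t.b1 @ t.b2 == 0


class TestContaminate:
    def test_rows_outside_mask_identical(self):
        gen = np.random.default_rng(4)
        Y = gen.standard_normal((50, 3))
        Yc, mask = contaminate(Y, 0.1, seed=5)
        assert mask.sum() == 5
        np.testing.assert_array_equal(Yc[~mask], Y[~mask])
        np.testing.assert_array_equal(Yc[mask, 2], Y[mask, 2])

    def test_values_exchanged_on_standardized_scale(self):
        gen = np.random.default_rng(7)
        Y = np.column_stack([20.0 * gen.standard_normal(60) + 5.0,
                             gen.standard_normal(60)])
        Yc, mask = contaminate(Y, 0.1, seed=8)
        m, s = Y.mean(axis=0), Y.std(axis=0, ddof=1)
        z = (Y - m) / s
        np.testing.assert_allclose(Yc[mask, 0], m[0] + s[0] * z[mask, 1], rtol=1e-12)
        np.testing.assert_allclose(Yc[mask, 1], m[1] + s[1] * z[mask, 0], rtol=1e-12)
        # each column's scale is essentially preserved despite the 20x
        # disparity between the two raw columns
        assert np.std(Yc[:, 1], ddof=1) < 2.0 * s[1]


class TestHiddenQuadratic:
    def test_blocks_uncorrelated_but_dependent(self):
        X, Y = simulate_hidden_quadratic(100_000, seed=6)
        cross = np.cov(np.column_stack([X, Y]), rowvar=False)[0:2, 2:4]
        assert np.max(np.abs(cross)) < 0.05
        assert np.all(Y[:, 0] - Y[:, 1] >= 0)  # Y1 - Y2 = X1^2

    def test_cca_blind_but_divergence_positive(self):
        X, Y = simulate_hidden_quadratic(5000, seed=7)
        _, _, corr = classical_cca(X, Y, 1)
        assert corr[0] < 0.2
        kl = rp_kl_hat(ProjectionScores(X[:, 0], Y[:, 0])).value
        assert kl > 0.1


class TestMetrics:
    def test_abs_corr_sign_invariance(self, benchmark_data):
        X, _ = benchmark_data
        t = TRUE_STRUCTURE
        assert abs_corr(t.a1, t.a1, X) == pytest.approx(1.0)
        assert abs_corr(t.a1, -t.a1, X) == pytest.approx(1.0)

    def test_abs_corr_independent_components(self):
        X, _ = simulate_linear_quadratic(50_000, 0.0, seed=8)
        e2, e6 = np.eye(8)[1], np.eye(8)[5]
        assert abs_corr(e2, e6, X) < 0.05

    def test_abs_corr_degenerate(self, benchmark_data):
        X, _ = benchmark_data
        with pytest.raises(InvalidInputError):
            abs_corr(np.zeros(8), TRUE_STRUCTURE.a1, X)

    def test_l2_dist(self):
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert l2_dist(e1, e1) == 0.0
        assert l2_dist(e1, -e1) == 0.0  # sign alignment
        assert l2_dist(e1, e2) == pytest.approx(np.sqrt(2))
        with pytest.raises(InvalidInputError):
            l2_dist(e1, np.ones(4))

    def test_p2_dist(self):
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert p2_dist(e1, e1) == 0.0
        assert p2_dist(e1, e2) == pytest.approx(1.0)
        assert p2_dist(e1, -e2) == pytest.approx(p2_dist(e1, e2))
        assert p2_dist(5.0 * e1, e1) == 0.0  # projector built from the unit vector


class TestMonteCarlo:
    def test_deterministic_under_seeding(self):
        cfg = SimulationConfig(n=60, epsilon=0.0, tau_grid=(0.0,), replicates=1,
                               seed=11, restarts=2)
        r1 = run_monte_carlo(cfg)
        r2 = run_monte_carlo(cfg)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_contaminated_metrics_only_with_epsilon(self):
        clean = run_monte_carlo(
            SimulationConfig(n=60, epsilon=0.0, tau_grid=(0.0,), replicates=1,
                             seed=12, restarts=2)
        )
        cont = run_monte_carlo(
            SimulationConfig(n=60, epsilon=0.1, tau_grid=(0.0,), replicates=1,
                             seed=12, restarts=2)
        )
        assert "p2_a" not in set(clean.table["metric"])
        assert {"p2_a", "l2_a", "rho_a_cont"} <= set(cont.table["metric"])
        wide = cont.to_wide()
        assert "tau=0" in wide.columns

    def test_config_validation(self):
        with pytest.raises(DomainError):
            SimulationConfig(epsilon=1.2)
        with pytest.raises(DomainError):
            SimulationConfig(dgp="unknown")
        with pytest.raises(DomainError):
            SimulationConfig(tau_grid=(-0.1,))
        assert SimulationConfig(n=100, epsilon=0.05).n_contaminated == 5
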