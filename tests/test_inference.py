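"""Boosting inference: standardization, score components, fit, binarization."""

import math

import numpy as np
import pytest
from scipy import stats

from netsam.inference import (
    BoostingConfig,
    CoefficientMatrix,
    _degree_prior,
    boosting_fit,
    build_network,
    edge_confidence,
    initial_coefficients,
    posterior_score,
    residual_sum_squares,
    scale_free_prior,
    score_components,
    standardize,
)
from netsam.io import ExpressionMatrix
from netsam.simulate import SimulationConfig, generate_case_control


def _expr(rows, log_scale=True):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return ExpressionMatrix(
        [f"g{i}" for i in range(rows.shape[0])],
        [f"s{j}" for j in range(rows.shape[1])],
        rows,
        log_scale,
    )


def _orthonormal_zero_mean_rows(n_rows, n_cols, seed=0):
    """Random zero-mean rows orthonormalized by QR on the centered matrix."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(n_cols, n_rows + 1))
    m -= m.mean(axis=0)
    q, _ = np.linalg.qr(m)
    rows = q[:, :n_rows].T
    rows -= rows.mean(axis=1, keepdims=True)  # QR of centered cols keeps mean ~0
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


class TestStandardize:
    def test_three_point_row(self):
        out = standardize(_expr([[1.0, 2.0, 3.0]] * 2))
        expected = np.array([-1, 0, 1]) / math.sqrt(2)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-15)

    def test_constant_row_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = standardize(_expr([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        assert out.gene_ids == ["g0"]
        assert "zero-variance" in caplog.text

    def test_idempotent(self):
        once = standardize(_expr(np.random.default_rng(1).normal(size=(4, 9))))
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(_expr([[1.0, 1.0, 1.0]]))


class TestInitialCoefficients:
    def test_orthogonal_identical_and_opposite_rows(self):
        base = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2)
        orth = np.array([1.0, -2.0, 1.0]) / math.sqrt(6)
        expr = _expr(np.vstack([base, base, -base, orth]))
        beta = initial_coefficients(expr).beta
        assert beta[0, 0] == 0.0
        np.testing.assert_allclose(beta[0, 1], 1.0, atol=1e-12)
        np.testing.assert_allclose(beta[0, 2], -1.0, atol=1e-12)
        np.testing.assert_allclose(beta[0, 3], 0.0, atol=1e-12)
        # correlations are bounded
        assert np.all(np.abs(beta) <= 1 + 1e-12)


class TestRSS:
    def test_zero_coefficients_on_unit_norm_target(self):
        expr = standardize(_expr(np.random.default_rng(0).normal(size=(3, 6))))
        rss = residual_sum_squares(0, expr, np.zeros(3))
        np.testing.assert_allclose(rss, 1.0, atol=1e-12)

    def test_perfect_fit_gives_zero(self):
        rows = np.array([[1.0, 2.0, -1.0], [0.5, 1.0, -0.5], [3.0, 0.0, 1.0]])
        expr = _expr(rows)
        rss = residual_sum_squares(0, expr, np.array([0.0, 2.0, 0.0]))
        np.testing.assert_allclose(rss, 0.0, atol=1e-12)

    def test_hand_expanded_two_gene_example(self):
        # x0=(1,0), x1=(0,1), beta_01=0.5 -> residual (1, -0.5), RSS=1.25
        expr = _expr([[1.0, 0.0], [0.0, 1.0]])
        assert residual_sum_squares(0, expr, np.array([0.0, 0.5])) == 1.25

    def test_nonzero_at_target_rejected(self):
        expr = _expr([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero at the target"):
            residual_sum_squares(0, expr, np.array([1.0, 0.5]))


class TestScaleFreePrior:
    def test_perfect_power_law_gives_maximal_prior(self):
        # degree bins {1,2,4,8} with counts {8,4,2,1}: log-freq exactly
        # linear in log-degree, so |C| = 1 and log C^2 = 0.
        degrees = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])
        c, log_prior = _degree_prior(degrees)
        np.testing.assert_allclose(c, -1.0, atol=1e-12)
        np.testing.assert_allclose(log_prior, 0.0, atol=1e-12)

    def test_two_bins_is_neutral(self):
        c, log_prior = _degree_prior(np.array([1.0, 1.0, 2.0]))
        assert math.isnan(c)
        assert log_prior == 0.0

    def test_three_bin_pearson_oracle(self):
        # bins {1,2,3} with counts {5,3,2}: compare against a direct
        # Pearson correlation on the (log d, log freq) points.
        degrees = np.repeat([1.0, 2.0, 3.0], [5, 3, 2])
        c, log_prior = _degree_prior(degrees)
        ref = stats.pearsonr(
            np.log([1.0, 2.0, 3.0]), np.log(np.array([5, 3, 2]) / 10)
        ).statistic
        np.testing.assert_allclose(c, ref, atol=1e-12)
        np.testing.assert_allclose(log_prior, math.log(ref**2), atol=1e-12)

    def test_matrix_interface_uses_column_sums(self):
        p = 15
        beta = np.zeros((p, p))
        degrees = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])
        beta[0, 1:] = degrees[1:]
        beta[1, 0] = degrees[0]
        c, log_prior = scale_free_prior(CoefficientMatrix([f"g{i}" for i in range(p)], beta))
        np.testing.assert_allclose(abs(c), 1.0, atol=1e-12)
        np.testing.assert_allclose(log_prior, 0.0, atol=1e-12)


class TestPosteriorScore:
    def test_unit_rss_neutral_prior(self):
        assert abs(posterior_score(1.0, 0.0)) < 1e-9

    def test_inverse_e_rss(self):
        np.testing.assert_allclose(posterior_score(math.exp(-1), 0.0), 1.0, atol=1e-9)

    def test_direct_arithmetic(self):
        eps = 1e-12
        expected = -math.log(0.5 + eps) + math.log(0.81)
        np.testing.assert_allclose(
            posterior_score(0.5, math.log(0.81), eps), expected, rtol=1e-15
        )

    def test_perfect_fit_hits_epsilon_floor(self):
        np.testing.assert_allclose(
            posterior_score(0.0, 0.0, 1e-12), -math.log(1e-12), rtol=1e-15
        )

    def test_decomposition_matches_components(self):
        rng = np.random.default_rng(2)
        expr = standardize(_expr(rng.normal(size=(8, 12))))
        beta = boosting_fit(expr, BoostingConfig(n_iterations=20))
        for i in (0, 3, 7):
            comp = score_components(expr, beta, i)
            assert abs(comp.posterior - (comp.log_likelihood + comp.log_prior)) < 1e-12
            assert comp.log_likelihood == -math.log(comp.rss + 1e-12)


class TestBoostingFit:
    def test_zero_iterations_gives_zero_matrix(self):
        expr = standardize(_expr(np.random.default_rng(0).normal(size=(4, 8))))
        beta = boosting_fit(expr, BoostingConfig(n_iterations=0))
        assert np.all(beta.beta == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_collinear_gene_always_selected_first(self, seed):
        """With x2 = 0.8 * x0 (noiseless) and an independent x1, the
        regression of gene 2 must select gene 0 at every round and never
        touch gene 1."""
        rng = np.random.default_rng(seed)
        x0 = rng.normal(size=20)
        x1 = rng.normal(size=20)
        expr = standardize(_expr(np.vstack([x0, x1, 0.8 * x0])))
        beta = boosting_fit(expr, BoostingConfig(n_iterations=50, use_prior=False))
        assert beta.beta[2, 0] > 0.5
        assert beta.beta[2, 1] == 0.0

    def test_accepted_scores_are_nondecreasing(self):
        _, control, _ = generate_case_control(
            SimulationConfig(n_genes=10, n_samples=30, target_edges=15,
                             n_de_genes=2, seed=3)
        )
        expr = standardize(control)
        _, traces = boosting_fit(expr, return_score_trace=True)
        for trace in traces:
            diffs = np.diff(trace)
            assert np.all(diffs > 0)

    def test_requires_standardized_input(self):
        expr = _expr(np.random.default_rng(0).normal(size=(3, 6)) + 5.0)
        with pytest.raises(ValueError, match="standardize"):
            boosting_fit(expr)

    def test_prior_disabled_recovers_orthonormal_projections(self):
        """On a target that is a linear combination of orthonormal
        predictors, likelihood-only boosting converges to the univariate
        projections x_j^T x_i (closed-form least squares)."""
        preds = _orthonormal_zero_mean_rows(4, 12, seed=7)
        target = 0.9 * preds[0] - 0.5 * preds[1] + 0.2 * preds[2]
        target /= np.linalg.norm(target)
        rows = np.vstack([target, preds])
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(12)], rows, True
        )
        beta = boosting_fit(
            expr, BoostingConfig(n_iterations=600, use_prior=False)
        )
        projections = rows[1:] @ rows[0]
        np.testing.assert_allclose(beta.beta[0, 1:], projections, atol=1e-4)


class TestBuildNetwork:
    def test_sign_rule_examples(self):
        beta = np.zeros((3, 3))
        beta[0, 1], beta[1, 0] = 0.5, -0.2  # nonzero product -> edge
        beta[0, 2], beta[2, 0] = 0.5, 0.0   # zero product -> no edge
        net = build_network(CoefficientMatrix(["a", "b", "c"], beta))
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 0] == 1
        assert net.adjacency[0, 2] == 0

    def test_same_sign_variant_drops_opposed_pairs(self):
        beta = np.zeros((2, 2))
        beta[0, 1], beta[1, 0] = 0.5, -0.2
        net = build_network(CoefficientMatrix(["a", "b"], beta),
                            require_same_sign=True)
        assert net.n_edges == 0

    def test_all_zero_beta_gives_empty_network(self):
        net = build_network(CoefficientMatrix(["a", "b"], np.zeros((2, 2))))
        assert net.n_edges == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_zero_diagonal_on_random_beta(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=(10, 10)) * rng.integers(0, 2, size=(10, 10))
        np.fill_diagonal(b, 0.0)
        net = build_network(CoefficientMatrix([f"g{i}" for i in range(10)], b))
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert np.all(np.diag(net.adjacency) == 0)

    def test_edge_confidence_is_mean_of_directed_magnitudes(self):
        beta = np.zeros((2, 2))
        beta[0, 1], beta[1, 0] = 0.6, -0.2
        conf = edge_confidence(CoefficientMatrix(["a", "b"], beta))
        np.testing.assert_allclose(conf[0, 1], 0.4)
        np.testing.assert_allclose(conf, conf.T)
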