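import numpy as np
import pytest
from scipy.optimize import minimize

from lldnet.association import AssociationMatrix
from lldnet.network import (
    GlassoConfig,
    GlassoError,
    ebic_score,
    fit_network,
    glasso_path,
    select_ebic,
)


def assoc(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"v{i}" for i in range(values.shape[0])]
    return AssociationMatrix(labels=labels, values=values)


def glasso_objective(K, S, lam):
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    off = np.abs(K - np.diag(np.diag(K))).sum()
    return -logdet + np.sum(S * K) + lam * off


def brute_force_glasso(S, lam, n_starts=6):
    """Direct minimization of the penalized negative log-likelihood over
    symmetric matrices via Cholesky parametrization (independent oracle
    for <= 4 nodes)."""
    p = S.shape[0]
    tril = np.tril_indices(p)

    def unpack(theta):
        L = np.zeros((p, p))
        L[tril] = theta
        return L @ L.T

    best = None
    rng = np.random.default_rng(0)
    for s in range(n_starts):
        L0 = np.linalg.cholesky(np.linalg.inv(S) if s == 0 else
                                np.eye(p) + 0.1 * s * np.diag(rng.random(p)))
        res = minimize(lambda th: glasso_objective(unpack(th), S, lam),
                       L0[tril], method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestGlassoPath:
    def test_identity_gives_no_edges(self):
        path = glasso_path(assoc(np.eye(4)), n=100, config=GlassoConfig(n_lambda=10))
        for _, K, _ in path:
            assert np.allclose(K - np.diag(np.diag(K)), 0.0)

    def test_lambda_max_boundary_is_empty(self):
        S = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1.0]])
        lam, K, _ = glasso_path(assoc(S), n=500, config=GlassoConfig(n_lambda=5))[0]
        assert np.allclose(K - np.diag(np.diag(K)), 0.0, atol=1e-10)

    def test_three_node_partial_correlation_closed_form(self):
        """r12 = r23 = .5, r13 = .25: the 1-3 partial correlation is exactly
        0 ((.25 - .25)/.75), and w12 = w23 = .5/sqrt(1.25) ~ .447."""
        S = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1.0]])
        path = glasso_path(assoc(S), n=10_000, config=GlassoConfig(lambda_min_ratio=0.001))
        from lldnet.network import _partial_corr
        W = _partial_corr(path[-1][1])
        assert abs(W[0, 2]) < 0.02
        assert W[0, 1] == pytest.approx(0.447, abs=0.01)
        assert W[1, 2] == pytest.approx(0.447, abs=0.01)

    def test_two_node_soft_threshold_closed_form(self):
        """2-node graphical lasso has the closed form: off-diagonal of the
        covariance estimate is sign(r) max(|r| - lambda, 0)."""
        for r, lam_frac in [(0.6, 0.5), (0.6, 0.05), (-0.4, 0.3)]:
            S = np.array([[1.0, r], [r, 1.0]])
            cfg = GlassoConfig(n_lambda=2, lambda_min_ratio=lam_frac)
            path = glasso_path(assoc(S), 1000, cfg)
            for lam, K, _ in path:
                rt = np.sign(r) * max(abs(r) - lam, 0.0)
                K_expect = np.linalg.inv(np.array([[1.0, rt], [rt, 1.0]]))
                assert np.abs(K - K_expect).max() < 1e-4

    def test_matches_brute_force_objective(self):
        """Solver objective matches a derivative-free direct minimization."""
        rng = np.random.default_rng(3)
        A = rng.standard_normal((40, 3))
        S = np.corrcoef(A.T)
        for lam in (0.05, 0.2):
            path = glasso_path(assoc(S), n=40,
                               config=GlassoConfig(n_lambda=2, lambda_min_ratio=lam / 1.0))
            lam_used, K, _ = path[-1]
            obj = glasso_objective(K, S, lam_used)
            oracle = brute_force_glasso(S, lam_used)
            assert obj <= oracle + 1e-5

    def test_sample_size_guard(self):
        with pytest.raises(GlassoError, match="exceed"):
            glasso_path(assoc(np.eye(4)), n=4)


class TestEbicSelection:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(1)
        K = np.eye(3)
        K[0, 1] = K[1, 0] = -0.3
        assert ebic_score(-10.0, K, 100, gamma=0.0) == pytest.approx(
            20.0 + 1 * np.log(100))

    def test_tie_breaks_toward_sparser_model(self):
        K_sparse = np.eye(2)
        K_dense = np.array([[1.0, -0.2], [-0.2, 1.0]])
        # craft two path entries with identical EBIC: loglik compensates
        n = 100
        ll_sparse = -5.0
        ll_dense = ll_sparse - np.log(n) / 2  # dense pays one edge penalty
        path = [(0.5, K_sparse, ll_sparse), (0.1, K_dense, ll_dense)]
        net = select_ebic(path, n=n)
        assert net.lambda_selected == 0.5
        assert net.n_edges == 0

    def test_null_two_node_selects_empty_network(self):
        rng = np.random.default_rng(2)
        best_empty = 0
        for _ in range(5):
            X = rng.standard_normal((1000, 2))
            S = np.corrcoef(X.T)
            net = fit_network(assoc(S), n=1000)
            best_empty += net.n_edges == 0
        assert best_empty >= 4

    def test_weights_are_partial_correlations(self, baseline_cohort):
        from lldnet.association import association_matrix
        table, _ = baseline_cohort
        A = association_matrix(table)
        path = glasso_path(A, table.n, GlassoConfig(n_lambda=20))
        net = select_ebic(path, table.n, GlassoConfig(n_lambda=20), labels=A.labels)
        W = net.weights
        assert np.allclose(W, W.T, atol=1e-8)
        assert np.allclose(np.diag(W), 0.0)
        assert np.all(np.abs(W) < 1)
        # sign of w_ij equals the negated precision sign
        k = next((lam, K) for lam, K, _ in path if lam == net.lambda_selected)[1]
        nz = np.abs(W) > 0
        assert np.all(np.sign(W[nz]) == -np.sign(k[nz]))

    def test_refit_is_bit_reproducible(self, baseline_cohort):
        from lldnet.association import association_matrix
        table, _ = baseline_cohort
        A = association_matrix(table)
        n1 = fit_network(A, table.n, GlassoConfig(n_lambda=15))
        n2 = fit_network(A, table.n, GlassoConfig(n_lambda=15))
        assert np.array_equal(n1.weights, n2.weights)
        assert n1.lambda_selected == n2.lambda_selected
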