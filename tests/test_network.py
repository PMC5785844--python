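import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdim import (
    DS_ES_32,
    ItemResponseMatrix,
    SimulationConfig,
    ebic,
    glasso_path,
    nearest_positive_definite,
    network_to_edgelist,
    pearson_correlation,
    polychoric_correlation,
    precision_to_pcor,
    select_network,
    simulate_dataset,
)
from netdim.network import CorrelationEstimate, EstimationError
from netdim.simulate import QUINTILE_THRESHOLDS


def kkt_residual(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Largest violation of the penalized-likelihood stationarity conditions.

    With W = theta^-1: diagonal W_ii = S_ii; for nonzero off-diagonal
    theta_ij, S_ij - W_ij + lam*sign(theta_ij) = 0; for zero entries
    |S_ij - W_ij| <= lam."""
    W = np.linalg.inv(theta)
    p = S.shape[0]
    resid = abs(np.diag(W) - np.diag(S)).max()
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if theta[i, j] != 0.0:
                resid = max(resid, abs(S[i, j] - W[i, j] + lam * np.sign(theta[i, j])))
            else:
                resid = max(resid, max(abs(S[i, j] - W[i, j]) - lam, 0.0))
    return resid


class TestPearson:
    def test_duplicate_and_reversed_columns(self):
        x = np.array([[0, 0, 4], [1, 1, 3], [2, 2, 2], [3, 3, 1], [4, 4, 0]])
        r = pearson_correlation(x).matrix
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_hand_table(self):
        x = np.array([[1, 2, 0], [3, 1, 2], [0, 4, 1], [2, 0, 3], [4, 3, 4]], dtype=float)

        def hand_r(a, b):
            n = len(a)
            num = n * np.sum(a * b) - a.sum() * b.sum()
            den = np.sqrt(n * np.sum(a**2) - a.sum() ** 2) * np.sqrt(
                n * np.sum(b**2) - b.sum() ** 2)
            return num / den

        r = pearson_correlation(x).matrix
        for i in range(3):
            for j in range(3):
                assert r[i, j] == pytest.approx(hand_r(x[:, i], x[:, j]), abs=1e-12)

    def test_constant_column_names_item(self):
        x = np.ones((10, 3))
        x[:, 1] = np.arange(10)
        with pytest.raises(EstimationError, match="column 0"):
            pearson_correlation(x)


def _two_item_matrix(rho, n, seed):
    lam = np.full((2, 1), np.sqrt(rho))
    cfg = SimulationConfig(n=n, loading_matrix=lam, factor_correlations=np.eye(1),
                           thresholds=np.asarray(QUINTILE_THRESHOLDS), seed=seed)
    return simulate_dataset(cfg).responses


class TestPolychoric:
    def test_recovers_generating_correlation(self):
        m = _two_item_matrix(0.6, 20_000, 1)
        est = polychoric_correlation(m)
        assert est.matrix[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_independent_items_near_zero(self):
        m = _two_item_matrix(0.0, 20_000, 2)
        est = polychoric_correlation(m)
        assert abs(est.matrix[0, 1]) < 0.02

    def test_identical_columns_clamp_to_one(self):
        m = _two_item_matrix(0.5, 200, 3)
        vals = np.column_stack([m.values[:, 0], m.values[:, 0]])
        dup = ItemResponseMatrix(values=vals, scale=m.scale)
        est = polychoric_correlation(dup)
        assert est.matrix[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_single_category_item_rejected(self):
        m = _two_item_matrix(0.5, 50, 4)
        vals = m.values.copy()
        vals[:, 1] = 2
        with pytest.raises(EstimationError, match="single category"):
            polychoric_correlation(ItemResponseMatrix(values=vals, scale=m.scale))


class TestNearestPD:
    def test_identity_on_pd_input(self, online_corr):
        assert nearest_positive_definite(online_corr) is online_corr

    def test_indefinite_input_becomes_pd(self):
        m = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(m).min() < 0
        est = CorrelationEstimate(matrix=m, method="pearson", n=50,
                                  positive_definite=False)
        sm = nearest_positive_definite(est)
        assert np.linalg.eigvalsh(sm.matrix).min() >= 1e-6 - 1e-12
        assert np.allclose(np.diag(sm.matrix), 1.0)
        assert sm.smoothed


class TestGlassoPath:
    def test_full_shrinkage_gives_diagonal_precision(self, online_corr):
        lam_max = np.abs(online_corr.matrix[np.triu_indices(32, 1)]).max()
        theta = glasso_path(online_corr, np.array([lam_max * 1.001]))[0]
        off = theta[~np.eye(32, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_lambda_to_zero_recovers_inverse(self):
        m = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        est = CorrelationEstimate(matrix=m, method="pearson", n=100,
                                  positive_definite=True)
        theta = glasso_path(est, np.array([1e-8]))[0]
        assert np.abs(theta - np.linalg.inv(m)).max() < 1e-4

    def test_kkt_conditions_along_path(self, online_corr):
        lams = np.logspace(np.log10(0.3), np.log10(0.01), 8)
        thetas = glasso_path(online_corr, lams)
        for lam, theta in zip(lams, thetas):
            assert kkt_residual(online_corr.matrix, theta, lam) < 1e-4

    def test_matches_independent_solver(self):
        graphical_lasso = pytest.importorskip("sklearn.covariance").graphical_lasso
        corr = pearson_correlation(_chain_sample(1))
        for lam in (0.15, 0.05, 0.01):
            ours = glasso_path(corr, np.array([lam]))[0]
            _, ref = graphical_lasso(corr.matrix, alpha=lam, max_iter=2000,
                                     tol=1e-10)
            assert np.abs(ours - ref).max() < 1e-4

    def test_increasing_path_rejected(self, online_corr):
        with pytest.raises(ValueError):
            glasso_path(online_corr, np.array([0.01, 0.1]))


class TestEbic:
    def test_gamma_zero_is_bic(self):
        assert ebic(-50.0, 7, 200, 10, 0.0) == pytest.approx(100 + 7 * np.log(200))

    def test_no_edges_reduces_to_deviance(self):
        assert ebic(-50.0, 0, 200, 10, 0.5) == pytest.approx(100.0)

    def test_hand_evaluation(self):
        expected = 200 + 10 * np.log(480) + 4 * 0.5 * 10 * np.log(32)
        assert ebic(-100.0, 10, 480, 32, 0.5) == pytest.approx(expected)


class TestPrecisionToPcor:
    def test_diagonal_precision_gives_zero(self):
        assert np.allclose(precision_to_pcor(np.diag([2.0, 2.0])), 0.0)

    def test_two_by_two_closed_form(self):
        theta = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert precision_to_pcor(theta)[0, 1] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_properties_for_pd_precision(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 6))
        theta = a @ a.T + 6 * np.eye(6)
        pcor = precision_to_pcor(theta)
        assert np.allclose(pcor, pcor.T)
        assert np.allclose(np.diag(pcor), 0.0)
        assert np.all(np.abs(pcor[~np.eye(6, dtype=bool)]) < 1.0)


def _chain_sample(seed, n=5000, p=6, val=-0.35):
    theta = np.eye(p)
    for i in range(p - 1):
        theta[i, i + 1] = theta[i + 1, i] = val
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(p), cov / np.outer(d, d), size=n)


class TestSelectNetwork:
    def test_recovers_strong_true_edges_of_chain_graph(self):
        # glasso path selection keeps every true edge; any spurious extras
        # are an order of magnitude weaker than the true partial
        # correlations, so a mild threshold isolates the exact support
        true_edges = {(i, i + 1) for i in range(5)}
        for seed in range(3):
            net = select_network(pearson_correlation(_chain_sample(seed)))
            pc = net.partial_correlations
            strong = {tuple(e) for e in np.argwhere(np.triu(np.abs(pc) > 0.05, 1))}
            support = {tuple(e) for e in np.argwhere(np.triu(np.abs(pc) > 1e-7, 1))}
            assert strong == true_edges
            assert support >= true_edges

    def test_selected_solution_satisfies_kkt(self, online_corr):
        net = select_network(online_corr)
        assert kkt_residual(online_corr.matrix, net.precision, net.lambda_selected) < 1e-4

    def test_edge_count_monotone_in_lambda(self):
        # strict monotone sparsity holds away from the dense end of the
        # path; near-saturated solutions can swap an edge or two, so the
        # clean invariant is checked on a sparse ground-truth graph
        corr = pearson_correlation(_chain_sample(0))
        lams = np.logspace(np.log10(0.5), np.log10(0.005), 40)
        thetas = glasso_path(corr, lams)
        counts = []
        for theta in thetas:
            pc = precision_to_pcor(theta)
            counts.append(int((np.abs(pc[np.triu_indices(6, 1)]) > 1e-7).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_larger_gamma_never_denser(self, online_corr):
        sparse = select_network(online_corr, gamma=1.0, n_lambda=40)
        dense = select_network(online_corr, gamma=0.0, n_lambda=40)
        assert sparse.edge_count <= dense.edge_count

    def test_population_factor_model_has_positive_within_edges(self):
        from netdim import population_correlation, scenario_config

        cfg = scenario_config("online_4dim")
        sigma = population_correlation(cfg)
        est = CorrelationEstimate(matrix=sigma, method="pearson", n=100_000,
                                  positive_definite=True)
        net = select_network(est)
        membership = cfg.true_membership
        pc = net.partial_correlations
        for i in range(32):
            for j in range(i + 1, 32):
                if membership[i] == membership[j]:
                    assert pc[i, j] > 0.0

    def test_edgelist_matches_matrix(self, online_corr):
        net = select_network(online_corr)
        df = network_to_edgelist(net, item_ids=DS_ES_32.item_ids)
        assert len(df) == net.edge_count
        row = df.iloc[0]
        i, j = int(row.source) - 1, int(row.target) - 1
        assert row.partial_correlation == pytest.approx(
            net.partial_correlations[i, j])
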