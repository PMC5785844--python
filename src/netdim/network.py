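"""Regularized partial-correlation network estimation.

Pipeline: item correlations (Pearson by default, polychoric for ordinal
purists) -> positive-definiteness check and smoothing -> graphical-lasso
penalty path -> EBIC selection -> sparse partial-correlation network.
Zeroed partial correlations are absent edges: the selected network contains
only direct, non-spurious item relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._glasso import glasso_path_kernel
from .scale import ItemResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEstimate",
    "RegularizedNetwork",
    "pearson_correlation",
    "polychoric_correlation",
    "nearest_positive_definite",
    "glasso_path",
    "ebic",
    "select_network",
    "precision_to_pcor",
    "network_to_edgelist",
    "write_graphml",
]

#: |partial correlation| above this counts as an edge (guards float noise).
EDGE_EPS = 1e-7

#: Smallest eigenvalue for a matrix to be called positive definite.
PD_EPS = 1e-8


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CorrelationEstimate:
    matrix: np.ndarray
    method: str
    n: int
    positive_definite: bool
    smoothed: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RegularizedNetwork:
    """EBIC-selected sparse Gaussian graphical model."""

    partial_correlations: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    gamma: float
    n: int
    p: int

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.sum(np.abs(self.partial_correlations[iu]) > EDGE_EPS))


def pearson_correlation(matrix: ItemResponseMatrix | np.ndarray) -> CorrelationEstimate:
    """Product-moment correlations of the (integer or continuous) columns."""
    x = matrix.values if isinstance(matrix, ItemResponseMatrix) else np.asarray(matrix, float)
    n, p = x.shape
    if n < 3:
        raise EstimationError("need at least 3 observations")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise EstimationError(f"column {j} is constant; correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    pd_flag = bool(np.linalg.eigvalsh(r).min() > PD_EPS)
    return CorrelationEstimate(matrix=r, method="pearson", n=n, positive_definite=pd_flag)


def _bivariate_cell_probs(rho: float, ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal.

    ta, tb: thresholds including -inf/+inf sentinels.  Uses the rectangle
    identity on the bivariate normal CDF."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
    big = 8.0
    a = np.clip(ta, -big, big)
    b = np.clip(tb, -big, big)
    aa, bb = np.meshgrid(a, b, indexing="ij")
    pts = np.column_stack([aa.ravel(), bb.ravel()])
    cdf = mvn.cdf(pts).reshape(len(a), len(b))
    cells = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def _polychoric_pair(table: np.ndarray) -> float:
    """Two-step polychoric estimate for one contingency table."""
    pa = table.sum(axis=1) / table.sum()
    pb = table.sum(axis=0) / table.sum()
    ta = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(pa)[:-1]), [np.inf]])
    tb = np.concatenate([[-np.inf], stats.norm.ppf(np.cumsum(pb)[:-1]), [np.inf]])

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(_bivariate_cell_probs(rho, ta, tb))))

    res = optimize.minimize_scalar(nll, bounds=(-1 + 1e-6, 1 - 1e-6), method="bounded",
                                   options={"xatol": 1e-5})
    if not res.success:
        raise EstimationError("polychoric optimization failed")
    return float(res.x)


def polychoric_correlation(matrix: ItemResponseMatrix) -> CorrelationEstimate:
    """Pairwise two-step polychoric correlations for ordinal items.

    Thresholds come from the marginal category proportions via the inverse
    normal CDF; the latent correlation of each pair then maximizes the
    bivariate-normal cell likelihood by bounded 1-D optimization.
    """
    x = matrix.values
    n, p = x.shape
    lo = matrix.scale.response_min
    ncat = matrix.scale.response_max - lo + 1
    for j in range(p):
        if len(np.unique(x[:, j])) < 2:
            raise EstimationError(
                f"item {matrix.scale.items[j].item_id} uses a single category"
            )
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if np.array_equal(x[:, i], x[:, j]):
                rho = 1.0 - 1e-6
            else:
                table = np.zeros((ncat, ncat))
                np.add.at(table, (x[:, i] - lo, x[:, j] - lo), 1.0)
                # drop empty marginal categories pairwise
                table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
                rho = _polychoric_pair(table)
            r[i, j] = r[j, i] = rho
    pd_flag = bool(np.linalg.eigvalsh(r).min() > PD_EPS)
    return CorrelationEstimate(matrix=r, method="polychoric", n=n,
                               positive_definite=pd_flag)


def nearest_positive_definite(corr: CorrelationEstimate, eps: float = 1e-6) -> CorrelationEstimate:
    """Eigenvalue-clipping projection to the nearest PD correlation matrix.

    Already-PD input is returned unchanged.  Otherwise eigenvalues are
    clipped below at eps and the matrix rescaled to unit diagonal,
    iterating until the smallest eigenvalue clears eps; the smoothing is
    logged (undersized samples routinely produce indefinite polychoric
    matrices, and smoothed results warrant cautious interpretation).
    """
    if corr.positive_definite:
        return corr
    m = corr.matrix.copy()
    for _ in range(100):
        w, v = np.linalg.eigh(m)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
    logger.warning(
        "correlation matrix was not positive definite; smoothed by eigenvalue "
        "clipping — interpret results with caution"
    )
    return CorrelationEstimate(matrix=m, method=corr.method, n=corr.n,
                               positive_definite=True, smoothed=True)


def glasso_path(
    corr: CorrelationEstimate,
    lambda_path: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> np.ndarray:
    """L1-penalized Gaussian MLE precision matrices along a decreasing
    penalty path (off-diagonal penalty only, warm starts).

    Returns an (n_lambda, p, p) array.  Each solution satisfies the KKT
    stationarity conditions of the penalized likelihood to within the
    convergence tolerance.
    """
    lams = np.asarray(lambda_path, dtype=float)
    if np.any(lams <= 0) or np.any(np.diff(lams) > 0):
        raise ValueError("lambda_path must be positive and non-increasing")
    S = corr.matrix
    if np.linalg.eigvalsh(S).min() <= 0:
        raise EstimationError(
            "correlation matrix is not positive definite; smooth it first "
            "(nearest_positive_definite)"
        )
    thetas, sweeps, conv = glasso_path_kernel(S, lams, max_iter, tol)
    if not conv.all():
        i = int(np.argmin(conv))
        raise EstimationError(
            f"glasso did not converge at lambda={lams[i]:.5g} "
            f"after {int(sweeps[i])} sweeps"
        )
    return thetas


def gaussian_loglik(S: np.ndarray, theta: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood of a precision matrix given sample
    correlation S (constants included)."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ theta) - p * np.log(2 * np.pi))


def ebic(loglik: float, E: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2*loglik + E*log(n) + 4*gamma*E*log(p).

    gamma=0 reduces to the ordinary BIC; larger gamma penalizes dense
    graphs more heavily.
    """
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def precision_to_pcor(theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix:
    rho_ij = -theta_ij / sqrt(theta_ii * theta_jj), zero diagonal."""
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return 0.5 * (pcor + pcor.T)


def _count_edges(theta: np.ndarray) -> int:
    pcor = precision_to_pcor(theta)
    iu = np.triu_indices(theta.shape[0], 1)
    return int(np.sum(np.abs(pcor[iu]) > EDGE_EPS))


def select_network(
    corr: CorrelationEstimate,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> RegularizedNetwork:
    """EBIC-selected sparse partial-correlation network.

    A log-spaced path of n_lambda penalties runs from the smallest penalty
    that zeroes every edge (max |off-diagonal correlation|) down to
    lambda_min_ratio times that; the EBIC minimizer along the path is
    returned as a partial-correlation network.  Non-PD input is smoothed
    first with a logged warning.
    """
    corr = nearest_positive_definite(corr)
    S = corr.matrix
    p, n = corr.p, corr.n
    off = np.abs(S[np.triu_indices(p, 1)])
    lam_max = float(off.max())
    if lam_max <= EDGE_EPS:
        lam_max = 0.1  # no association at all; any penalty gives the empty graph
    lams = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)
    # scan the path at a loose tolerance (selection is insensitive to it),
    # then re-solve the winner tightly so the returned precision matrix
    # satisfies the KKT conditions to high accuracy
    thetas = glasso_path(corr, lams, tol=1e-4)
    ebics = np.empty(n_lambda)
    for i, theta in enumerate(thetas):
        E = _count_edges(theta)
        ll = gaussian_loglik(S, theta, n)
        ebics[i] = ebic(ll, E, n, p, gamma)
    best = int(np.argmin(ebics))
    theta = glasso_path(corr, lams[best:best + 1])[0]
    return RegularizedNetwork(
        partial_correlations=precision_to_pcor(theta),
        precision=theta,
        lambda_selected=float(lams[best]),
        lambda_path=lams,
        ebic_path=ebics,
        gamma=gamma,
        n=n,
        p=p,
    )


def network_to_edgelist(network: RegularizedNetwork,
                        item_ids: list[int] | None = None) -> pd.DataFrame:
    """Long-format edge list (source, target, partial_correlation)."""
    p = network.p
    ids = item_ids if item_ids is not None else list(range(1, p + 1))
    rows = []
    pc = network.partial_correlations
    for i in range(p):
        for j in range(i + 1, p):
            if abs(pc[i, j]) > EDGE_EPS:
                rows.append((ids[i], ids[j], pc[i, j]))
    return pd.DataFrame(rows, columns=["source", "target", "partial_correlation"])


def write_graphml(
    network: RegularizedNetwork,
    path: str | Path,
    item_ids: list[int] | None = None,
    membership: np.ndarray | None = None,
) -> None:
    """Write the network as GraphML; optional community labels color nodes."""
    import networkx as nx

    p = network.p
    ids = item_ids if item_ids is not None else list(range(1, p + 1))
    g = nx.Graph()
    for i in range(p):
        attrs = {"item_id": int(ids[i])}
        if membership is not None:
            attrs["community"] = int(membership[i])
        g.add_node(ids[i], **attrs)
    pc = network.partial_correlations
    for i in range(p):
        for j in range(i + 1, p):
            if abs(pc[i, j]) > EDGE_EPS:
                g.add_edge(ids[i], ids[j], weight=float(pc[i, j]))
    nx.write_graphml(g, str(path))
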