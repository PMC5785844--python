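"""Dimension counting by community detection on the item network.

The number of dimensions underlying the items is read off as the number of
dense subgraphs in the regularized partial-correlation network.  Short
random walks started inside a tight cluster of items tend to stay there, so
walk-based distances between nodes recover the cluster structure; the
walktrap procedure turns this into an agglomerative clustering whose best
cut (by modularity) is the dimension count.  A parametric bootstrap —
resampling datasets from a multivariate normal with the estimated
correlations and re-running the whole estimation — stabilizes the count;
the median solution over replicates is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    EDGE_EPS,
    CorrelationEstimate,
    RegularizedNetwork,
    nearest_positive_definite,
    pearson_correlation,
    polychoric_correlation,
    select_network,
)
from .scale import ItemResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGraph",
    "CommunityPartition",
    "EGAResult",
    "BootstrapEGAResult",
    "EGASettings",
    "build_graph",
    "walktrap",
    "modularity",
    "ega",
    "bootstrap_ega",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph: symmetric nonnegative W, zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum() / 2.0)

    @property
    def isolated(self) -> np.ndarray:
        return np.flatnonzero(self.strengths == 0)


@dataclass(frozen=True)
class CommunityPartition:
    """Node memberships with the merge history that produced them.

    membership labels are contiguous 1..n_communities; modularity is the
    weighted Newman-Girvan Q of this partition; dendrogram lists
    (merged_a, merged_b, Q_after_merge) triples.
    """

    membership: np.ndarray
    modularity: float
    dendrogram: tuple[tuple[int, int, float], ...]

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) if self.membership.size else 0


@dataclass(frozen=True)
class EGAResult:
    network: RegularizedNetwork
    partition: CommunityPartition | None
    membership: np.ndarray  # over all p items; 0 marks isolated nodes
    n_dimensions: int
    isolated_nodes: tuple[int, ...]


@dataclass(frozen=True)
class BootstrapEGAResult:
    B: int
    dimension_counts: np.ndarray
    median_dimensions: float
    n_dimensions: int  # headline: median rounded half-up
    frequency_table: dict[int, float]
    replicate_memberships: tuple[np.ndarray, ...]
    seed: int
    n_failed: int
    sample_result: EGAResult


@dataclass(frozen=True)
class EGASettings:
    """Knobs for the network + walktrap stage.

    Defaults follow common practice for questionnaire networks: Pearson
    input, EBIC gamma 0.5 over a 100-point penalty path, 4-step walks,
    absolute-value edge weights.
    """

    corr_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    steps: int = 4
    negative_policy: str = "absolute"


def build_graph(network: RegularizedNetwork, negative_policy: str = "absolute") -> WeightedGraph:
    """Nonnegative walktrap weights from signed partial correlations.

    absolute: w = |rho| (keeps the strength of negative dependencies);
    truncate: w = max(rho, 0) (drops them).
    """
    pc = network.partial_correlations
    if negative_policy == "absolute":
        w = np.abs(pc)
    elif negative_policy == "truncate":
        w = np.clip(pc, 0.0, None)
    else:
        raise ValueError("negative_policy must be 'absolute' or 'truncate'")
    w = np.where(w > EDGE_EPS, w, 0.0)  # float noise is not an edge
    return WeightedGraph(weights=w)


def modularity(graph: WeightedGraph, membership: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2)."""
    w = graph.weights
    labels = np.asarray(membership)
    if labels.shape[0] != graph.p:
        raise ValueError("membership must cover all nodes")
    m = graph.total_weight
    if m == 0:
        raise ValueError("graph has zero total weight")
    q = 0.0
    d = graph.strengths
    for c in np.unique(labels):
        idx = labels == c
        e_c = w[np.ix_(idx, idx)].sum() / 2.0
        d_c = d[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def walktrap(graph: WeightedGraph, t: int = 4) -> CommunityPartition:
    """Agglomerative community detection from t-step random-walk distances.

    Transition matrix P = D^-1 W; the distance between nodes i and j is
    the degree-weighted L2 distance between rows of P^t.  Communities start
    as singletons and only adjacent communities merge, each step choosing
    the pair whose merge least increases the mean squared node-to-community
    distance (Ward's rule); community walk profiles merge as size-weighted
    means.  The returned partition is the dendrogram cut with maximum
    modularity.  Separate connected components never merge.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    w = graph.weights
    p = graph.p
    d = graph.strengths
    if graph.total_weight == 0:
        raise ValueError(
            "graph has zero total weight; handle the isolated-only case upstream"
        )
    if np.any(d == 0):
        raise ValueError("walktrap requires no isolated nodes; subset them out first")

    P = w / d[:, None]
    Pt = np.linalg.matrix_power(P, t)
    inv_sqrt_d = 1.0 / np.sqrt(d)

    # community state: walk profile (size-weighted mean of member rows),
    # size, member sets, adjacency between communities
    profiles = {i: Pt[i].copy() for i in range(p)}
    sizes = {i: 1 for i in range(p)}
    members = {i: [i] for i in range(p)}
    adj = {i: set(np.flatnonzero(w[i] > 0)) - {i} for i in range(p)}

    def delta_sigma(a: int, b: int) -> float:
        diff = (profiles[a] - profiles[b]) * inv_sqrt_d
        r2 = float(diff @ diff)
        return sizes[a] * sizes[b] / (sizes[a] + sizes[b]) * r2 / p

    labels = np.arange(p)
    best_membership = _contiguous(labels)
    best_q = modularity(graph, best_membership)
    dendrogram: list[tuple[int, int, float]] = []

    while True:
        # cheapest merge among adjacent community pairs
        best_pair = None
        best_cost = np.inf
        for a in list(profiles):
            for b in adj[a]:
                if b <= a:
                    continue
                cost = delta_sigma(a, b)
                if cost < best_cost - 1e-15:
                    best_cost = cost
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        profiles[a] = (sizes[a] * profiles[a] + sizes[b] * profiles[b]) / (sizes[a] + sizes[b])
        sizes[a] += sizes[b]
        members[a].extend(members[b])
        adj[a] = (adj[a] | adj[b]) - {a, b}
        for c in adj[b]:
            adj[c].discard(b)
            if c != a:
                adj[c].add(a)
        del profiles[b], sizes[b], members[b], adj[b]
        labels[np.asarray(members[a])] = a
        cand = _contiguous(labels)
        q = modularity(graph, cand)
        dendrogram.append((a, b, q))
        if q > best_q + 1e-12:
            best_q = q
            best_membership = cand

    return CommunityPartition(
        membership=best_membership,
        modularity=best_q,
        dendrogram=tuple(dendrogram),
    )


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel arbitrary labels to contiguous 1..K preserving first-seen order."""
    out = np.zeros(len(labels), dtype=int)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


def _estimate_correlation(data, method: str) -> CorrelationEstimate:
    if method == "pearson":
        return pearson_correlation(data)
    if method == "polychoric":
        if not isinstance(data, ItemResponseMatrix):
            raise ValueError("polychoric correlations need ordinal item responses")
        return polychoric_correlation(data)
    raise ValueError("corr_method must be 'pearson' or 'polychoric'")


def ega(
    data: ItemResponseMatrix | np.ndarray,
    settings: EGASettings = EGASettings(),
) -> EGAResult:
    """One pass of exploratory graph analysis.

    correlations -> EBIC-glasso network -> nonnegative graph -> walktrap.
    Isolated items (no surviving edges) are excluded from the community
    count and listed separately; membership label 0 marks them.
    """
    corr = _estimate_correlation(data, settings.corr_method)
    network = select_network(
        corr,
        gamma=settings.gamma,
        n_lambda=settings.n_lambda,
        lambda_min_ratio=settings.lambda_min_ratio,
    )
    graph = build_graph(network, settings.negative_policy)
    isolated = tuple(int(i) for i in graph.isolated)
    p = graph.p
    membership = np.zeros(p, dtype=int)
    active = np.setdiff1d(np.arange(p), isolated)
    if active.size == 0:
        logger.warning("selected network has no edges; no dimensions supported")
        return EGAResult(network=network, partition=None, membership=membership,
                         n_dimensions=0, isolated_nodes=isolated)
    sub = WeightedGraph(weights=graph.weights[np.ix_(active, active)])
    partition = walktrap(sub, t=settings.steps)
    membership[active] = partition.membership
    if isolated:
        logger.warning("%d isolated items excluded from the dimension count", len(isolated))
    return EGAResult(
        network=network,
        partition=partition,
        membership=membership,
        n_dimensions=partition.n_communities,
        isolated_nodes=isolated,
    )


def bootstrap_ega(
    data: ItemResponseMatrix | np.ndarray,
    B: int = 1000,
    seed: int = 0,
    settings: EGASettings = EGASettings(),
) -> BootstrapEGAResult:
    """Parametric bootstrap of the dimension count; the median community
    solution over B replicates is returned.

    The item correlation matrix is estimated once from the sample; each
    replicate draws n observations from a zero-mean multivariate normal
    with that correlation (child seed = seed + b) and re-runs the full
    estimation.  Replicate failures are logged and excluded; more than 10%
    failures aborts.  A fractional median (tie between counts) is kept in
    median_dimensions and rounded half-up for the headline n_dimensions.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if settings.corr_method == "polychoric":
        logger.warning(
            "parametric bootstrap draws from the Pearson correlation even though "
            "polychoric estimation was requested"
        )
    sample_result = ega(data, settings)
    x = data.values if isinstance(data, ItemResponseMatrix) else np.asarray(data, float)
    n = x.shape[0]
    corr = nearest_positive_definite(pearson_correlation(x))
    chol = np.linalg.cholesky(corr.matrix)
    boot_settings = replace(settings, corr_method="pearson")

    counts: list[int] = []
    memberships: list[np.ndarray] = []
    n_failed = 0
    for b in range(1, B + 1):
        rng = np.random.default_rng(seed + b)
        z = rng.standard_normal((n, corr.p)) @ chol.T
        try:
            res = ega(z, boot_settings)
        except Exception as exc:  # noqa: BLE001 — replicate-level robustness
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        counts.append(res.n_dimensions)
        memberships.append(res.membership)
    if n_failed > 0.1 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    counts_arr = np.asarray(counts)
    median = float(np.median(counts_arr))
    headline = int(math.floor(median + 0.5))
    uniq, freq = np.unique(counts_arr, return_counts=True)
    table = {int(u): float(f) / len(counts_arr) for u, f in zip(uniq, freq)}
    return BootstrapEGAResult(
        B=B,
        dimension_counts=counts_arr,
        median_dimensions=median,
        n_dimensions=headline,
        frequency_table=table,
        replicate_memberships=tuple(memberships),
        seed=seed,
        n_failed=n_failed,
        sample_result=sample_result,
    )


def modal_partition(result: BootstrapEGAResult) -> np.ndarray:
    """Most frequent membership pattern among replicates whose dimension
    count equals the headline count (canonical relabeling before counting).
    Used to derive a concrete confirmatory model from the bootstrap."""
    target = result.n_dimensions
    from collections import Counter

    canon = [
        tuple(_contiguous(m))
        for m, c in zip(result.replicate_memberships, result.dimension_counts)
        if c == target
    ]
    if not canon:
        return result.sample_result.membership
    most, _ = Counter(canon).most_common(1)[0]
    return np.asarray(most, dtype=int)
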