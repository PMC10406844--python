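"""Null-model analysis of co-occurrence network architecture.

Answers two questions about an inferred association network. First, is its
degree distribution consistent with an Erdős–Rényi G(n, m) random graph of
the same size? — tested by drawing a large ensemble of uniform G(n, m)
graphs and running a two-sample Kolmogorov–Smirnov test per replicate.
Second, does it carry more community structure than its degree sequence
alone implies? — tested by comparing Clauset–Newman–Moore modularity
against a degree-preserved randomization ensemble built from accepted
double-edge swaps. A keystone summary relates node centrality to taxon
relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .diversity import to_proportions
from .table import AbundanceTable

__all__ = [
    "sample_gnm",
    "ks_two_sample",
    "er_consistency_test",
    "cnm_modularity",
    "degree_preserved_modularity_null",
    "keystone_summary",
    "mean_degree",
    "KsResult",
    "Partition",
    "EnsembleResult",
]

logger = logging.getLogger("micronet")


def mean_degree(graph: nx.Graph) -> float:
    """2|E|/|V| — derived, never stored."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return 2.0 * graph.number_of_edges() / n


# --------------------------------------------------------------------------
# G(n, m) sampling


def _pair_table(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_nodes, k=1)


def _sample_edge_indices(
    n_pairs: int, n_edges: int, rng: np.random.Generator, size: int
) -> np.ndarray:
    """(size, n_edges) uniform draws of distinct pair indices per row."""
    keys = rng.random((size, n_pairs))
    return np.argpartition(keys, n_edges - 1, axis=1)[:, :n_edges]


def sample_gnm(n_nodes: int, n_edges: int, seed=None) -> nx.Graph:
    """Draw uniformly from all simple graphs with n_nodes nodes, n_edges edges."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for {n_nodes} nodes (max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    iu, ju = _pair_table(n_nodes)
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    if n_edges:
        chosen = _sample_edge_indices(iu.size, n_edges, rng, 1)[0]
        graph.add_edges_from(zip(iu[chosen], ju[chosen]))
    return graph


def _sample_gnm_degrees(
    n_nodes: int, n_edges: int, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Degree sequences of `size` independent G(n, m) draws, (size, n_nodes)."""
    iu, ju = _pair_table(n_nodes)
    chosen = _sample_edge_indices(iu.size, n_edges, rng, size)
    ends = np.concatenate([iu[chosen], ju[chosen]], axis=1)  # (size, 2m)
    offsets = np.arange(size)[:, None] * n_nodes
    flat = (ends + offsets).ravel()
    return np.bincount(flat, minlength=size * n_nodes).reshape(size, n_nodes)


# --------------------------------------------------------------------------
# Kolmogorov–Smirnov


@dataclass
class KsResult:
    statistic: float
    p: float
    n_a: int
    n_b: int


def _ks_batch(samples: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample KS of each row of `samples` against `reference`.

    Both inputs must hold small non-negative integers (degree multisets).
    p-values use the asymptotic Smirnov formula; ties in the integer ECDFs
    make the test conservative.
    """
    r, n_b = samples.shape
    n_a = reference.size
    k = int(max(samples.max(initial=0), reference.max(initial=0))) + 1
    offsets = np.arange(r)[:, None] * k
    counts = np.bincount(
        (samples + offsets).ravel(), minlength=r * k
    ).reshape(r, k)
    ecdf_b = np.cumsum(counts, axis=1) / n_b
    ref_counts = np.bincount(reference, minlength=k)
    ecdf_a = np.cumsum(ref_counts) / n_a
    d = np.abs(ecdf_b - ecdf_a).max(axis=1)
    en = n_a * n_b / (n_a + n_b)
    p = np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0)
    p[d == 0] = 1.0
    return d, np.where(p <= 0, np.finfo(float).tiny, p)


def ks_two_sample(a, b) -> KsResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|.

    The p-value uses exact enumeration when the smaller sample has at most
    10 observations, otherwise the asymptotic Smirnov formula.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if min(a.size, b.size) <= 10:
        res = stats.ks_2samp(a, b, method="exact")
        return KsResult(float(res.statistic), float(res.pvalue), a.size, b.size)
    # integer fast path shares the ensemble implementation
    if np.allclose(a, np.round(a)) and np.allclose(b, np.round(b)) and \
            a.min() >= 0 and b.min() >= 0:
        d, p = _ks_batch(
            np.asarray([b], dtype=np.int64), a.astype(np.int64)
        )
        return KsResult(float(d[0]), float(p[0]), a.size, b.size)
    res = stats.ks_2samp(a, b, method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue), a.size, b.size)


# --------------------------------------------------------------------------
# Ensembles


@dataclass
class EnsembleResult:
    kind: str
    n_replicates: int
    samples: np.ndarray
    ci_lower: float
    ci_upper: float
    verdict: bool
    seed: int | None
    alpha: float = 0.05
    frac_p_above_alpha: float | None = None
    empirical_statistic: float | None = None
    warning: str | None = None

    def summary(self) -> dict:
        out = {
            "kind": self.kind,
            "n_replicates": self.n_replicates,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "verdict": bool(self.verdict),
            "seed": self.seed,
            "alpha": self.alpha,
            "mean": float(np.mean(self.samples)),
        }
        if self.frac_p_above_alpha is not None:
            out["frac_p_above_alpha"] = self.frac_p_above_alpha
        if self.empirical_statistic is not None:
            out["empirical_statistic"] = self.empirical_statistic
        if self.warning:
            out["warning"] = self.warning
        return out


def er_consistency_test(
    graph: nx.Graph,
    n_replicates: int = 5000,
    seed=None,
    alpha: float = 0.05,
    consistency_threshold: float = 0.95,
) -> EnsembleResult:
    """Test whether a graph's degree distribution matches G(n, m).

    Draws `n_replicates` uniform G(n, m) graphs with the input's node and
    edge counts and KS-tests each replicate's degree multiset against the
    input's. The verdict is "consistent with Erdős–Rényi" when the fraction
    of replicate p-values above `alpha` reaches `consistency_threshold`.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    m = graph.number_of_edges()
    observed = np.asarray([d for _, d in graph.degree], dtype=np.int64)
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    chunk = max(1, min(n_replicates, 2_000_000 // max(n * (n - 1) // 2, 1)))
    done = 0
    while done < n_replicates:
        b = min(chunk, n_replicates - done)
        degs = _sample_gnm_degrees(n, m, rng, b)
        _, p = _ks_batch(degs, observed)
        pvals[done:done + b] = p
        done += b
    frac = float(np.mean(pvals > alpha))
    lo, hi = np.percentile(pvals, [2.5, 97.5])
    return EnsembleResult(
        kind="gnm",
        n_replicates=n_replicates,
        samples=pvals,
        ci_lower=float(lo),
        ci_upper=float(hi),
        verdict=frac >= consistency_threshold,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        alpha=alpha,
        frac_p_above_alpha=frac,
    )


# --------------------------------------------------------------------------
# Modularity


@dataclass
class Partition:
    membership: dict
    q: float
    n_clusters: int


def _nonisolated(graph: nx.Graph) -> list:
    return [v for v, d in graph.degree if d > 0]


def cnm_modularity(graph: nx.Graph) -> Partition:
    """Clauset–Newman–Moore greedy modularity maximization.

    Isolated (degree-0) nodes are excluded before community detection;
    Q = sum_c [L_c/m - (D_c/2m)^2]. Deterministic for a given node order.
    """
    nodes = sorted(_nonisolated(graph), key=str)
    if not nodes:
        raise ValueError("modularity is undefined for a graph with no edges")
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges if u != v]
    g = ig.Graph(n=len(nodes), edges=edges)
    clustering = g.community_fastgreedy().as_clustering()
    membership = {v: int(c) for v, c in zip(nodes, clustering.membership)}
    q = float(g.modularity(clustering.membership))
    return Partition(membership, q, len(set(clustering.membership)))


def _double_edge_swaps(
    edges: list[tuple], rng: np.random.Generator, n_swaps: int,
    max_attempts: int,
) -> tuple[list[tuple], int]:
    """Accepted-swap double-edge randomization on an edge list.

    Rejects proposals that would create self-loops or multi-edges; returns
    the rewired edge list and the number of accepted swaps.
    """
    edges = list(edges)
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    accepted = 0
    attempts = 0
    # draw randomness in blocks to keep the loop tight
    block = 4096
    buf_idx = rng.integers(0, m, size=(block, 2))
    buf_flip = rng.random(block) < 0.5
    bp = 0
    while accepted < n_swaps and attempts < max_attempts:
        if bp == block:
            buf_idx = rng.integers(0, m, size=(block, 2))
            buf_flip = rng.random(block) < 0.5
            bp = 0
        e1, e2 = buf_idx[bp]
        flip = buf_flip[bp]
        bp += 1
        attempts += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a, c), (b, d)
        if a == c or b == d or a == d or b == c:
            continue
        new1, new2 = frozenset((a, c)), frozenset((b, d))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = (a, c)
        edges[e2] = (b, d)
        accepted += 1
    return edges, accepted


def degree_preserved_modularity_null(
    graph: nx.Graph,
    n_replicates: int = 5000,
    swaps_per_edge: int = 10,
    seed=None,
    percentile: float = 97.5,
) -> EnsembleResult:
    """Degree-preserved randomization null for modularity.

    Each replicate rewires the graph with `swaps_per_edge * |E|` accepted
    double-edge swaps (degree sequence exactly preserved) and recomputes
    CNM modularity. The verdict is True when the empirical Q exceeds the
    upper percentile bound (97.5th by default; 95 gives the one-sided
    variant).
    """
    if graph.number_of_edges() < 2:
        raise ValueError("need at least 2 edges for degree-preserved swaps")
    nodes = sorted(_nonisolated(graph), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    base_edges = [tuple(sorted((index[u], index[v]))) for u, v in graph.edges]
    m = len(base_edges)
    target = swaps_per_edge * m
    rng = np.random.default_rng(seed)
    empirical_q = cnm_modularity(graph).q
    qs = np.empty(n_replicates)
    warning = None
    for r in range(n_replicates):
        rewired, accepted = _double_edge_swaps(
            base_edges, rng, target, max_attempts=100 * target
        )
        if accepted < target and warning is None:
            warning = (
                f"only {accepted}/{target} swaps accepted; graph admits "
                "few or no degree-preserving rewirings"
            )
            logger.warning(warning)
        g = ig.Graph(n=len(nodes), edges=rewired)
        clustering = g.community_fastgreedy().as_clustering()
        qs[r] = g.modularity(clustering.membership)
    lo, hi = np.percentile(qs, [100.0 - percentile, percentile])
    verdict = bool(empirical_q > hi)
    if warning is not None and np.allclose(qs, empirical_q):
        verdict = False
    return EnsembleResult(
        kind="degree_preserved",
        n_replicates=n_replicates,
        samples=qs,
        ci_lower=float(lo),
        ci_upper=float(hi),
        verdict=verdict,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        empirical_statistic=float(empirical_q),
        warning=warning,
    )


# --------------------------------------------------------------------------
# Keystones


@dataclass
class KeystoneSummary:
    records: pd.DataFrame
    spearman_rho: float
    spearman_p: float


def keystone_summary(
    network: nx.Graph,
    table: AbundanceTable,
    n_permutations: int = 999,
    seed=None,
) -> KeystoneSummary:
    """Per-taxon degree, betweenness, cluster and mean relative abundance.

    Betweenness is shortest-path based and unnormalized. The summary also
    reports the Spearman rank correlation between betweenness and mean
    relative abundance with a permutation p-value — the keystone question:
    are central taxa the abundant ones?
    """
    missing = [v for v in network.nodes if v not in table.counts.columns]
    if missing:
        raise ValueError(f"taxon {missing[0]!r} missing from the table")
    props = to_proportions(table).mean(axis=0)
    betweenness = nx.betweenness_centrality(network, normalized=False)
    connected = set(_nonisolated(network))
    clusters = (
        cnm_modularity(network).membership if connected else {}
    )
    rows = []
    for v in network.nodes:
        rows.append(
            {
                "taxon": v,
                "degree": network.degree[v],
                "betweenness": betweenness[v],
                "cluster": clusters.get(v, -1),
                "mean_relative_abundance": float(props[v]),
            }
        )
    records = pd.DataFrame(rows).set_index("taxon")
    x = records["betweenness"].to_numpy()
    y = records["mean_relative_abundance"].to_numpy()
    # Spearman = Pearson on (average) ranks; permutations vectorized
    rx = stats.rankdata(x) - (x.size + 1) / 2.0
    ry = stats.rankdata(y) - (y.size + 1) / 2.0
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return KeystoneSummary(records, float("nan"), 1.0)
    rho = float(rx @ ry / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
    rhos = perms @ rx / denom
    exceed = int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    return KeystoneSummary(records, rho, float(p))
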