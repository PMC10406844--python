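"""Synthetic abundance tables with planted association structure.

The generator follows a logistic-normal--multinomial composition model: a
sparse association graph among taxa is planted as the zero pattern of a
latent Gaussian precision matrix, latent log-abundances are drawn from the
corresponding multivariate normal, mapped to compositions by softmax, and
observed as multinomial read counts at a sample-specific sequencing depth.
Group-level compositional shifts enter as multiplicative effects on the
latent (log) means of designated taxa, so an effect of 1.0 for every taxon
yields exchangeable groups — the null used for calibration tests.

Defaults mirror the study design the pipeline targets: 74 samples in five
aggregation groups of sizes 14, 19, 6, 16 and 19, a ~150-taxon family table,
and sequencing depths scaled down from metagenome library sizes for
desk-scale runtimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .table import AbundanceTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_association_graph",
    "graph_to_covariance",
    "simulate_counts",
    "simulate_grouped_study",
]

DEFAULT_GROUP_SIZES = {
    "LaPaz": 14,
    "Cancun": 19,
    "Tanzania": 6,
    "Ningaloo": 16,
    "Philippines": 19,
}


def taxon_labels(n_taxa: int) -> list[str]:
    width = max(3, len(str(n_taxa - 1)))
    return [f"F{i:0{width}d}" for i in range(n_taxa)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: association graph, latent covariance, effects."""

    graph: nx.Graph
    covariance: np.ndarray
    taxon_ids: list[str]
    group_effects: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def adjacency(self) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        p = len(self.taxon_ids)
        adj = np.zeros((p, p), dtype=bool)
        for u, v in self.graph.edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
        return adj


@dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    group_sizes default to the five-aggregation design {14, 19, 6, 16, 19};
    depths are drawn uniformly on ``depth_range`` (a scaled-down stand-in
    for metagenome library sizes of order 10^5, configurable back up).
    """

    n_taxa: int = 150
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    topology: str = "modular"
    n_edges: int = 180
    n_blocks: int = 5
    within_fraction: float = 0.9
    attachment: int = 2
    edge_magnitude: float = 0.35
    cond_target: float = 100.0
    depth_range: tuple[int, int] = (5000, 20000)
    effect_size: float = 3.0
    affected_fraction: float = 0.2
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("depth bounds must be positive with min <= max")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")


def make_association_graph(
    topology: str,
    n_taxa: int,
    params: dict | None = None,
    seed: int | None = None,
) -> nx.Graph:
    """Sample a planted association graph among ``n_taxa`` labelled taxa.

    Topologies
    ----------
    ``erdos_renyi``: exactly ``n_edges`` edges drawn uniformly at random.
    ``modular``: planted-partition structure over ``n_blocks`` blocks.
        Either Bernoulli densities (``p_within``/``p_between``) or an exact
        edge budget (``n_edges`` with ``within_fraction`` of edges placed
        inside blocks) may be given.
    ``scale_free``: Barabási–Albert preferential attachment with
        ``attachment`` edges per arriving node.
    """
    params = dict(params or {})
    labels = taxon_labels(n_taxa)
    rng = np.random.default_rng(seed)
    max_edges = n_taxa * (n_taxa - 1) // 2

    if topology == "erdos_renyi":
        n_edges = int(params["n_edges"])
        if not 0 <= n_edges <= max_edges:
            raise ValueError(
                f"n_edges={n_edges} infeasible for {n_taxa} taxa "
                f"(max {max_edges})"
            )
        graph = nx.gnm_random_graph(
            n_taxa, n_edges, seed=int(rng.integers(2**31))
        )
    elif topology == "modular":
        n_blocks = int(params.get("n_blocks", 2))
        if n_blocks < 2:
            raise ValueError("modular topology needs n_blocks >= 2")
        blocks = np.array_split(np.arange(n_taxa), n_blocks)
        block_of = np.empty(n_taxa, dtype=int)
        for b, members in enumerate(blocks):
            block_of[members] = b
        iu, ju = np.triu_indices(n_taxa, k=1)
        within = block_of[iu] == block_of[ju]
        if "n_edges" in params:
            n_edges = int(params["n_edges"])
            if not 0 <= n_edges <= max_edges:
                raise ValueError(f"n_edges={n_edges} infeasible")
            frac = float(params.get("within_fraction", 0.9))
            n_within = min(int(round(frac * n_edges)), int(within.sum()))
            n_between = n_edges - n_within
            w_idx = rng.choice(np.flatnonzero(within), n_within, replace=False)
            b_idx = rng.choice(
                np.flatnonzero(~within), n_between, replace=False
            )
            chosen = np.concatenate([w_idx, b_idx])
        else:
            p_in = float(params.get("p_within", 0.3))
            p_out = float(params.get("p_between", 0.02))
            u = rng.random(iu.size)
            chosen = np.flatnonzero(u < np.where(within, p_in, p_out))
        graph = nx.Graph()
        graph.add_nodes_from(range(n_taxa))
        graph.add_edges_from(zip(iu[chosen], ju[chosen]))
    elif topology == "scale_free":
        m_a = int(params.get("attachment", params.get("m_a", 1)))
        if m_a < 1:
            raise ValueError("attachment count must be >= 1")
        graph = nx.barabasi_albert_graph(
            n_taxa, m_a, seed=int(rng.integers(2**31))
        )
    else:
        raise ValueError(f"unknown topology {topology!r}")

    return nx.relabel_nodes(graph, dict(enumerate(labels)))


def graph_to_covariance(
    graph: nx.Graph,
    edge_magnitude: float = 0.35,
    cond_target: float = 100.0,
    seed: int | None = None,
    max_steps: int = 1000,
) -> np.ndarray:
    """Latent covariance whose inverse has the graph as its zero pattern.

    Builds a precision matrix with off-diagonal entries ±``edge_magnitude``
    exactly on graph edges (random signs), inflates a uniform diagonal by
    multiplicative 1.05 steps — starting from the maximum absolute
    off-diagonal row sum, which guarantees diagonal dominance — until the
    matrix is positive definite with condition number at most
    ``cond_target``, then returns the inverse rescaled to unit diagonal.
    """
    if edge_magnitude <= 0:
        raise ValueError("edge_magnitude must be > 0")
    if cond_target <= 1:
        raise ValueError("cond_target must be > 1")
    nodes = sorted(graph.nodes)
    idx = {t: i for i, t in enumerate(nodes)}
    p = len(nodes)
    rng = np.random.default_rng(seed)
    precision = np.zeros((p, p))
    for u, v in sorted(graph.edges):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        precision[idx[u], idx[v]] = precision[idx[v], idx[u]] = (
            sign * edge_magnitude
        )
    row_sum = np.abs(precision).sum(axis=1).max()
    diag = row_sum if row_sum > 0 else 1.0
    for _ in range(max_steps):
        candidate = precision + diag * np.eye(p)
        eigvals = np.linalg.eigvalsh(candidate)
        if eigvals[0] > 0 and eigvals[-1] / eigvals[0] <= cond_target:
            cov = np.linalg.inv(candidate)
            d = np.sqrt(np.diag(cov))
            return cov / np.outer(d, d)
        diag *= 1.05
    raise ValueError(
        "could not reach the requested condition number; "
        "try a smaller edge_magnitude"
    )


def _resolve_depths(depths, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    depths = np.asarray(depths)
    if depths.shape == (2,):
        lo, hi = int(depths[0]), int(depths[1])
        if lo <= 0 or hi < lo:
            raise ValueError("depth bounds must be positive with min <= max")
        return rng.integers(lo, hi + 1, size=n_samples)
    if depths.shape == (n_samples,):
        if (depths <= 0).any():
            raise ValueError("depths must be positive")
        return depths.astype(np.int64)
    raise ValueError(
        "depths must be a (min, max) pair or one depth per sample"
    )


def simulate_counts(
    covariance: np.ndarray,
    n_samples: int,
    depths,
    seed: int | None = None,
    mean: np.ndarray | None = None,
    taxon_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> AbundanceTable:
    """Draw count samples from the logistic-normal--multinomial model.

    Per sample: latent z ~ N(mean, covariance); composition = softmax(z);
    counts ~ Multinomial(depth, composition). Row sums equal the requested
    depths exactly.
    """
    covariance = np.asarray(covariance, dtype=float)
    p = covariance.shape[0]
    eigvals = np.linalg.eigvalsh(covariance)
    if eigvals[0] <= 0:
        raise ValueError("covariance must be positive definite")
    rng = np.random.default_rng(seed)
    depths = _resolve_depths(depths, n_samples, rng)
    mu = np.zeros((n_samples, p)) if mean is None else np.atleast_2d(mean)
    if mu.shape[0] == 1:
        mu = np.broadcast_to(mu, (n_samples, p))
    latent = rng.multivariate_normal(
        np.zeros(p), covariance, size=n_samples, method="cholesky"
    ) + mu
    latent -= latent.max(axis=1, keepdims=True)  # stable softmax
    comp = np.exp(latent)
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, p), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depths[i], comp[i])
    taxon_ids = taxon_ids or taxon_labels(p)
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n_samples)]
    return AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    )


def simulate_grouped_study(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Simulate a grouped study with one shared truth graph.

    Every group draws from the same planted association structure; group
    separation comes from multiplicative effects (``effect_size``) applied
    to the latent means of a per-group random subset of taxa
    (``affected_fraction``). ``effect_size=1.0`` gives exchangeable groups.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_graph, s_cov, s_fx, s_counts = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    params = {
        "n_edges": config.n_edges,
        "n_blocks": config.n_blocks,
        "within_fraction": config.within_fraction,
        "attachment": config.attachment,
    }
    graph = make_association_graph(
        config.topology, config.n_taxa, params, seed=s_graph
    )
    cov = graph_to_covariance(
        graph, config.edge_magnitude, config.cond_target, seed=s_cov
    )
    taxa = taxon_labels(config.n_taxa)

    fx_rng = np.random.default_rng(s_fx)
    n_affected = int(round(config.affected_fraction * config.n_taxa))
    group_effects: dict[str, np.ndarray] = {}
    for group in config.group_sizes:
        effects = np.ones(config.n_taxa)
        if config.effect_size != 1.0 and n_affected > 0:
            chosen = fx_rng.choice(config.n_taxa, n_affected, replace=False)
            effects[chosen] = config.effect_size
        group_effects[group] = effects

    count_rng = np.random.default_rng(s_counts)
    tables = []
    labels = []
    offset = 0
    for group, n_g in config.group_sizes.items():
        mean = np.log(group_effects[group])
        sub = simulate_counts(
            cov,
            n_g,
            config.depth_range,
            seed=int(count_rng.integers(2**31)),
            mean=mean,
            taxon_ids=taxa,
            sample_ids=[f"S{offset + i:03d}" for i in range(n_g)],
        )
        tables.append(sub.counts)
        labels.extend([group] * n_g)
        offset += n_g
    counts = pd.concat(tables, axis=0)
    metadata = pd.DataFrame(
        {"aggregation": labels}, index=counts.index
    )
    table = AbundanceTable(counts, metadata)
    truth = SyntheticTruth(
        graph=graph,
        covariance=cov,
        taxon_ids=taxa,
        group_effects=group_effects,
        seed=config.seed,
    )
    return table, truth
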