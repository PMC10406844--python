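"""Diversity and compositional statistics for abundance tables.

Implements the per-sample alpha-diversity panel (richness S, Shannon H on
natural logs, effective diversity e^H, Pielou evenness J = H/ln S),
Kruskal–Wallis tests with Dunn post-hoc comparisons, Bray–Curtis
dissimilarity on proportional abundances, classical principal-coordinates
ordination, and a one-way PERMANOVA with optional pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .table import AbundanceTable

__all__ = [
    "to_proportions",
    "alpha_diversity",
    "kruskal_dunn",
    "bray_curtis",
    "ordinate_pcoa",
    "permanova",
    "GroupTestResult",
    "PermanovaResult",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, AbundanceTable):
        return table.values().astype(float), table.sample_ids, table.taxon_ids
    df = pd.DataFrame(table)
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def to_proportions(table) -> pd.DataFrame:
    """Row-normalize counts to proportional abundances (rows sum to 1)."""
    mat, samples, taxa = _as_matrix(table)
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        bad = samples[int(np.flatnonzero(totals <= 0)[0])]
        raise ValueError(f"sample {bad!r} has zero total count")
    return pd.DataFrame(mat / totals[:, None], index=samples, columns=taxa)


def alpha_diversity(table) -> pd.DataFrame:
    """Per-sample richness, Shannon index, effective diversity, evenness.

    H uses natural logarithms over nonzero proportions, so e^H is the
    effective number of taxa; J = H / ln(S) is reported as NaN when fewer
    than two taxa are present.
    """
    props = to_proportions(table).to_numpy()
    S = (props > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    H = -plogp.sum(axis=1)
    eH = np.exp(H)
    J = np.where(S >= 2, H / np.log(np.maximum(S, 2)), np.nan)
    samples = to_proportions(table).index
    return pd.DataFrame(
        {"richness": S, "shannon": H, "effective_diversity": eH, "evenness": J},
        index=samples,
    )


@dataclass
class DunnRecord:
    group_a: str
    group_b: str
    z: float
    p: float
    p_adjusted: float


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p: float
    pairwise: list[DunnRecord] = field(default_factory=list)


def adjust_pvalues(pvals: np.ndarray, method: str) -> np.ndarray:
    """Multiplicity adjustment: none, bonferroni, holm, or bh."""
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if method == "none" or m == 0:
        return pvals.copy()
    if method == "bonferroni":
        return np.minimum(pvals * m, 1.0)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adjusted[idx] = min(running, 1.0)
        return adjusted
    if method == "bh":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, pvals[idx] * m / (rank + 1))
            adjusted[idx] = running
        return adjusted
    raise ValueError(f"unknown adjustment method {method!r}")


def kruskal_dunn(values, groups, adjust: str = "none") -> GroupTestResult:
    """Kruskal–Wallis H test with Dunn pairwise post-hoc comparisons.

    Both the H statistic and the Dunn z statistics use the standard
    tie-correction; the chi-square reference has k-1 degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    split = {g: values[groups == g] for g in levels}
    if any(len(v) == 0 for v in split.values()):
        empty = next(g for g, v in split.items() if len(v) == 0)
        raise ValueError(f"group {empty!r} is empty")
    k = len(levels)
    if np.ptp(values) == 0:
        return GroupTestResult(statistic=0.0, df=k - 1, p=1.0)
    H, p = stats.kruskal(*split.values())

    # Dunn z: difference of mean ranks over tie-corrected pooled SE
    N = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    pooled = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    records = []
    raw = []
    for a, b in combinations(levels, 2):
        se = np.sqrt(pooled * (1.0 / len(split[a]) + 1.0 / len(split[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pz = 2.0 * stats.norm.sf(abs(z))
        records.append((str(a), str(b), z, pz))
        raw.append(pz)
    adj = adjust_pvalues(np.array(raw), adjust)
    pairwise = [
        DunnRecord(a, b, float(z), float(pz), float(pa))
        for (a, b, z, pz), pa in zip(records, adj)
    ]
    return GroupTestResult(float(H), k - 1, float(p), pairwise)


def bray_curtis(table, on_proportions: bool = True) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity matrix.

    Computed on proportional abundances by default so that dissimilarities
    are invariant to per-sample sequencing depth.
    """
    if on_proportions:
        mat = to_proportions(table)
    else:
        mat, samples, taxa = _as_matrix(table)
        if (mat.sum(axis=1) <= 0).sum() >= 2:
            raise ValueError(
                "Bray–Curtis undefined between two all-zero samples"
            )
        mat = pd.DataFrame(mat, index=samples, columns=taxa)
    dist = squareform(pdist(mat.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dist, index=mat.index, columns=mat.index)


def ordinate_pcoa(dist: pd.DataFrame, k: int = 2):
    """Classical (metric) principal-coordinates analysis.

    Double-centers the squared dissimilarities, eigendecomposes, and
    returns coordinates on the leading ``k`` positive-eigenvalue axes
    together with the full eigenvalue spectrum (negative eigenvalues are
    reported, not dropped).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if n else 0.0
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            "truncating"
        )
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    labels = list(dist.index) if hasattr(dist, "index") else list(range(n))
    coords_df = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    return coords_df, eigvals


@dataclass
class PairwisePermanova:
    group_a: str
    group_b: str
    pseudo_f: float
    r2: float
    p: float
    p_adjusted: float


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    df_between: int
    df_within: int
    n_permutations: int
    pairwise: list[PairwisePermanova] = field(default_factory=list)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, levels) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in levels:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    pairwise: bool = False,
    adjust: str = "bonferroni",
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Partitions squared dissimilarities into between/within-group sums of
    squares; the permutation p-value uses free relabelling of samples and
    the (1 + exceedances) / (1 + permutations) convention.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    if labels.size != D.shape[0]:
        raise ValueError("groups length must match distance matrix size")
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    n, k = labels.size, len(levels)
    d2 = D**2
    ss_total, ss_within = _permanova_ss(d2, labels, levels)
    if ss_total <= 0:
        raise ValueError(
            "all pairwise dissimilarities are zero; pseudo-F is undefined"
        )
    df_between, df_within = k - 1, n - k
    if df_within <= 0:
        raise ValueError("within-group degrees of freedom is zero")
    ss_between = ss_total - ss_within
    f_obs = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    perm_labels = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm_labels)
        _, ssw = _permanova_ss(d2, perm_labels, levels)
        # F >= F_obs iff SS_within <= SS_within_obs (SS_total, dfs fixed)
        if ssw <= ss_within + 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)

    result = PermanovaResult(
        float(f_obs), float(r2), float(p), df_between, df_within,
        n_permutations,
    )
    if pairwise:
        raw = []
        partial = []
        dist_df = pd.DataFrame(D)
        for a, b in combinations(levels, 2):
            idx = np.flatnonzero((labels == a) | (labels == b))
            if idx.size - 2 <= 0:
                raise ValueError(
                    f"pairwise test {a!r} vs {b!r} has zero within-group "
                    "degrees of freedom"
                )
            sub = dist_df.iloc[idx, idx]
            sub_res = permanova(
                sub, labels[idx], n_permutations,
                seed=int(rng.integers(2**31)), pairwise=False,
            )
            partial.append((str(a), str(b), sub_res))
            raw.append(sub_res.p)
        adj = adjust_pvalues(np.array(raw), adjust)
        result.pairwise = [
            PairwisePermanova(a, b, r.pseudo_f, r.r2, r.p, float(pa))
            for (a, b, r), pa in zip(partial, adj)
        ]
    return result
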