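"""Compositional co-occurrence network inference.

Pipeline: abundance filter -> centered log-ratio (CLR) transform ->
Meinshausen–Bühlmann neighborhood selection (per-taxon L1-penalized
regressions along a decreasing lambda path, OR-rule symmetrization) ->
StARS stability selection at a target edge instability.

The lambda path is log-spaced from lambda_max (the largest absolute
pairwise correlation of the standardized CLR columns, at which the lasso
solution is exactly empty) down to lambda_max * lambda_min_ratio, with
nlambda = 150 and lambda_min_ratio = 0.05 as defaults. StARS subsamples
the rows without replacement, recomputes the whole path per subsample and
selects the densest lambda whose monotonized edge instability stays at or
below the target beta (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_is_fitted

from .table import AbundanceTable

__all__ = [
    "filter_taxa",
    "clr_transform",
    "lambda_path",
    "mb_network_path",
    "stars_select",
    "StarsNetworkInference",
    "ClrMatrix",
    "StabilityProfile",
]

logger = logging.getLogger("micronet")


@dataclass
class ClrMatrix:
    """Samples x taxa matrix of centered log-ratios (rows sum to zero)."""

    values: pd.DataFrame
    pseudocount: float

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class StabilityProfile:
    lambdas: np.ndarray
    instability: np.ndarray
    monotonized: np.ndarray
    selected_index: int
    selection_frequencies: np.ndarray  # p x p at the selected lambda
    n_subsamples: int
    subsample_ratio: float
    beta: float
    seed: int | None
    bound_satisfied: bool


def filter_taxa(table: AbundanceTable, min_mean: float = 100.0) -> AbundanceTable:
    """Drop rare taxa whose mean count across all samples is below ``min_mean``.

    A taxon with mean exactly equal to the threshold is retained (the filter
    removes taxa with *less than* the threshold mean).
    """
    means = table.counts.mean(axis=0)
    keep = means[means >= min_mean].index
    if len(keep) == 0:
        raise ValueError(
            f"abundance filter (min mean {min_mean}) removed every taxon"
        )
    removed = table.n_taxa - len(keep)
    logger.info(
        "abundance filter: removed %d of %d taxa (mean < %g)",
        removed, table.n_taxa, min_mean,
    )
    return table.select_taxa(keep)


def clr_transform(table, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform with an additive pseudocount.

    clr_i = ln(x_i) - mean_j ln(x_j) per sample, where x = counts +
    pseudocount; every output row sums to zero.
    """
    if isinstance(table, AbundanceTable):
        mat = table.counts.astype(float)
    else:
        mat = pd.DataFrame(table).astype(float)
    arr = mat.to_numpy() + pseudocount
    if (arr <= 0).any():
        raise ValueError(
            "zero or negative entries require a positive pseudocount"
        )
    logs = np.log(arr)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=mat.index, columns=mat.columns),
        pseudocount=float(pseudocount),
    )


def _as_clr_array(clr) -> tuple[np.ndarray, list[str]]:
    if isinstance(clr, ClrMatrix):
        return clr.values.to_numpy(dtype=float), clr.taxon_ids
    df = pd.DataFrame(clr)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd <= 0).any():
        j = int(np.flatnonzero(sd <= 0)[0])
        raise ValueError(f"column {j} is constant after standardization")
    return (X - mu) / sd


def _lambda_max(Z: np.ndarray) -> float:
    n = Z.shape[0]
    corr = Z.T @ Z / n
    np.fill_diagonal(corr, 0.0)
    return float(np.abs(corr).max())


def lambda_path(
    lambda_max: float, nlambda: int = 150, lambda_min_ratio: float = 0.05
) -> np.ndarray:
    """Strictly decreasing log-spaced regularization path."""
    if lambda_max <= 0:
        raise ValueError("lambda_max must be > 0")
    if not 0 < lambda_min_ratio < 1:
        raise ValueError("lambda_min_ratio must be in (0, 1)")
    if nlambda < 2:
        raise ValueError("nlambda must be >= 2")
    return lambda_max * np.logspace(
        0.0, np.log10(lambda_min_ratio), nlambda
    )


def mb_network_path(clr, path: np.ndarray) -> np.ndarray:
    """Neighborhood-selection adjacency stack along a lambda path.

    For every lambda and every taxon j, an L1-penalized least-squares
    regression of the standardized column j on all other columns defines
    the neighborhood of j; the OR rule symmetrizes neighborhoods into an
    undirected adjacency. Returns a boolean array of shape
    (len(path), p, p).
    """
    X, _ = _as_clr_array(clr)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    Z = _standardize(X)
    path = np.asarray(path, dtype=float)
    adj = np.zeros((path.size, p, p), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            _, coefs, _ = lasso_path(
                Z[:, others], Z[:, j], alphas=path, tol=1e-6, max_iter=5000
            )
            nonzero = coefs != 0.0  # (p-1, nlambda)
            adj[:, j, others] = nonzero.T
    adj |= adj.transpose(0, 2, 1)  # OR rule
    return adj


class StarsNetworkInference(BaseEstimator):
    """MB neighborhood selection with StARS stability selection.

    A scikit-learn-style estimator: ``fit`` takes a samples x taxa CLR
    matrix (:class:`ClrMatrix`, DataFrame or array) and produces the
    selected association network.

    Parameters
    ----------
    nlambda : int
        Number of points on the log-spaced regularization path.
    lambda_min_ratio : float
        Ratio of the smallest to the largest path value.
    beta : float
        Target edge instability for StARS selection.
    n_subsamples : int
        Number of row subsamples (without replacement).
    subsample_ratio : float
        Fraction of rows per subsample.
    random_state : int or None
        Seed for the subsampling.

    Attributes
    ----------
    graph_ : networkx.Graph
        Selected network over all input taxa (isolated nodes retained).
    lambda_path_ : ndarray
        The regularization path.
    lambda_index_, lambda_ : selected path position and value.
    stability_profile_ : StabilityProfile
        Per-lambda instabilities, selection frequencies, settings.
    """

    def __init__(
        self,
        nlambda: int = 150,
        lambda_min_ratio: float = 0.05,
        beta: float = 0.05,
        n_subsamples: int = 50,
        subsample_ratio: float = 0.8,
        random_state: int | None = None,
    ):
        self.nlambda = nlambda
        self.lambda_min_ratio = lambda_min_ratio
        self.beta = beta
        self.n_subsamples = n_subsamples
        self.subsample_ratio = subsample_ratio
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_subsamples < 20:
            raise ValueError("n_subsamples must be >= 20")
        if not 0 < self.subsample_ratio <= 1:
            raise ValueError("subsample_ratio must be in (0, 1]")
        arr, taxa = _as_clr_array(X)
        n, p = arr.shape
        Z = _standardize(arr)
        path = lambda_path(
            _lambda_max(Z), self.nlambda, self.lambda_min_ratio
        )
        rng = np.random.default_rng(self.random_state)
        m = int(np.ceil(self.subsample_ratio * n))
        freq = np.zeros((path.size, p, p), dtype=np.uint16)
        for _ in range(self.n_subsamples):
            rows = rng.choice(n, size=m, replace=False)
            freq += mb_network_path(arr[rows], path)
        theta = freq / float(self.n_subsamples)
        xi = 2.0 * theta * (1.0 - theta)
        iu = np.triu_indices(p, k=1)
        n_pairs = len(iu[0])
        instability = xi[:, iu[0], iu[1]].sum(axis=1) / n_pairs
        monotonized = np.maximum.accumulate(instability)
        ok = np.flatnonzero(monotonized <= self.beta)
        if ok.size:
            selected = int(ok[-1])  # densest lambda within the bound
            bound_satisfied = True
        else:
            selected = path.size - 1
            bound_satisfied = False
            warnings.warn(
                "no lambda met the instability target; returning the "
                "densest fit"
            )
        full_adj = mb_network_path(arr, path[selected:selected + 1])[0]
        graph = nx.Graph()
        graph.add_nodes_from(taxa)
        ii, jj = np.nonzero(np.triu(full_adj, k=1))
        graph.add_edges_from((taxa[a], taxa[b]) for a, b in zip(ii, jj))

        self.n_features_in_ = p
        self.taxon_ids_ = list(taxa)
        self.lambda_path_ = path
        self.lambda_index_ = selected
        self.lambda_ = float(path[selected])
        self.graph_ = graph
        self.stability_profile_ = StabilityProfile(
            lambdas=path,
            instability=instability,
            monotonized=monotonized,
            selected_index=selected,
            selection_frequencies=theta[selected],
            n_subsamples=self.n_subsamples,
            subsample_ratio=self.subsample_ratio,
            beta=self.beta,
            seed=self.random_state,
            bound_satisfied=bound_satisfied,
        )
        return self

    def transform(self, X=None) -> nx.Graph:
        """Return the selected network (fitted artifact)."""
        check_is_fitted(self, "graph_")
        return self.graph_


def stars_select(
    clr,
    nlambda: int = 150,
    lambda_min_ratio: float = 0.05,
    n_subsamples: int = 50,
    subsample_ratio: float = 0.8,
    beta: float = 0.05,
    seed: int | None = None,
) -> tuple[StabilityProfile, nx.Graph]:
    """Functional wrapper around :class:`StarsNetworkInference`."""
    est = StarsNetworkInference(
        nlambda=nlambda,
        lambda_min_ratio=lambda_min_ratio,
        beta=beta,
        n_subsamples=n_subsamples,
        subsample_ratio=subsample_ratio,
        random_state=seed,
    ).fit(clr)
    return est.stability_profile_, est.graph_
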