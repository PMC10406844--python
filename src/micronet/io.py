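"""Reading and writing the pipeline's on-disk artifacts.

Canonical formats are plain text: TSV for count tables and metadata,
GraphML (attribute-preserving) or a two-column edge list for graphs,
JSON for machine-readable results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .table import AbundanceTable, TableValidationError

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_graph",
    "write_graph",
    "write_results_json",
]

logger = logging.getLogger("micronet")

SPEC_VERSION = "1.0"


def read_abundance_table(path, orientation: str = "samples_in_rows") -> AbundanceTable:
    """Read a TSV count table (one header row, one label column).

    ``orientation='taxa_in_rows'`` transposes the parsed matrix so that rows
    are always samples in the returned table.
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    if orientation == "taxa_in_rows":
        df = df.T
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path, table: AbundanceTable) -> AbundanceTable:
    """Join a metadata TSV (sample-id column first) onto *table*.

    Metadata rows for samples absent from the table are dropped with a
    warning; a table sample missing from the metadata is an error.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    missing = pd.Index(table.sample_ids).difference(meta.index)
    if len(missing):
        raise TableValidationError(f"metadata missing sample {missing[0]!r}")
    extra = meta.index.difference(table.sample_ids)
    if len(extra):
        logger.warning(
            "metadata contains %d sample(s) absent from the table "
            "(e.g. %r); dropped", len(extra), extra[0]
        )
    meta = meta.loc[table.sample_ids]
    return AbundanceTable(table.counts, meta)


def _check_graph(graph: nx.Graph) -> None:
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph contains a self-loop")
    if graph.is_multigraph() or graph.is_directed():
        raise ValueError("graph must be simple and undirected")


def write_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a simple undirected graph.

    GraphML round-trips node attributes; the edge-list format stores only
    the edge set (node attributes and isolated nodes are dropped — documented
    format contract).
    """
    _check_graph(graph)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in graph.edges:
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.Graph(graph)  # collapse to simple undirected
    elif fmt == "edgelist":
        graph = nx.read_edgelist(path, delimiter="\t")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    _check_graph(graph)
    return graph


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results_json(results: dict, path, seed: int | None = None) -> None:
    """Write a versioned, seed-stamped results document."""
    doc = {"spec_version": SPEC_VERSION, "seed": seed}
    doc.update(_jsonable(results))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
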