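"""Protein--protein interaction hub extraction.

STRING-style edge-list loading, exact Maximal Clique Centrality via
Bron--Kerbosch enumeration, exact unnormalized betweenness, and the joint
MCC/betweenness hub filter.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, SchemaError, SizeError

logger = logging.getLogger(__name__)

__all__ = [
    "load_edges",
    "mcc_scores",
    "betweenness_scores",
    "hub_table",
    "select_hubs",
    "ppi_enrichment_diagnostic",
]

#: exact clique enumeration refuses graphs larger than this
MCC_NODE_CAP = 2000


def load_edges(path, score_min: float = 400.0) -> nx.Graph:
    """Load a STRING-dialect edge list (``protein1 protein2 combined_score``).

    Whitespace- or tab-separated; a header row is tolerated.  Keeps edges
    with ``score >= score_min``; self-loops are dropped with a warning and
    duplicate rows collapse to the highest-scoring edge.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            u, v, raw = fields[0], fields[1], fields[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if not 0 <= score <= 1000:
                raise SchemaError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if u == v:
                n_self += 1
                continue
            if score < score_min:
                continue
            if graph.has_edge(u, v):
                graph[u][v]["score"] = max(graph[u][v]["score"], score)
            else:
                graph.add_edge(u, v, score=score)
    if n_self:
        logger.warning("load_edges: dropped %d self-loop row(s)", n_self)
    return graph


def mcc_scores(graph: nx.Graph, node_cap: int = MCC_NODE_CAP) -> dict[str, float]:
    """Maximal Clique Centrality: ``sum over maximal cliques C containing v of (|C|-1)!``.

    Cliques are enumerated exactly (Bron--Kerbosch with pivoting).  A node
    whose neighborhood induces no edges scores its degree (each incident
    edge is then itself a maximal 2-clique, so the formula already reduces
    to the degree); isolated nodes score 0.
    """
    n = graph.number_of_nodes()
    if n > node_cap:
        raise SizeError(
            f"{n} nodes exceeds the exact clique-enumeration cap ({node_cap}); "
            "restrict to a subgraph"
        )
    scores = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) == 1:
            continue  # isolated nodes stay at 0
        w = float(math.factorial(len(clique) - 1))
        for v in clique:
            scores[v] += w
    return scores


def betweenness_scores(graph: nx.Graph) -> dict[str, float]:
    """Exact unnormalized shortest-path betweenness (unordered pairs counted once)."""
    return nx.betweenness_centrality(graph, normalized=False)


def hub_table(graph: nx.Graph, mcc_min: float = 5.0, betweenness_gt: float = 0.0) -> pd.DataFrame:
    """Per-node MCC and betweenness with the hub flag, sorted by (-MCC, gene)."""
    mcc = mcc_scores(graph)
    btw = betweenness_scores(graph)
    df = pd.DataFrame(
        {
            "gene": list(graph.nodes),
            "mcc": [mcc[v] for v in graph.nodes],
            "betweenness": [btw[v] for v in graph.nodes],
        }
    )
    df["is_hub"] = (df["mcc"] >= mcc_min) & (df["betweenness"] > betweenness_gt)
    return df.sort_values(["mcc", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)


def select_hubs(scores: pd.DataFrame, mcc_min: float = 5.0, betweenness_gt: float = 0.0) -> list[str]:
    """Genes passing ``MCC >= mcc_min`` and ``betweenness > betweenness_gt``."""
    sel = scores[(scores["mcc"] >= mcc_min) & (scores["betweenness"] > betweenness_gt)]
    sel = sel.sort_values(["mcc", "gene"], ascending=[False, True], kind="stable")
    return list(sel["gene"])


def ppi_enrichment_diagnostic(graph: nx.Graph, background_density: float) -> float:
    """Binomial-null edge-count enrichment p; a warning-only diagnostic.

    The observed edge count is compared with Binomial(n_pairs, density);
    this stands in for an interaction-enrichment gate whose exact null is
    not reproducible offline, so it never blocks the pipeline.
    """
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    pairs = n * (n - 1) // 2
    if pairs == 0:
        return 1.0
    p = float(stats.binom.sf(m - 1, pairs, background_density))
    if p >= 0.01:
        logger.warning(
            "PPI enrichment diagnostic not significant (p=%.3g, %d edges / %d pairs)", p, m, pairs
        )
    return p
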