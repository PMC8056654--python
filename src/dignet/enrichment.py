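"""Gene-set over-representation (one-sided Fisher / hypergeometric tail)
with Benjamini--Hochberg FDR, and required-term module selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "enrich", "select_target_module"]


@dataclass
class GeneSetCollection:
    """Term -> (name, genes) plus the background universe.

    Set genes are restricted to the universe on construction.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str]

    def __post_init__(self):
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ParameterError("universe contains duplicate gene ids")
        restricted = {}
        for term, (name, genes) in self.sets.items():
            kept = sorted(set(genes) & uni)
            restricted[term] = (name, kept)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, sets: Mapping[str, tuple[str, Sequence[str]]], universe: Sequence[str]):
        return cls({t: (n, list(g)) for t, (n, g) in sets.items()}, list(universe))


def enrich(genes: Sequence[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of ``genes`` in every set of the collection.

    ``p = P(X >= k)`` for X hypergeometric(N, K, n); ``q`` by
    Benjamini--Hochberg over all tested terms.  Query genes outside the
    universe are dropped with a warning.  Sorted by (p, term id).
    """
    uni = set(collection.universe)
    query = sorted(set(genes))
    outside = [g for g in query if g not in uni]
    if outside:
        logger.warning("enrich: dropped %d query gene(s) outside the universe", len(outside))
        query = [g for g in query if g in uni]
    if not query:
        raise DegenerateInputError("query is empty after restriction to the universe")
    qset = set(query)
    N, n = len(uni), len(query)
    rows = []
    for term, (name, set_genes) in collection.sets.items():
        K = len(set_genes)
        k = len(qset.intersection(set_genes))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term_id=term, term_name=name, k=k, K=K, n=n, N=N, p=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
        out = out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return out


def select_target_module(
    module_genes: Mapping[int, Sequence[str]],
    collection: GeneSetCollection,
    required_terms: Sequence[str],
    q_max: float = 0.05,
) -> list[int]:
    """Modules in which every required term is enriched at ``q <= q_max``.

    ``module_genes`` maps module id -> gene list.  The result is ordered by
    decreasing module size (ties by module id); an empty ``required_terms``
    vacuously admits every module.
    """
    for term in required_terms:
        if term not in collection.sets:
            raise ParameterError(f"required term {term!r} not in the collection")
    ordered = sorted(module_genes, key=lambda m: (-len(module_genes[m]), m))
    selected = []
    for module in ordered:
        if not required_terms:
            selected.append(module)
            continue
        table = enrich(module_genes[module], collection)
        qs = table.set_index("term_id")["q"]
        if all(qs.get(t, 1.0) <= q_max for t in required_terms):
            selected.append(module)
    return selected
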