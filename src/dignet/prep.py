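"""Perturbation-profile preparation.

Representative-profile selection (replicate and significance filters), DEG
election by absolute perturbation, and the site-of-action tissue-propensity
contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LookupMissError, ParameterError, SchemaError
from .ranktests import rank_sum_greater

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileSet",
    "DEGSet",
    "select_representative_profiles",
    "select_degs",
    "drug_level_matrix",
    "tissue_propensity",
]

META_COLUMNS = ("drug", "cell_type", "dose", "time", "n_replicates", "p_value")


@dataclass
class ProfileSet:
    """Genes x profiles perturbation matrix plus per-profile metadata.

    ``matrix`` columns and ``meta`` index are profile ids, aligned 1:1.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"profile metadata missing column(s) {missing}")
        if list(self.matrix.columns) != list(self.meta.index):
            if set(self.matrix.columns) != set(self.meta.index):
                raise SchemaError("matrix columns and metadata rows do not match 1:1")
            self.meta = self.meta.loc[self.matrix.columns]
        if self.matrix.index.duplicated().any():
            raise SchemaError("duplicate gene ids in profile matrix")
        self.meta = self.meta.astype({"n_replicates": int, "p_value": float})

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def profile_ids(self) -> pd.Index:
        return self.matrix.columns

    def subset(self, profile_ids: Sequence[str]) -> "ProfileSet":
        ids = list(profile_ids)
        return ProfileSet(self.matrix[ids], self.meta.loc[ids])


@dataclass
class DEGSet:
    """Top-|perturbation| genes of one profile, in non-increasing order."""

    profile_id: str
    genes: list[str]
    n_top: int
    degenerate: bool = False


def select_representative_profiles(
    profiles: ProfileSet,
    p_max: float = 0.01,
    min_replicates: int = 2,
    per: str = "drug_cell",
) -> ProfileSet:
    """Keep the most-perturbed qualifying profile per drug (or drug x cell type).

    Drops profiles with fewer than ``min_replicates`` biological replicates,
    then keeps, per group, the profile with the minimum perturbation p-value
    subject to ``p < p_max``.  Drugs with no qualifying profile are dropped
    and logged.  Ties resolve to the lexicographically smallest profile id.
    """
    if per not in ("drug_cell", "drug"):
        raise ParameterError(f"per must be 'drug_cell' or 'drug', got {per!r}")
    meta = profiles.meta
    eligible = meta[(meta["n_replicates"] >= min_replicates) & (meta["p_value"] < p_max)]
    keys = ["drug", "cell_type"] if per == "drug_cell" else ["drug"]
    keep: list[str] = []
    for _, grp in eligible.sort_index().groupby(keys, sort=True):
        best = grp.sort_values(["p_value"], kind="stable").index[0]
        keep.append(best)
    dropped_drugs = set(meta["drug"]) - set(meta.loc[keep, "drug"])
    if dropped_drugs:
        logger.info(
            "select_representative_profiles: dropped %d drug(s) with no qualifying profile: %s",
            len(dropped_drugs), sorted(dropped_drugs)[:10],
        )
    keep = [pid for pid in profiles.profile_ids if pid in set(keep)]
    return profiles.subset(keep)


def select_degs(profiles: ProfileSet, n_top: int = 100) -> dict[str, DEGSet]:
    """Per profile, the ``n_top`` genes of largest absolute perturbation.

    Ties break by lexicographic gene id so the election is deterministic;
    an all-zero profile is flagged degenerate.
    """
    if n_top < 1:
        raise ParameterError("n_top must be >= 1")
    n_genes = profiles.matrix.shape[0]
    if n_top > n_genes:
        logger.warning("select_degs: n_top=%d > %d genes; truncating", n_top, n_genes)
        n_top = n_genes
    out: dict[str, DEGSet] = {}
    genes = np.asarray(profiles.genes, dtype=object)
    for pid in profiles.profile_ids:
        vals = profiles.matrix[pid].to_numpy()
        order = sorted(range(n_genes), key=lambda i: (-abs(vals[i]), genes[i]))
        top = [genes[i] for i in order[:n_top]]
        out[pid] = DEGSet(pid, top, n_top, degenerate=bool(np.all(vals == 0)))
    return out


def drug_level_matrix(profiles: ProfileSet) -> pd.DataFrame:
    """Collapse a (representative) profile set to one column per drug.

    If a drug still has several profiles (e.g. per-cell representatives),
    their perturbation values are averaged.
    """
    by_drug: dict[str, np.ndarray] = {}
    for drug, grp in profiles.meta.groupby("drug", sort=True):
        by_drug[drug] = profiles.matrix[list(grp.index)].mean(axis=1).to_numpy()
    return pd.DataFrame(by_drug, index=profiles.genes)


def tissue_propensity(
    profiles: ProfileSet,
    degs: Mapping[str, DEGSet],
    atc_map: Mapping[str, Sequence[str]],
    cell_organ_map: Mapping[str, str],
    absolute: bool = True,
) -> pd.DataFrame:
    """Site-of-action contrast of per-profile average DEG perturbation.

    Each profile is reduced to the mean (absolute, by default) perturbation
    of its DEGs.  Per cell type, profiles split into site-of-action (the
    drug's ATC first letters include the cell's organ letter) vs the rest;
    a one-sided rank-sum test (SOA greater) is reported per cell type.
    """
    rows = []
    for pid in profiles.profile_ids:
        cell = profiles.meta.at[pid, "cell_type"]
        if cell not in cell_organ_map:
            raise LookupMissError(f"cell type {cell!r} has no organ mapping")
        deg = degs[pid]
        vals = profiles.matrix.loc[deg.genes, pid].to_numpy()
        avg = float(np.mean(np.abs(vals))) if absolute else float(np.mean(vals))
        drug = profiles.meta.at[pid, "drug"]
        letters = {str(c)[0] for c in atc_map.get(drug, [])}
        rows.append(dict(profile_id=pid, cell_type=cell, drug=drug,
                         avg_perturbation=avg, soa=cell_organ_map[cell] in letters))
    per_profile = pd.DataFrame(rows)

    results = []
    for cell, grp in per_profile.groupby("cell_type", sort=True):
        soa = grp.loc[grp["soa"], "avg_perturbation"].to_numpy()
        other = grp.loc[~grp["soa"], "avg_perturbation"].to_numpy()
        if len(soa) == 0 or len(other) == 0:
            logger.warning("tissue_propensity: cell type %s has an empty group; p set to NaN", cell)
            p = np.nan
        else:
            p = rank_sum_greater(soa, other)
        results.append(dict(
            cell_type=cell, n_soa=len(soa), n_other=len(other),
            mean_soa=float(np.mean(soa)) if len(soa) else np.nan,
            mean_other=float(np.mean(other)) if len(other) else np.nan,
            p=p,
        ))
    return pd.DataFrame(results)
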