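"""Drug--adverse-event disproportionality mining.

Standardizes ADR terms against a synonym map, builds 2x2 contingency tables
by exact report counting, scans per-drug reporting odds ratios with Fisher
exact significance, and contrasts ATC categories with a one-sided rank-sum
test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    GroupingError,
    LookupMissError,
    SchemaError,
)
from .ranktests import rank_sum_greater

logger = logging.getLogger(__name__)

__all__ = [
    "ADEDataset",
    "ContingencyTable",
    "standardize_terms",
    "build_contingency",
    "odds_ratio",
    "association_scan",
    "compare_categories",
]

REPORT_COLUMNS = ("report_id", "drug", "adr", "source")


@dataclass
class ADEDataset:
    """One row per (report, drug, ADR term); the substrate for OR scans."""

    reports: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REPORT_COLUMNS if c not in self.reports.columns]
        if missing:
            raise SchemaError(f"report table missing column(s) {missing}")
        self.reports = self.reports[list(REPORT_COLUMNS)].reset_index(drop=True)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.reports["drug"].unique())

    @property
    def adrs(self) -> list[str]:
        return sorted(self.reports["adr"].unique())

    def __len__(self) -> int:
        return len(self.reports)


@dataclass
class ContingencyTable:
    """2x2 report counts: a=drug&adr, b=drug&~adr, c=~drug&adr, d=neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _resolve_synonyms(synonym_map: Mapping[str, str]) -> dict[str, str]:
    """Follow synonym chains to their preferred terms; reject cycles."""
    resolved: dict[str, str] = {}
    for raw in synonym_map:
        seen = [raw]
        term = raw
        while term in synonym_map and synonym_map[term] != term:
            term = synonym_map[term]
            if term in seen:
                raise ConfigurationError(f"cyclic synonym map at {' -> '.join(seen + [term])}")
            seen.append(term)
        resolved[raw] = term
    return resolved


def standardize_terms(dataset: ADEDataset, synonym_map: Mapping[str, str]) -> ADEDataset:
    """Replace each report's ADR term by its preferred term.

    Unmapped terms are kept verbatim (and logged); the report count never
    changes.  Synonym chains are resolved transitively; cycles raise.
    """
    resolved = _resolve_synonyms(synonym_map)
    reports = dataset.reports.copy()
    unmapped = set(reports["adr"]) - set(resolved)
    if unmapped:
        logger.info("standardize_terms: %d term(s) left verbatim (no synonym entry)", len(unmapped))
    reports["adr"] = reports["adr"].map(lambda t: resolved.get(t, t))
    return ADEDataset(reports)


def build_contingency(dataset: ADEDataset, drug: str, adr: str) -> ContingencyTable:
    """Exact 2x2 report counts for one drug--ADR pair."""
    df = dataset.reports
    if drug not in set(df["drug"]):
        raise LookupMissError(f"drug {drug!r} not in dataset")
    if adr not in set(df["adr"]):
        raise LookupMissError(f"ADR term {adr!r} not in dataset")
    is_drug = (df["drug"] == drug).to_numpy()
    is_adr = (df["adr"] == adr).to_numpy()
    a = int((is_drug & is_adr).sum())
    b = int((is_drug & ~is_adr).sum())
    c = int((~is_drug & is_adr).sum())
    d = int((~is_drug & ~is_adr).sum())
    return ContingencyTable(a, b, c, d)


def odds_ratio(table: ContingencyTable, haldane: bool = True) -> tuple[float, float]:
    """Reporting odds ratio and two-sided Fisher exact p for a 2x2 table.

    The Haldane--Anscombe +0.5 is added to *all* cells iff any cell is zero
    (keeps the OR finite); the Fisher p always uses the raw counts.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.total == 0:
        raise DegenerateInputError("odds ratio undefined on an all-zero table")
    if haldane and 0 in (a, b, c, d):
        oa, ob, oc, od = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    else:
        oa, ob, oc, od = a, b, c, d
    if ob * oc == 0:
        raise DegenerateInputError("odds ratio undefined: zero denominator with correction off")
    or_ = (oa * od) / (ob * oc)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(or_), float(p)


def association_scan(
    dataset: ADEDataset,
    adr: str,
    min_reports: int = 3,
    or_significant: float = 2.0,
    p_significant: float = 0.05,
    or_strong: float = 10.0,
    p_strong: float = 0.01,
) -> pd.DataFrame:
    """Per-drug OR scan for one ADR term.

    Drugs with fewer than ``min_reports`` co-reports are skipped.  Returns a
    frame with contingency cells, OR, Fisher p and the two significance
    flags, sorted by descending OR (ties by drug id).
    """
    df = dataset.reports
    if adr not in set(df["adr"]):
        raise LookupMissError(f"ADR term {adr!r} not in dataset")
    n_total = len(df)
    drug_totals = df["drug"].value_counts()
    co = df.loc[df["adr"] == adr, "drug"].value_counts()
    n_adr = int(co.sum())

    records = []
    for drug, a in co.items():
        a = int(a)
        if a < min_reports:
            continue
        b = int(drug_totals[drug]) - a
        c = n_adr - a
        d = n_total - a - b - c
        tab = ContingencyTable(a, b, c, d)
        or_, p = odds_ratio(tab)
        records.append(
            dict(
                drug=drug, adr=adr, a=a, b=b, c=c, d=d,
                odds_ratio=or_, fisher_p=p,
                significant=bool(or_ > or_significant and p < p_significant),
                strong=bool(or_ > or_strong and p < p_strong),
            )
        )
    out = pd.DataFrame(
        records,
        columns=["drug", "adr", "a", "b", "c", "d", "odds_ratio", "fisher_p",
                 "significant", "strong"],
    )
    if len(out):
        out = out.sort_values(["odds_ratio", "drug"], ascending=[False, True]).reset_index(drop=True)
    return out


def compare_categories(
    records: pd.DataFrame,
    atc_map: Mapping[str, Sequence[str]],
    category: str,
) -> tuple[float, float, float]:
    """Contrast in-category vs out-of-category ORs.

    A drug is in-category if ANY of its ATC codes starts with the category
    letter.  Returns ``(one_sided_p, mean_or_in, mean_or_out)`` where the
    alternative is that in-category ORs are greater.
    """
    if not len(records):
        raise GroupingError("no association records to compare")
    in_cat, out_cat = [], []
    for _, row in records.iterrows():
        codes = atc_map.get(row["drug"], [])
        (in_cat if any(str(c).startswith(category) for c in codes) else out_cat).append(
            float(row["odds_ratio"])
        )
    if not in_cat or not out_cat:
        raise GroupingError(
            f"category {category!r} split left an empty group "
            f"({len(in_cat)} in, {len(out_cat)} out)"
        )
    p = rank_sum_greater(in_cat, out_cat)
    return p, float(np.mean(in_cat)), float(np.mean(out_cat))
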