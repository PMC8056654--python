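"""Synthetic data generators with planted, recoverable structure.

Every downstream stage of the pipeline can be exercised against ground
truth produced here: adverse-event reports with planted drug--ADR odds
ratios, latent-factor expression profiles with planted modules and
group-wise down-regulation, clique-planted interaction graphs, and drug
fingerprints/property tables with a target mean similarity.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ade import ADEDataset
from .errors import ParameterError
from .prep import ProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "ADETruth",
    "ExpressionTruth",
    "SimulatedProfiles",
    "simulate_ade_reports",
    "simulate_expression_profiles",
    "simulate_ppi",
    "simulate_drug_chemistry",
]


# ------------------------------------------------------------------ ADE

@dataclass
class ADETruth:
    """Planted drug--ADR associations over categorical background rates.

    ``planted_pairs`` holds ``(drug, adr, target_odds_ratio)``;
    ``background_drug_rates`` / ``background_adr_rates`` are per-id
    sampling weights (normalized internally).
    """

    planted_pairs: list[tuple[str, str, float]]
    background_drug_rates: dict[str, float]
    background_adr_rates: dict[str, float]

    def __post_init__(self):
        for _, _, or_ in self.planted_pairs:
            if not or_ > 0:
                raise ParameterError("target odds ratio must be > 0")
        for name, rates in (("drug", self.background_drug_rates),
                            ("adr", self.background_adr_rates)):
            if not rates:
                raise ParameterError(f"empty background {name} rates")
            for v in rates.values():
                if not 0 < v < 1:
                    raise ParameterError(f"background {name} rate {v} outside (0, 1)")
        pairs = [(d, a) for d, a, _ in self.planted_pairs]
        if len(set(pairs)) != len(pairs):
            raise ParameterError("duplicate planted (drug, adr) pairs")
        for d, a, _ in self.planted_pairs:
            if d not in self.background_drug_rates:
                raise ParameterError(f"planted drug {d!r} missing from drug rates")
            if a not in self.background_adr_rates:
                raise ParameterError(f"planted adr {a!r} missing from adr rates")


def _planted_adr_probs(truth: ADETruth) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Per-drug ADR categoricals solving every planted probability from its OR.

    Each planted conditional ``p = P(adr | drug)`` solves
    ``OR = [p/(1-p)] / [q/(1-q)]`` where ``q = P(adr | not drug)`` -- and
    ``q`` itself reflects all other planted pairs, so the expected 2x2 odds
    ratio equals the target even when several drugs are planted on the same
    ADR.  The mutual dependence is resolved by fixed-point iteration on the
    full per-drug probability vectors.
    """
    adrs = sorted(truth.background_adr_rates)
    base = np.array([truth.background_adr_rates[a] for a in adrs], dtype=float)
    base = base / base.sum()
    adr_pos = {a: i for i, a in enumerate(adrs)}

    drugs = sorted(truth.background_drug_rates)
    w = np.array([truth.background_drug_rates[d] for d in drugs], dtype=float)
    w = w / w.sum()
    drug_pos = {d: i for i, d in enumerate(drugs)}

    by_drug: dict[str, list[tuple[int, float]]] = {}
    for d, a, or_ in truth.planted_pairs:
        by_drug.setdefault(d, []).append((adr_pos[a], or_))

    # P[i, j] = P(adr_j | drug_i); start from the background categorical
    P = np.tile(base, (len(drugs), 1))
    for _ in range(200):
        prev = P.copy()
        for drug, pairs in sorted(by_drug.items()):
            i = drug_pos[drug]
            probs = base.copy()
            planted_mass = base_mass = 0.0
            planted_idx = []
            for j, or_ in pairs:
                # marginal of this ADR over all other drugs, under current P
                q = (w @ P[:, j] - w[i] * P[i, j]) / (1.0 - w[i])
                p = or_ * q / (1 - q + or_ * q)
                if not 0 < p < 1:
                    raise ParameterError(
                        f"target OR {or_} for ({drug}, {adrs[j]}) implies "
                        f"probability {p} outside (0, 1)"
                    )
                probs[j] = p
                planted_mass += p
                base_mass += base[j]
                planted_idx.append(j)
            if planted_mass >= 1.0:
                raise ParameterError(
                    f"planted ADR probabilities for drug {drug!r} sum to "
                    f"{planted_mass:.3f} >= 1"
                )
            other = np.ones(len(adrs), dtype=bool)
            other[planted_idx] = False
            probs[other] = base[other] * (1 - planted_mass) / (1 - base_mass)
            P[i] = probs
        if np.abs(P - prev).max() < 1e-12:
            break

    per_drug = {d: P[drug_pos[d]] for d in by_drug}
    return adrs, base, per_drug


def simulate_ade_reports(truth: ADETruth, n_reports: int, seed: int) -> ADEDataset:
    """Sample one (drug, ADR) per report under the planted association model."""
    if n_reports < 1:
        raise ParameterError("n_reports must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = sorted(truth.background_drug_rates)
    drug_p = np.array([truth.background_drug_rates[d] for d in drugs], dtype=float)
    drug_p = drug_p / drug_p.sum()
    adrs, base, per_drug = _planted_adr_probs(truth)

    drug_idx = rng.choice(len(drugs), size=n_reports, p=drug_p)
    adr_idx = rng.choice(len(adrs), size=n_reports, p=base)
    for drug, probs in sorted(per_drug.items()):
        rows = np.where(drug_idx == drugs.index(drug))[0]
        if rows.size:
            adr_idx[rows] = rng.choice(len(adrs), size=rows.size, p=probs)

    reports = pd.DataFrame(
        {
            "report_id": [f"R{i:08d}" for i in range(1, n_reports + 1)],
            "drug": [drugs[i] for i in drug_idx],
            "adr": [adrs[i] for i in adr_idx],
            "source": "SIM",
        }
    )
    return ADEDataset(reports)


# ------------------------------------------------------------- expression

@dataclass
class ExpressionTruth:
    """Planted co-expression modules plus a group-wise down-regulation contrast."""

    module_assignment: dict[str, int]  # gene -> module id (1-based)
    group_a_drugs: list[str]
    group_b_drugs: list[str]
    downregulated_genes: set[str] = field(default_factory=set)
    effect_size: float = 0.0
    noise_sd: float = 0.3
    factor_sd: float = 1.0
    loading_range: tuple[float, float] = (0.7, 1.0)
    down_loading: float | None = None  # override loading of down-regulated genes
    positive_loadings: bool = True
    other_drugs: list[str] = field(default_factory=list)
    cell_types: dict[str, str] = field(default_factory=dict)  # drug -> cell type

    def __post_init__(self):
        if set(self.group_a_drugs) & set(self.group_b_drugs):
            raise ParameterError("drug groups must be disjoint")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        extra = self.downregulated_genes - set(self.module_assignment)
        if extra:
            raise ParameterError(
                f"downregulated genes outside the assigned gene universe: {sorted(extra)[:5]}"
            )
        counts = pd.Series(list(self.module_assignment.values())).value_counts()
        if (counts < 2).any():
            raise ParameterError("every planted module needs >= 2 genes")

    @property
    def all_drugs(self) -> list[str]:
        return list(self.group_a_drugs) + list(self.group_b_drugs) + list(self.other_drugs)


@dataclass
class SimulatedProfiles:
    """A profile set together with its generating latent state."""

    profiles: ProfileSet
    factors: pd.DataFrame  # modules x profiles latent factor values
    loadings: pd.Series  # gene -> loading


def simulate_expression_profiles(
    truth: ExpressionTruth,
    n_genes: int,
    n_profiles_per_drug: int = 1,
    seed: int = 0,
) -> SimulatedProfiles:
    """Linear latent-factor profiles: ``x = loading * factor + group shift + noise``.

    Genes beyond the planted assignment are pure-noise background.  Genes in
    ``downregulated_genes`` are shifted by ``-effect_size`` in group-A
    profiles only.  Per-profile perturbation p-values are small for the
    best condition of group drugs and uniform otherwise, so the
    representative-profile filter has something to do.
    """
    assigned = sorted(truth.module_assignment)
    if n_genes < len(assigned):
        raise ParameterError(f"n_genes={n_genes} smaller than {len(assigned)} assigned genes")
    rng = np.random.default_rng(seed)

    genes = assigned + [f"NULL{i:05d}" for i in range(1, n_genes - len(assigned) + 1)]
    modules = np.array([truth.module_assignment.get(g, 0) for g in genes])
    lo, hi = truth.loading_range
    loadings = rng.uniform(lo, hi, size=len(genes))
    if truth.down_loading is not None:
        loadings[[g in truth.downregulated_genes for g in genes]] = truth.down_loading
    if not truth.positive_loadings:
        loadings *= rng.choice([-1.0, 1.0], size=len(genes))
    loadings[modules == 0] = 0.0

    drugs = truth.all_drugs
    grouped = set(truth.group_a_drugs) | set(truth.group_b_drugs)
    down_mask = np.array([g in truth.downregulated_genes for g in genes])
    module_ids = sorted(set(modules) - {0})

    cols, meta_rows = [], []
    values = np.empty((len(genes), len(drugs) * n_profiles_per_drug))
    factor_cols = {}
    j = 0
    for drug in drugs:
        in_a = drug in truth.group_a_drugs
        for c in range(n_profiles_per_drug):
            pid = f"{drug}_c{c + 1}"
            f = {m: rng.normal(0.0, truth.factor_sd) for m in module_ids}
            col = loadings * np.array([f.get(m, 0.0) for m in modules])
            col = col + rng.normal(0.0, truth.noise_sd, size=len(genes))
            if in_a and truth.effect_size > 0:
                col = col - truth.effect_size * down_mask
            values[:, j] = col
            factor_cols[pid] = [f[m] for m in module_ids]
            if drug in grouped and c == 0:
                p_val = rng.uniform(1e-6, 5e-3)
                n_rep = 3
            else:
                p_val = rng.uniform(0.0, 1.0)
                n_rep = int(rng.integers(1, 4))
            meta_rows.append(
                dict(
                    profile_id=pid,
                    drug=drug,
                    cell_type=truth.cell_types.get(drug, "CELL1"),
                    dose="10uM",
                    time="24h",
                    n_replicates=n_rep,
                    p_value=p_val,
                )
            )
            cols.append(pid)
            j += 1

    matrix = pd.DataFrame(values, index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("profile_id")
    factors = pd.DataFrame(factor_cols, index=module_ids)
    return SimulatedProfiles(
        ProfileSet(matrix, meta), factors, pd.Series(loadings, index=genes)
    )


# -------------------------------------------------------------------- PPI

def simulate_ppi(
    core_genes: list[str],
    background_genes: list[str],
    p_core: float,
    p_background: float,
    seed: int = 0,
) -> nx.Graph:
    """Planted-clique-ish random graph: dense among core genes, sparse elsewhere.

    Edge scores are drawn uniformly in [400, 1000); all nodes (including
    isolated background nodes) are present in the graph.
    """
    if not 0 <= p_background <= p_core <= 1:
        raise ParameterError("require 0 <= p_background <= p_core <= 1")
    if set(core_genes) & set(background_genes):
        raise ParameterError("core and background gene lists must be disjoint")
    rng = np.random.default_rng(seed)
    nodes = list(core_genes) + list(background_genes)
    n_core = len(core_genes)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_core if (i < n_core and j < n_core) else p_background
            if rng.random() < p:
                graph.add_edge(nodes[i], nodes[j], score=float(rng.integers(400, 1000)))
    return graph


def write_ppi_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('score', 999):.0f}\n")


# -------------------------------------------------------------- chemistry

def simulate_drug_chemistry(
    n_drugs: int,
    n_bits: int = 256,
    mean_similarity: float = 0.4,
    seed: int = 0,
    drug_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary fingerprints with a target expected pairwise Tanimoto + properties.

    Shared-template model: a bit is "common" (on in every drug) with
    probability ``a``, otherwise on independently per drug with probability
    ``b``; ``a`` is solved so the per-bit intersection/union ratio equals
    the target.  ``mean_similarity = 0`` instead assigns disjoint on-bit
    blocks.  Returns ``(fingerprints, properties)`` with drugs as rows.
    """
    if not 0 <= mean_similarity <= 1:
        raise ParameterError("mean_similarity must be in [0, 1]")
    if n_bits < 8:
        raise ParameterError("n_bits must be >= 8")
    if drug_ids is None:
        drug_ids = [f"D{i:03d}" for i in range(1, n_drugs + 1)]
    elif len(drug_ids) != n_drugs:
        raise ParameterError("drug_ids length must equal n_drugs")
    rng = np.random.default_rng(seed)

    if mean_similarity == 0:
        if n_bits < n_drugs:
            raise ParameterError("n_bits < n_drugs: cannot assign disjoint on-bit blocks")
        fps = np.zeros((n_drugs, n_bits), dtype=int)
        block = n_bits // n_drugs
        for i in range(n_drugs):
            fps[i, i * block: i * block + block] = 1
    else:
        t = mean_similarity
        b = min(0.2, t) if t < 1 else 0.0
        u, v = b * b, 2 * b - b * b
        a = 1.0 if t == 1 else (t * v - u) / ((1 - t) + (t * v - u))
        template = rng.random(n_bits) < a
        fps = (template[None, :] | (rng.random((n_drugs, n_bits)) < b)).astype(int)
        for i in range(n_drugs):  # guarantee >= 1 on-bit per drug
            if fps[i].sum() == 0:
                fps[i, int(rng.integers(n_bits))] = 1

    fingerprints = pd.DataFrame(fps, index=drug_ids, columns=[f"b{i}" for i in range(n_bits)])
    properties = pd.DataFrame(
        {
            "mol_weight": rng.normal(350.0, 80.0, n_drugs),
            "logp": rng.normal(2.0, 1.5, n_drugs),
            "tpsa": rng.normal(80.0, 30.0, n_drugs),
            "hbd": rng.poisson(2.0, n_drugs).astype(float) + 1.0,
        },
        index=drug_ids,
    )
    return fingerprints, properties
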