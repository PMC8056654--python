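"""Seeded end-to-end synthetic scenario: every pipeline input, with ground truth.

``make_scenario`` writes a coherent fixture set to a directory -- adverse
event reports with 13 planted strong drug--ADR associations in ATC
category S, latent-factor expression profiles with four planted modules
and a down-regulated risk-gene block, a matching gene-set collection, a
clique-planted interaction graph over the risk genes, fingerprints,
property and mapping tables -- plus a ready-to-run pipeline config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .synthetic import (
    ADETruth,
    ExpressionTruth,
    simulate_ade_reports,
    simulate_drug_chemistry,
    simulate_expression_profiles,
    simulate_ppi,
    write_ppi_tsv,
)

__all__ = ["ScenarioTruth", "make_scenario"]

ADR_TERM = "Glaucoma"
RAW_SYNONYMS = ["Glaucoma NOS", "glaucoma aggravated"]


@dataclasses.dataclass
class ScenarioTruth:
    """Ground truth of a generated scenario, for recovery checks."""

    glaucoma_drugs: list[str]  # planted strong + S-category (group A)
    other_s_drugs: list[str]  # S-category, no planted association (group B)
    decoy_strong_drug: str  # strong association but non-S (must be filtered out)
    module_assignment: dict[str, int]
    downregulated_genes: list[str]
    target_term: str
    adr_term: str = ADR_TERM


def make_scenario(
    outdir,
    seed: int = 0,
    n_reports: int = 150_000,
    n_group_a: int = 13,
    n_group_b: int = 63,
    n_other_drugs: int = 24,
    module_sizes: tuple[int, ...] = (300, 300, 300, 300),
    n_down: int = 60,
    planted_or: float = 30.0,
    effect_size: float = 2.5,
    noise_sd: float = 0.2,
    n_perm: int = 10_000,
) -> ScenarioTruth:
    """Write a full synthetic fixture set under ``outdir``; returns the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_ade, s_expr, s_ppi, s_chem, s_misc = [s.generate_state(1)[0] for s in root.spawn(5)]

    group_a = [f"DGA{i:02d}" for i in range(1, n_group_a + 1)]
    group_b = [f"DGB{i:02d}" for i in range(1, n_group_b + 1)]
    others = [f"DGN{i:02d}" for i in range(1, n_other_drugs + 1)]
    decoy = others[0]
    all_drugs = group_a + group_b + others

    # ---- ADE reports with planted strong associations -------------------
    adr_terms = [ADR_TERM] + [f"ADR{i:03d}" for i in range(1, 21)]
    adr_rates = {t: (0.03 if t == ADR_TERM else 0.97 / 20) for t in adr_terms}
    planted = [(d, ADR_TERM, planted_or) for d in group_a]
    planted.append((decoy, ADR_TERM, planted_or))  # strong but non-S: selection must drop it
    truth_ade = ADETruth(
        planted_pairs=planted,
        background_drug_rates={d: 1.0 / len(all_drugs) for d in all_drugs},
        background_adr_rates=adr_rates,
    )
    dataset = simulate_ade_reports(truth_ade, n_reports, seed=int(s_ade))

    # de-standardize a third of the target-term rows to exercise the synonym map
    rng = np.random.default_rng(int(s_misc))
    reports = dataset.reports.copy()
    hits = reports.index[reports["adr"] == ADR_TERM]
    raw = rng.choice(len(RAW_SYNONYMS) + 1, size=len(hits))
    for k, syn in enumerate(RAW_SYNONYMS, start=1):
        reports.loc[hits[raw == k], "adr"] = syn
    io.write_tsv(reports, outdir / "reports.tsv")
    io.write_tsv(
        pd.DataFrame({"raw_term": RAW_SYNONYMS, "preferred_term": ADR_TERM}),
        outdir / "synonyms.tsv",
    )

    # ---- ATC codes ------------------------------------------------------
    atc_rows = []
    for i, d in enumerate(group_a + group_b):
        atc_rows.append((d, f"S01E{i:02d}"))
    for i, d in enumerate(others):
        atc_rows.append((d, f"N05A{i:02d}"))
    group_a_set = set(group_a)
    for d in group_a[:3]:  # some drugs hold several codes
        atc_rows.append((d, "C07AA05"))
    io.write_tsv(pd.DataFrame(atc_rows, columns=["drug", "atc_code"]), outdir / "atc.tsv")

    # ---- expression profiles with planted modules + down-regulation -----
    gene_names, assignment = [], {}
    g = 0
    for m, size in enumerate(module_sizes, start=1):
        for _ in range(size):
            g += 1
            name = f"GENE{g:04d}"
            gene_names.append(name)
            assignment[name] = m
    down = gene_names[:n_down]  # first block of module 1

    truth_expr = ExpressionTruth(
        module_assignment=assignment,
        group_a_drugs=group_a,
        group_b_drugs=group_b,
        downregulated_genes=set(down),
        effect_size=effect_size,
        noise_sd=noise_sd,
        loading_range=(0.9, 1.0),
        down_loading=1.0,
        cell_types={d: "RETINA" for d in all_drugs},
    )
    sim = simulate_expression_profiles(
        truth_expr, n_genes=len(gene_names), n_profiles_per_drug=3, seed=int(s_expr)
    )
    io.write_gct(sim.profiles.matrix, outdir / "matrix.gct")
    io.write_tsv(sim.profiles.meta.reset_index(), outdir / "meta.tsv")
    io.write_tsv(
        pd.DataFrame({"cell_type": ["RETINA"], "organ_letter": ["S"]}),
        outdir / "cell_organ.tsv",
    )

    # ---- gene sets ------------------------------------------------------
    module1 = [g for g, m in assignment.items() if m == 1]
    decoy_sets = {
        f"RANDOM{i:02d}": (f"random set {i}", sorted(rng.choice(gene_names, 100, replace=False)))
        for i in (1, 2)
    }
    sets = {"SENSORY01": ("sensory organ response", module1), **decoy_sets}
    io.write_gmt(sets, outdir / "sets.gmt")

    # ---- PPI over module-1 genes, dense among the risk block ------------
    background = [g for g in module1 if g not in set(down)]
    graph = simulate_ppi(down, background, p_core=0.5, p_background=0.01, seed=int(s_ppi))
    write_ppi_tsv(graph, outdir / "ppi.tsv")

    # ---- chemistry ------------------------------------------------------
    fps, props = simulate_drug_chemistry(
        n_group_a, n_bits=256, mean_similarity=0.4, seed=int(s_chem), drug_ids=group_a
    )
    io.write_fingerprints(fps, outdir / "fingerprints.tsv")
    io.write_tsv(props.reset_index(names="drug"), outdir / "properties.tsv")

    # ---- pipeline config ------------------------------------------------
    config = {
        "seed": seed,
        "adr_term": ADR_TERM,
        "inputs": {
            "reports": str(outdir / "reports.tsv"),
            "synonyms": str(outdir / "synonyms.tsv"),
            "atc": str(outdir / "atc.tsv"),
            "matrix": str(outdir / "matrix.gct"),
            "meta": str(outdir / "meta.tsv"),
            "gmt": str(outdir / "sets.gmt"),
            "ppi": str(outdir / "ppi.tsv"),
            "cell_organ": str(outdir / "cell_organ.tsv"),
            "fingerprints": str(outdir / "fingerprints.tsv"),
            "properties": str(outdir / "properties.tsv"),
        },
        "thresholds": {
            "min_reports": 3,
            "or_significant": 2.0,
            "p_significant": 0.05,
            "or_strong": 10.0,
            "p_strong": 0.01,
            "atc_category": "S",
            "rep_p_max": 0.01,
            "n_top_degs": 100,
            "beta": 5,
            "min_module_size": 30,
            "cut_height_quantile": 0.998,
            "merge_dissim": 0.3,
            "mm_min": 0.95,
            "required_terms": ["SENSORY01"],
            "enrich_q_max": 0.05,
            "ppi_score_min": 400,
            "mcc_min": 5,
            "betweenness_gt": 0.0,
            "n_perm": n_perm,
            "or_min": 6.0,
            "auc_min": 0.7,
            "risk_sign": -1,
        },
        "outdir": str(outdir / "out"),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    truth = ScenarioTruth(
        glaucoma_drugs=group_a,
        other_s_drugs=group_b,
        decoy_strong_drug=decoy,
        module_assignment=assignment,
        downregulated_genes=list(down),
        target_term="SENSORY01",
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1)
    return truth
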