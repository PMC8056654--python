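"""End-to-end orchestration: reports -> drug selection -> profiles -> modules
-> enrichment -> core genes -> hubs -> permutation test -> risk panel.

Every stage writes its table under the configured output directory with a
header carrying the tool version, config hash and seed; a stage with an
empty result halts with a diagnostic naming the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ade, coexpression as cx, enrichment, hubs, io, prep, stats
from .errors import PipelineHalt

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "run_pipeline"]

DEFAULT_THRESHOLDS = {
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
    "cut_height_quantile": 0.99,
    "merge_dissim": 0.3,
    "mm_min": 0.95,
    "required_terms": [],
    "enrich_q_max": 0.05,
    "ppi_score_min": 400,
    "mcc_min": 5,
    "betweenness_gt": 0.0,
    "n_perm": 10_000,
    "or_min": 6.0,
    "auc_min": 0.7,
    "risk_sign": -1,
}


def default_config() -> dict:
    """Config skeleton with the documented default thresholds."""
    return {
        "seed": 0,
        "adr_term": "Glaucoma",
        "inputs": {k: "" for k in ("reports", "synonyms", "atc", "matrix", "meta",
                                   "gmt", "ppi", "cell_organ", "fingerprints", "properties")},
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "outdir": "dignet_out",
    }


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(config.get("thresholds", {}))
    config["thresholds"] = thr
    return config


def _write(df: pd.DataFrame, path: Path, header: str, **kw) -> None:
    io.write_tsv(df, path, header_comment=header, **kw)


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns the machine-readable run report."""
    thr = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))
    paths = config["inputs"]
    outdir = Path(config.get("outdir", "dignet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash({"thresholds": thr, "seed": seed, "adr_term": config.get("adr_term")})
    header = io.output_header(__version__, seed=seed, cfg_hash=cfg_hash)
    report: dict = {"version": __version__, "seed": seed, "config_hash": cfg_hash,
                    "thresholds": thr, "counts": {}}
    counts = report["counts"]

    # ---- stage 1: ADE mining -------------------------------------------
    dataset = ade.ADEDataset(io.read_reports(paths["reports"]))
    counts["reports"] = len(dataset)
    if paths.get("synonyms"):
        dataset = ade.standardize_terms(dataset, io.read_synonym_map(paths["synonyms"]))
    adr_term = config.get("adr_term", "Glaucoma")
    assoc = ade.association_scan(
        dataset, adr_term,
        min_reports=thr["min_reports"],
        or_significant=thr["or_significant"], p_significant=thr["p_significant"],
        or_strong=thr["or_strong"], p_strong=thr["p_strong"],
    )
    _write(assoc, outdir / "associations.tsv", header)
    counts["associations"] = int(len(assoc))
    counts["significant_associations"] = int(assoc["significant"].sum()) if len(assoc) else 0
    counts["strong_associations"] = int(assoc["strong"].sum()) if len(assoc) else 0

    atc_map = io.read_atc_map(paths["atc"])
    try:
        cat_p, mean_in, mean_out = ade.compare_categories(
            assoc[assoc["significant"]], atc_map, thr["atc_category"]
        )
        report["category_contrast"] = {
            "category": thr["atc_category"], "p": cat_p,
            "mean_or_in": mean_in, "mean_or_out": mean_out,
        }
    except Exception as exc:  # diagnostic only
        logger.warning("category contrast unavailable: %s", exc)

    # ---- stage 2: drug selection (strong AND in-category) ---------------
    letter = thr["atc_category"]
    strong = assoc.loc[assoc["strong"], "drug"] if len(assoc) else pd.Series(dtype=str)
    selected = [
        d for d in strong
        if any(str(c).startswith(letter) for c in atc_map.get(d, []))
    ]
    if not selected:
        raise PipelineHalt("drug_selection", "empty selection: no strong in-category drug")
    selected = sorted(selected)
    io.write_group_file(selected, outdir / "selected_drugs.txt")
    counts["selected_drugs"] = len(selected)

    # ---- stage 3: profile preparation ----------------------------------
    matrix = io.read_matrix(paths["matrix"])
    meta = io.read_tsv(paths["meta"]).set_index("profile_id")
    profiles = prep.ProfileSet(matrix, meta)
    rep = prep.select_representative_profiles(profiles, p_max=thr["rep_p_max"], per="drug")
    if not len(rep.profile_ids):
        raise PipelineHalt("expression_prep", "no profile survived the representative filter")
    _write(rep.meta.reset_index(), outdir / "representative_profiles.tsv", header)
    counts["representative_profiles"] = int(len(rep.profile_ids))

    if paths.get("cell_organ"):
        degs = prep.select_degs(rep, n_top=thr["n_top_degs"])
        propensity = prep.tissue_propensity(
            rep, degs, atc_map, io.read_cell_organ_map(paths["cell_organ"])
        )
        _write(propensity, outdir / "tissue_propensity.tsv", header)

    drug_matrix = prep.drug_level_matrix(rep)
    selected_in_expr = [d for d in selected if d in drug_matrix.columns]
    if not selected_in_expr:
        raise PipelineHalt("expression_prep", "no selected drug has a representative profile")
    counts["selected_drugs_with_profiles"] = len(selected_in_expr)

    # ---- stage 4: co-expression network --------------------------------
    wg_matrix = drug_matrix[selected_in_expr]
    adjacency = cx.soft_adjacency(wg_matrix, beta=thr["beta"])
    try:
        report["scale_free_r2"] = cx.scale_free_fit(adjacency)
    except Exception as exc:
        logger.warning("scale-free fit unavailable: %s", exc)
    tom = cx.topological_overlap(adjacency)
    module_set = cx.detect_modules(
        1.0 - tom, wg_matrix.index,
        min_module_size=thr["min_module_size"],
        cut_height_quantile=thr["cut_height_quantile"],
    )
    counts["modules_pre_merge"] = len(module_set.module_ids())
    if not module_set.module_ids():
        raise PipelineHalt("coexpression", "no module passed the size filter")
    merged = cx.merge_modules(wg_matrix, module_set.labels, dissim_threshold=thr["merge_dissim"])
    counts["modules_post_merge"] = len(merged.module_ids())
    labels_df = merged.labels.rename("module").rename_axis("gene").reset_index()
    _write(labels_df, outdir / "module_labels.tsv", header)
    _write(merged.eigengenes, outdir / "module_eigengenes.tsv", header,
           index=True, index_label="module")
    membership = cx.module_membership(wg_matrix, merged)
    _write(membership, outdir / "module_membership.tsv", header, index=True, index_label="gene")

    # ---- stage 5: enrichment-driven module selection --------------------
    collection = enrichment.GeneSetCollection.from_gmt(
        io.read_gmt(paths["gmt"]), universe=list(wg_matrix.index)
    )
    module_genes = {m: merged.genes_in(m) for m in merged.module_ids()}
    targets = enrichment.select_target_module(
        module_genes, collection, thr["required_terms"], q_max=thr["enrich_q_max"]
    )
    if not targets:
        raise PipelineHalt("enrichment", "no module satisfies the required terms")
    target = targets[0]
    report["target_module"] = int(target)
    enr = enrichment.enrich(module_genes[target], collection)
    _write(enr, outdir / "target_module_enrichment.tsv", header)

    # ---- stage 6: core genes and hubs ----------------------------------
    core_genes = cx.select_core_genes(membership, target, mm_min=thr["mm_min"])
    if not core_genes:
        raise PipelineHalt("core_genes", f"no gene exceeds MM > {thr['mm_min']}")
    io.write_group_file(core_genes, outdir / "core_genes.txt")
    counts["core_genes"] = len(core_genes)

    graph = hubs.load_edges(paths["ppi"], score_min=thr["ppi_score_min"]).subgraph(core_genes).copy()
    counts["ppi_edges"] = graph.number_of_edges()
    density = 2 * graph.number_of_edges() / max(len(core_genes) * (len(core_genes) - 1), 1)
    hubs.ppi_enrichment_diagnostic(graph, background_density=min(0.05, max(density / 2, 1e-6)))
    scores = hubs.hub_table(graph, mcc_min=thr["mcc_min"], betweenness_gt=thr["betweenness_gt"])
    _write(scores, outdir / "hub_scores.tsv", header)
    hub_genes = hubs.select_hubs(scores, mcc_min=thr["mcc_min"], betweenness_gt=thr["betweenness_gt"])
    if not hub_genes:
        raise PipelineHalt("hub_network", "no hub passes the MCC/betweenness filter")
    io.write_group_file(hub_genes, outdir / "hub_genes.txt")
    counts["hub_genes"] = len(hub_genes)

    # ---- stage 7: permutation test and risk panel ----------------------
    s_letter = thr["atc_category"]
    group_b = sorted(
        d for d in drug_matrix.columns
        if d not in set(selected_in_expr)
        and any(str(c).startswith(s_letter) for c in atc_map.get(d, []))
    )
    if len(group_b) < 2:
        raise PipelineHalt("association_stats", "fewer than 2 comparator in-category drugs")
    counts["comparator_drugs"] = len(group_b)
    perm = stats.permutation_test(
        drug_matrix.loc[hub_genes], selected_in_expr, group_b,
        n_perm=thr["n_perm"], seed=seed,
    )
    _write(perm, outdir / "permutation_test.tsv", header)
    counts["perm_significant"] = int((perm["perm_p"] < 0.05).sum())

    ab_profiles = rep.meta.index[rep.meta["drug"].isin(selected_in_expr + group_b)]
    risk_matrix = rep.matrix.loc[hub_genes, ab_profiles] * thr["risk_sign"]
    y = rep.meta.loc[ab_profiles, "drug"].isin(selected_in_expr).astype(int)
    risk = stats.gene_risk(risk_matrix, y)
    _write(risk, outdir / "gene_risk.tsv", header)

    try:
        r, p = stats.significance_strength_correlation(perm, risk)
        report["significance_strength"] = {"pearson_r": r, "p": p}
    except Exception as exc:
        logger.warning("significance-strength correlation unavailable: %s", exc)

    panel = stats.select_panel(risk, or_min=thr["or_min"], auc_min=thr["auc_min"])
    if not panel:
        raise PipelineHalt("panel", "no gene passes the OR/AUC panel thresholds")
    io.write_group_file(panel, outdir / "panel_genes.txt")
    counts["panel_genes"] = len(panel)
    report["panel"] = panel

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
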