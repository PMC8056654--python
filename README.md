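# dignet

Pipeline for discovering adverse-event-associated drugs, co-expression
modules, hub genes and biomarker panels from adverse-drug-event reports and
drug-perturbation expression profiles.

Stages (each is an importable module and a CLI subcommand):

| stage | module | what it does |
|---|---|---|
| ADE mining | `dignet.ade` | ADR term standardization, 2x2 contingency tables, reporting odds-ratio scan with Fisher exact significance, ATC category contrast (one-sided rank-sum) |
| profile prep | `dignet.prep` | replicate / p-value representative-profile filter, DEG election by \|perturbation\|, site-of-action tissue-propensity contrast |
| co-expression | `dignet.coexpression` | unsigned soft-threshold adjacency, scale-free fit R2, topological overlap, average-linkage clustering with static quantile cut, SVD module eigengenes, eigengene-dissimilarity merging, module membership (kME) |
| enrichment | `dignet.enrichment` | hypergeometric over-representation with Benjamini-Hochberg FDR, required-term module selection |
| hub network | `dignet.hubs` | STRING-style edge loading, exact Maximal Clique Centrality (Bron-Kerbosch), unnormalized betweenness, joint hub filter |
| association stats | `dignet.stats` | left-tail permutation test with shared label permutations, univariate logistic OR (IRLS) + midrank AUC, panel selection, significance-strength correlation |
| chem diversity | `dignet.chem` | pairwise Tanimoto on binary fingerprints, coefficient-of-variation dispersion |
| synthetic data | `dignet.synthetic`, `dignet.scenario` | generators with planted, recoverable structure for every stage |
| orchestration | `dignet.pipeline`, `dignet.cli` | YAML-configured end-to-end run with a machine-readable run report |

## CLI

```sh
dignet init-config --out config.yaml          # emit default thresholds
dignet simulate scenario --outdir scn --seed 1  # full synthetic fixture set
dignet run-all --config scn/config.yaml       # end-to-end run
```

Individual stages: `dignet simulate {reports,expression,ppi,chemistry}`,
`dignet mine-ade`, `dignet prep`, `dignet wgcna`, `dignet enrich`,
`dignet hubs`, `dignet permtest`, `dignet risk`, `dignet chemdiv`.

All file formats are plain text: report/metadata/mapping TSVs with headers,
GCT v1.2 matrices, GMT gene sets, STRING-dialect edge lists. Every output
table carries a `#` header with the tool version, config hash and seed.

Example end to end on synthetic data:

```sh
dignet simulate scenario --outdir scn --seed 1
dignet run-all --config scn/config.yaml
cat scn/out/run_report.json          # stage counts, thresholds, panel
```

The scenario plants 13 strongly ADR-associated sensory-category drugs, four
latent co-expression modules, a down-regulated risk-gene block inside one
module, a dense interaction core over those genes, and drug fingerprints
with a target mean Tanimoto; the pipeline recovers the planted panel with
zero false positives (see `tests/test_acceptance.py`).

## Statistical conventions

- Odds ratios use the Haldane-Anscombe +0.5 on all cells iff any cell is
  zero; Fisher p is the two-sided probability-mass test on raw counts.
- The exact rank-sum test uses midranks; with tied data a mid-p is
  reported, otherwise the classical `P(T >= t)`.
- Permutation p-values count ties into the (left) tail with the
  finite-sample +1 correction: `p = (#{d* <= d} + 1) / (m + 1)`; the raw
  strictly-less fraction is also reported. Enumeration replaces sampling
  when the group sizes allow it.
- Logistic fits are unpenalized IRLS; perfect separation is flagged and
  reported as a +inf odds-ratio sentinel, not silently regularized.
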