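# pathscore

Pathway activity scoring for tumour/benign expression cohorts, with the
downstream analyses that typically accompany it: per-gene z-scores anchored
to a reference population (all tumours of a cohort, or the benign samples),
averaged into per-sample pathway scores; tumour-vs-benign Wilcoxon and Welch
t tests; hierarchical clustering of the score matrix; and Kaplan–Meier /
log-rank survival analysis stratified by >2-SD pathway-score outliers. A
seeded synthetic-cohort generator makes every stage testable without any
data downloads.

## What's inside

| Module | Purpose |
| --- | --- |
| `pathscore.pathway_catalog` | GMT gene-set loading/validation; the bundled 23-pathway metabolic catalog; the <6-gene testability floor |
| `pathscore.expression_io` | TSV gene×sample matrices (counts or continuous) and sample annotation tables |
| `pathscore.normalization` | Quantile normalization, median-of-ratios size factors, log2 transform |
| `pathscore.scoring` | Reference-anchored z-scores, averaged pathway scores, strict ±k·SD outlier calls |
| `pathscore.group_tests` | Exact/approximate Wilcoxon rank-sum on pathway scores, Welch t-test on mean log2 expression, heterogeneity summaries |
| `pathscore.clustering` | Deterministic agglomerative clustering (average/complete/ward/single; euclidean/correlation), Newick export, matched-pair adjacency |
| `pathscore.survival` | Product-limit KM curves, Mantel–Cox and Gehan–Breslow tests, outlier stratification, Spearman correlation with ordinal stage |
| `pathscore.synthetic_data` | Seeded cohorts with planted pathway shifts, matched pairs, and outlier-dependent survival |
| `pathscore.pipeline` / `pathscore.cli` | One-command orchestration with a YAML config and full output audit trail |

The bundled catalog (`pathscore/data/metabolic_pathways.gmt`) is a
reconstruction assembled from standard pathway references; each line's
description field says so. Supply your own GMT to use curated lists.

## CLI

```sh
# generate a seeded synthetic cohort (expr.tsv, annotations.tsv, catalog.gmt, truth.json)
pathscore simulate --seed 1 --effect pathway_01:2.0:0.3 --hazard-ratio 3 --out-dir synthetic

# full pipeline from a YAML config
pathscore run --config run.yaml

# individual stages
pathscore normalize --platform counts in.tsv out.tsv
pathscore score expr.tsv annotations.tsv --reference benign --threshold 2
pathscore test expr.tsv annotations.tsv --method wilcoxon --alpha 0.05
pathscore cluster scores.tsv --distance euclidean --linkage average -k 2
pathscore survive outliers.tsv annotations.tsv --pathway pathway_01 --direction up
```

A minimal `run.yaml`:

```yaml
expression: synthetic/expr.tsv
annotations: synthetic/annotations.tsv
catalog: synthetic/catalog.gmt   # omit to use the bundled 23-pathway catalog
reference: benign                # or: cohort
outlier_threshold: 2.0
survival_pathways: [pathway_01]
out_dir: run1
```

## Conventions worth knowing

- Gene symbols are matched case-insensitively after trimming whitespace.
- SDs use the n−1 denominator throughout (small reference sets).
- Outlier thresholds default to the score re-standardized by the reference
  samples' pathway-score mean/SD (`scale="reference"`); raw averaged-z
  thresholds are available via `scale="raw"`. Comparisons are strict.
- Ties between events and censoring at the same time: events first.
- Duplicate gene rows collapse to the highest-mean row; missing values are
  an error (no NA policy in the scoring math).
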