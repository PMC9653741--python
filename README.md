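# paircoda

Compositional analysis of paired luminal (stool) / mucosal (brush biopsy)
gut-microbiome cohorts. The package implements, as a reusable tested
pipeline:

- **Compositional core** — zero replacement (0.5 pseudocount), closure,
  clr/ilr transforms, Aitchison distances, perturbation, taxonomic
  aggregation, and an ilr-shift correction that moves stool samples onto
  the biopsy mean (`paircoda.coda`).
- **Nearest-balance association search** — per-taxon clr regression
  against a factor (paired and random-grouping designs handled exactly),
  the balance whose contrast is closest to the coefficient vector, a
  500×50%-subsample reproducibility refinement, balance evaluation on
  external relative-abundance tables with clade fallback, and a
  cross-validated stool-vs-biopsy AUC analysis (`paircoda.balances`).
- **Distance-based and per-taxon statistics** — PERMANOVA on a fixed
  distance matrix with sequential covariate adjustment and
  strata-restricted permutations, alpha-diversity association models,
  arcsine-sqrt component-wise analysis after rarefaction, and
  Benjamini–Hochberg adjustment (`paircoda.stats`).
- **Co-abundance cooperatives** — Meinshausen–Bühlmann neighborhood
  selection on clr abundances with stability subsampling and a
  StARS-style penalty choice, Louvain clustering, and cluster-vs-rest
  cooperative balances (`paircoda.networks`).
- **Diversity** — multivariate-hypergeometric rarefaction, Shannon
  (nats) and chao1 (`paircoda.diversity`).
- **Synthetic paired cohorts** — a logistic-normal/multinomial generator
  with planted sample-type, batch, balance and co-abundance-block
  effects plus recovery metrics, so every stage is testable without any
  external data (`paircoda.simulate`).
- **I/O** — TSV count tables with SILVA-style lineages, BIOM 1.0 JSON
  (read-only), metadata validation, negative-control contaminant
  removal, and lesion-characteristic category aggregation
  (`paircoda.io`).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (aggregation
worked examples, nearest-balance oracle equivalence against exhaustive
search, correction exactness, PERMANOVA type-I calibration, end-to-end
recovery of planted balances and network blocks, closed-form hand
examples). The full suite takes a few minutes; the recovery tests
simulate twenty 50-patient × 150-taxon cohorts.

## CLI

Everything is exposed through one entry point:

```bash
paircoda simulate --n-patients 50 --n-taxa 150 --seed 1 --out cohort/
paircoda diversity --counts cohort/counts.tsv --out alpha.tsv
paircoda compare-types --counts cohort/counts.tsv --metadata cohort/metadata.tsv --out types.json
paircoda correct --counts cohort/counts.tsv --metadata cohort/metadata.tsv --out corrected.tsv
paircoda permanova-screen --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --factor n_lesions --covariate shannon --out screen.tsv
paircoda nearest-balance --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --factor sample_type --random-group patient_id --out balance.json
paircoda cooperatives --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --factor n_lesions --out coop/
paircoda componentwise --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --factor n_lesions --out cw.tsv
paircoda run-all --simulate --out results/ --seed 1
```

`run-all` accepts a YAML config (`--config pipeline.yaml`) mirroring
`paircoda.pipeline.PipelineConfig`; unknown keys are rejected and every
seed and filtering decision is recorded in `run_manifest.json`.

## Input formats

Count tables are tab-separated with a `taxon_id` column, a `lineage`
column (semicolon-delimited `domain;...;species`, missing ranks empty or
`unclassified`) and one integer column per sample. Metadata is a TSV
with `sample_id`, `patient_id`, `sample_type` (`stool`/`biopsy`),
`batch` and optional lesion-characteristic columns (`location`, `nice`,
`n_lesions`, `size`, `pathway`, ...); raw category values are collapsed
with `paircoda.aggregate_metadata`.
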