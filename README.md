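# sspkit

Single-sample intrinsic-subtype prediction and consistency analysis for
log2-scale expression cohorts: Spearman nearest-centroid classification
against five-subtype centroid sets, two systemic bias-adjustment methods
(gene mean-centring and distance-weighted discrimination), pairwise agreement
via unweighted Cohen's kappa, clinical cross-tabulation, and Kaplan-Meier /
log-rank survival comparison. A synthetic-cohort generator makes the whole
pipeline exercisable end-to-end without any external data.

## Library overview

| module | contents |
| --- | --- |
| `sspkit.core` | domain types: `ExpressionMatrix`, `CentroidSet`, `SubtypeCall`, clinical/survival records |
| `sspkit.io` | TSV and GCT 1.2 matrix I/O; typed tables (signatures, centroids, calls, clinical, survival, batches) |
| `sspkit.preprocess` | `quantile_normalize`, `mean_center_genes`, `pool_cohorts` |
| `sspkit.dwd` | `fit_dwd`, `dwd_adjust`, `auto_cost` (C = 100 / median cross-batch distance²) |
| `sspkit.subtype` | `collapse_probes`, `compute_centroids`, `spearman_rho`, `classify_sample`, `classify_cohort` |
| `sspkit.agreement` | `crosstab`, `cohen_kappa` (with large-sample SE and 95% CI), `consistent_samples`, `multi_way_consistent` |
| `sspkit.clinical_survival` | `clinical_by_subtype`, `marginal_summary`, `ihc_surrogate`, `km_curve`, `logrank_test` |
| `sspkit.simulate` | `SimulationConfig` and generators for centroids, cohorts, clinical covariates and survival |
| `sspkit.pipeline` | `validate_config`, `run_full` — config-driven end-to-end runs |

Classification rule: a sample is assigned the subtype with the highest
Spearman correlation over the shared gene panel; if all five correlations are
below the threshold (default 0.1, strict `<`) the call is `Unclassified`.
Exact ties resolve deterministically in the order LumA, LumB, Normal, Her2E,
Basal and set a tie flag.

## CLI

```bash
# synthetic cohort
sspkit simulate --config sim.yaml --out-dir cohort/

# pooling + normalization, centring, DWD adjustment
sspkit preprocess pool --a taiwan.tsv --b china.tsv --out pooled.tsv --batches batches.tsv
sspkit preprocess center --in pooled.tsv --method mean --out centred.tsv
sspkit adjust dwd --in pooled.tsv --batches batches.tsv --cost auto --out adjusted.tsv --model model.tsv

# classification and agreement
sspkit centroids --train train.tsv --labels labels.tsv --signature sig.tsv --out centroids.tsv
sspkit classify --in adjusted.tsv --centroids centroids.tsv --threshold 0.1 --min-genes 10 --out calls.tsv
sspkit agree --a callsA.tsv --b callsB.tsv --unclassified category --out agreement.json

# clinical association and survival
sspkit clinical --calls calls.tsv --clinical clinical.tsv --out tables.json
sspkit survive --calls calls.tsv --survival surv.tsv --clinical clinical.tsv \
    --filter er=negative --labels Basal,Her2E --out km.json

# full workflow (exit 0 ok / 2 config error / 1 runtime error)
sspkit pipeline run --config run.yaml --out-dir results/
```

A minimal pipeline config:

```yaml
seed: 7
simulate:
  n_genes: 50
  subtype_sizes: [40, 40, 40, 40, 40]
  sigma: 0.5
  batch_beta: 1.0
adjustments: [none, center, dwd]
threshold: 0.1
```

File-based runs replace `simulate:` with `inputs:` (expression, optional
batches/clinical/survival) plus a `signatures:` list pointing at centroid
tables or training matrices.

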