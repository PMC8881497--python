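# lncpair

Rank-pair lncRNA prognostic signatures for censored survival data.

The pipeline builds binary *pair indicators* over dysregulated
immune-correlated lncRNAs — for an unordered gene pair (A, B), a sample's
feature is 1 iff expression(A) > expression(B) — so the model depends only
on within-sample expression ranks, not on expression magnitudes or
normalization. On top of these features it fits a stability-selected
LASSO-Cox risk signature and evaluates it with censoring-aware
time-dependent ROC analysis plus downstream clinical / immune /
chemosensitivity association statistics.

## Workflow

1. **ingest** — parse wide expression TSVs (genes × samples), a GTF with
   `gene_type` attributes (to split lncRNA from mRNA), an immune-gene list
   and a clinical table (dropping records with no clinical data or zero
   survival time).
2. **screen** — keep lncRNAs with Pearson r > 0.4 (p < 0.001) against at
   least one immune gene on log2(x+1) values, then the dysregulated subset
   with |log2FC| > 1.5 and BH-FDR < 0.05 via moderated-t (empirical-Bayes
   variance shrinkage).
3. **pairing** — all n(n−1)/2 pair indicators over the dysregulated
   lncRNAs in tumor samples; keep *effective matches* whose minority
   indicator value covers > 20% of samples.
4. **signature_fit** — univariate Cox screen (p < 0.05), then 1000 cycles
   of ten-fold cross-validated LASSO-Cox with fresh fold draws; pairs with
   selection frequency > 100 enter a joint Cox fit defining
   RS = Σᵢ βᵢSᵢ.
5. **risk_eval** — IPCW cumulative/dynamic ROC and AUC at 1/3/5-year
   horizons, Youden-maximal cutoff on the one-year curve, high/low group
   assignment, Kaplan–Meier / log-rank comparison, and uni-/multivariate
   Cox independence tables over clinical covariates.
6. **association** — chi-square (risk group × clinical category),
   Wilcoxon / Kruskal–Wallis RS comparisons across clinical subgroups,
   Spearman + Wilcoxon statistics against precomputed immune-infiltration
   matrices, and Wilcoxon comparisons of checkpoint-gene expression and
   drug IC50 between risk groups.

A seeded synthetic-cohort generator (`lncpair.simulate`) produces
TCGA-like inputs with known ground truth (latent immune factor,
tumor-only DE shifts, exponential survival driven by known pair
indicators) so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic cohort
lncpair simulate-cohort --outdir cohort --seed 1

# run everything (writes stage artifacts + manifest.json)
lncpair run-all --config run.yaml
# or with flags only:
lncpair run-all --outdir run --seed 1 --n-reps 1000 --freq-threshold 100 \
    --config run.yaml

# individual stages compose to the same artifacts
lncpair screen --config run.yaml
lncpair pair --config run.yaml
lncpair fit --config run.yaml
lncpair evaluate --config run.yaml
lncpair associate --config run.yaml
```

`run.yaml` holds input paths and thresholds (all keys of
`lncpair.config.PipelineConfig`); CLI flags override file values. Example:

```yaml
expression: cohort/expression.tsv
gtf: cohort/annotation.gtf
clinical: cohort/clinical.tsv
immune_genes: cohort/immune_genes.txt
outdir: run
n_reps: 1000
freq_threshold: 100
seed: 1
```

Exit codes: 0 success, 1 validation error, 2 runtime error. All artifacts
are TSV/JSON; `manifest.json` records the effective config, seed and
per-stage funnel counts, and is byte-identical across reruns with the
same config and seed.

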