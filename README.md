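# tfatlas

Tissue-specific discovery of **trans**-regulation of gene expression by
transcription factors (TFs), with downstream atlas analytics.

Transcriptome-imputation methods (PrediXcan-style) explain a gene's
expression from *cis* variants near the gene, but most heritable expression
variability is *trans*.  `tfatlas` targets one well-motivated slice of that
trans space: a gene's own transcription factors.  For each gene *g* in each
tissue it models the residual expression left after removing covariates and
the cis-genetic component,

```
T_g = GReX_cis + GReX_trans + ε,      GReX_trans ≈ T_g,norm − GReX_cis
```

with two sparse (LASSO) models over the gene's curated TFs:

* **TF-Expression**:  `GReX_trans = Σ_k α_k · T_k` — the normalized
  expression levels `T_k` of the gene's TFs;
* **TF-Binding**:  `GReX_trans = Σ_k β_k · V_k` — the dosages `V_k` of
  nonsynonymous, deleterious (SIFT < 0.05) SNPs inside those TFs.

A gene becomes a **hit gene** when its model's R² beats two empirical
backgrounds — refits on shuffled residuals and on random TF sets of matched
size (B runs each, default 100) — at BH-FDR < 0.05 for both, and stays
significant in a strict majority of ten reruns of the entire pipeline on
random 90% sample subsets.  On the hit-gene table the package then computes
tissue–tissue Jaccard similarity, average-linkage tissue clustering (cut at
the median depth-2 inconsistency coefficient), common and cluster-specific
genes, co-regulation networks, multi-level regulation cascades, gene-set
enrichment and a conservation comparison.

A first-class synthetic-cohort generator plants known cis and trans effects
(both mechanisms, with configurable sharing across tissues and an optional
TF→TF layer for cascades) and records them in a truth table, so recall and
empirical FDR of the whole pipeline are measurable exactly.

## Worked example

```python
from tfatlas import RunConfig, SimulationConfig, simulate_cohort, run_pipeline
from tfatlas.evaluation import planted_recall, empirical_fdr

sim = SimulationConfig(n_tissues=2, n_samples_per_tissue=200, n_genes=60,
                       n_tfs=25, frac_trans_expression_genes=0.15,
                       frac_trans_binding_genes=0.15,
                       trans_effect_size=1.2, seed=42)
cohort = simulate_cohort(sim)
result = run_pipeline(cohort, RunConfig(b_background=30, n_robustness_runs=10,
                                        seed=42))
print(result.hits.head())
print(planted_recall(cohort, result, "expression"),
      empirical_fdr(cohort, result))
```

Running this (it is `examples/01_simulate_and_discover.py`) prints, among
other things:

```
cohort: 2 tissues x 200 samples, 60 genes, 25 TFs, 22 planted (tissue, gene) effects

hit genes (significant AND stable in >50% of 90% subsamples):
  tissue model_type  gene       r2  n_significant_runs                           tfs
tissue_1 expression G0008 0.416819                  10                   TF010;TF021
tissue_1 expression G0010 0.460887                  10       TF004;TF011;TF013;TF020
...
recall of planted TF-expression effects: 1.00
empirical FDR among hit genes:           0.04
```

i.e. every planted TF-expression effect was recovered as a hit gene and 4%
of the hit-table rows had no planted effect behind them.  The `tfs` column
lists the TFs with nonzero LASSO weight in the full-data model — the
candidate regulators.  The other scripts in `examples/` walk through the
tissue atlas (similarity, clustering, common / cluster-specific genes),
co-regulation networks and cascades, and enrichment.

A thin CLI mirrors the library for shell use:

```bash
tfatlas simulate --seed 1 --out cohort/
tfatlas all --cohort cohort/ --seed 1 --out results/
```

Repeated seeded `all` runs are byte-identical.

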