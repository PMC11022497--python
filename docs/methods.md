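# Methods

## The model

Observed expression of a gene *g* in a tissue is treated as
`T_g = GReX + ε`, the sum of a genetically regulated component and
everything else.  GReX is split additively into a cis part (local
variants) and a trans part; interaction terms between the two are
neglected.  The trans target is formed in two steps:

1. **Normalization.**  Each gene (TFs included) is residualized by
   ordinary least squares on the covariate table (intercept, sex,
   genotype-PC-like columns, any expression factors supplied) and scaled
   to unit variance.  This is deliberately a linear adjustment — it keeps
   the whole pipeline linear and leaves the residuals exactly orthogonal
   to the covariates (checked to 1e-8 in the tests).  A rank-based
   inverse-normal transform is *not* applied by default.
2. **Cis removal.**  A per-gene elastic-net (mixing 0.5, penalty chosen
   by 5-fold CV) is fit on SNP dosages within ±1 Mb of the gene
   (1-based inclusive gene start/end, strand ignored) and its in-sample
   prediction is subtracted.  Genes with no cis SNP are *not* dropped:
   they proceed with a zero cis prediction and a provenance flag, which
   maximizes the testable gene set while keeping the decision auditable.
   A precomputed cis-GReX matrix can be supplied instead of fitting one.

The residual is then modeled per gene by L1-penalized (LASSO) regression
on either (a) the normalized expression of the gene's curated TFs
(TF-Expression) or (b) the dosages of nonsynonymous SNPs with SIFT
strictly below 0.05 located in those TFs (TF-Binding).  A SNP with a
missing SIFT score counts as non-deleterious.  A gene that is its own TF
does not receive itself as a feature.

## Fitting

Features are standardized to unit variance inside the fitter; reported
weights are on the standardized scale with the centers/scales stored, so
"highest weight" comparisons across features are meaningful.  The penalty
is chosen at the minimum of the 5-fold cross-validation error over a
12-point log-spaced path from the data-derived `alpha_max` down to
`alpha_max / 100` (no 1-SE rule — the pipeline is a discovery screen and
the backgrounds are scored identically, so the more powerful choice is
calibrated).  The model is then refit on all samples at the chosen
penalty.  Model quality is the in-sample squared Pearson correlation
between prediction and residual (a constant prediction scores 0; an
anti-correlated prediction scores the same as a correlated one).  CV-R²
is *not* used: both empirical backgrounds are scored with exactly the
same in-sample statistic, which is what makes the comparison fair.

Genes are skipped (not tested) when they offer no features, fewer than 30
samples (or fewer than twice the fold count), or a constant residual.

The solver is an own numba-compiled cyclic coordinate-descent on the Gram
matrix `X'X` with warm starts along the penalty path, using the same
objective parameterisation as scikit-learn; the test-suite verifies
coefficient agreement with `sklearn.linear_model.Lasso`/`ElasticNet` at
fixed penalties.  The Gram form makes one sweep O(p²) instead of O(np),
which matters because a full cohort run performs ~10⁶ cross-validated
fits (observed fit + 2·B background refits per gene, times eleven
pipeline passes).  Convergence tolerance is 1e-5 on the maximum
coefficient change; tightening it only moves coefficients at the ~1e-6
level.

## Significance

Two empirical null distributions per tested gene, B = 100 runs each by
default (configurable; the shipped end-to-end suites use B = 50, stated
below):

* **shuffled residuals** — the residual vector is permuted across
  samples and the *entire* fitting procedure (CV penalty search
  included) is repeated;
* **random TF sets** — a random set of TFs of the same size as the
  gene's true set, drawn without replacement from the TF universe
  excluding the true TFs and the gene itself; for TF-Binding the random
  set's deleterious SNPs form the features, and a draw with no usable
  feature scores 0, exactly as an unmodelable gene would.

Both backgrounds reuse the observed fit's CV fold assignment so the R²
distributions are comparable.  The empirical p-value is the plain
counting rule `p = #{background R² ≥ observed} / B`, ties counting
against the observation, so p = 0 is attainable.  The add-one
(Phipson–Smyth) variant is available (`smoothed=True`) but is not used
for discovery: it bounds p below by 1/(B+1), and a step-up FDR procedure
across hundreds of genes can then never reject a small minority of true
signals at any effect size — the screen would be structurally blind.
The cost of the counting rule is mild anti-conservatism at the
granularity 1/B, which the null-calibration suite bounds empirically.

Benjamini–Hochberg adjustment is applied separately to each background's
p-values within each tissue × model stratum (matching the per-tissue
discovery framing); a gene is significant only when **both** adjusted
values are below 0.05.  The pass-both rule is never less stringent than
either single background.

## Robustness and hit genes

The entire per-tissue pipeline — normalization, cis fit, residuals,
model fits, both backgrounds, FDR — is rerun ten times on random 90%
subsamples (normalization recomputed on each subsample).  A **hit gene**
must be significant on the full data *and* in strictly more than half of
the reruns (≥ 6 of 10).  Requiring the full-data call as well is the
strictest reading of "retained"; with ten runs the strict majority is 6.

## Atlas analytics

* **Tissue similarity**: Jaccard index of per-tissue hit-gene sets, per
  model type; two empty sets score 0 with a warning.  External
  (asymmetric) similarity matrices are symmetrized by averaging with
  their transpose and compared by Spearman correlation over
  strictly-lower-triangle entries.
* **Common genes**: a gene is common when its tissue count is at least
  ⌈max observed count / 2⌉.  The ceiling rule is the only reading of
  "more than half" consistent with both anchor cases 41→21 and 16→8
  (a strict > half would give 9, not 8, for 16).
* **Clustering**: average linkage on 1 − Jaccard, quality summarized by
  the cophenetic correlation.  Flat clusters are formed with the
  inconsistency criterion at depth 2 (the conventional default), cutting
  at the **median** of the per-link inconsistency values; tissues left
  alone are singletons and are excluded from cluster-specific testing.
* **Cluster-specific genes**: per (gene, cluster) upper-tail
  hypergeometric test with population = all tissue slots in
  non-singleton clusters, successes = the cluster's tissues, draws = the
  gene's clustered hit tissues; BH across all pairs, flag at q < 0.05.
  Gene presence is binary (hit / not hit), not R²-weighted.
* **Co-regulation**: candidate genes are hit in ≥ 3 tissues; an edge
  requires tissue-set Jaccard ≥ 0.5 (inclusive) *and* BH q < 0.05 of the
  upper-tail hypergeometric overlap test with population = the number of
  tissues analyzed in the run (not a fixed 49), so the test stays
  calibrated on subsets.  Pairs are not required to share TFs.  Modules
  are connected components with their share of total edges.
* **Cascades**: per tissue and model, a directed edge TF → gene for
  every TF with nonzero weight in a hit gene's model (for TF-Binding, a
  TF contributes an edge when any of its deleterious SNPs is selected).
  Depth counts levels of trans-regulation on the longest chain ending at
  a node (unmodeled root TF = 0, flat hit gene = 1), truncated at 4.
  Mutual-regulation cycles are reported explicitly and collapsed via the
  acyclic condensation for the depth computation, never silently broken.
* **Enrichment / conservation**: upper-tail hypergeometric enrichment of
  hit genes against named sets, universe = tested genes, BH across sets.
  Conservation scores are per-residue values averaged per protein; hit
  genes are compared against tested-but-not-hit genes ("did not pass the
  model filtering" is read as tested-but-not-hit) with a two-sided
  Wilcoxon rank-sum test — exact null for tie-free groups of ≤ 25,
  normal approximation with tie correction otherwise.

## The synthetic cohort generator

No published generative model exists for this pipeline's inputs, so the
generator uses deliberately simple stand-ins chosen to exercise every
code path rather than to imitate any real cohort:

* a donor pool 1.5× the per-tissue sample size, genotyped once
  (`dosages ~ Binomial(2, maf)`, maf ~ U(0.1, 0.5), monomorphic columns
  resampled), from which each tissue draws its samples — so tissues
  overlap in donors as in a real multi-tissue study;
* donor-level covariates (binary sex + Gaussian columns) with per-gene,
  per-tissue effect sizes ~ N(0, 0.5²);
* a TF map with per-gene TF counts uniform on [2, 5]; each TF carries
  5 SNPs, a Bernoulli(0.3) fraction flagged nonsynonymous with
  SIFT ~ U(0, 0.05), the rest SIFT ~ U(0.05, 1) with a random
  nonsynonymous flag so the strict deleteriousness filter is exercised
  on both clauses;
* a cis component scaled to variance `cis_h2` (default 0.3), a planted
  trans component scaled to variance `trans_effect_size²` (default 1.0)
  against unit-variance Gaussian noise, giving planted model R² around
  0.5 — a strong but not trivial signal;
* planted effects live in a random home tissue and are copied into each
  other tissue independently with probability `tissue_sharing`
  (default 0.5), which qualitatively reproduces the predominance of
  tissue-specific discoveries;
* TF expression is covariates + independent Gaussian; an opt-in TF→TF
  layer (`tf_tf_edges`) plants expression effects of unregulated TFs on
  a fraction of TFs, giving multi-level truth for cascade tests.

What the generator does **not** emulate: linkage disequilibrium,
population structure, non-Gaussian expression noise, unequal tissue
sizes, correlated TF modules, and real TF-target topology.  Passing
tests therefore demonstrate correctness and calibration of the
*procedure* under its stated assumptions, not performance on real
GTEx-scale data.

## Study-condition runs and problem sizes

The end-to-end suites run 3-tissue cohorts with 300 samples/tissue,
150 genes, 40 TFs, 10% of genes planted per mechanism at 1.0 sd, with
B = 50 background runs and the full ten 90% robustness reruns (three
seeds for recovery, one null cohort).  At these sizes the pipeline
performs ≈ 10⁶ CV fits per cohort in ~1.5 minutes on one CPU.  Under
these conditions measured recall of planted TF-expression effects is
1.0, empirical FDR among hits ≤ 0.08, and the null-cohort hit fraction
per stratum ≤ 0.007.  `scripts/acceptance.py` reproduces these numbers
from scratch at any seed.

## Known limitations

* Associations only; no causal claims, no cis×trans or SNP×SNP
  interactions, no penalties other than LASSO for the trans models.
* The counting-rule p-value is anti-conservative by up to ~1/B; B below
  ~50 makes the BH step coarse.
* In-sample R² inflates with the number of offered features; this
  cancels in the background comparison only because backgrounds offer
  matched feature counts — the random-TF null is therefore not optional.
* With very small TF universes the matched random-TF draw can be
  impossible (it raises, advising shuffled-only operation) or degenerate
  (warned).
* Whether normalization in robustness runs should be computed on the
  subsample or inherited from the full data is ambiguous; it is
  recomputed on the subsample here, which is the stricter choice.
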