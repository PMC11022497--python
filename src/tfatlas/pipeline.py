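"""End-to-end orchestration of the trans-regulation discovery pipeline.

One tissue run is: covariate normalization -> cis prediction ->
trans residuals -> per-gene LASSO fits for each model type -> dual
empirical backgrounds -> BH-FDR significance calls.  The full pipeline
repeats this on every tissue, then reruns it ``n_robustness_runs`` times
per tissue on random 90% subsamples and intersects the calls into the
final hit-gene table.

All randomness descends from one master seed through keyed child seeds
(see :mod:`tfatlas._seeds`); a tissue run is fully determined by
``(data, config, base_seed)`` regardless of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed, rng_for
from .config import RunConfig
from .lasso import make_folds
from .models import (TFModelFit, build_tf_binding_features,
                     build_tf_expression_features, deleterious_snps_by_tf,
                     fit_trans_model, tf_map_dict)
from .preprocess import (compute_trans_residuals, fit_cis_predictor,
                         normalize_expression)
from .significance import (call_significant_genes, empirical_pvalue,
                           run_random_tf_background, run_shuffled_background)
from .simulate import SimulatedCohort

__all__ = ["TissueData", "TissueRunResult", "PipelineResult", "run_tissue",
           "run_pipeline", "tissue_data_from_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class TissueData:
    """All inputs needed to run one tissue."""

    tissue: str
    expression: pd.DataFrame        # samples x (genes incl. TFs)
    covariates: pd.DataFrame
    dosages: pd.DataFrame           # samples x SNPs
    tf_map: pd.DataFrame
    snp_annotation: pd.DataFrame
    gene_positions: pd.DataFrame | None = None
    cis_prediction: pd.DataFrame | None = None   # optional precomputed GReX_cis

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    def subset(self, samples) -> "TissueData":
        samples = list(samples)
        return TissueData(
            tissue=self.tissue,
            expression=self.expression.loc[samples],
            covariates=self.covariates.loc[samples],
            dosages=self.dosages.loc[samples],
            tf_map=self.tf_map,
            snp_annotation=self.snp_annotation,
            gene_positions=self.gene_positions,
            cis_prediction=(None if self.cis_prediction is None
                            else self.cis_prediction.loc[samples]),
        )


@dataclass
class TissueRunResult:
    tissue: str
    results: pd.DataFrame                      # one row per tested gene x model
    fits: dict[tuple[str, str], TFModelFit] = field(default_factory=dict)
    skipped: pd.DataFrame | None = None


def tissue_data_from_cohort(cohort: SimulatedCohort, tissue: str) -> TissueData:
    return TissueData(
        tissue=tissue,
        expression=cohort.expression[tissue],
        covariates=cohort.covariates[tissue],
        dosages=cohort.dosages_for(tissue),
        tf_map=cohort.tf_map,
        snp_annotation=cohort.snp_annotation,
        gene_positions=cohort.gene_positions,
    )


def run_tissue(data: TissueData, cfg: RunConfig, base_seed: int,
               keep_fits: bool = True) -> TissueRunResult:
    """Run normalization, residualization, model fits, both backgrounds
    and the FDR calls for one tissue on the samples in ``data``."""
    cfg.validate()
    tissue = data.tissue
    norm = normalize_expression(data.expression, data.covariates)
    if data.cis_prediction is not None:
        cis = data.cis_prediction
    else:
        ann = data.snp_annotation.set_index("snp_id")
        snp_positions = ann["position"] if "position" in ann.columns else None
        if snp_positions is None or data.gene_positions is None:
            logger.info("tissue %s: no position metadata, GReX_cis = 0", tissue)
            cis = pd.DataFrame(index=norm.index)
        else:
            cis = fit_cis_predictor(
                norm, data.dosages, snp_positions, data.gene_positions,
                cis_window=cfg.cis_window, l1_ratio=cfg.cis_l1_ratio,
                cv_folds=cfg.cv_folds, n_alphas=cfg.n_alphas,
                seed=child_seed(base_seed, "cis", tissue)).prediction
    resid = compute_trans_residuals(norm, cis)

    tfs_of = tf_map_dict(data.tf_map)
    del_by_tf = deleterious_snps_by_tf(data.snp_annotation, cfg.sift_cutoff)
    targets = [g for g in resid.columns if g in tfs_of]
    universe_expr = sorted(set(data.tf_map["tf"]) & set(norm.columns))
    universe_bind = sorted(set(data.tf_map["tf"]))

    rows = []
    skipped = []
    fits: dict[tuple[str, str], TFModelFit] = {}
    for model_type in cfg.model_types:
        for gene in targets:
            if model_type == "expression":
                fs = build_tf_expression_features(gene, tfs_of, norm)
                universe = universe_expr
            else:
                fs = build_tf_binding_features(gene, tfs_of, data.dosages,
                                               del_by_tf, cfg.sift_cutoff)
                universe = universe_bind
            y = resid[gene].to_numpy()
            folds = make_folds(len(y), cfg.cv_folds,
                               rng_for(base_seed, "folds", tissue, model_type, gene))
            fit = fit_trans_model(fs, y, folds, tissue=tissue,
                                  min_samples=cfg.min_samples,
                                  n_alphas=cfg.n_alphas)
            if fit.status != "fit":
                skipped.append((tissue, model_type, gene, fit.status))
                continue
            bg_sh = run_shuffled_background(fs, y, folds, cfg.b_background,
                                            base_seed, tissue=tissue,
                                            n_alphas=cfg.n_alphas)
            true_tfs = [t for t in tfs_of[gene] if t != gene]
            bg_rt = run_random_tf_background(
                gene, true_tfs, universe, y, folds,
                cfg.b_background, base_seed, model_type,
                norm_expr=norm, dosages=data.dosages, del_by_tf=del_by_tf,
                tissue=tissue, n_alphas=cfg.n_alphas)
            rows.append({
                "tissue": tissue, "model_type": model_type, "gene": gene,
                "r2": fit.r2, "n_features_offered": fit.n_features_offered,
                "n_features_selected": fit.n_features_selected,
                "p_shuffled": empirical_pvalue(fit.r2, bg_sh),
                "p_random_tf": empirical_pvalue(fit.r2, bg_rt),
            })
            if keep_fits:
                fit.fit = None  # drop the heavy internals, keep weights
                fits[(model_type, gene)] = fit
    results = pd.DataFrame(rows, columns=[
        "tissue", "model_type", "gene", "r2", "n_features_offered",
        "n_features_selected", "p_shuffled", "p_random_tf"])
    if len(results):
        results = call_significant_genes(results, cfg.fdr_level)
    else:
        results["q_shuffled"] = results["q_random_tf"] = []
        results["significant"] = []
    skipped_df = pd.DataFrame(
        skipped, columns=["tissue", "model_type", "gene", "status"])
    return TissueRunResult(tissue=tissue, results=results, fits=fits,
                           skipped=skipped_df)


@dataclass
class PipelineResult:
    """Aggregated output of a full multi-tissue run."""

    results: pd.DataFrame           # full-data significance per tissue x model x gene
    hits: pd.DataFrame              # final hit-gene table
    robustness: pd.DataFrame        # per gene: runs significant / total
    fits: dict[tuple[str, str, str], TFModelFit]   # (tissue, model, gene)
    n_tissues: int = 0

    def hit_genes(self, tissue: str, model_type: str) -> set[str]:
        h = self.hits
        sel = (h["tissue"] == tissue) & (h["model_type"] == model_type)
        return set(h.loc[sel, "gene"])


def run_pipeline(cohort: SimulatedCohort, cfg: RunConfig) -> PipelineResult:
    """Full-data significance plus robustness subsampling for every tissue
    of the cohort, intersected into the final hit-gene table."""
    from .robustness import call_hit_genes, robustness_subsample_run

    cfg.validate()
    tissues = list(cfg.tissues) if cfg.tissues else cohort.tissues
    all_results = []
    all_hits = []
    all_rob = []
    fits: dict[tuple[str, str, str], TFModelFit] = {}
    for tissue in tissues:
        data = tissue_data_from_cohort(cohort, tissue)
        base_seed = child_seed(cfg.seed, "tissue_run", tissue)
        full = run_tissue(data, cfg, base_seed)
        for (m, g), f in full.fits.items():
            fits[(tissue, m, g)] = f
        run_flags = []
        for r in range(cfg.n_robustness_runs):
            run_seed = child_seed(cfg.seed, "robustness", tissue, r)
            flags = robustness_subsample_run(data, cfg,
                                             cfg.subsample_fraction, run_seed)
            run_flags.append(flags)
        hits, rob = call_hit_genes(full.results, run_flags,
                                   cfg.n_robustness_runs, fits=full.fits)
        all_results.append(full.results)
        all_hits.append(hits)
        all_rob.append(rob)
        logger.info("tissue %s: %d tested, %d significant, %d hits",
                    tissue, len(full.results),
                    int(full.results["significant"].sum()) if len(full.results) else 0,
                    len(hits))
    def _concat(frames):
        nonempty = [f for f in frames if len(f)]
        return (pd.concat(nonempty, ignore_index=True) if nonempty
                else frames[0].iloc[0:0].copy())

    return PipelineResult(
        results=_concat(all_results), hits=_concat(all_hits),
        robustness=_concat(all_rob), fits=fits, n_tissues=len(tissues))
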