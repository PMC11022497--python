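"""Per-gene trans models: TF-Expression and TF-Binding.

For each candidate gene the trans residual is modeled by L1-penalised
(LASSO) regression on either

* the normalized expression of the gene's curated TFs ("expression"
  mechanism), or
* the dosages of nonsynonymous, SIFT-deleterious (SIFT < 0.05, strict)
  SNPs located in those TFs ("binding" mechanism).

Model quality is summarised as the in-sample squared Pearson correlation
between the model prediction and the residual; the same score is applied
to the empirical background refits so the comparison is calibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lasso import SparseLinearFit, fit_sparse_cv

__all__ = ["TFFeatureSet", "TFModelFit", "build_tf_expression_features",
           "build_tf_binding_features", "fit_trans_model", "model_r2",
           "deleterious_snps_by_tf"]

logger = logging.getLogger(__name__)

MIN_SAMPLES = 30


@dataclass
class TFFeatureSet:
    """The design matrix offered to one gene's trans model."""

    gene: str
    model_type: str                       # "expression" | "binding"
    feature_ids: list[str]                # TF ids, or SNP ids
    matrix: np.ndarray                    # samples x features
    feature_owner: dict[str, str] = field(default_factory=dict)  # SNP -> TF

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class TFModelFit:
    """A fitted (or skipped) trans model for one gene in one tissue."""

    gene: str
    tissue: str
    model_type: str
    status: str                           # "fit" | "skipped_no_features" | "skipped_low_n" | "skipped_constant"
    r2: float = 0.0
    weights: dict[str, float] = field(default_factory=dict)  # standardized scale
    intercept: float = 0.0
    alpha: float = float("nan")
    n_samples: int = 0
    n_features_offered: int = 0
    n_features_selected: int = 0
    fit: SparseLinearFit | None = field(default=None, repr=False)
    feature_owner: dict[str, str] = field(default_factory=dict)

    @property
    def selected_tfs(self) -> list[str]:
        """TFs with nonzero weight (binding-model SNPs map to their TF)."""
        tfs = []
        for f, w in self.weights.items():
            if w != 0.0:
                tfs.append(self.feature_owner.get(f, f))
        return sorted(set(tfs))


def tf_map_dict(tf_map: pd.DataFrame) -> dict[str, list[str]]:
    return tf_map.groupby("target")["tf"].apply(list).to_dict()


def build_tf_expression_features(gene: str, tf_map: pd.DataFrame | dict,
                                 norm_expr: pd.DataFrame) -> TFFeatureSet:
    """One column per mapped TF of ``gene`` that is present in the
    normalized expression matrix; the gene's own column is excluded when
    it regulates itself."""
    tfs_of = tf_map if isinstance(tf_map, dict) else tf_map_dict(tf_map)
    tfs = [tf for tf in tfs_of.get(gene, []) if tf != gene]
    present = [tf for tf in tfs if tf in norm_expr.columns]
    absent = set(tfs) - set(present)
    if absent:
        logger.debug("gene %s: %d TFs unexpressed, dropped", gene, len(absent))
    mat = norm_expr[present].to_numpy() if present else np.empty((len(norm_expr), 0))
    return TFFeatureSet(gene=gene, model_type="expression",
                        feature_ids=present, matrix=mat)


def deleterious_snps_by_tf(snp_annotation: pd.DataFrame,
                           sift_cutoff: float = 0.05) -> dict[str, list[str]]:
    """SNPs passing the strict deleteriousness filter, grouped by owning
    gene.  Missing SIFT scores count as non-deleterious."""
    sift = pd.to_numeric(snp_annotation["sift"], errors="coerce")
    keep = snp_annotation["nonsynonymous"].astype(bool) & (sift < sift_cutoff)
    n_missing = int(sift.isna().sum())
    if n_missing:
        logger.debug("%d SNPs without SIFT treated as non-deleterious", n_missing)
    sel = snp_annotation.loc[keep.fillna(False)]
    return sel.groupby("gene")["snp_id"].apply(list).to_dict()


def build_tf_binding_features(gene: str, tf_map: pd.DataFrame | dict,
                              dosages: pd.DataFrame,
                              snp_annotation: pd.DataFrame | dict,
                              sift_cutoff: float = 0.05) -> TFFeatureSet:
    """Dosage columns of deleterious nonsynonymous SNPs in the gene's TFs.

    ``snp_annotation`` may be the raw annotation table or a precomputed
    ``deleterious_snps_by_tf`` mapping.  Monomorphic columns are dropped.
    """
    tfs_of = tf_map if isinstance(tf_map, dict) else tf_map_dict(tf_map)
    del_by_tf = (snp_annotation if isinstance(snp_annotation, dict)
                 else deleterious_snps_by_tf(snp_annotation, sift_cutoff))
    owner: dict[str, str] = {}
    snps: list[str] = []
    for tf in tfs_of.get(gene, []):
        if tf == gene:
            continue
        for s in del_by_tf.get(tf, []):
            if s in dosages.columns and s not in owner:
                owner[s] = tf
                snps.append(s)
    if snps:
        mat = dosages[snps].to_numpy(dtype=float)
        poly = mat.std(axis=0) > 0
        snps = [s for s, p in zip(snps, poly) if p]
        mat = mat[:, poly]
        owner = {s: owner[s] for s in snps}
    else:
        mat = np.empty((len(dosages), 0))
    return TFFeatureSet(gene=gene, model_type="binding", feature_ids=snps,
                        matrix=mat, feature_owner=owner)


def model_r2(prediction: np.ndarray, target: np.ndarray) -> float:
    """Squared Pearson correlation between prediction and target.

    By this definition a perfectly anti-correlated prediction also scores
    1; a constant prediction scores 0 by convention.
    """
    if len(prediction) != len(target):
        raise ValueError("prediction / target length mismatch")
    sp = prediction.std()
    st = target.std()
    # relative guard: summation rounding gives std ~1e-19 on constant arrays
    if sp <= 1e-12 * max(1.0, float(np.abs(prediction).max())) or st == 0.0:
        return 0.0
    r = float(np.corrcoef(prediction, target)[0, 1])
    return r * r


def fit_trans_model(features: TFFeatureSet, residual: np.ndarray,
                    fold_ids: np.ndarray, tissue: str = "",
                    min_samples: int = MIN_SAMPLES, n_alphas: int = 12,
                    alpha_override: float | None = None) -> TFModelFit:
    """LASSO fit of one gene's trans residual on its feature set.

    The penalty is chosen at the cross-validation error minimum over the
    folds given in ``fold_ids`` (shared with the background refits), then
    the model is refit on all samples.  Genes are skipped (not fit) when
    they offer no features, fewer samples than ``min_samples`` (or than
    twice the fold count), or a constant residual.
    """
    n = len(residual)
    base = dict(gene=features.gene, tissue=tissue, model_type=features.model_type,
                n_samples=n, n_features_offered=features.n_features,
                feature_owner=features.feature_owner)
    if features.n_features == 0:
        return TFModelFit(status="skipped_no_features", **base)
    n_folds = int(fold_ids.max()) + 1 if len(fold_ids) else 0
    if n < max(min_samples, 2 * n_folds):
        return TFModelFit(status="skipped_low_n", **base)
    if residual.std() == 0.0:
        return TFModelFit(status="skipped_constant", **base)
    fit = fit_sparse_cv(features.matrix, residual, fold_ids,
                        n_alphas=n_alphas, alpha_override=alpha_override)
    pred = fit.predict(features.matrix)
    r2 = model_r2(pred, residual)
    weights = dict(zip(features.feature_ids, (float(w) for w in fit.coef)))
    return TFModelFit(status="fit", r2=r2, weights=weights,
                      intercept=fit.intercept, alpha=fit.alpha,
                      n_features_selected=fit.n_selected, fit=fit, **base)
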