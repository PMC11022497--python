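"""Empirical significance of trans models against dual backgrounds.

A gene's observed model R-squared is compared against two empirical null
distributions, each of B refits with the identical fitting procedure
(cross-validated penalty included):

* **shuffled residuals** — the residual vector is permuted across
  samples, breaking any sample-level association while keeping the
  feature matrix intact;
* **random TF sets** — a random set of TFs of the same size as the
  gene's true set (excluding the true TFs and the gene itself) supplies
  the features.

Empirical p-values are the plain counting rule p = #{null >= obs} / B,
with ties counting against the observation; a gene whose observed fit
beats every background scores p = 0.  (The add-one-smoothed variant
p = (1 + #{null >= obs}) / (B + 1) is available via
``empirical_pvalue(..., smoothed=True)`` but is not used for discovery:
at finite B it bounds p away from 0 and a step-up FDR procedure over
hundreds of genes could then never reject a minority of true signals.)
Benjamini-Hochberg adjustment is applied separately to each background's
p-values within a tissue x model stratum and a gene is significant only
when both adjusted values fall below the FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import rng_for
from .lasso import _background_r2_columns, _background_r2_perms
from .models import (TFFeatureSet, TFModelFit, build_tf_binding_features,
                     build_tf_expression_features, fit_trans_model, model_r2)

_EPS = 1e-2
_TOL = 1e-5
_MAX_ITER = 2000

__all__ = ["BackgroundDistribution", "run_shuffled_background",
           "run_random_tf_background", "empirical_pvalue", "bh_adjust",
           "call_significant_genes"]

logger = logging.getLogger(__name__)


@dataclass
class BackgroundDistribution:
    gene: str
    background_type: str       # "shuffled_residuals" | "random_tfs"
    r2: np.ndarray

    @property
    def B(self) -> int:
        return len(self.r2)


def run_shuffled_background(features: TFFeatureSet, residual: np.ndarray,
                            fold_ids: np.ndarray, B: int, seed: int,
                            tissue: str = "",
                            n_alphas: int = 12) -> BackgroundDistribution:
    """B refits on permuted residual vectors; each refit repeats the full
    CV penalty search on the same folds as the observed fit."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng_for(seed, "shuffle", tissue, features.model_type, features.gene)
    if features.n_features == 0 or residual.std() == 0.0:
        return BackgroundDistribution(features.gene, "shuffled_residuals",
                                      np.zeros(B))
    perms = np.empty((B, len(residual)))
    for b in range(B):
        perms[b] = rng.permutation(residual)
    n_folds = int(fold_ids.max()) + 1
    r2 = _background_r2_perms(
        np.ascontiguousarray(features.matrix, dtype=np.float64), perms,
        fold_ids, n_folds, n_alphas, _EPS, 1.0, _TOL, _MAX_ITER)
    return BackgroundDistribution(features.gene, "shuffled_residuals", r2)


def run_random_tf_background(gene: str, true_tfs: list[str],
                             tf_universe: list[str], residual: np.ndarray,
                             fold_ids: np.ndarray, B: int, seed: int,
                             model_type: str, norm_expr: pd.DataFrame = None,
                             dosages: pd.DataFrame = None,
                             del_by_tf: dict[str, list[str]] = None,
                             tissue: str = "",
                             n_alphas: int = 12) -> BackgroundDistribution:
    """B refits on random TF sets matched in size to the true set.

    TFs are drawn without replacement from ``tf_universe`` minus the true
    TFs and the gene itself.  For the expression model the features are
    the drawn TFs' normalized expression columns; for the binding model
    the drawn TFs' deleterious SNP dosage columns (monomorphic columns
    dropped).  A draw offering no usable feature scores r2 = 0, mirroring
    how an unmodelable gene would score.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    k = len(true_tfs)
    pool = sorted(set(tf_universe) - set(true_tfs) - {gene})
    if k == 0:
        raise ValueError(f"gene {gene}: empty true TF set (should have been "
                         "skipped upstream)")
    if len(pool) < k:
        raise ValueError(
            f"gene {gene}: TF universe too small for matched random sets "
            f"({len(pool)} < {k}); run in shuffled-only mode")
    if len(pool) == k:
        logger.warning("gene %s: TF universe exactly exhausted; all random "
                       "draws identical", gene)
    rng = rng_for(seed, "random_tf", tissue, model_type, gene)
    draws = [list(rng.choice(pool, size=k, replace=False)) for _ in range(B)]

    if residual.std() == 0.0:
        return BackgroundDistribution(gene, "random_tfs", np.zeros(B))

    # resolve each draw to design-matrix column indices once, then score
    # every draw inside the compiled kernel
    if model_type == "expression":
        M = np.ascontiguousarray(norm_expr.to_numpy(dtype=np.float64, copy=False))
        col_of = {c: i for i, c in enumerate(norm_expr.columns)}
        idx_lists = [[col_of[tf] for tf in draw if tf in col_of]
                     for draw in draws]
    elif model_type == "binding":
        M = np.ascontiguousarray(dosages.to_numpy(dtype=np.float64, copy=False))
        col_of = {c: i for i, c in enumerate(dosages.columns)}
        idx_lists = []
        for draw in draws:
            seen: dict[int, None] = {}
            for tf in draw:
                for s in del_by_tf.get(tf, []):
                    ci = col_of.get(s)
                    if ci is not None:
                        seen[ci] = None
            idx_lists.append(list(seen))
    else:
        raise ValueError(f"unknown model_type {model_type!r}")

    offsets = np.zeros(B + 1, dtype=np.int64)
    for b, idx in enumerate(idx_lists):
        offsets[b + 1] = offsets[b] + len(idx)
    col_idx = np.fromiter((c for idx in idx_lists for c in idx),
                          dtype=np.int64, count=int(offsets[-1]))
    n_folds = int(fold_ids.max()) + 1
    r2 = _background_r2_columns(M, col_idx, offsets, residual, fold_ids,
                                n_folds, n_alphas, _EPS, 1.0, _TOL, _MAX_ITER)
    return BackgroundDistribution(gene, "random_tfs", r2)


def empirical_pvalue(observed_r2: float,
                     background: BackgroundDistribution | np.ndarray,
                     smoothed: bool = False) -> float:
    """Permutation p-value of an observed R-squared against a background.

    Default is the counting rule p = #{background >= observed} / B, with
    ties counting against the observation (so an observation beating all
    B backgrounds scores exactly 0).  ``smoothed=True`` gives the
    add-one variant (1 + count) / (B + 1), which is bounded away from 0.
    """
    r2 = background.r2 if isinstance(background, BackgroundDistribution) else np.asarray(background)
    B = len(r2)
    if B == 0:
        raise ValueError("empty background distribution")
    count = int(np.sum(r2 >= observed_r2))
    if smoothed:
        return (1.0 + count) / (B + 1.0)
    return count / B


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant_genes(results: pd.DataFrame,
                           fdr_level: float = 0.05) -> pd.DataFrame:
    """Apply BH within each (tissue, model_type) stratum to both
    background p-value columns and call genes significant when both
    adjusted values are below ``fdr_level``.

    ``results`` needs columns tissue, model_type, gene, r2, p_shuffled,
    p_random_tf; the returned copy adds q_shuffled, q_random_tf and
    significant.
    """
    need = {"tissue", "model_type", "gene", "p_shuffled", "p_random_tf"}
    missing = need - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns {sorted(missing)}")
    if results[["p_shuffled", "p_random_tf"]].isna().any().any():
        bad = results.loc[results[["p_shuffled", "p_random_tf"]].isna().any(axis=1), "gene"]
        raise ValueError(f"missing background p-values for genes {list(bad)[:5]}")
    out = results.copy()
    out["q_shuffled"] = np.nan
    out["q_random_tf"] = np.nan
    for _, idx in out.groupby(["tissue", "model_type"]).groups.items():
        out.loc[idx, "q_shuffled"] = bh_adjust(out.loc[idx, "p_shuffled"])
        out.loc[idx, "q_random_tf"] = bh_adjust(out.loc[idx, "p_random_tf"])
    out["significant"] = ((out["q_shuffled"] < fdr_level)
                          & (out["q_random_tf"] < fdr_level))
    return out
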