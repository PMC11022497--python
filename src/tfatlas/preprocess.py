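"""Expression normalization and removal of the cis-genetic component.

The trans-discovery target for each gene is the residual of its
covariate-adjusted, variance-standardised expression after subtracting a
cross-validated sparse cis prediction built from SNPs within a window of
the gene.  Genes without any cis SNP keep their normalized values (cis
prediction treated as zero) and are flagged, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .lasso import fit_sparse_cv, make_folds, SparseLinearFit

__all__ = ["normalize_expression", "fit_cis_predictor",
           "compute_trans_residuals", "CisGrexResult"]

logger = logging.getLogger(__name__)


def normalize_expression(expr: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """Residualize each gene on the covariates (OLS with intercept), then
    scale to unit variance.

    Returns a samples x genes matrix whose columns have mean 0 and
    variance 1.  Genes whose covariate residual has zero variance (e.g. a
    gene that is an exact linear function of the covariates) are dropped
    with a log entry.  Raises on rank-deficient covariate matrices, naming
    the collinear columns.
    """
    if set(expr.index) != set(cov.index):
        raise ValueError("expression and covariate sample ids differ")
    cov = cov.loc[expr.index]
    n, k = cov.shape
    if n <= k + 2:
        raise ValueError(f"need n_samples > n_covariates + 2 (n={n}, k={k})")
    C = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        cur = C[:, :1]
        for j, name in enumerate(cov.columns):
            cand = np.column_stack([cur, C[:, j + 1]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"covariate matrix is rank-deficient; collinear "
                         f"columns: {bad}")
    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta
    sd = resid.std(axis=0)
    keep = sd > 1e-12
    dropped = [g for g, k_ in zip(expr.columns, keep) if not k_]
    if dropped:
        logger.info("normalize_expression: dropped %d zero-variance genes: %s",
                    len(dropped), dropped[:5])
    out = resid[:, keep] / sd[keep]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns[keep])


@dataclass
class CisGrexResult:
    """Cis-predicted expression plus per-gene fit provenance."""

    prediction: pd.DataFrame                     # samples x genes with a cis model
    fits: dict[str, SparseLinearFit] = field(default_factory=dict)
    snps: dict[str, list[str]] = field(default_factory=dict)
    no_cis_genes: list[str] = field(default_factory=list)
    provenance: str = "fitted"


def fit_cis_predictor(expr: pd.DataFrame, dosages: pd.DataFrame,
                      snp_positions: pd.Series, gene_positions: pd.DataFrame,
                      cis_window: float = 1e6, l1_ratio: float = 0.5,
                      cv_folds: int = 5, n_alphas: int = 12,
                      seed: int = 0) -> CisGrexResult:
    """Per-gene sparse elastic-net model of expression from cis SNP dosages.

    A SNP is cis to a gene when its position falls within
    ``[start - cis_window, end + cis_window]`` (1-based inclusive; strand
    ignored).  The penalty is chosen by K-fold cross-validation.  Genes
    with no cis SNP are recorded in ``no_cis_genes`` rather than given an
    all-zero model.
    """
    if gene_positions is None or snp_positions is None:
        raise ValueError("no position metadata: supply a precomputed cis "
                         "prediction matrix instead of fitting one")
    dosages = dosages.loc[expr.index]
    pos = snp_positions
    gp = gene_positions.set_index("gene")
    pred = {}
    fits: dict[str, SparseLinearFit] = {}
    snps_used: dict[str, list[str]] = {}
    no_cis: list[str] = []
    snp_pos_arr = pos.reindex(dosages.columns)
    for g in expr.columns:
        if g not in gp.index:
            no_cis.append(g)
            continue
        start, end = gp.loc[g, "start"], gp.loc[g, "end"]
        in_win = (snp_pos_arr >= start - cis_window) & (snp_pos_arr <= end + cis_window)
        snps = list(dosages.columns[in_win.to_numpy(dtype=bool)])
        if not snps:
            no_cis.append(g)
            continue
        X = dosages[snps].to_numpy()
        y = expr[g].to_numpy()
        folds = make_folds(len(y), cv_folds, rng_for(seed, "cis_folds", g))
        fit = fit_sparse_cv(X, y, folds, l1_ratio=l1_ratio, n_alphas=n_alphas)
        fits[g] = fit
        snps_used[g] = snps
        pred[g] = fit.predict(X)
    if no_cis:
        logger.info("fit_cis_predictor: %d genes without cis SNPs (GReX_cis "
                    "treated as 0 downstream)", len(no_cis))
    prediction = pd.DataFrame(pred, index=expr.index)
    return CisGrexResult(prediction=prediction, fits=fits, snps=snps_used,
                         no_cis_genes=no_cis)


def compute_trans_residuals(norm: pd.DataFrame,
                            cis: CisGrexResult | pd.DataFrame) -> pd.DataFrame:
    """Subtract the cis prediction from the normalized expression.

    Genes without a cis model pass through unchanged.  The result is
    re-centered per gene (mean 0) so downstream fits see a clean target.
    Raises when the cis matrix contains genes absent from ``norm``.
    """
    cis_pred = cis.prediction if isinstance(cis, CisGrexResult) else cis
    extra = set(cis_pred.columns) - set(norm.columns)
    if extra:
        raise ValueError(f"cis prediction covers genes absent from the "
                         f"normalized matrix: {sorted(extra)[:5]}")
    out = norm.copy()
    if len(cis_pred.columns):
        common = [g for g in norm.columns if g in cis_pred.columns]
        out[common] = norm[common] - cis_pred.loc[norm.index, common]
    return out - out.mean(axis=0)
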