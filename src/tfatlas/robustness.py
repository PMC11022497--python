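"""Robustness subsampling and the final hit-gene call.

The entire per-tissue pipeline — normalization, cis residualization,
model fits and both empirical backgrounds — is rerun ten times on random
90% subsamples of the tissue's samples.  A gene becomes a **hit gene**
when it is significant on the full data *and* in a strict majority of
the subsample reruns (more than ``n_runs / 2``, i.e. at least 6 of 10).
"""

from __future__ import annotations

import logging

import pandas as pd

from ._seeds import rng_for
from .config import RunConfig

__all__ = ["robustness_subsample_run", "call_hit_genes"]

logger = logging.getLogger(__name__)


def robustness_subsample_run(data, cfg: RunConfig, fraction: float,
                             run_seed: int) -> dict[tuple[str, str], bool]:
    """One subsample rerun; returns ``{(model_type, gene): significant}``.

    Samples are drawn without replacement.  With ``fraction == 1.0`` and
    ``run_seed`` equal to the full-data base seed this reproduces the
    full-data significance calls exactly.  A subsample smaller than the
    fitter's minimum records every gene as not significant, with a
    warning.
    """
    from .pipeline import run_tissue

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = data.n_samples
    n_sub = int(fraction * n)
    if n_sub < cfg.min_samples:
        logger.warning("tissue %s: subsample of %d below minimum %d; run "
                       "recorded as all-false", data.tissue, n_sub,
                       cfg.min_samples)
        return {}
    if n_sub == n:
        sub = data
    else:
        rng = rng_for(run_seed, "subsample", data.tissue)
        samples = sorted(rng.choice(data.expression.index.to_numpy(),
                                    size=n_sub, replace=False))
        sub = data.subset(samples)
    res = run_tissue(sub, cfg, base_seed=run_seed, keep_fits=False)
    return {(row.model_type, row.gene): bool(row.significant)
            for row in res.results.itertuples()}


def call_hit_genes(full_results: pd.DataFrame,
                   run_flags: list[dict[tuple[str, str], bool]],
                   n_runs: int, fits: dict | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine full-data significance with the subsample reruns.

    Returns ``(hit_table, robustness_table)``.  The robustness table has
    one row per tested (tissue, model, gene) with the number of
    significant runs; the hit table keeps only genes passing both the
    full-data call and the strict-majority rule, with the TFs selected
    (nonzero weight) in the full-data model.
    """
    if len(run_flags) != n_runs:
        raise ValueError(f"expected {n_runs} run results, got {len(run_flags)}")
    rob_rows = []
    hit_rows = []
    for row in full_results.itertuples():
        key = (row.model_type, row.gene)
        n_sig = sum(1 for fl in run_flags if fl.get(key, False))
        hit = bool(row.significant) and (n_sig > n_runs / 2 if n_runs else True)
        rob_rows.append({"tissue": row.tissue, "model_type": row.model_type,
                         "gene": row.gene, "n_runs": n_runs,
                         "n_significant_runs": n_sig, "hit": hit})
        if hit:
            tfs = []
            if fits is not None and key in fits:
                tfs = fits[key].selected_tfs
            hit_rows.append({"tissue": row.tissue, "model_type": row.model_type,
                             "gene": row.gene, "r2": row.r2,
                             "n_significant_runs": n_sig,
                             "tfs": ";".join(tfs)})
    rob = pd.DataFrame(rob_rows, columns=["tissue", "model_type", "gene",
                                          "n_runs", "n_significant_runs", "hit"])
    hits = pd.DataFrame(hit_rows, columns=["tissue", "model_type", "gene",
                                           "r2", "n_significant_runs", "tfs"])
    return hits, rob
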