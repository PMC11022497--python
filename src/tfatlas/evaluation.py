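"""Scoring pipeline output against a simulated cohort's truth table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import PipelineResult
from .simulate import SimulatedCohort

__all__ = ["planted_recall", "empirical_fdr", "hit_fraction_by_stratum"]

_MECH_TO_MODEL = {"expression": "expression", "binding": "binding"}


def _truth_keys(cohort: SimulatedCohort, mechanism: str | None = None):
    t = cohort.truth
    if mechanism is not None:
        t = t[t["mechanism"] == mechanism]
    return {(r.tissue, _MECH_TO_MODEL[r.mechanism], r.gene)
            for r in t.itertuples()}


def _hit_keys(result: PipelineResult, model_type: str | None = None):
    h = result.hits
    if model_type is not None:
        h = h[h["model_type"] == model_type]
    return set(zip(h["tissue"], h["model_type"], h["gene"]))


def planted_recall(cohort: SimulatedCohort, result: PipelineResult,
                   mechanism: str = "expression",
                   include_tf_targets: bool = False) -> float:
    """Fraction of planted (tissue, gene) effects of one mechanism that
    appear in the final hit table under the matching model type."""
    planted = _truth_keys(cohort, mechanism)
    if not include_tf_targets:
        planted = {k for k in planted if not k[2].startswith("TF")}
    if not planted:
        raise ValueError(f"cohort has no planted {mechanism!r} effects")
    hits = _hit_keys(result, _MECH_TO_MODEL[mechanism])
    return len(planted & hits) / len(planted)


def empirical_fdr(cohort: SimulatedCohort, result: PipelineResult) -> float:
    """Fraction of hit-table rows (both model types) that do not match any
    planted effect of the corresponding mechanism; 0 when there are no
    hits."""
    planted = _truth_keys(cohort)
    hits = _hit_keys(result)
    if not hits:
        return 0.0
    return len(hits - planted) / len(hits)


def hit_fraction_by_stratum(result: PipelineResult) -> pd.DataFrame:
    """Per (tissue, model_type): tested genes, hit genes, hit fraction and
    the 3-sigma binomial band around a nominal 0.05 rate."""
    rows = []
    for (t, m), grp in result.robustness.groupby(["tissue", "model_type"]):
        n = len(grp)
        k = int(grp["hit"].sum())
        se = np.sqrt(0.05 * 0.95 / n) if n else 0.0
        rows.append({"tissue": t, "model_type": m, "n_tested": n,
                     "n_hits": k, "hit_fraction": k / n if n else 0.0,
                     "bound_3se": 0.05 + 3 * se})
    return pd.DataFrame(rows)
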