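"""Gene-set enrichment and the conservation comparison.

Enrichment of hit genes in a target set (pharmacogenes, pathway members)
is an upper-tail hypergeometric test relative to the tested-gene
universe.  The conservation comparison asks whether hit genes carry
higher protein conservation scores than tested-but-not-hit genes, by a
two-sided Wilcoxon rank-sum test (exact null for small tie-free samples,
normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .significance import bh_adjust

__all__ = ["hypergeometric_enrichment", "enrich_gene_sets",
           "mean_protein_conservation", "conservation_comparison"]

logger = logging.getLogger(__name__)


def hypergeometric_enrichment(query: set[str], target: set[str],
                              universe: set[str]):
    """Upper-tail hypergeometric p for the overlap of ``query`` and
    ``target`` within ``universe``; returns ``(p, overlap, fold)`` where
    fold is observed / expected overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not (query <= universe and target <= universe):
        raise ValueError("query and target must be subsets of the universe")
    N, K, n = len(universe), len(target), len(query)
    k = len(query & target)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    fold = k / expected if expected > 0 else np.nan
    return p, k, fold


def enrich_gene_sets(query: set[str], gene_sets: dict[str, set[str]],
                     universe: set[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against every named set,
    BH-adjusted across sets.  Set members outside the universe are
    dropped (with a logged count), matching how curated collections are
    intersected with the tested genes."""
    rows = []
    q = query & universe
    if len(q) < len(query):
        logger.info("%d query genes outside universe dropped", len(query) - len(q))
    for name, members in sorted(gene_sets.items()):
        t = members & universe
        if len(t) < len(members):
            logger.debug("set %s: %d members outside universe dropped",
                         name, len(members) - len(t))
        if not t:
            continue
        p, k, fold = hypergeometric_enrichment(q, t, universe)
        rows.append({"set": name, "set_size": len(t), "overlap": k,
                     "fold": fold, "p": p})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "fold", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = []
    return out


def mean_protein_conservation(residue_scores: dict[str, np.ndarray] | pd.DataFrame
                              ) -> pd.Series:
    """Average per-residue conservation scores into one score per protein.

    Accepts a mapping protein -> residue-score vector, or a long table
    with columns (gene, score).  Proteins with no residues are excluded
    with a log entry.
    """
    if isinstance(residue_scores, pd.DataFrame):
        grouped = {g: grp["score"].to_numpy()
                   for g, grp in residue_scores.groupby("gene")}
    else:
        grouped = residue_scores
    out = {}
    for g, scores in grouped.items():
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            logger.info("protein %s has no residue scores; excluded", g)
            continue
        out[g] = float(scores.mean())
    return pd.Series(out, dtype=float).sort_index()


def conservation_comparison(hit_genes: set[str], background_genes: set[str],
                            conservation: pd.Series):
    """Two-sided rank-sum comparison of conservation between hit genes and
    the background (tested-but-not-hit) genes.

    Returns ``(statistic, p, direction)`` where direction names the group
    with the larger median.  Genes without a score are dropped with a
    logged count; the groups must be disjoint and non-empty after the
    drop.
    """
    if hit_genes & background_genes:
        raise ValueError("hit and background gene sets must be disjoint")
    x = conservation.reindex(sorted(hit_genes)).dropna()
    y = conservation.reindex(sorted(background_genes)).dropna()
    n_drop = (len(hit_genes) - len(x)) + (len(background_genes) - len(y))
    if n_drop:
        logger.info("conservation_comparison: %d genes without scores dropped",
                    n_drop)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty after dropping "
                         "unscored genes")
    pooled = np.concatenate([x.to_numpy(), y.to_numpy()])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = ("hit_genes" if np.median(x) > np.median(y)
                 else "background_genes" if np.median(y) > np.median(x)
                 else "tied")
    return float(res.statistic), float(res.pvalue), direction
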