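"""Co-regulation networks and multi-level regulation cascades.

Two hit genes are **co-regulated** when each is a hit in at least three
tissues, their hit-tissue sets overlap with Jaccard >= 0.5, and the
overlap is larger than expected by chance (upper-tail hypergeometric,
BH-FDR < 0.05 across all candidate pairs).  **Regulation cascades** chain
the fitted models of one tissue: every TF with nonzero weight in a hit
gene's model contributes a directed TF -> gene edge, and a node's cascade
depth is the number of trans-regulation levels on the longest chain
ending at it (cycles are reported and excluded from depth computation via
the acyclic condensation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .significance import bh_adjust

__all__ = ["CoRegulationNetwork", "RegulationCascade", "find_coregulated_pairs",
           "extract_modules", "build_regulation_cascades"]

logger = logging.getLogger(__name__)


@dataclass
class CoRegulationNetwork:
    model_type: str
    edges: pd.DataFrame          # gene_a, gene_b, n_shared, jaccard, p, q
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)


def find_coregulated_pairs(hits: pd.DataFrame, n_tissues_total: int,
                           model_type: str, min_tissues: int = 3,
                           jaccard_cutoff: float = 0.5,
                           fdr_level: float = 0.05) -> CoRegulationNetwork:
    """Pairs of hit genes sharing tissues beyond chance.

    The hypergeometric null draws gene B's tissues from the
    ``n_tissues_total`` analyzed tissues and asks for at least the
    observed overlap with gene A's tissues.  BH runs over every pair of
    candidate genes (those hit in >= ``min_tissues`` tissues); an edge
    needs all three filters.
    """
    sub = hits[hits["model_type"] == model_type]
    tissues_of = {g: set(t) for g, t in sub.groupby("gene")["tissue"]}
    max_count = max((len(t) for t in tissues_of.values()), default=0)
    if n_tissues_total < max_count:
        raise ValueError(f"n_tissues_total={n_tissues_total} below observed "
                         f"max tissue count {max_count}")
    candidates = sorted(g for g, t in tissues_of.items() if len(t) >= min_tissues)
    rows = []
    for a, b in combinations(candidates, 2):
        ta, tb = tissues_of[a], tissues_of[b]
        inter = len(ta & tb)
        union = len(ta | tb)
        jac = inter / union if union else 0.0
        p = float(stats.hypergeom.sf(inter - 1, n_tissues_total, len(ta), len(tb)))
        rows.append({"gene_a": a, "gene_b": b, "n_shared": inter,
                     "jaccard": jac, "p": p})
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_shared",
                                     "jaccard", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"])
        keep = (df["jaccard"] >= jaccard_cutoff) & (df["q"] < fdr_level)
        edges = df[keep].reset_index(drop=True)
    else:
        df["q"] = []
        edges = df
    G = nx.Graph()
    G.add_nodes_from(candidates)
    for row in edges.itertuples():
        G.add_edge(row.gene_a, row.gene_b, jaccard=row.jaccard,
                   n_shared=row.n_shared, q=row.q)
    return CoRegulationNetwork(model_type=model_type, edges=edges, graph=G)


def extract_modules(net: CoRegulationNetwork) -> pd.DataFrame:
    """Connected components of the co-regulation network with node counts
    and each component's fraction of all edges."""
    G = net.graph
    total_edges = G.number_of_edges()
    rows = []
    comps = [c for c in nx.connected_components(G) if len(c) > 1]
    for i, comp in enumerate(sorted(comps, key=len, reverse=True)):
        sg = G.subgraph(comp)
        rows.append({"module": i, "n_genes": len(comp),
                     "n_edges": sg.number_of_edges(),
                     "edge_fraction": (sg.number_of_edges() / total_edges
                                       if total_edges else 0.0),
                     "genes": ";".join(sorted(comp))})
    return pd.DataFrame(rows, columns=["module", "n_genes", "n_edges",
                                       "edge_fraction", "genes"])


@dataclass
class RegulationCascade:
    tissue: str
    model_type: str
    graph: nx.DiGraph                     # TF -> modeled gene, weighted
    depth: pd.Series                      # node -> trans-regulation levels
    max_depth: int
    cycles: list[list[str]] = field(default_factory=list)


def build_regulation_cascades(fits: dict, hits: pd.DataFrame, tissue: str,
                              model_type: str,
                              max_depth: int = 4) -> RegulationCascade:
    """Chained trans models of one tissue.

    ``fits`` maps ``(tissue, model_type, gene) -> TFModelFit`` (the
    pipeline's fit store).  An edge TF -> gene exists for every TF with a
    nonzero weight in a hit gene's model; for the binding model a TF
    contributes an edge when any of its deleterious SNPs has nonzero
    weight.  Depth counts levels of trans-regulation on the longest
    chain ending at a node: an unmodeled root TF has depth 0, a hit gene
    whose TFs are all unmodeled has depth 1, and a chain C -> A -> B
    gives B depth 2.  Depths are truncated at ``max_depth``; mutual
    regulation (cycles) is reported separately and collapsed for the
    depth computation.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    hit_genes = set(hits[(hits["tissue"] == tissue)
                         & (hits["model_type"] == model_type)]["gene"])
    G = nx.DiGraph()
    for key, fit in fits.items():
        if len(key) == 3:
            t, m, g = key
        else:
            m, g = key
            t = tissue
        if t != tissue or m != model_type or g not in hit_genes:
            continue
        for tf in fit.selected_tfs:
            w = sum(abs(v) for f, v in fit.weights.items()
                    if fit.feature_owner.get(f, f) == tf and v != 0.0)
            G.add_edge(tf, g, weight=w)
    cycles = [list(c) for c in nx.simple_cycles(G)]
    if cycles:
        logger.info("tissue %s/%s: %d regulatory cycles reported", tissue,
                    model_type, len(cycles))
    cond = nx.condensation(G)
    order = list(nx.topological_sort(cond))
    # depth counts levels of trans-regulation (edges on the longest chain):
    # an unmodeled root TF has depth 0, a flat hit gene depth 1
    comp_depth: dict[int, int] = {}
    for c in order:
        preds = list(cond.predecessors(c))
        comp_depth[c] = max((comp_depth[p] + 1 for p in preds), default=0)
    depth = {}
    for node in G.nodes:
        c = cond.graph["mapping"][node]
        depth[node] = min(comp_depth[c], max_depth)
    depth_s = pd.Series(depth, dtype=int)
    return RegulationCascade(tissue=tissue, model_type=model_type, graph=G,
                             depth=depth_s,
                             max_depth=int(depth_s.max()) if len(depth_s) else 0,
                             cycles=cycles)
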