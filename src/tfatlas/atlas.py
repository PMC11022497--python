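"""Tissue-level analytics over the hit-gene table.

Tissue similarity is the Jaccard index of the tissues' hit-gene sets per
model type.  Tissues are clustered by average-linkage hierarchical
clustering on 1 - Jaccard distances; the flat-cluster cutoff is the
median of the depth-2 inconsistency coefficients of the dendrogram
links.  Cluster-specific genes are hit genes over-represented in one
cluster by an upper-tail hypergeometric test (BH-adjusted), with
singleton clusters excluded from the universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .significance import bh_adjust

__all__ = ["TissueClustering", "tissue_jaccard_similarity",
           "symmetrize_external_similarity", "compare_similarity_matrices",
           "common_gene_threshold", "find_common_genes", "cluster_tissues",
           "find_cluster_specific_genes", "hit_sets_by_tissue"]

logger = logging.getLogger(__name__)


def hit_sets_by_tissue(hits: pd.DataFrame, model_type: str) -> dict[str, set[str]]:
    if model_type not in ("expression", "binding"):
        raise ValueError(f"unknown model_type {model_type!r}")
    sub = hits[hits["model_type"] == model_type]
    return {t: set(g) for t, g in sub.groupby("tissue")["gene"]}


def tissue_jaccard_similarity(hits: pd.DataFrame, model_type: str,
                              tissues: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Jaccard similarity of hit-gene sets; two empty sets score
    0 (with a warning), and the diagonal is fixed at 1."""
    sets = hit_sets_by_tissue(hits, model_type)
    if tissues is None:
        tissues = sorted(sets)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues with hit genes")
    n = len(tissues)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = sets.get(tissues[i], set())
            b = sets.get(tissues[j], set())
            union = len(a | b)
            if union == 0:
                warnings.warn(f"tissues {tissues[i]}/{tissues[j]}: both hit "
                              "sets empty, Jaccard defined as 0")
                val = 0.0
            else:
                val = len(a & b) / union
            M[i, j] = M[j, i] = val
    return pd.DataFrame(M, index=tissues, columns=tissues)


def symmetrize_external_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average an asymmetric similarity with its transpose."""
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("similarity matrix must be square")
    if list(matrix.index) != list(matrix.columns):
        matrix = matrix.loc[matrix.index, matrix.index]
    return (matrix + matrix.T) / 2.0


def compare_similarity_matrices(A: pd.DataFrame, B: pd.DataFrame):
    """Spearman correlation over the strictly-lower-triangle entries of
    two tissue-similarity matrices (intersecting tissue sets first)."""
    shared = [t for t in A.index if t in set(B.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared tissues")
    if len(shared) < len(A) or len(shared) < len(B):
        logger.warning("similarity comparison restricted to %d shared tissues",
                       len(shared))
    a = A.loc[shared, shared].to_numpy()
    b = B.loc[shared, shared].to_numpy()
    il = np.tril_indices(len(shared), k=-1)
    rho, p = stats.spearmanr(a[il], b[il])
    return float(rho), float(p)


def common_gene_threshold(max_tissue_count: int) -> int:
    """Tissue-count threshold for "common" hit genes: half the maximum
    observed tissue count, rounded up."""
    if max_tissue_count < 1:
        raise ValueError("max_tissue_count must be >= 1")
    return -(-max_tissue_count // 2)  # ceil division


def find_common_genes(hits: pd.DataFrame, model_type: str) -> pd.DataFrame:
    """Genes whose hit-tissue count reaches the common-gene threshold for
    the model's maximum observed count, sorted by count descending."""
    sub = hits[hits["model_type"] == model_type]
    if sub.empty:
        raise ValueError(f"no hit genes for model_type {model_type!r}")
    counts = sub.groupby("gene")["tissue"].nunique().sort_values(ascending=False)
    thr = common_gene_threshold(int(counts.max()))
    out = counts[counts >= thr].reset_index()
    out.columns = ["gene", "n_tissues"]
    out["threshold"] = thr
    return out


@dataclass
class TissueClustering:
    linkage: np.ndarray                  # scipy linkage matrix
    tissues: list[str]
    assignment: pd.Series                # tissue -> cluster id
    cophenetic: float
    cutoff: float                        # median depth-2 inconsistency
    inconsistency: np.ndarray            # per-link inconsistency coefficients
    singletons: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for t, c in self.assignment.items():
            out.setdefault(int(c), []).append(t)
        return out

    def non_singleton_clusters(self) -> dict[int, list[str]]:
        return {c: ts for c, ts in self.clusters.items() if len(ts) > 1}


def cluster_tissues(sim: pd.DataFrame, depth: int = 2) -> TissueClustering:
    """Average-linkage clustering of tissues on 1 - Jaccard distances.

    The dendrogram is cut with scipy's inconsistency criterion at the
    median of the per-link depth-``depth`` inconsistency coefficients;
    tissues left alone by the cut are flagged singleton.  The cophenetic
    correlation against the input distances is reported as the linkage
    quality measure.
    """
    if sim.shape[0] < 3:
        raise ValueError("need at least 3 tissues to cluster")
    D = 1.0 - sim.to_numpy()
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(Z, condensed)
    R = hierarchy.inconsistent(Z, d=depth)
    incons = R[:, 3]
    cutoff = float(np.median(incons))
    flat = hierarchy.fcluster(Z, t=cutoff, criterion="inconsistent", depth=depth)
    tissues = list(sim.index)
    assignment = pd.Series(flat, index=tissues)
    sizes = assignment.value_counts()
    singletons = [t for t in tissues if sizes[assignment[t]] == 1]
    return TissueClustering(linkage=Z, tissues=tissues, assignment=assignment,
                            cophenetic=float(coph), cutoff=cutoff,
                            inconsistency=incons, singletons=singletons)


def find_cluster_specific_genes(hits: pd.DataFrame, clustering: TissueClustering,
                                model_type: str,
                                fdr_level: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene's hit tissues
    within each non-singleton cluster.

    Population: all tissue slots in non-singleton clusters (N); successes:
    the cluster's tissues (K); draws: the clustered tissues where the gene
    is a hit (n); observed: the gene's hits inside the cluster (k).  BH is
    applied across all (gene, cluster) pairs.
    """
    clusters = clustering.non_singleton_clusters()
    if len(clusters) < 2:
        raise ValueError("need at least 2 non-singleton clusters")
    clustered_tissues = {t for ts in clusters.values() for t in ts}
    N = len(clustered_tissues)
    sets = hit_sets_by_tissue(hits, model_type)
    gene_tissues: dict[str, set[str]] = {}
    for t, gs in sets.items():
        if t in clustered_tissues:
            for g in gs:
                gene_tissues.setdefault(g, set()).add(t)
    rows = []
    for g, ts in sorted(gene_tissues.items()):
        n_draws = len(ts)
        if n_draws == 0:
            logger.debug("gene %s has no clustered-tissue hits; excluded", g)
            continue
        for c, members in sorted(clusters.items()):
            K = len(members)
            k = len(ts & set(members))
            if k == 0:
                continue
            p = float(stats.hypergeom.sf(k - 1, N, K, n_draws))
            rows.append({"cluster": c, "gene": g, "in_cluster": k,
                         "out_of_cluster": n_draws - k, "p": p})
    out = pd.DataFrame(rows, columns=["cluster", "gene", "in_cluster",
                                      "out_of_cluster", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out["cluster_specific"] = out["q"] < fdr_level
    else:
        out["q"] = []
        out["cluster_specific"] = []
    return out
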