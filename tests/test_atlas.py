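"""Tissue similarity, clustering, common and cluster-specific genes."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfatlas.atlas import (TissueClustering, cluster_tissues,
                           common_gene_threshold, compare_similarity_matrices,
                           find_cluster_specific_genes, find_common_genes,
                           symmetrize_external_similarity,
                           tissue_jaccard_similarity)
from conftest import make_hit_table


def _hits_from_sets(sets, model="expression"):
    return make_hit_table([(t, model, g) for t, gs in sets.items() for g in gs])


class TestJaccard:
    def test_worked_examples(self):
        hits = _hits_from_sets({"t1": {"a", "b", "c"}, "t2": {"b", "c", "d"},
                                "t3": {"a", "b", "c"}, "t4": {"x"}})
        M = tissue_jaccard_similarity(hits, "expression")
        assert M.loc["t1", "t2"] == pytest.approx(0.5)   # {b,c} / {a,b,c,d}
        assert M.loc["t1", "t3"] == 1.0                  # identical sets
        assert M.loc["t1", "t4"] == 0.0                  # disjoint sets
        assert np.allclose(np.diag(M), 1.0)

    def test_matches_bruteforce_on_random_tables(self, rng):
        tissues = [f"t{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(25)]
        sets = {t: {g for g in genes if rng.random() < 0.3} for t in tissues}
        for t in sets:
            if not sets[t]:
                sets[t] = {genes[0]}
        M = tissue_jaccard_similarity(_hits_from_sets(sets), "expression",
                                      tissues=tissues)
        for a, b in combinations(tissues, 2):
            expected = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
            assert M.loc[a, b] == pytest.approx(expected)
            assert M.loc[b, a] == M.loc[a, b]

    def test_unknown_model_type_rejected(self):
        with pytest.raises(ValueError):
            tissue_jaccard_similarity(make_hit_table([]), "nonsense")


class TestExternalSimilarity:
    def test_symmetrization(self):
        M = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        S = symmetrize_external_similarity(M)
        assert S.loc["a", "b"] == S.loc["b", "a"] == pytest.approx(0.3)
        # a symmetric matrix is a fixed point
        assert np.allclose(symmetrize_external_similarity(S), S)

    def test_random_matrix_result_symmetric(self, rng):
        M = pd.DataFrame(rng.random((5, 5)), index=list("abcde"),
                         columns=list("abcde"))
        S = symmetrize_external_similarity(M)
        assert np.max(np.abs(S.to_numpy() - S.to_numpy().T)) < 1e-15

    def test_spearman_identity_and_antitone(self, rng):
        M = pd.DataFrame(rng.random((6, 6)), index=list("abcdef"),
                         columns=list("abcdef"))
        M = symmetrize_external_similarity(M)
        rho, _ = compare_similarity_matrices(M, M)
        assert rho == pytest.approx(1.0)
        rho, _ = compare_similarity_matrices(M, 1.0 - M)
        assert rho == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self, rng):
        A = pd.DataFrame(rng.random((6, 6)), index=list("abcdef"),
                         columns=list("abcdef"))
        B = pd.DataFrame(rng.random((6, 6)), index=list("abcdef"),
                         columns=list("abcdef"))
        A, B = symmetrize_external_similarity(A), symmetrize_external_similarity(B)
        rho, _ = compare_similarity_matrices(A, B)
        il = np.tril_indices(6, k=-1)
        a, b = A.to_numpy()[il], B.to_numpy()[il]
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        manual = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_too_few_shared_tissues_rejected(self):
        M = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            compare_similarity_matrices(M, M)


class TestCommonGenes:
    @pytest.mark.parametrize("max_count,expected", [(41, 21), (16, 8), (1, 1),
                                                    (2, 1), (3, 2), (10, 5)])
    def test_half_rounded_up(self, max_count, expected):
        assert common_gene_threshold(max_count) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            common_gene_threshold(0)

    def test_counting_oracle(self):
        sets = {f"t{i}": set() for i in range(10)}
        counts = {"gA": 10, "gB": 6, "gC": 5, "gD": 2}
        for g, c in counts.items():
            for i in range(c):
                sets[f"t{i}"].add(g)
        out = find_common_genes(_hits_from_sets(sets), "expression")
        assert list(out["gene"]) == ["gA", "gB", "gC"]   # threshold ceil(10/2)=5
        assert out["threshold"].iloc[0] == 5

    def test_all_singleton_edge_returns_everything(self):
        sets = {"t1": {"a"}, "t2": {"b"}}
        out = find_common_genes(_hits_from_sets(sets), "expression")
        assert set(out["gene"]) == {"a", "b"}            # max=1 -> threshold 1


class TestClustering:
    def test_identical_hit_sets_merge_at_zero_height(self):
        sets = {"t1": {"a", "b"}, "t2": {"a", "b"}, "t3": {"x", "y"}}
        M = tissue_jaccard_similarity(_hits_from_sets(sets), "expression")
        cl = cluster_tissues(M)
        first = cl.linkage[0]
        assert first[2] == 0.0
        merged = {cl.tissues[int(first[0])], cl.tissues[int(first[1])]}
        assert merged == {"t1", "t2"}

    def test_ultrametric_distances_give_cophenetic_one(self):
        # two tight pairs far apart: distances are exactly ultrametric
        D = np.array([[0.0, 0.1, 0.9, 0.9],
                      [0.1, 0.0, 0.9, 0.9],
                      [0.9, 0.9, 0.0, 0.1],
                      [0.9, 0.9, 0.1, 0.0]])
        sim = pd.DataFrame(1.0 - D, index=list("abcd"), columns=list("abcd"))
        cl = cluster_tissues(sim)
        assert cl.cophenetic == pytest.approx(1.0)

    def test_depth2_inconsistency_matches_direct_formula(self, rng):
        sim = pd.DataFrame(rng.random((6, 6)), index=list("abcdef"),
                           columns=list("abcdef"))
        sim = symmetrize_external_similarity(sim)
        np.fill_diagonal(sim.values, 1.0)
        cl = cluster_tissues(sim)
        Z = cl.linkage
        n = 6

        def heights(i, depth):
            hs = [Z[i, 2]]
            if depth > 1:
                for c in (int(Z[i, 0]), int(Z[i, 1])):
                    if c >= n:
                        hs += heights(c - n, depth - 1)
            return hs

        for i in range(len(Z)):
            hs = np.array(heights(i, 2))
            s = hs.std(ddof=1) if len(hs) > 1 else 0.0
            expected = 0.0 if s == 0 else (Z[i, 2] - hs.mean()) / s
            assert cl.inconsistency[i] == pytest.approx(expected, abs=1e-12)
        assert cl.cutoff == pytest.approx(np.median(cl.inconsistency))

    def test_partition_invariant_under_tissue_relabeling(self, rng):
        tissues = [f"t{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(30)]
        sets = {t: {g for g in genes if rng.random() < 0.3} or {genes[0]}
                for t in tissues}
        hits = _hits_from_sets(sets)
        M = tissue_jaccard_similarity(hits, "expression", tissues=tissues)
        cl1 = cluster_tissues(M)
        perm = list(reversed(tissues))
        cl2 = cluster_tissues(M.loc[perm, perm])

        def as_partition(cl):
            return {frozenset(ts) for ts in cl.clusters.values()}

        assert as_partition(cl1) == as_partition(cl2)

    def test_too_few_tissues_rejected(self):
        M = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_tissues(M)


def _manual_clustering(clusters, singletons=()):
    tissues = [t for ts in clusters.values() for t in ts] + list(singletons)
    assignment = {}
    for c, ts in clusters.items():
        for t in ts:
            assignment[t] = c
    for i, t in enumerate(singletons):
        assignment[t] = 1000 + i
    return TissueClustering(
        linkage=np.zeros((0, 4)), tissues=tissues,
        assignment=pd.Series(assignment), cophenetic=1.0, cutoff=0.0,
        inconsistency=np.zeros(0), singletons=list(singletons))


class TestClusterSpecific:
    def test_exact_combinatorial_p_for_perfect_cluster_gene(self):
        # 12 clustered tissues, gene hit in exactly the 3 tissues of one cluster
        clusters = {1: ["t1", "t2", "t3"], 2: [f"t{i}" for i in range(4, 13)]}
        cl = _manual_clustering(clusters)
        sets = {t: set() for t in cl.tissues}
        for t in clusters[1]:
            sets[t].add("gA")
        for t in cl.tissues:
            sets[t].add("gBg")  # saturated gene, hit everywhere
        sets["t4"].add("gC")    # single-draw gene
        out = find_cluster_specific_genes(_hits_from_sets(sets), cl,
                                          "expression")
        pa = out[(out.gene == "gA") & (out.cluster == 1)]["p"].iloc[0]
        assert pa == pytest.approx(1 / comb(12, 3))
        pb = out[(out.gene == "gBg") & (out.cluster == 1)]["p"].iloc[0]
        assert pb == pytest.approx(1.0)
        pc = out[(out.gene == "gC") & (out.cluster == 2)]["p"].iloc[0]
        assert pc == pytest.approx(9 / 12)               # K/N for one draw

    def test_matches_exhaustive_enumeration_small_universe(self, rng):
        clusters = {1: ["t1", "t2", "t3"], 2: ["t4", "t5"],
                    3: ["t6", "t7", "t8", "t9"]}
        cl = _manual_clustering(clusters)
        tissues = cl.tissues
        N = len(tissues)
        sets = {t: set() for t in tissues}
        for g in range(8):
            for t in tissues:
                if rng.random() < 0.4:
                    sets[t].add(f"g{g}")
        out = find_cluster_specific_genes(_hits_from_sets(sets), cl,
                                          "expression")
        for row in out.itertuples():
            members = set(clusters[row.cluster])
            gene_ts = {t for t in tissues if row.gene in sets[t]}
            n_draw = len(gene_ts)
            # enumeration over all C(N, n_draw) placements
            total = comb(N, n_draw)
            atleast = sum(comb(len(members), k) * comb(N - len(members), n_draw - k)
                          for k in range(row.in_cluster, min(len(members), n_draw) + 1))
            assert row.p == pytest.approx(atleast / total, rel=1e-10)

    def test_requires_two_nonsingleton_clusters(self):
        cl = _manual_clustering({1: ["t1", "t2"]}, singletons=["t3"])
        with pytest.raises(ValueError):
            find_cluster_specific_genes(make_hit_table([]), cl, "expression")
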