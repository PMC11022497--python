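"""Co-regulation pairs, modules and regulation cascades."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfatlas import RunConfig, SimulationConfig, simulate_cohort, run_pipeline
from tfatlas.models import TFModelFit
from tfatlas.networks import (build_regulation_cascades, extract_modules,
                              find_coregulated_pairs)
from conftest import make_hit_table


def _hits(gene_tissues, model="expression"):
    return make_hit_table([(t, model, g) for g, ts in gene_tissues.items()
                           for t in ts])


class TestCoregulation:
    def test_exact_p_for_identical_three_tissue_sets(self):
        hits = _hits({"gA": ["t1", "t2", "t3"], "gB": ["t1", "t2", "t3"]})
        net = find_coregulated_pairs(hits, n_tissues_total=49,
                                     model_type="expression")
        assert len(net.edges) == 1
        row = net.edges.iloc[0]
        assert row["jaccard"] == 1.0
        assert row["p"] == pytest.approx(1 / comb(49, 3))

    def test_disjoint_sets_have_no_edge(self):
        hits = _hits({"gA": ["t1", "t2", "t3"], "gB": ["t4", "t5", "t6"]})
        net = find_coregulated_pairs(hits, 49, "expression")
        assert net.edges.empty

    def test_genes_below_min_tissues_excluded(self):
        hits = _hits({"gA": ["t1", "t2"], "gB": ["t1", "t2"],
                      "gC": ["t1", "t2", "t3"], "gD": ["t1", "t2", "t3"]})
        net = find_coregulated_pairs(hits, 49, "expression")
        assert "gA" not in net.graph.nodes
        assert set(net.edges[["gene_a", "gene_b"]].iloc[0]) == {"gC", "gD"}

    def test_total_tissue_count_must_cover_observations(self):
        hits = _hits({"gA": [f"t{i}" for i in range(10)]})
        with pytest.raises(ValueError):
            find_coregulated_pairs(hits, 5, "expression")

    def test_reported_edges_recompute_from_hit_table(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        gene_tissues = {}
        for g in range(15):
            k = rng.integers(3, 8)
            gene_tissues[f"g{g}"] = list(rng.choice(tissues, size=k,
                                                    replace=False))
        hits = _hits(gene_tissues)
        net = find_coregulated_pairs(hits, 12, "expression")
        for row in net.edges.itertuples():
            ta = set(gene_tissues[row.gene_a])
            tb = set(gene_tissues[row.gene_b])
            assert row.n_shared == len(ta & tb)
            assert row.jaccard == pytest.approx(len(ta & tb) / len(ta | tb))
            assert row.jaccard >= 0.5 and row.q < 0.05
            assert row.p == pytest.approx(
                float(stats.hypergeom.sf(row.n_shared - 1, 12, len(ta), len(tb))))


class TestModules:
    def _net(self, edges):
        from tfatlas.networks import CoRegulationNetwork
        G = nx.Graph(edges)
        return CoRegulationNetwork("expression",
                                   pd.DataFrame(edges, columns=["gene_a", "gene_b"]),
                                   G)

    def test_empty_network(self):
        assert extract_modules(self._net([])).empty

    def test_two_disjoint_triangles_split_edges_evenly(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("x", "y"), ("y", "z"), ("x", "z")]
        mods = extract_modules(self._net(edges))
        assert len(mods) == 2
        assert np.allclose(mods["edge_fraction"], [0.5, 0.5])

    def test_single_edge_single_module(self):
        mods = extract_modules(self._net([("a", "b")]))
        assert len(mods) == 1 and mods["n_genes"].iloc[0] == 2


def _fit(gene, tfs, model="expression", tissue="t1"):
    return TFModelFit(gene=gene, tissue=tissue, model_type=model, status="fit",
                      weights={tf: w for tf, w in tfs.items()})


class TestCascades:
    def test_two_level_chain_depths(self):
        """C regulates A, A regulates B: depth(C)=0, depth(A)=1, depth(B)=2."""
        fits = {("t1", "expression", "B"): _fit("B", {"A": 0.5}),
                ("t1", "expression", "A"): _fit("A", {"C": 0.7})}
        hits = _hits({"B": ["t1"], "A": ["t1"]})
        casc = build_regulation_cascades(fits, hits, "t1", "expression")
        assert set(casc.graph.edges) == {("A", "B"), ("C", "A")}
        assert casc.depth["C"] == 0 and casc.depth["A"] == 1 and casc.depth["B"] == 2
        assert casc.max_depth == 2 and not casc.cycles

    def test_flat_when_no_tf_is_modeled(self):
        fits = {("t1", "expression", "B"): _fit("B", {"A": 0.5})}
        hits = _hits({"B": ["t1"]})
        casc = build_regulation_cascades(fits, hits, "t1", "expression")
        assert casc.depth["B"] == 1 and casc.depth["A"] == 0
        assert casc.max_depth == 1

    def test_zero_weight_features_contribute_no_edge(self):
        fits = {("t1", "expression", "B"): _fit("B", {"A": 0.0, "C": 0.3})}
        hits = _hits({"B": ["t1"]})
        casc = build_regulation_cascades(fits, hits, "t1", "expression")
        assert ("A", "B") not in casc.graph.edges
        assert ("C", "B") in casc.graph.edges

    def test_cycles_reported_and_depth_bounded(self):
        fits = {("t1", "expression", "A"): _fit("A", {"B": 0.5}),
                ("t1", "expression", "B"): _fit("B", {"A": 0.5})}
        hits = _hits({"A": ["t1"], "B": ["t1"]})
        casc = build_regulation_cascades(fits, hits, "t1", "expression")
        assert len(casc.cycles) == 1
        with pytest.raises(ValueError):
            build_regulation_cascades(fits, hits, "t1", "expression",
                                      max_depth=0)

    def test_binding_model_snp_features_map_to_owner_tf(self):
        fit = TFModelFit(gene="B", tissue="t1", model_type="binding",
                         status="fit", weights={"snp1": 0.4, "snp2": 0.0},
                         feature_owner={"snp1": "TFX", "snp2": "TFY"})
        hits = _hits({"B": ["t1"]}, model="binding")
        casc = build_regulation_cascades({("t1", "binding", "B"): fit}, hits,
                                         "t1", "binding")
        assert set(casc.graph.edges) == {("TFX", "B")}


def test_planted_tf_cascade_recovered_end_to_end():
    """With the TF->TF layer enabled, a strongly planted two-level chain
    (upstream TF -> regulated TF -> gene) should appear in the cascade of
    the discovering tissue for most planted genes."""
    sim = SimulationConfig(
        n_tissues=1, n_samples_per_tissue=250, n_genes=40, n_tfs=20,
        tf_per_gene_range=(2, 3), frac_trans_expression_genes=0.3,
        frac_trans_binding_genes=0.0, trans_effect_size=1.5,
        tf_tf_edges=True, frac_regulated_tfs=0.5, seed=31)
    cohort = simulate_cohort(sim)
    cfg = RunConfig(b_background=25, n_robustness_runs=4,
                    model_types=("expression",), seed=31)
    res = run_pipeline(cohort, cfg)
    casc = build_regulation_cascades(res.fits, res.hits, "tissue_1",
                                     "expression")
    truth = cohort.truth
    tf_rows = truth[truth["gene"].str.startswith("TF")]
    gene_rows = truth[~truth["gene"].str.startswith("TF")]
    regulated_tfs = set(tf_rows["gene"])
    chains = 0
    found = 0
    for row in gene_rows.itertuples():
        ctfs = set(row.causal_tfs.split(";")) & regulated_tfs
        if not ctfs:
            continue
        chains += 1
        if any(casc.depth.get(row.gene, 0) >= 2 for tf in ctfs
               if (tf, row.gene) in casc.graph.edges):
            found += 1
    assert chains >= 2
    assert found / chains >= 0.8
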