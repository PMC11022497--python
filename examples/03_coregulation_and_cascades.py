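"""Co-regulation networks and multi-level regulation cascades.

Simulates one tissue with a TF->TF regulatory layer enabled, runs the
discovery pipeline, then (i) extracts pairs of genes co-discovered
across tissues from a synthetic multi-tissue hit table and (ii) builds
the tissue's regulation cascade, where hit genes' TFs are themselves
modeled by further TFs.
"""

import numpy as np
import pandas as pd

from tfatlas import (RunConfig, SimulationConfig, simulate_cohort,
                     run_pipeline, find_coregulated_pairs, extract_modules,
                     build_regulation_cascades)

# --- co-regulation: genes sharing hit tissues beyond chance -----------------
rng = np.random.default_rng(3)
tissues = [f"t{i}" for i in range(20)]
rows = []
shared = list(rng.choice(tissues, size=6, replace=False))
for g in ("gA", "gB", "gC"):          # a planted co-regulated trio
    for t in shared:
        rows.append((t, "expression", g))
for g in range(25):                   # background genes with random tissues
    for t in rng.choice(tissues, size=rng.integers(3, 6), replace=False):
        rows.append((t, "expression", f"bg{g}"))
hits = pd.DataFrame(rows, columns=["tissue", "model_type", "gene"])

net = find_coregulated_pairs(hits, n_tissues_total=20, model_type="expression")
print(f"co-regulated pairs (>=3 tissues each, Jaccard >= 0.5, BH q < 0.05): "
      f"{len(net.edges)}")
print(net.edges.to_string(index=False))
mods = extract_modules(net)
print("\nconnected modules (the planted trio should form one):")
print(mods.to_string(index=False))

# --- cascades: chained trans models in one tissue ---------------------------
sim = SimulationConfig(
    n_tissues=1, n_samples_per_tissue=250, n_genes=30, n_tfs=16,
    tf_per_gene_range=(2, 3), frac_trans_expression_genes=0.3,
    frac_trans_binding_genes=0.0, trans_effect_size=1.5,
    tf_tf_edges=True, frac_regulated_tfs=0.4, seed=8)
cohort = simulate_cohort(sim)
cfg = RunConfig(b_background=25, n_robustness_runs=5,
                model_types=("expression",), seed=8)
result = run_pipeline(cohort, cfg)

casc = build_regulation_cascades(result.fits, result.hits, "tissue_1",
                                 "expression")
print(f"\ncascade graph: {casc.graph.number_of_nodes()} nodes, "
      f"{casc.graph.number_of_edges()} TF->gene edges, "
      f"max depth {casc.max_depth} levels of trans-regulation")
deep = casc.depth[casc.depth >= 2].sort_values(ascending=False)
print("genes at depth >= 2 (their TFs are themselves modeled hit genes):")
print(deep.to_string())
planted_tf_targets = set(
    cohort.truth[cohort.truth['gene'].str.startswith('TF')]['gene'])
print(f"\nplanted TF->TF layer targets: {sorted(planted_tf_targets)}")
print("(depth 2 means gene <- TF <- TF: two levels of regulation recovered)")
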