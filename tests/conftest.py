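"""Shared fixtures: small simulated cohorts and one reusable pipeline run.

Everything is generated programmatically with fixed seeds; the session-
scoped pipeline result keeps the expensive end-to-end run to a single
execution shared by the robustness / atlas / network tests.
"""

import numpy as np
import pandas as pd
import pytest

from tfatlas import RunConfig, SimulationConfig, simulate_cohort, run_pipeline


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_tissues=3, n_samples_per_tissue=100, n_genes=30, n_tfs=15,
        tf_per_gene_range=(2, 3), frac_trans_expression_genes=0.2,
        frac_trans_binding_genes=0.2, trans_effect_size=1.2,
        tissue_sharing=0.6, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(b_background=12, n_robustness_runs=4, seed=11)


@pytest.fixture(scope="session")
def small_pipeline_result(small_cohort, small_run_config):
    return run_pipeline(small_cohort, small_run_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_hit_table(entries):
    """Helper: build a hit table from (tissue, model_type, gene) tuples."""
    return pd.DataFrame(entries, columns=["tissue", "model_type", "gene"])
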