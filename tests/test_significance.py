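"""Empirical p-values, dual backgrounds and the BH / pass-both calls."""

import numpy as np
import pandas as pd
import pytest

from tfatlas import SimulationConfig, simulate_cohort
from tfatlas.lasso import make_folds
from tfatlas.models import build_tf_expression_features, fit_trans_model
from tfatlas.preprocess import normalize_expression
from tfatlas.significance import (bh_adjust, call_significant_genes,
                                  empirical_pvalue, run_random_tf_background,
                                  run_shuffled_background)


def bh_bruteforce(p):
    """Step-up definition computed literally, as an independent oracle."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestEmpiricalPvalue:
    def test_counting_rule_extremes_and_ties(self):
        bg = np.linspace(0.01, 0.5, 100)
        assert empirical_pvalue(0.9, bg) == 0.0
        assert empirical_pvalue(0.001, bg) == 1.0
        # observed equal to exactly 5 background values, above the rest
        bg = np.array([0.1] * 95 + [0.5] * 5)
        assert empirical_pvalue(0.5, bg) == 5 / 100

    def test_smoothed_variant(self):
        bg = np.linspace(0.01, 0.5, 100)
        assert empirical_pvalue(0.9, bg, smoothed=True) == pytest.approx(1 / 101)
        bg = np.array([0.1] * 95 + [0.5] * 5)
        assert empirical_pvalue(0.5, bg, smoothed=True) == pytest.approx(6 / 101)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.5, np.array([]))


class TestBH:
    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - bh_bruteforce(p))) < 1e-12

    def test_hand_computed_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestCalls:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["tissue", "model_type", "gene",
                                           "r2", "p_shuffled", "p_random_tf"])

    def test_and_rule_requires_both_backgrounds(self):
        df = self._results([
            ("t1", "expression", "g1", 0.4, 0.0, 0.30),
            ("t1", "expression", "g2", 0.4, 0.0, 0.00),
        ])
        out = call_significant_genes(df)
        assert not out.loc[out.gene == "g1", "significant"].iloc[0]
        assert out.loc[out.gene == "g2", "significant"].iloc[0]

    def test_single_gene_stratum_reduces_to_raw_p(self):
        df = self._results([("t1", "expression", "g1", 0.4, 0.01, 0.04)])
        out = call_significant_genes(df)
        assert out["significant"].iloc[0]

    def test_pass_both_never_less_stringent_than_single(self):
        rng = np.random.default_rng(3)
        df = self._results([
            ("t1", "expression", f"g{i}", 0.1, rng.uniform(0, 0.3),
             rng.uniform(0, 0.3)) for i in range(30)])
        out = call_significant_genes(df)
        single = (out["q_shuffled"] < 0.05)
        assert (out["significant"] <= single).all()

    def test_missing_background_rejected(self):
        df = self._results([("t1", "expression", "g1", 0.4, 0.01, np.nan)])
        with pytest.raises(ValueError, match="g1"):
            call_significant_genes(df)


@pytest.fixture(scope="module")
def null_tissue():
    cfg = SimulationConfig(n_tissues=1, n_samples_per_tissue=120, n_genes=60,
                           n_tfs=25, tf_per_gene_range=(2, 4),
                           frac_trans_expression_genes=0.0,
                           frac_trans_binding_genes=0.0, seed=21)
    cohort = simulate_cohort(cfg)
    t = cohort.tissues[0]
    norm = normalize_expression(cohort.expression[t], cohort.covariates[t])
    return cohort, norm


class TestBackgrounds:
    def test_shuffled_background_determinism_and_separation(self, null_tissue):
        cohort, norm = null_tissue
        tf_map = cohort.tf_map.groupby("target")["tf"].apply(list).to_dict()
        gene = cohort.genes[0]
        fs = build_tf_expression_features(gene, tf_map, norm)
        # noiseless linear target: observed r2 ~ 1, shuffled r2 low
        y = norm[fs.feature_ids[0]].to_numpy() * 1.0
        folds = make_folds(len(y), 5, np.random.default_rng(0))
        obs = fit_trans_model(fs, y, folds)
        bg1 = run_shuffled_background(fs, y, folds, B=30, seed=5)
        bg2 = run_shuffled_background(fs, y, folds, B=30, seed=5)
        assert np.array_equal(bg1.r2, bg2.r2)
        assert obs.r2 > 0.999
        assert (bg1.r2 < 0.5).all()
        assert empirical_pvalue(obs.r2, bg1) == 0.0

    def test_random_tf_background_null_super_uniform(self, null_tissue):
        """On a null cohort the fraction of empirical p-values below t is
        close to t for several thresholds."""
        cohort, norm = null_tissue
        tf_map = cohort.tf_map.groupby("target")["tf"].apply(list).to_dict()
        universe = sorted(set(cohort.tf_map["tf"]))
        ps = []
        B = 40
        for gene in cohort.genes:
            fs = build_tf_expression_features(gene, tf_map, norm)
            y = norm[gene].to_numpy()
            folds = make_folds(len(y), 5, np.random.default_rng(hash(gene) % 2**31))
            obs = fit_trans_model(fs, y, folds)
            if obs.status != "fit":
                continue
            bg = run_random_tf_background(gene, tf_map[gene], universe, y,
                                          folds, B, 17, "expression",
                                          norm_expr=norm)
            ps.append(empirical_pvalue(obs.r2, bg))
        ps = np.array(ps)
        for t in (0.05, 0.1, 0.2):
            se = np.sqrt(t * (1 - t) / len(ps))
            # counting-rule granularity adds at most ~1/B
            assert (ps <= t).mean() <= t + 1 / B + 3 * se

    def test_random_tf_background_excludes_true_tfs_and_errors(self, null_tissue):
        cohort, norm = null_tissue
        y = norm[cohort.genes[0]].to_numpy()
        folds = make_folds(len(y), 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="universe too small"):
            run_random_tf_background("g", ["a", "b"], ["a", "b", "c"], y,
                                     folds, 5, 0, "expression", norm_expr=norm)
        with pytest.raises(ValueError, match="empty true TF set"):
            run_random_tf_background("g", [], ["a", "b"], y, folds, 5, 0,
                                     "expression", norm_expr=norm)


def test_planted_gene_beats_random_tf_background(null_tissue):
    """A strong planted effect should exceed the 95th percentile of the
    matched random-TF background in nearly every repeat."""
    cohort, norm = null_tissue
    tf_map = cohort.tf_map.groupby("target")["tf"].apply(list).to_dict()
    universe = sorted(set(cohort.tf_map["tf"]))
    wins = 0
    reps = 12
    rng = np.random.default_rng(2)
    genes = cohort.genes[:reps]
    for gene in genes:
        fs = build_tf_expression_features(gene, tf_map, norm)
        sig = norm[fs.feature_ids].to_numpy() @ rng.choice([-1., 1.], fs.n_features)
        sig = (sig - sig.mean()) / sig.std()
        y = sig + rng.standard_normal(len(sig))
        folds = make_folds(len(y), 5, np.random.default_rng(1))
        obs = fit_trans_model(fs, y, folds)
        bg = run_random_tf_background(gene, tf_map[gene], universe, y, folds,
                                      40, 3, "expression", norm_expr=norm)
        if obs.r2 > np.quantile(bg.r2, 0.95):
            wins += 1
    assert wins >= 0.9 * reps
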