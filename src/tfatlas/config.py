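"""Configuration objects for the simulator and the discovery pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "RunConfig", "load_config"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-tissue cohort generator.

    Effect sizes are expressed in standard-deviation units of the
    non-genetic noise; proportions are in [0, 1].  ``tissue_sharing`` is
    the probability that a planted effect is copied into each additional
    tissue beyond its home tissue.
    """

    n_tissues: int = 3
    n_samples_per_tissue: int = 300
    n_genes: int = 150
    n_tfs: int = 40
    n_snps_per_tf: int = 5
    n_cis_snps_per_gene: int = 4
    tf_per_gene_range: tuple[int, int] = (2, 5)
    frac_trans_expression_genes: float = 0.10
    frac_trans_binding_genes: float = 0.10
    trans_effect_size: float = 1.0
    cis_h2: float = 0.3
    noise_sd: float = 1.0
    frac_deleterious: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_covariates: int = 3
    covariate_effect_sd: float = 0.5
    tissue_sharing: float = 0.5
    n_causal_tfs: int = 2
    allow_mechanism_overlap: bool = False
    tf_tf_edges: bool = False
    frac_regulated_tfs: float = 0.2
    donor_pool_factor: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_trans_expression_genes", "frac_trans_binding_genes",
                     "cis_h2", "frac_deleterious", "tissue_sharing",
                     "frac_regulated_tfs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("n_tissues", "n_samples_per_tissue", "n_genes", "n_tfs",
                     "n_snps_per_tf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range={self.maf_range} must lie within (0, 0.5]")
        lo, hi = self.tf_per_gene_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid tf_per_gene_range={self.tf_per_gene_range}")
        if hi > self.n_tfs:
            raise ValueError(
                f"tf_per_gene_range upper bound {hi} exceeds n_tfs={self.n_tfs}")
        if self.noise_sd < 0 or self.trans_effect_size < 0:
            raise ValueError("noise_sd and trans_effect_size must be >= 0")


@dataclass
class RunConfig:
    """Parameters of the discovery pipeline (one run over a cohort).

    Defaults are the atlas's operating constants: B = 100 background runs
    per null, 10 robustness reruns on 90% subsamples, FDR level 0.05,
    SIFT deleteriousness cutoff 0.05 (strict ``<``), co-regulation
    requires >= 3 tissues and Jaccard >= 0.5, cascades explored to depth 4.
    """

    model_types: tuple[str, ...] = ("expression", "binding")
    b_background: int = 100
    n_robustness_runs: int = 10
    subsample_fraction: float = 0.9
    fdr_level: float = 0.05
    sift_cutoff: float = 0.05
    min_tissues_coregulation: int = 3
    jaccard_cutoff: float = 0.5
    cascade_max_depth: int = 4
    cv_folds: int = 5
    n_alphas: int = 12
    min_samples: int = 30
    cis_window: float = 1e6
    cis_l1_ratio: float = 0.5
    seed: int = 0
    tissues: tuple[str, ...] | None = None
    output_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.b_background < 1 or self.n_robustness_runs < 0:
            raise ValueError("b_background >= 1 and n_robustness_runs >= 0 required")
        bad = set(self.model_types) - {"expression", "binding"}
        if bad:
            raise ValueError(f"unknown model types: {sorted(bad)}")


def load_config(path: str | Path) -> tuple[SimulationConfig, RunConfig]:
    """Read a YAML config file with optional ``simulation:`` and ``run:``
    sections into the two config objects (missing keys keep defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_kwargs = raw.get("simulation", {}) or {}
    run_kwargs = raw.get("run", {}) or {}
    for kw in (sim_kwargs, run_kwargs):
        for k, v in list(kw.items()):
            if isinstance(v, list):
                kw[k] = tuple(v)
    sim = SimulationConfig(**sim_kwargs)
    run = RunConfig(**run_kwargs)
    sim.validate()
    run.validate()
    return sim, run


def dump_config(sim: SimulationConfig, run: RunConfig, path: str | Path) -> None:
    data = {"simulation": asdict(sim), "run": asdict(run)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
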