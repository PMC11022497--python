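"""Synthetic multi-tissue cohorts with planted cis and trans effects.

The generator emulates the data layout of a GTEx-style study: a shared
donor pool genotyped once, several tissues each sampling an overlapping
subset of donors, a sparse curated TF -> target-gene map, and per-tissue
expression assembled as

    expression = covariate term + cis term + planted trans term + noise

The cis term is a linear combination of the gene's local SNP dosages
scaled to a configured variance (``cis_h2``).  Planted trans effects come
in the two mechanisms the discovery models test for: a linear effect of
the expression of a subset of the gene's TFs ("expression" mechanism), or
a linear effect of the dosages of deleterious nonsynonymous SNPs inside
those TFs ("binding" mechanism).  Each planted effect lives in a random
home tissue and is copied into every other tissue independently with
probability ``tissue_sharing``.  All planted effects are recorded in a
truth table so recall and empirical FDR of the full pipeline can be
measured exactly.

No published generative model exists for this process; the distributional
choices here (binomial dosages, Gaussian covariates and noise, uniform
SIFT scores) are deliberately simple stand-ins, documented in the methods
note, and are not estimates of any real cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .config import SimulationConfig

__all__ = ["SimulatedCohort", "simulate_regulatory_map", "simulate_cohort",
           "write_cohort"]

logger = logging.getLogger(__name__)

_GENE_SPACING = 3_000_000  # bp between gene starts; >> cis window so cis SNPs are unambiguous
_CIS_SPREAD = 100_000


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth of its planted effects."""

    tissues: list[str]
    samples: dict[str, list[str]]               # tissue -> donor ids
    dosages: pd.DataFrame                       # donors x SNPs, values in [0, 2]
    expression: dict[str, pd.DataFrame]         # tissue -> samples x (genes + TFs)
    covariates: dict[str, pd.DataFrame]         # tissue -> samples x covariates
    tf_map: pd.DataFrame                        # columns: target, tf
    snp_annotation: pd.DataFrame                # snp_id, gene, position, nonsynonymous, sift
    gene_positions: pd.DataFrame                # gene, start, end
    cis_weights: dict[str, dict[str, float]]    # gene -> snp -> weight (as planted)
    truth: pd.DataFrame                         # tissue, gene, mechanism, causal_tfs, causal_snps, effect_size
    config: SimulationConfig

    @property
    def genes(self) -> list[str]:
        return [g for g in self.gene_positions["gene"] if not g.startswith("TF")]

    @property
    def tfs(self) -> list[str]:
        return [g for g in self.gene_positions["gene"] if g.startswith("TF")]

    def dosages_for(self, tissue: str) -> pd.DataFrame:
        """Per-tissue dosage view (rows = that tissue's samples)."""
        return self.dosages.loc[self.samples[tissue]]


def simulate_regulatory_map(cfg: SimulationConfig):
    """Draw the TF -> target map and the SNP annotation table.

    Each gene receives a TF count uniform on ``tf_per_gene_range``; each TF
    carries ``n_snps_per_tf`` SNPs of which a ``frac_deleterious`` Bernoulli
    fraction is flagged nonsynonymous with SIFT ~ U(0, 0.05), the remainder
    getting SIFT ~ U(0.05, 1).  Returns ``(tf_map, snp_annotation,
    gene_positions, regulated_tfs)``.
    """
    cfg.validate()
    rng = rng_for(cfg.seed, "regulatory_map")
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tfs = [f"TF{i:03d}" for i in range(cfg.n_tfs)]

    lo, hi = cfg.tf_per_gene_range
    pairs = []
    for g in genes:
        k = int(rng.integers(lo, hi + 1))
        for tf in rng.choice(tfs, size=k, replace=False):
            pairs.append((g, tf))

    regulated_tfs: dict[str, list[str]] = {}
    if cfg.tf_tf_edges:
        n_reg = int(round(cfg.frac_regulated_tfs * cfg.n_tfs))
        reg = list(rng.choice(tfs, size=n_reg, replace=False))
        upstream_pool = [t for t in tfs if t not in reg]
        for tf in reg:
            if not upstream_pool:
                break
            k = min(2, len(upstream_pool))
            ups = list(rng.choice(upstream_pool, size=k, replace=False))
            regulated_tfs[tf] = ups
            for u in ups:
                pairs.append((tf, u))
    tf_map = pd.DataFrame(pairs, columns=["target", "tf"])

    # genomic layout: everything on one contig, genes then TFs, widely spaced
    all_entities = genes + tfs
    starts = 10_000_000 + _GENE_SPACING * np.arange(len(all_entities))
    gene_positions = pd.DataFrame(
        {"gene": all_entities, "start": starts, "end": starts + 10_000})

    rows = []
    for gi, g in enumerate(genes):
        for s in range(cfg.n_cis_snps_per_gene):
            pos = int(starts[gi] + rng.integers(-_CIS_SPREAD, _CIS_SPREAD))
            rows.append((f"snp_{g}_{s}", g, pos, False,
                         float(rng.uniform(0.05, 1.0))))
    for ti, tf in enumerate(tfs):
        base = starts[cfg.n_genes + ti]
        for s in range(cfg.n_snps_per_tf):
            pos = int(base + rng.integers(-_CIS_SPREAD, _CIS_SPREAD))
            if rng.random() < cfg.frac_deleterious:
                rows.append((f"snp_{tf}_{s}", tf, pos, True,
                             float(rng.uniform(0.0, 0.05))))
            else:
                # non-deleterious remainder; half still nonsynonymous so the
                # strict (nonsyn AND SIFT < 0.05) filter is exercised on both clauses
                rows.append((f"snp_{tf}_{s}", tf, pos, bool(rng.random() < 0.5),
                             float(rng.uniform(0.05, 1.0))))
    snp_annotation = pd.DataFrame(
        rows, columns=["snp_id", "gene", "position", "nonsynonymous", "sift"])
    return tf_map, snp_annotation, gene_positions, regulated_tfs


def _draw_dosages(rng: np.random.Generator, n: int, n_snps: int,
                  maf_range: tuple[float, float]) -> np.ndarray:
    out = np.empty((n, n_snps))
    for j in range(n_snps):
        for attempt in range(50):
            maf = rng.uniform(*maf_range)
            col = rng.binomial(2, maf, size=n).astype(float)
            if col.std() > 0:
                break
            if attempt == 0:
                warnings.warn(f"monomorphic SNP column {j} resampled")
        out[:, j] = col
    return out


def _standardize_to(x: np.ndarray, target_sd: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd * target_sd


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort; deterministic given ``cfg.seed``."""
    cfg.validate()
    tf_map, snp_annotation, gene_positions, regulated_tfs = simulate_regulatory_map(cfg)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tfs = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    tissues = [f"tissue_{t + 1}" for t in range(cfg.n_tissues)]

    n_donors = max(cfg.n_samples_per_tissue,
                   int(round(cfg.n_samples_per_tissue * cfg.donor_pool_factor)))
    donors = [f"D{i:04d}" for i in range(n_donors)]

    rng = rng_for(cfg.seed, "dosages")
    snp_ids = list(snp_annotation["snp_id"])
    dosages = pd.DataFrame(
        _draw_dosages(rng, n_donors, len(snp_ids), cfg.maf_range),
        index=donors, columns=snp_ids)

    # donor-level covariates (sex + genotype-PC-like continuous columns)
    rng_cov = rng_for(cfg.seed, "covariates")
    cov_cols = {"sex": rng_cov.integers(0, 2, size=n_donors).astype(float)}
    for c in range(cfg.n_covariates):
        cov_cols[f"cov{c + 1}"] = rng_cov.standard_normal(n_donors)
    donor_cov = pd.DataFrame(cov_cols, index=donors)

    # cis weights, scaled so the planted cis component has variance cis_h2
    rng_cis = rng_for(cfg.seed, "cis_weights")
    cis_weights: dict[str, dict[str, float]] = {}
    cis_component = pd.DataFrame(0.0, index=donors, columns=genes)
    ann_by_gene = snp_annotation.groupby("gene")
    for g in genes:
        snps = list(ann_by_gene.get_group(g)["snp_id"]) if g in ann_by_gene.groups else []
        if not snps or cfg.cis_h2 == 0:
            cis_weights[g] = {}
            continue
        w = rng_cis.standard_normal(len(snps))
        raw = dosages[snps].to_numpy() @ w
        sd = raw.std()
        if sd == 0:
            cis_weights[g] = {}
            continue
        w *= np.sqrt(cfg.cis_h2) / sd
        raw = raw * np.sqrt(cfg.cis_h2) / sd
        cis_weights[g] = dict(zip(snps, (float(x) for x in w)))
        cis_component[g] = raw - raw.mean()

    # choose planted genes and their causal elements
    rng_plant = rng_for(cfg.seed, "planting")
    tfs_of = tf_map[~tf_map["target"].str.startswith("TF")].groupby("target")["tf"].apply(list).to_dict()
    delet = snp_annotation[(snp_annotation["nonsynonymous"]) & (snp_annotation["sift"] < 0.05)]
    delet_by_tf = delet.groupby("gene")["snp_id"].apply(list).to_dict()

    n_expr = int(round(cfg.frac_trans_expression_genes * cfg.n_genes))
    n_bind = int(round(cfg.frac_trans_binding_genes * cfg.n_genes))
    mappable = [g for g in genes if g in tfs_of]
    expr_genes = list(rng_plant.choice(mappable, size=min(n_expr, len(mappable)),
                                       replace=False))
    bind_pool = [g for g in mappable
                 if any(tf in delet_by_tf for tf in tfs_of[g])]
    if not cfg.allow_mechanism_overlap:
        bind_pool = [g for g in bind_pool if g not in expr_genes]
    bind_genes = list(rng_plant.choice(bind_pool, size=min(n_bind, len(bind_pool)),
                                       replace=False))
    if len(bind_genes) < n_bind:
        logger.info("only %d of %d requested binding-mechanism genes plantable",
                    len(bind_genes), n_bind)

    plantings = []  # (gene, mechanism, causal_tfs, causal_snps, signs, tissue flags)
    for g in expr_genes:
        cand = tfs_of[g]
        k = min(cfg.n_causal_tfs, len(cand))
        ctfs = list(rng_plant.choice(cand, size=k, replace=False))
        signs = rng_plant.choice([-1.0, 1.0], size=k)
        plantings.append((g, "expression", ctfs, [], signs))
    for g in bind_genes:
        cand = [tf for tf in tfs_of[g] if tf in delet_by_tf]
        k = min(cfg.n_causal_tfs, len(cand))
        ctfs = list(rng_plant.choice(cand, size=k, replace=False))
        csnps = [s for tf in ctfs for s in delet_by_tf[tf]]
        signs = rng_plant.choice([-1.0, 1.0], size=len(csnps))
        plantings.append((g, "binding", ctfs, csnps, signs))

    planted_in: dict[tuple[str, str, str], tuple] = {}
    for g, mech, ctfs, csnps, signs in plantings:
        home = int(rng_plant.integers(0, cfg.n_tissues))
        for t in range(cfg.n_tissues):
            if t == home or rng_plant.random() < cfg.tissue_sharing:
                planted_in[(tissues[t], g, mech)] = (ctfs, csnps, signs)

    # planted TF->TF effects (cascade layer), always expression mechanism
    tf_plant: dict[str, tuple[list[str], np.ndarray]] = {}
    tf_planted_in: dict[tuple[str, str], tuple] = {}
    for tf, ups in regulated_tfs.items():
        signs = rng_plant.choice([-1.0, 1.0], size=len(ups))
        tf_plant[tf] = (ups, signs)
        home = int(rng_plant.integers(0, cfg.n_tissues))
        for t in range(cfg.n_tissues):
            if t == home or rng_plant.random() < cfg.tissue_sharing:
                tf_planted_in[(tissues[t], tf)] = (ups, signs)

    expression: dict[str, pd.DataFrame] = {}
    covariates: dict[str, pd.DataFrame] = {}
    samples: dict[str, list[str]] = {}
    truth_rows = []
    for t in tissues:
        rng_t = rng_for(cfg.seed, "tissue", t)
        chosen = sorted(rng_t.choice(donors, size=cfg.n_samples_per_tissue,
                                     replace=False))
        samples[t] = chosen
        cov = donor_cov.loc[chosen]
        covariates[t] = cov
        n = len(chosen)
        covmat = cov.to_numpy()

        # TF expression: covariate term + independent Gaussian, plus the
        # optional planted TF->TF layer (upstream TFs are never themselves regulated)
        tf_expr = pd.DataFrame(index=chosen, columns=tfs, dtype=float)
        for tf in tfs:
            b = rng_t.normal(0, cfg.covariate_effect_sd, size=covmat.shape[1])
            tf_expr[tf] = covmat @ b + rng_t.standard_normal(n)
        for tf in tfs:
            key = (t, tf)
            if key in tf_planted_in:
                ups, signs = tf_planted_in[key]
                sig = np.zeros(n)
                for u, s in zip(ups, signs):
                    sig += s * tf_expr[u].to_numpy()
                tf_expr[tf] = tf_expr[tf].to_numpy() + _standardize_to(
                    sig, cfg.trans_effect_size)
                truth_rows.append((t, tf, "expression", ";".join(ups), "",
                                   cfg.trans_effect_size))

        gene_expr = pd.DataFrame(index=chosen, columns=genes, dtype=float)
        dos_t = dosages.loc[chosen]
        for g in genes:
            b = rng_t.normal(0, cfg.covariate_effect_sd, size=covmat.shape[1])
            y = covmat @ b
            y = y + cis_component.loc[chosen, g].to_numpy()
            key = (t, g, "expression")
            if key in planted_in:
                ctfs, _, signs = planted_in[key]
                sig = np.zeros(n)
                for tf, s in zip(ctfs, signs):
                    sig += s * tf_expr[tf].to_numpy()
                y = y + _standardize_to(sig, cfg.trans_effect_size)
                truth_rows.append((t, g, "expression", ";".join(ctfs), "",
                                   cfg.trans_effect_size))
            key = (t, g, "binding")
            if key in planted_in:
                ctfs, csnps, signs = planted_in[key]
                sig = np.zeros(n)
                for s_id, s in zip(csnps, signs):
                    sig += s * dos_t[s_id].to_numpy()
                y = y + _standardize_to(sig, cfg.trans_effect_size)
                truth_rows.append((t, g, "binding", ";".join(ctfs),
                                   ";".join(csnps), cfg.trans_effect_size))
            if cfg.noise_sd > 0:
                y = y + rng_t.normal(0, cfg.noise_sd, size=n)
            gene_expr[g] = y
        expression[t] = pd.concat([gene_expr, tf_expr], axis=1)

    truth = pd.DataFrame(
        truth_rows, columns=["tissue", "gene", "mechanism", "causal_tfs",
                             "causal_snps", "effect_size"])
    return SimulatedCohort(
        tissues=tissues, samples=samples, dosages=dosages,
        expression=expression, covariates=covariates, tf_map=tf_map,
        snp_annotation=snp_annotation, gene_positions=gene_positions,
        cis_weights=cis_weights, truth=truth, config=cfg)


def write_cohort(cohort: SimulatedCohort, directory: str | Path,
                 overwrite: bool = False) -> list[Path]:
    """Write the cohort in the pipeline's on-disk TSV dialects.

    One expression and covariate file per tissue; genotype, annotation,
    map and truth files are shared.  Refuses to write into an existing
    non-empty directory unless ``overwrite`` is set.
    """
    from . import io as tio

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(df: pd.DataFrame, name: str, index_label: str | None):
        p = directory / name
        df.to_csv(p, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.17g")
        written.append(p)

    for t in cohort.tissues:
        _w(cohort.expression[t], f"expression_{t}.tsv", "sample_id")
        _w(cohort.covariates[t], f"covariates_{t}.tsv", "sample_id")
    _w(cohort.dosages, "dosages.tsv", "sample_id")
    _w(cohort.tf_map, "tf_map.tsv", None)
    _w(cohort.snp_annotation, "snp_annotation.tsv", None)
    _w(cohort.gene_positions, "gene_positions.tsv", None)
    _w(cohort.truth, "truth.tsv", None)
    cw = pd.DataFrame(
        [(g, s, w) for g, ws in cohort.cis_weights.items() for s, w in ws.items()],
        columns=["gene", "snp_id", "weight"])
    _w(cw, "cis_weights.tsv", None)
    meta = pd.DataFrame({"tissue": cohort.tissues})
    _w(meta, "tissues.tsv", None)
    return written
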