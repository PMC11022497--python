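"""Readers and writers for the pipeline's on-disk table dialects.

All tables are TSV with a header row.  Expression and covariate matrices
are samples-by-columns with a leading ``sample_id`` column; dosage
matrices are samples-by-SNPs on the same layout.  A GCT 1.2 reader is
provided for expression since that is the common interchange format for
bulk expression matrices.  Every reader validates ids and value ranges
and raises a named error rather than propagating malformed data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression", "read_dosages", "read_covariates", "read_tf_map",
    "read_snp_annotation", "read_gene_positions", "read_gmt",
    "read_conservation", "read_cohort",
]

logger = logging.getLogger(__name__)

DOSAGE_TOL = 1e-6


class ValidationError(ValueError):
    """A table failed one of the documented dialect checks."""


def _read_indexed_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{what} {path}: duplicate sample ids {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{what} {path}: duplicate column ids {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValidationError(f"{what} {path}: non-numeric cell ({e})") from None
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError(f"{what} {path}: non-finite values present")
    df.index.name = None
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix, TSV (samples x genes) or GCT 1.2 (genes x samples,
    transposed on read so the in-memory convention is samples x genes)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValidationError(f"{path}: unsupported GCT version {version!r}")
            fh.readline()  # dimensions line; pandas infers them
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
        return _validate_expr(df.T.astype(float), path)
    return _validate_expr(_read_indexed_matrix(path, "expression"), path)


def _validate_expr(df: pd.DataFrame, path) -> pd.DataFrame:
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError(f"expression {path}: non-finite values present")
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    return _read_indexed_matrix(path, "covariates")


def read_dosages(path: str | Path) -> pd.DataFrame:
    df = _read_indexed_matrix(path, "dosages")
    arr = df.to_numpy()
    bad = (arr < -DOSAGE_TOL) | (arr > 2 + DOSAGE_TOL)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"dosages {path}: value {arr[i, j]} outside [0, 2] at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}")
    return df.clip(0.0, 2.0)


def read_tf_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"target", "tf"} <= set(df.columns):
        raise ValidationError(f"tf_map {path}: needs columns 'target' and 'tf'")
    n0 = len(df)
    df = df.drop_duplicates(subset=["target", "tf"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("tf_map %s: removed %d duplicate pairs", path, n0 - len(df))
    return df[["target", "tf"]]


def read_snp_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "gene", "nonsynonymous", "sift"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"snp_annotation {path}: missing columns {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise ValidationError(f"snp_annotation {path}: duplicate snp ids")
    df["nonsynonymous"] = df["nonsynonymous"].astype(bool)
    sift = pd.to_numeric(df["sift"], errors="coerce")
    n_missing = int(sift.isna().sum())
    if n_missing:
        # missing SIFT => treated as non-deleterious downstream
        logger.info("snp_annotation %s: %d SNPs lack SIFT scores", path, n_missing)
    ok = sift.dropna()
    if ((ok < 0) | (ok > 1)).any():
        raise ValidationError(f"snp_annotation {path}: SIFT scores outside [0, 1]")
    df["sift"] = sift
    return df


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "start", "end"}
    if not need <= set(df.columns):
        raise ValidationError(f"gene_positions {path}: missing columns "
                              f"{sorted(need - set(df.columns))}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"gmt {path}: line with fewer than 3 fields")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_conservation(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "score"} <= set(df.columns):
        raise ValidationError(f"conservation {path}: needs columns 'gene', 'score'")
    s = pd.Series(pd.to_numeric(df["score"]).to_numpy(), index=df["gene"])
    if not np.isfinite(s.to_numpy()).all():
        raise ValidationError(f"conservation {path}: non-finite scores")
    return s


def read_cohort(directory: str | Path):
    """Load a cohort directory written by :func:`tfatlas.simulate.write_cohort`
    (or assembled by hand in the same dialect) into a
    :class:`~tfatlas.simulate.SimulatedCohort`."""
    from .config import SimulationConfig
    from .simulate import SimulatedCohort

    d = Path(directory)
    tissues = pd.read_csv(d / "tissues.tsv", sep="\t")["tissue"].tolist()
    expression = {t: read_expression(d / f"expression_{t}.tsv") for t in tissues}
    covariates = {t: read_covariates(d / f"covariates_{t}.tsv") for t in tissues}
    dosages = read_dosages(d / "dosages.tsv")
    ann = read_snp_annotation(d / "snp_annotation.tsv")
    missing = set(dosages.columns) - set(ann["snp_id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} dosage SNPs missing from annotation, e.g. "
            f"{sorted(missing)[:3]}")
    for t in tissues:
        if set(expression[t].index) != set(covariates[t].index):
            raise ValidationError(f"tissue {t}: expression / covariate sample "
                                  "ids differ")
        unknown = set(expression[t].index) - set(dosages.index)
        if unknown:
            raise ValidationError(f"tissue {t}: samples absent from dosages: "
                                  f"{sorted(unknown)[:3]}")
    cw_path = d / "cis_weights.tsv"
    cis_weights: dict[str, dict[str, float]] = {}
    if cw_path.exists():
        cw = pd.read_csv(cw_path, sep="\t")
        for g, grp in cw.groupby("gene"):
            cis_weights[g] = dict(zip(grp["snp_id"], grp["weight"]))
    truth_path = d / "truth.tsv"
    truth = (pd.read_csv(truth_path, sep="\t").fillna({"causal_tfs": "", "causal_snps": ""})
             if truth_path.exists()
             else pd.DataFrame(columns=["tissue", "gene", "mechanism",
                                        "causal_tfs", "causal_snps", "effect_size"]))
    return SimulatedCohort(
        tissues=tissues,
        samples={t: expression[t].index.tolist() for t in tissues},
        dosages=dosages, expression=expression, covariates=covariates,
        tf_map=read_tf_map(d / "tf_map.tsv"),
        snp_annotation=ann,
        gene_positions=read_gene_positions(d / "gene_positions.tsv"),
        cis_weights=cis_weights, truth=truth, config=SimulationConfig())
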