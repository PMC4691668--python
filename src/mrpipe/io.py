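"""Readers and writers for the cohort and summary-panel TSV dialects.

Cohort tables are tab-delimited with a header row and columns
``iid genotype exposure sbp dbp`` plus any covariate / ancestry-score
columns; when two blood-pressure measurement columns ``sbp1 sbp2`` (or
``dbp1 dbp2``) are present they are averaged into ``sbp`` (``dbp``) on read,
mirroring the convention of recording the mean of two seated measurements.
Missing values are forbidden.

Summary panels are tab-delimited with header
``snp effect_allele other_allele beta_exp se_exp beta_out se_out`` (an
optional ``gene`` column is carried through). A wide two-file layout —
separate exposure and outcome association files joined on SNP id and
alleles — is also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import DataError
from .simulate import PANEL_COLUMNS

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_panel",
    "write_panel",
    "read_panel_wide",
    "load_config_file",
]

_COHORT_REQUIRED = ["iid", "genotype", "exposure"]
_PANEL_REQUIRED = [c for c in PANEL_COLUMNS if c != "gene"]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV, averaging duplicate BP measurement columns."""
    df = _read_tsv(path)
    for out in ("sbp", "dbp"):
        c1, c2 = f"{out}1", f"{out}2"
        if c1 in df.columns and c2 in df.columns:
            df[out] = (df[c1] + df[c2]) / 2.0
            df = df.drop(columns=[c1, c2])
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"cohort file {path} lacks required column(s): {', '.join(missing)}")
    if not ("sbp" in df.columns or "dbp" in df.columns):
        raise DataError(f"cohort file {path} has no outcome column (sbp or dbp)")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise DataError(f"cohort file {path} contains missing values in: {', '.join(bad)}")
    if not df["genotype"].isin([0, 1, 2]).all():
        raise DataError(f"cohort file {path}: genotype dosages must be 0, 1 or 2")
    if not (df["exposure"] > 0).all():
        raise DataError(f"cohort file {path}: exposure must be strictly positive")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a summary-statistic panel TSV."""
    df = _read_tsv(path)
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"panel file {path} lacks required column(s): {', '.join(missing)}")
    if df.isna().any().any():
        raise DataError(f"panel file {path} contains missing values")
    if not ((df["se_exp"] > 0).all() and (df["se_out"] > 0).all()):
        raise DataError(f"panel file {path}: standard errors must be > 0")
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        raise DataError(
            f"panel file {path}: identical effect/other alleles for "
            f"{', '.join(df.loc[same, 'snp'].astype(str))}"
        )
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in PANEL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_panel_wide(exposure_path, outcome_path) -> pd.DataFrame:
    """Join separate exposure / outcome association files into one panel.

    Each file needs ``snp effect_allele other_allele beta se``; records are
    matched on SNP id, re-orienting the outcome record when its effect and
    other alleles are swapped relative to the exposure file. SNPs with
    irreconcilable alleles are dropped with an error listing them.
    """
    exp = _read_tsv(exposure_path)
    out = _read_tsv(outcome_path)
    for name, df in (("exposure", exp), ("outcome", out)):
        need = ["snp", "effect_allele", "other_allele", "beta", "se"]
        lack = [c for c in need if c not in df.columns]
        if lack:
            raise DataError(f"{name} file lacks column(s): {', '.join(lack)}")
    merged = exp.merge(out, on="snp", suffixes=("_exp", "_out"), how="inner")
    same = (merged["effect_allele_exp"] == merged["effect_allele_out"]) & (
        merged["other_allele_exp"] == merged["other_allele_out"]
    )
    swapped = (merged["effect_allele_exp"] == merged["other_allele_out"]) & (
        merged["other_allele_exp"] == merged["effect_allele_out"]
    )
    bad = ~(same | swapped)
    if bad.any():
        raise DataError(
            "allele mismatch between exposure and outcome files for: "
            + ", ".join(merged.loc[bad, "snp"].astype(str))
        )
    beta_out = merged["beta_out"].where(same, -merged["beta_out"])
    panel = pd.DataFrame(
        {
            "snp": merged["snp"],
            "effect_allele": merged["effect_allele_exp"],
            "other_allele": merged["other_allele_exp"],
            "beta_exp": merged["beta_exp"],
            "se_exp": merged["se_exp"],
            "beta_out": beta_out,
            "se_out": merged["se_out"],
        }
    )
    if "gene" in exp.columns:
        panel["gene"] = merged["gene"] if "gene" in merged.columns else exp["gene"]
    return panel


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration document as a plain dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise DataError(f"config file {path} must contain a mapping")
    return loaded
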