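"""Readers and writers for the interchange formats.

All tables are UTF-8 text with '.' decimals and ``NA`` as the missing-value
token. Frequency tables and strata maps are tab-separated; environment
tables and category maps are comma-separated; distance matrices are square
TSVs with population labels as both header and first column (the square
PHYLIP-style dialect is accepted on input). BED input (0-based, half-open)
is converted to 1-based inclusive coordinates at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (ANNOTATION_COLS, EnvironmentTable, FrequencyTable,
                         GroundTruth)
from .distances import DistanceMatrix

NA = "NA"


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# -- frequency table --------------------------------------------------------

def write_frequency_table(ft: FrequencyTable, path) -> None:
    ann = ft.annotations
    out = pd.DataFrame({
        "snp_id": ft.snp_ids,
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "class": ann["snp_class"].to_numpy(),
        "gene_id": ann["gene_id"].replace("", NA).to_numpy(),
    })
    out = pd.concat([out.set_index("snp_id"), ft.freqs], axis=1)
    out.to_csv(path, sep="\t", na_rep=NA)


def read_frequency_table(path, sample_size: int = 20) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    _require_columns(df, ["snp_id", "chrom", "pos", "class", "gene_id"], path)
    df = df.set_index("snp_id")
    ann = df[["chrom", "pos", "class", "gene_id"]].rename(
        columns={"class": "snp_class"})
    ann["gene_id"] = ann["gene_id"].fillna("")
    pops = [c for c in df.columns if c not in ("chrom", "pos", "class", "gene_id")]
    freqs = df[pops].astype(float)
    if freqs.isna().any().any():
        bad = int(freqs.isna().any(axis=1).to_numpy().argmax())
        raise ValueError(f"{path}: malformed frequency at data line {bad + 2}")
    sizes = pd.Series(sample_size, index=freqs.columns)
    return FrequencyTable(ann, freqs, sizes)


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", na_rep=NA, index_label="snp_id")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                       index_col="snp_id")


# -- environment table ------------------------------------------------------

def write_environment(env: EnvironmentTable, values_path, categories_path) -> None:
    env.values.to_csv(values_path, na_rep=NA, index_label="population")
    cats = pd.DataFrame({"variable": list(env.categories),
                         "category": list(env.categories.values())})
    cats.to_csv(categories_path, index=False)


def read_environment(values_path, categories_path) -> EnvironmentTable:
    values = pd.read_csv(values_path, na_values=[NA], keep_default_na=False,
                         index_col="population").astype(float)
    cp = Path(categories_path)
    if cp.suffix in (".yaml", ".yml"):
        categories = yaml.safe_load(cp.read_text())
    else:
        cats = pd.read_csv(cp)
        _require_columns(cats, ["variable", "category"], categories_path)
        categories = dict(zip(cats["variable"], cats["category"]))
    return EnvironmentTable(values, categories)


# -- strata -----------------------------------------------------------------

def write_strata(strata: pd.Series, path) -> None:
    strata.rename("continent").to_csv(path, sep="\t", index_label="population")


def read_strata(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["population", "continent"], path)
    return df.set_index("population")["continent"]


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps({
        "selected_gene_ids": truth.selected_gene_ids,
        "driving_variable": truth.driving_variable,
        "snp_class": truth.snp_class,
    }, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(d["selected_gene_ids"], d["driving_variable"],
                       d["snp_class"])


# -- gene annotation (BED) --------------------------------------------------

def read_bed_genes(path) -> pd.DataFrame:
    """BED (0-based half-open) -> gene intervals (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: need at least 4 BED columns "
                         "(chrom, start, end, gene_id)")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    out = pd.DataFrame({
        "gene_id": df["gene_id"].astype(str),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int) + 1,
        "end": df["end"].astype(int),
        "strand": df["strand"].astype(str),
    })
    bad = out.index[out["start"] > out["end"]]
    if len(bad):
        raise ValueError(f"{path}: degenerate interval at data line {bad[0] + 1}")
    return out


def write_bed_genes(genes: pd.DataFrame, path) -> None:
    """Gene intervals (1-based inclusive) -> BED (0-based half-open)."""
    out = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "gene_id": genes["gene_id"],
        "score": 0,
        "strand": genes["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# -- distance matrices ------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels) \
        .to_csv(path, sep="\t", na_rep=NA, index_label="population")


def read_distance_matrix(path, role: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                     index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(list(df.columns), df.to_numpy(float), role,
                          {"path": str(path)})


# -- result tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                       **kwargs)
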