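"""Readers and writers for the plain-text formats of the pipeline.

Allelic counts and expression matrices travel as TSV, peak sets as 6-column
BED (0-based half-open, strand in column 6), gene models as a TSV with
gene_id / chrom / start / end / strand.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_allelic_counts",
    "write_allelic_counts",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_expression_tsv",
    "write_expression_tsv",
    "load_yaml_config",
]

_ALLELIC_COLS = ["feature_id", "reads_xi", "reads_xa"]
_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def read_allelic_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ALLELIC_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[_ALLELIC_COLS].astype({"reads_xi": "int64", "reads_xa": "int64"})


def write_allelic_counts(df: pd.DataFrame, path) -> None:
    df[_ALLELIC_COLS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """6-column BED (name/score/strand optional); returns chrom, start, end
    plus id and strand when present."""
    names = ["chrom", "start", "end", "id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    for i, row in df.iterrows():
        if row["start"] >= row["end"]:
            raise ValueError(f"{path}: line {i + 1}: start >= end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "id" not in out.columns:
        out["id"] = [f"peak_{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[["chrom", "start", "end", "id", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[_GENE_COLS].astype({"start": "int64", "end": "int64"})


def write_gene_models(df: pd.DataFrame, path) -> None:
    df[_GENE_COLS].to_csv(path, sep="\t", index=False)


def read_expression_tsv(path):
    """Expression TSV: gene_id, length_bp, then one column per sample.
    Returns (counts DataFrame indexed by gene_id, length Series)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp")
    return df, lengths


def write_expression_tsv(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
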