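"""Readers and writers for the plain-text table dialects used throughout.

All tables are tab-separated with a header row unless noted.  Genomic
intervals follow the BED convention (0-based, half-open, stranded);
amino-acid coordinates are 1-based inclusive.

Dialects
--------
gene model          gene_id, protein_id, transcript_id (one row per isoform)
3' UTR table        gene_id, utr_id, length [, chrom, start, end, strand]
target predictions  utr_id, mirna_family, n_sites
regulator bindings  regulator_id, regulator_class {TF,RBP,CLIP}, target_gene_id
phosphosites        protein_id, residue_index [, residue]
detection list      one gene_id per line, no header
BED                 chrom, start, end, name, score, strand (no header)
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "FormatError",
    "read_gene_model",
    "read_utrs",
    "read_target_predictions",
    "read_bindings",
    "read_phosphosites",
    "read_detection_list",
    "read_bed",
    "write_bed",
]

PathLike = Union[str, Path]

REGULATOR_CLASSES = ("TF", "RBP", "CLIP")


class FormatError(ValueError):
    """Raised when an input table violates its dialect."""


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_gene_model(path: PathLike) -> pd.DataFrame:
    """Gene ↔ isoform table; one row per protein isoform.

    A protein may appear only once: isoform→gene mapping must be a function.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ("gene_id", "protein_id"), "gene model")
    if "transcript_id" not in df.columns:
        df["transcript_id"] = df["protein_id"]
    dup = df[df.duplicated("protein_id", keep=False)]
    if not dup.empty and dup.groupby("protein_id")["gene_id"].nunique().max() > 1:
        bad = (
            dup.groupby("protein_id")["gene_id"].nunique().loc[lambda s: s > 1].index.tolist()
        )
        raise FormatError(f"gene model: proteins mapped to multiple genes: {bad[:5]}")
    return df.drop_duplicates()


def protein_to_gene(gene_model: pd.DataFrame) -> dict[str, str]:
    """Isoform→gene lookup from a gene-model table."""
    return dict(zip(gene_model["protein_id"], gene_model["gene_id"]))


def read_utrs(path: PathLike) -> pd.DataFrame:
    """3' UTR annotation table; interval columns are optional."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "utr_id": str})
    _require(df, ("gene_id", "utr_id", "length"), "UTR table")
    df["length"] = df["length"].astype(int)
    if (df["length"] <= 0).any():
        bad = df.loc[df["length"] <= 0, "utr_id"].tolist()
        raise FormatError(f"UTR table: nonpositive lengths for {bad[:5]}")
    if {"chrom", "start", "end", "strand"}.issubset(df.columns):
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        mismatch = df["end"] - df["start"] != df["length"]
        if mismatch.any():
            bad = df.loc[mismatch, "utr_id"].tolist()
            raise FormatError(f"UTR table: end-start != length for {bad[:5]}")
    return df


def read_target_predictions(path: PathLike) -> pd.DataFrame:
    """miRNA-family target predictions per UTR (conserved-site counts)."""
    df = pd.read_csv(path, sep="\t", dtype={"utr_id": str, "mirna_family": str})
    _require(df, ("utr_id", "mirna_family", "n_sites"), "target predictions")
    df["n_sites"] = df["n_sites"].astype(int)
    if (df["n_sites"] < 1).any():
        bad = df.loc[df["n_sites"] < 1].index.tolist()
        raise FormatError(f"target predictions: n_sites < 1 at rows {bad[:5]}")
    if df.duplicated(["utr_id", "mirna_family"]).any():
        df = df.groupby(["utr_id", "mirna_family"], as_index=False)["n_sites"].max()
    return df


def read_bindings(path: PathLike) -> pd.DataFrame:
    """Regulator→target-gene binding events (ChIP-seq / RIP-Chip / CLIP)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ("regulator_id", "regulator_class", "target_gene_id"), "bindings")
    unknown = set(df["regulator_class"]) - set(REGULATOR_CLASSES)
    if unknown:
        raise FormatError(f"bindings: unknown regulator_class labels {sorted(unknown)}")
    return df


def read_phosphosites(path: PathLike) -> pd.DataFrame:
    """Phosphorylated residues per protein isoform (1-based positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    _require(df, ("protein_id", "residue_index"), "phosphosites")
    df["residue_index"] = df["residue_index"].astype(int)
    if (df["residue_index"] < 1).any():
        raise FormatError("phosphosites: residue_index must be >= 1")
    return df


def read_detection_list(path: PathLike) -> set[str]:
    """Mass-spectrometry detection reference: one gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_bed(path: PathLike) -> pd.DataFrame:
    """BED6 intervals (0-based half-open, stranded)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "name"].tolist()
        raise FormatError(f"BED: start >= end for {bad[:5]}")
    return df


def write_bed(df: pd.DataFrame, path: PathLike) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
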