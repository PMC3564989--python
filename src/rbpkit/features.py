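"""Per-gene regulatory feature integration.

Each operation reduces one annotation or interaction table to a per-gene
quantity; :func:`build_feature_table` assembles them into one row per gene
of the universe (defined by the gene-model table).

Counting is nonredundant throughout: duplicated input rows never change a
count.  Missingness is explicit and feature-class specific — a gene with
no 3' UTR annotation (or absent from the detection reference study) is
*unannotated* (NA), whereas a gene with no recorded binding or
phosphorylation among annotated ones has observed zero.

Genomic intervals are 0-based half-open and stranded (BED convention);
amino-acid residues are 1-based.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .io import REGULATOR_CLASSES, FormatError

__all__ = [
    "count_isoforms",
    "count_regulators",
    "utr_length_per_gene",
    "count_mirna_families",
    "detect_apa",
    "mirna_evasion",
    "intersect_sites_with_utrs",
    "count_phospho_residues",
    "build_feature_table",
    "utr_lengths_long",
]

UTR_POLICIES = ("longest", "shortest", "per_utr")


def count_isoforms(gene_model: pd.DataFrame) -> pd.Series:
    """Distinct protein isoforms per gene."""
    return (
        gene_model.drop_duplicates(["gene_id", "protein_id"])
        .groupby("gene_id")["protein_id"]
        .nunique()
        .rename("n_isoforms")
    )


def count_regulators(bindings: pd.DataFrame, regulator_class: str) -> pd.Series:
    """Distinct regulators of one class bound per target gene.

    Genes absent from the table simply do not appear; callers fill zero
    over their universe.
    """
    if regulator_class not in REGULATOR_CLASSES:
        raise ValueError(f"unknown regulator class {regulator_class!r}")
    unknown = set(bindings["regulator_class"]) - set(REGULATOR_CLASSES)
    if unknown:
        raise FormatError(f"bindings table has unknown class labels {sorted(unknown)}")
    sub = bindings[bindings["regulator_class"] == regulator_class]
    return sub.groupby("target_gene_id")["regulator_id"].nunique().rename(
        f"n_{regulator_class.lower()}s"
    )


def utr_length_per_gene(utrs: pd.DataFrame, policy: str = "longest"):
    """Representative 3' UTR length per gene.

    ``longest``/``shortest`` return a Series gene→length; ``per_utr``
    returns the full per-UTR multiset as a mapping gene→list of lengths
    (the unit of distribution comparisons is then the UTR, not the gene).
    """
    if policy not in UTR_POLICIES:
        raise ValueError(f"unknown UTR length policy {policy!r}")
    if (utrs["length"] <= 0).any():
        raise FormatError("UTR lengths must be positive")
    dedup = _distinct_utrs(utrs)
    if policy == "longest":
        return dedup.groupby("gene_id")["length"].max().rename("utr_len")
    if policy == "shortest":
        return dedup.groupby("gene_id")["length"].min().rename("utr_len")
    return {g: sorted(sub["length"]) for g, sub in dedup.groupby("gene_id")}


def utr_lengths_long(utrs: pd.DataFrame) -> pd.DataFrame:
    """Distinct UTRs as a long table (gene_id, utr_id, length)."""
    return _distinct_utrs(utrs)[["gene_id", "utr_id", "length"]]


def _distinct_utrs(utrs: pd.DataFrame) -> pd.DataFrame:
    """Collapse UTR records to distinct 3' UTR isoforms per gene.

    Two records of one gene are the same isoform iff their 3'-end
    coordinates coincide (end for + strand, start for −) when intervals
    are present, else iff their lengths coincide.  Rationale: 3'-seq-style
    annotations define a UTR isoform by its cleavage/poly(A) site.
    """
    df = utrs.copy()
    if {"chrom", "start", "end", "strand"}.issubset(df.columns):
        df["_three_prime"] = df["end"].where(df["strand"] == "+", df["start"])
        key = ["gene_id", "_three_prime"]
    else:
        key = ["gene_id", "length"]
    return df.drop_duplicates(key).drop(columns="_three_prime", errors="ignore")


def _utr_isoform_key(utrs: pd.DataFrame) -> pd.Series:
    """Map every UTR record id to its distinct-isoform representative id."""
    df = utrs.copy()
    if {"chrom", "start", "end", "strand"}.issubset(df.columns):
        df["_k"] = df["end"].where(df["strand"] == "+", df["start"]).astype(str)
    else:
        df["_k"] = df["length"].astype(str)
    rep = df.drop_duplicates(["gene_id", "_k"]).set_index(["gene_id", "_k"])["utr_id"]
    out = pd.Series(
        rep.loc[pd.MultiIndex.from_frame(df[["gene_id", "_k"]])].to_numpy(),
        index=df["utr_id"].to_numpy(),
    )
    return out[~out.index.duplicated()]


def detect_apa(utrs: pd.DataFrame) -> pd.DataFrame:
    """Distinct 3' UTR isoform count per gene and the APA flag (≥ 2)."""
    n = _distinct_utrs(utrs).groupby("gene_id").size().rename("n_utrs")
    return pd.DataFrame({"n_utrs": n, "uses_apa": n >= 2})


def _joined_predictions(predictions: pd.DataFrame, utrs: pd.DataFrame) -> pd.DataFrame:
    orphans = set(predictions["utr_id"]) - set(utrs["utr_id"])
    if orphans:
        raise FormatError(
            f"target predictions reference unknown UTR ids: {sorted(orphans)[:10]}"
        )
    return predictions.merge(utrs[["utr_id", "gene_id"]].drop_duplicates(), on="utr_id")


def count_mirna_families(predictions: pd.DataFrame, utrs: pd.DataFrame) -> pd.Series:
    """Unique miRNA families with ≥ 1 conserved site in any UTR of the gene."""
    joined = _joined_predictions(predictions, utrs)
    return joined.groupby("gene_id")["mirna_family"].nunique().rename("n_mirna_families")


def mirna_evasion(predictions: pd.DataFrame, utrs: pd.DataFrame) -> dict[str, set[str]]:
    """miRNA families a gene can escape through alternative 3' UTR choice.

    A family is evadable for a gene iff the gene has ≥ 2 distinct UTR
    isoforms and the family has ≥ 1 site in at least one isoform but none
    in at least one other — i.e. expressing the alternative UTR loses all
    of that family's sites.  Returns gene → set of evadable families
    (genes with an empty set omitted).
    """
    rep = _utr_isoform_key(utrs)
    joined = _joined_predictions(predictions, utrs)
    joined = joined.assign(utr_id=joined["utr_id"].map(rep))
    n_utrs = _distinct_utrs(utrs).groupby("gene_id").size()

    out: dict[str, set[str]] = {}
    presence = (
        joined.drop_duplicates(["gene_id", "utr_id", "mirna_family"])
        .groupby(["gene_id", "mirna_family"])["utr_id"]
        .nunique()
    )
    for (gene, family), n_present in presence.items():
        total = int(n_utrs.get(gene, 0))
        if total >= 2 and n_present < total:
            out.setdefault(gene, set()).add(family)
    return out


def intersect_sites_with_utrs(sites: pd.DataFrame, utrs: pd.DataFrame) -> pd.DataFrame:
    """Assign genomic binding sites (e.g. CLIP) to overlapping 3' UTRs.

    Overlap requires same chromosome, same strand and ≥ 1 nt of 0-based
    half-open overlap.  Emits every overlapping (utr_id, site_id) pair.
    """
    for df, what in ((sites, "sites"), (utrs, "UTRs")):
        if (df["start"] >= df["end"]).any():
            raise FormatError(f"{what}: start >= end")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in utrs.itertuples():
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, row.utr_id
        )
    pairs = [
        {"utr_id": iv.data, "site_id": site.name}
        for site in sites.itertuples()
        for iv in trees.get((site.chrom, site.strand), IntervalTree()).overlap(
            site.start, site.end
        )
    ]
    return pd.DataFrame(pairs, columns=["utr_id", "site_id"]).sort_values(
        ["utr_id", "site_id"]
    ).reset_index(drop=True)


def count_phospho_residues(sites: pd.DataFrame, gene_model: pd.DataFrame) -> pd.Series:
    """Distinct phosphorylated (protein, residue) pairs per gene.

    Residues are counted per isoform and combined nonredundantly for the
    gene; no cross-isoform residue alignment is attempted.
    """
    mapping = dict(zip(gene_model["protein_id"], gene_model["gene_id"]))
    orphans = set(sites["protein_id"]) - set(mapping)
    if orphans:
        raise FormatError(f"phosphosites reference unknown proteins: {sorted(orphans)[:10]}")
    df = sites.drop_duplicates(["protein_id", "residue_index"]).copy()
    df["gene_id"] = df["protein_id"].map(mapping)
    return df.groupby("gene_id").size().rename("n_phospho_residues")


def build_feature_table(
    gene_model: pd.DataFrame,
    utrs: Optional[pd.DataFrame] = None,
    predictions: Optional[pd.DataFrame] = None,
    bindings: Optional[pd.DataFrame] = None,
    phospho: Optional[pd.DataFrame] = None,
    detected_genes: Optional[Iterable[str]] = None,
    gene_sets: Optional[Mapping[str, Iterable[str]]] = None,
    utr_policy: str = "longest",
) -> pd.DataFrame:
    """One integrated feature row per gene of the universe.

    The universe is the set of genes in ``gene_model``.  UTR-derived
    columns (utr_len, n_utrs, uses_apa, n_mirna_families,
    n_evadable_families) are NA for genes without UTR annotation;
    ``detected_in_ms`` is NA when no detection reference is supplied.
    Binding and phosphorylation counts default to zero (none observed).
    Named gene sets are attached as a semicolon-joined label column; a set
    naming genes outside the universe triggers a warning with the count.
    """
    import warnings

    universe = sorted(gene_model["gene_id"].unique())
    table = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    table["n_isoforms"] = count_isoforms(gene_model).reindex(universe).fillna(0).astype(int)

    if bindings is not None:
        for cls, col in (("TF", "n_tfs"), ("RBP", "n_rbps")):
            table[col] = (
                count_regulators(bindings, cls).reindex(universe).fillna(0).astype(int)
            )
    else:
        table["n_tfs"] = 0
        table["n_rbps"] = 0

    if utrs is not None:
        if utr_policy == "per_utr":
            rep = utr_length_per_gene(utrs, "longest")  # scalar column needs one value
        else:
            rep = utr_length_per_gene(utrs, utr_policy)
        apa = detect_apa(utrs)
        table["utr_len"] = rep.reindex(universe)
        table["n_utrs"] = apa["n_utrs"].reindex(universe).astype("Int64")
        table["uses_apa"] = apa["uses_apa"].reindex(universe).astype("boolean")
        annotated = table["n_utrs"].notna()
        if predictions is not None:
            fam = count_mirna_families(predictions, utrs)
            evas = mirna_evasion(predictions, utrs)
            table["n_mirna_families"] = (
                fam.reindex(universe).where(~annotated, fam.reindex(universe).fillna(0))
            ).astype("Int64")
            n_ev = pd.Series({g: len(s) for g, s in evas.items()}, dtype="float64")
            table["n_evadable_families"] = (
                n_ev.reindex(universe).where(~annotated, n_ev.reindex(universe).fillna(0))
            ).astype("Int64")
        else:
            table["n_mirna_families"] = pd.array([pd.NA] * len(universe), dtype="Int64")
            table["n_evadable_families"] = pd.array([pd.NA] * len(universe), dtype="Int64")
    else:
        table["utr_len"] = float("nan")
        table["n_utrs"] = pd.array([pd.NA] * len(universe), dtype="Int64")
        table["uses_apa"] = pd.array([pd.NA] * len(universe), dtype="boolean")
        table["n_mirna_families"] = pd.array([pd.NA] * len(universe), dtype="Int64")
        table["n_evadable_families"] = pd.array([pd.NA] * len(universe), dtype="Int64")

    if phospho is not None:
        table["n_phospho_residues"] = (
            count_phospho_residues(phospho, gene_model)
            .reindex(universe)
            .fillna(0)
            .astype(int)
        )
    else:
        table["n_phospho_residues"] = 0

    if detected_genes is not None:
        detected = set(detected_genes)
        table["detected_in_ms"] = pd.array(
            [g in detected for g in universe], dtype="boolean"
        )
    else:
        table["detected_in_ms"] = pd.array([pd.NA] * len(universe), dtype="boolean")

    labels = {g: [] for g in universe}
    if gene_sets:
        for name, members in gene_sets.items():
            members = set(members)
            outside = members - set(universe)
            if outside:
                warnings.warn(
                    f"gene set {name!r}: {len(outside)} genes outside the universe",
                    stacklevel=2,
                )
            for g in members & set(universe):
                labels[g].append(name)
    table["gene_sets"] = [";".join(sorted(labels[g])) for g in universe]
    return table.reset_index()
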