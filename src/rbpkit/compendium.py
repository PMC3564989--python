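"""Build an RNA-binding-protein compendium from domain-scan output.

Pipeline: parse an InterProScan-style raw TSV → keep hits from the four
applications that detect RBDs reliably (Pfam, SMART, Superfamily, ProSite)
→ match hits against the RBD catalog → collapse protein isoforms to genes
(nonredundant union) → assign each gene to one of four groups → apply a
manual curation list (removals of false positives, literature-supported
additions).  The result is one record per gene.

Group assignment is deterministic: a gene with any group-1 (sequence-
specific) domain is group 1; otherwise groups are prioritised 3 > 2 > 4,
putting the putatively sequence-specific class ahead of the extrinsically
targeted one.  The priority order is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .catalog import ANY_APPLICATION, RBDCatalogEntry, default_catalog, validate_catalog
from .io import PathLike, protein_to_gene, read_gene_model

__all__ = [
    "DomainHit",
    "RBPRecord",
    "CurationList",
    "ParseError",
    "ACCEPTED_APPLICATIONS",
    "parse_interproscan",
    "filter_by_application",
    "map_to_rbds",
    "collapse_to_genes",
    "assign_group",
    "apply_curation",
    "build_compendium",
    "compare_gene_sets",
    "default_curation",
    "load_curation",
    "compendium_to_frame",
    "write_compendium",
    "read_compendium",
    "rbp_gene_set",
]

#: applications retained by the filtering step
ACCEPTED_APPLICATIONS = ("Pfam", "SMART", "Superfamily", "ProSite")

#: default group priority after "any group-1 domain wins"
DEFAULT_GROUP_PRIORITY: tuple[int, ...] = (1, 3, 2, 4)

# classic iprscan raw output spells applications by the search program
_APPLICATION_ALIASES = {
    "pfam": "Pfam",
    "hmmpfam": "Pfam",
    "smart": "SMART",
    "hmmsmart": "SMART",
    "superfamily": "Superfamily",
    "ssf": "Superfamily",
    "prosite": "ProSite",
    "profilescan": "ProSite",
    "scanregexp": "ProSite",
    "prositeprofiles": "ProSite",
    "prositepatterns": "ProSite",
}


class ParseError(ValueError):
    """Malformed domain-scan input; message names the offending line."""


@dataclass(frozen=True)
class DomainHit:
    """One domain call on one protein isoform (1-based inclusive coords)."""

    protein_id: str
    application: str
    accession: str
    name: str
    start: int
    end: int
    gene_id: Optional[str] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"invalid coordinates {self.start}..{self.end} on {self.protein_id}"
            )


@dataclass
class RBPRecord:
    """Gene-level compendium entry."""

    gene_id: str
    protein_ids: set[str] = field(default_factory=set)
    rbds: set[tuple[str, int]] = field(default_factory=set)
    assigned_group: int = 1
    provenance: str = "scan"  # or "curated_addition"
    applications_detected: set[str] = field(default_factory=set)
    note: str = ""


def normalize_application(raw: str) -> str:
    """Canonical application label; anything unrecognised maps to ``other``."""
    return _APPLICATION_ALIASES.get(raw.strip().lower(), "other")


def parse_interproscan(
    path: PathLike,
    gene_model: Optional[Union[pd.DataFrame, Mapping[str, str]]] = None,
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> list[DomainHit]:
    """Parse a classic InterProScan raw TSV into :class:`DomainHit` records.

    Expected columns (tab-separated, no header): protein id, checksum,
    length, application, accession, name, start, end, e-value, status,
    date, InterPro id, InterPro description.  Trailing columns may be
    missing; the first eight are required.

    ``gene_model`` (table or protein→gene mapping) resolves isoforms to
    genes; a protein without a mapping yields a warning and a hit with
    ``gene_id`` unset.  ``protein_lengths`` (e.g. from the proteome FASTA)
    optionally validates that hit coordinates fall inside the protein.
    """
    if isinstance(gene_model, pd.DataFrame):
        mapping: Mapping[str, str] = protein_to_gene(gene_model)
    else:
        mapping = gene_model or {}
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"line {lineno}: expected >= 8 tab-separated columns, got {len(fields)}"
                )
            protein_id = fields[0].strip()
            try:
                start = int(fields[6])
                end = int(fields[7])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            evalue: Optional[float] = None
            if len(fields) > 8 and fields[8].strip() not in ("", "NA", "-", "?"):
                try:
                    evalue = float(fields[8])
                except ValueError:
                    evalue = None
            gene_id = mapping.get(protein_id)
            if mapping and gene_id is None:
                warnings.warn(
                    f"line {lineno}: protein {protein_id!r} has no gene mapping",
                    stacklevel=2,
                )
            if protein_lengths and protein_id in protein_lengths:
                if end > protein_lengths[protein_id]:
                    raise ParseError(
                        f"line {lineno}: hit end {end} beyond protein length "
                        f"{protein_lengths[protein_id]} for {protein_id}"
                    )
            try:
                hit = DomainHit(
                    protein_id=protein_id,
                    application=normalize_application(fields[3]),
                    accession=fields[4].strip(),
                    name=fields[5].strip(),
                    start=start,
                    end=end,
                    gene_id=gene_id,
                    evalue=evalue,
                )
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            hits.append(hit)
    return hits


def read_protein_lengths(fasta_path: PathLike) -> dict[str, int]:
    """Protein lengths from a proteome FASTA (headers are protein ids)."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def filter_by_application(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Keep only Pfam/SMART/Superfamily/ProSite hits, preserving order."""
    accepted = set(ACCEPTED_APPLICATIONS)
    return [h for h in hits if h.application in accepted]


def _pattern_index(
    catalog: Sequence[RBDCatalogEntry],
) -> tuple[dict[tuple[str, str], tuple[str, int]], dict[str, tuple[str, int]]]:
    validate_catalog(catalog)
    by_accession: dict[tuple[str, str], tuple[str, int]] = {}
    by_name: dict[str, tuple[str, int]] = {}
    for entry in catalog:
        for app, pattern in entry.match_patterns:
            if app == ANY_APPLICATION:
                by_name[pattern.lower()] = (entry.rbd_name, entry.group)
            else:
                by_accession[(app, pattern)] = (entry.rbd_name, entry.group)
    return by_accession, by_name


def map_to_rbds(
    hits: Iterable[DomainHit],
    catalog: Optional[Sequence[RBDCatalogEntry]] = None,
) -> dict[str, set[tuple[str, int]]]:
    """Match hits to catalog entries, per protein.

    A hit contributes ``(rbd_name, group)`` when its (application,
    accession) pair matches a catalog accession pattern or its domain name
    matches a wildcard name pattern (case-insensitive).  Proteins with no
    matching hits are absent from the result.
    """
    if catalog is None:
        catalog = default_catalog()
    by_accession, by_name = _pattern_index(catalog)
    result: dict[str, set[tuple[str, int]]] = {}
    for hit in hits:
        match = by_accession.get((hit.application, hit.accession))
        if match is None:
            match = by_name.get(hit.name.lower())
        if match is not None:
            result.setdefault(hit.protein_id, set()).add(match)
    return result


def collapse_to_genes(
    protein_rbds: Mapping[str, set[tuple[str, int]]],
    gene_model: Union[pd.DataFrame, Mapping[str, str]],
) -> dict[str, set[tuple[str, int]]]:
    """Nonredundant union of isoform RBD sets per gene."""
    if isinstance(gene_model, pd.DataFrame):
        mapping: Mapping[str, str] = protein_to_gene(gene_model)
    else:
        mapping = gene_model
    orphans = [p for p in protein_rbds if p not in mapping]
    if orphans:
        raise KeyError(f"proteins without gene mapping: {sorted(orphans)[:10]}")
    genes: dict[str, set[tuple[str, int]]] = {}
    for protein_id, rbds in protein_rbds.items():
        genes.setdefault(mapping[protein_id], set()).update(rbds)
    return genes


def assign_group(
    rbds: set[tuple[str, int]],
    priority: Sequence[int] = DEFAULT_GROUP_PRIORITY,
) -> int:
    """Classify a gene from its RBD set.

    Any sequence-specific (group-1) domain wins; otherwise the first group
    in ``priority`` that is present.  Order-independent in the input set.
    """
    if not rbds:
        raise ValueError("cannot assign a group to an empty RBD set")
    present = {group for _, group in rbds}
    for group in priority:
        if group in present:
            return group
    raise ValueError(f"RBD set contains no group in priority {priority}: {rbds}")


@dataclass
class CurationList:
    """Manual curation: removals of false positives, literature additions.

    ``removals``: set of ``(gene_id, reason)`` with reason in
    {domain-length, pseudogene, no-homology}.  ``additions``: set of
    ``(gene_id, note, group_override)`` where ``group_override`` may be
    ``None`` (additions then default to group 1 — literature-supported
    specific binders).
    """

    removals: set[tuple[str, str]] = field(default_factory=set)
    additions: set[tuple[str, str, Optional[int]]] = field(default_factory=set)

    def __post_init__(self) -> None:
        removed = {g for g, _ in self.removals}
        added = {g for g, _, _ in self.additions}
        overlap = removed & added
        if overlap:
            raise ValueError(f"genes in both removals and additions: {sorted(overlap)}")

    @property
    def removed_genes(self) -> set[str]:
        return {g for g, _ in self.removals}


#: group assigned to curated additions without an explicit override
DEFAULT_ADDITION_GROUP = 1

# Printed removal list: over/under-length domain calls, one pseudogene and
# two genes lacking characteristic zinc-finger homology.
_REMOVALS = (
    ("R12B2.5", "domain-length"),
    ("T03G11.3", "domain-length"),
    ("D2005.1", "domain-length"),
    ("Y82E9BR.19", "domain-length"),
    ("R11H6.5", "domain-length"),
    ("C06A1.4", "pseudogene"),
    ("Y60A9.3", "no-homology"),
    ("R03D7.7", "no-homology"),
)

# 12 literature-supported RBPs (default group 1).
_LITERATURE_ADDITIONS = (
    "C18G1.4", "C50E10.4", "M04B2.1", "R06F6.1", "R144.7", "T12F5.5",
    "Y18D10A.17", "Y48G8AL.6", "Y53C12B.3", "ZK1127.1", "ZK1236.3", "ZK381.4",
)

# Additions from secondary annotation searches; mostly general factors
# (deaminases, initiation factors, tRNA binders), hence group-4 override.
_SECONDARY_ADDITIONS = (
    "C47D2.2", "F49E8.4", "T01C3.7", "F53A2.6", "R04A9.4", "C05D9.5",
    "Y57A10A.30", "C41G7.1", "F29C4.6", "C49H3.10", "C12D8.11", "C11D2.7",
    "C15C6.4", "C48B6.2", "F08B4.7",
)


def default_curation() -> CurationList:
    """The printed manual-curation lists (removals and additions)."""
    additions: set[tuple[str, str, Optional[int]]] = {
        (g, "literature", None) for g in _LITERATURE_ADDITIONS
    }
    additions |= {(g, "secondary-search", 4) for g in _SECONDARY_ADDITIONS}
    return CurationList(removals=set(_REMOVALS), additions=additions)


def load_curation(path: PathLike) -> CurationList:
    """Curation TSV: columns action {add,remove}, gene_id, reason, group_override."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    removals: set[tuple[str, str]] = set()
    additions: set[tuple[str, str, Optional[int]]] = set()
    for row in df.itertuples():
        action = row.action.strip().lower()
        if action == "remove":
            removals.add((row.gene_id, row.reason or "unspecified"))
        elif action == "add":
            override = getattr(row, "group_override", "")
            additions.add((row.gene_id, row.reason, int(override) if override else None))
        else:
            raise ValueError(f"unknown curation action {row.action!r}")
    return CurationList(removals=removals, additions=additions)


def apply_curation(
    records: Mapping[str, RBPRecord],
    curation: CurationList,
) -> dict[str, RBPRecord]:
    """Apply removals then additions; untouched records pass through."""
    out: dict[str, RBPRecord] = {}
    removed = curation.removed_genes
    for gene_id, rec in records.items():
        if gene_id in removed:
            continue
        out[gene_id] = rec
    for gene_id, _ in curation.removals:
        if gene_id not in records:
            warnings.warn(f"curation removal of absent gene {gene_id!r}", stacklevel=2)
    for gene_id, note, override in sorted(
        curation.additions, key=lambda t: (t[0], t[1])
    ):
        group = override if override is not None else DEFAULT_ADDITION_GROUP
        if gene_id in out:
            out[gene_id] = replace(out[gene_id], provenance="curated_addition", note=note)
        else:
            out[gene_id] = RBPRecord(
                gene_id=gene_id,
                assigned_group=group,
                provenance="curated_addition",
                note=note,
            )
    return out


def build_compendium(
    scan_path: PathLike,
    gene_model: Union[pd.DataFrame, PathLike],
    catalog: Optional[Sequence[RBDCatalogEntry]] = None,
    curation: Optional[CurationList] = None,
    fasta_path: Optional[PathLike] = None,
    priority: Sequence[int] = DEFAULT_GROUP_PRIORITY,
) -> tuple[dict[str, RBPRecord], dict[str, int]]:
    """Run the full prediction pipeline.

    Returns ``(records, stage_log)`` where ``stage_log`` records counts at
    each stage (hits parsed, hits after application filter, proteins with
    RBDs, genes before/after curation).
    """
    if not isinstance(gene_model, pd.DataFrame):
        gene_model = read_gene_model(gene_model)
    if catalog is None:
        catalog = default_catalog()
    lengths = read_protein_lengths(fasta_path) if fasta_path else None
    hits = parse_interproscan(scan_path, gene_model, protein_lengths=lengths)
    filtered = filter_by_application(hits)
    protein_rbds = map_to_rbds(filtered, catalog)
    gene_rbds = collapse_to_genes(protein_rbds, gene_model)

    gene_proteins: dict[str, set[str]] = {}
    gene_apps: dict[str, set[str]] = {}
    matched_proteins = set(protein_rbds)
    for hit in filtered:
        if hit.protein_id in matched_proteins and hit.gene_id is not None:
            gene_proteins.setdefault(hit.gene_id, set()).add(hit.protein_id)
            gene_apps.setdefault(hit.gene_id, set()).add(hit.application)

    records = {
        gene_id: RBPRecord(
            gene_id=gene_id,
            protein_ids=gene_proteins.get(gene_id, set()),
            rbds=rbds,
            assigned_group=assign_group(rbds, priority),
            provenance="scan",
            applications_detected=gene_apps.get(gene_id, set()),
        )
        for gene_id, rbds in gene_rbds.items()
    }
    log = {
        "hits_parsed": len(hits),
        "hits_after_application_filter": len(filtered),
        "proteins_with_rbds": len(protein_rbds),
        "genes_before_curation": len(records),
    }
    if curation is not None:
        records = apply_curation(records, curation)
    log["genes_final"] = len(records)
    return records, log


def compare_gene_sets(set_a: set[str], set_b: set[str]) -> dict[str, float]:
    """Exact overlap report between two gene sets (fractions both ways)."""
    inter = set_a & set_b
    return {
        "size_a": len(set_a),
        "size_b": len(set_b),
        "intersection": len(inter),
        "fraction_of_a": len(inter) / len(set_a) if set_a else 0.0,
        "fraction_of_b": len(inter) / len(set_b) if set_b else 0.0,
    }


# --- serialisation -----------------------------------------------------------

def compendium_to_frame(records: Mapping[str, RBPRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "group": r.assigned_group,
            "rbds": ";".join(f"{n}:{g}" for n, g in sorted(r.rbds)),
            "provenance": r.provenance,
            "applications": ";".join(sorted(r.applications_detected)),
            "protein_ids": ";".join(sorted(r.protein_ids)),
            "note": r.note,
        }
        for r in records.values()
    ]
    return (
        pd.DataFrame(
            rows,
            columns=[
                "gene_id", "group", "rbds", "provenance",
                "applications", "protein_ids", "note",
            ],
        )
        .sort_values("gene_id")
        .reset_index(drop=True)
    )


def write_compendium(records: Mapping[str, RBPRecord], path: PathLike) -> None:
    compendium_to_frame(records).to_csv(path, sep="\t", index=False)


def read_compendium(path: PathLike) -> dict[str, RBPRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: dict[str, RBPRecord] = {}
    for row in df.itertuples():
        rbds = set()
        if row.rbds:
            for token in row.rbds.split(";"):
                name, group = token.rsplit(":", 1)
                rbds.add((name, int(group)))
        records[row.gene_id] = RBPRecord(
            gene_id=row.gene_id,
            protein_ids=set(row.protein_ids.split(";")) if row.protein_ids else set(),
            rbds=rbds,
            assigned_group=int(row.group),
            provenance=row.provenance,
            applications_detected=(
                set(row.applications.split(";")) if row.applications else set()
            ),
            note=row.note,
        )
    return records


def rbp_gene_set(records: Mapping[str, RBPRecord], group: Optional[int] = None) -> set[str]:
    """Gene ids in the compendium, optionally restricted to one group."""
    if group is None:
        return set(records)
    return {g for g, r in records.items() if r.assigned_group == group}
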