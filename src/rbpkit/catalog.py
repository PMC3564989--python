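"""RNA-binding-domain (RBD) catalog and the four-group classification scheme.

The catalog is the curated list of 17 protein domain families taken as
evidence of RNA binding.  Each entry carries a group label:

* group 1 — sequence/structure-specific RNA binding (gene-specific RBPs),
  e.g. KH, RRM, CCCH zinc finger, dsRBD;
* group 2 — gene-specific binding whose specificity is not inherent to the
  domain itself (helicase, PAZ, PIWI, NTF2 — e.g. argonautes, which are
  targeted by the miRNA they carry);
* group 3 — putatively specific domains that can also bind DNA or protein
  (C2H2 zinc finger, SAM, ...), so the RNA-binding prediction is ambiguous;
* group 4 — general (non-gene-specific) RNA-binding machinery such as core
  splicing and ribosome-associated domains.

Group-2 membership and the named group-1/3 exemplars are fixed; the
remaining entries are reasonable defaults and are meant to be edited — the
catalog round-trips through a plain TSV so users can substitute their own
accession lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "RBDCatalogEntry",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "validate_catalog",
    "CatalogError",
]

#: wildcard application marker in match patterns
ANY_APPLICATION = "*"


class CatalogError(ValueError):
    """Raised for ambiguous or malformed catalogs."""


@dataclass(frozen=True)
class RBDCatalogEntry:
    """One RNA-binding domain family in the catalog.

    ``match_patterns`` is a set of ``(application, pattern)`` pairs.  A
    domain hit matches the entry when its accession equals ``pattern`` under
    the stated application, or — for ``application == "*"`` — when the hit's
    domain *name* equals ``pattern`` case-insensitively.
    """

    rbd_name: str
    group: int
    match_patterns: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    sequence_specific: bool = False

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3, 4):
            raise CatalogError(f"group must be 1-4, got {self.group!r} for {self.rbd_name}")


def _entry(name: str, group: int, pfam: str, specific: bool) -> RBDCatalogEntry:
    return RBDCatalogEntry(
        rbd_name=name,
        group=group,
        match_patterns=frozenset({("Pfam", pfam), (ANY_APPLICATION, name)}),
        sequence_specific=specific,
    )


# 17 entries: 8 + 4 + 3 + 2.  Group 2 membership (helicase, PAZ, PIWI, NTF2)
# and the named exemplars (KH, RRM, CCCH, dsRBD; C2H2, SAM) are authoritative;
# the rest are editable defaults pending a project-specific accession list.
_DEFAULT_ENTRIES: tuple[RBDCatalogEntry, ...] = (
    # group 1 — sequence-specific
    _entry("RRM", 1, "PF00076", True),
    _entry("KH", 1, "PF00013", True),
    _entry("PUF", 1, "PF00806", True),
    _entry("CCCH", 1, "PF00642", True),
    _entry("dsRBD", 1, "PF00035", True),
    _entry("CSD", 1, "PF00313", True),
    _entry("La", 1, "PF05383", True),
    _entry("CCHC", 1, "PF00098", True),
    # group 2 — gene-specific, specificity extrinsic to the domain
    _entry("helicase", 2, "PF00270", False),
    _entry("PAZ", 2, "PF02170", False),
    _entry("PIWI", 2, "PF02171", False),
    _entry("NTF2", 2, "PF02136", False),
    # group 3 — putatively specific (may bind DNA/protein instead)
    _entry("C2H2", 3, "PF00096", True),
    _entry("SAM", 3, "PF00536", True),
    _entry("R3H", 3, "PF01424", True),
    # group 4 — general machinery
    _entry("LSM", 4, "PF01423", False),
    _entry("S1", 4, "PF00575", False),
)


def default_catalog() -> list[RBDCatalogEntry]:
    """Return the default 17-entry RBD catalog."""
    return list(_DEFAULT_ENTRIES)


def validate_catalog(catalog: Iterable[RBDCatalogEntry]) -> list[RBDCatalogEntry]:
    """Check a catalog for ambiguity.

    No ``(application, pattern)`` pair — and in particular no accession —
    may map to two different entries; an ambiguous catalog is a
    configuration error, raised at load time rather than during matching.
    """
    catalog = list(catalog)
    seen: dict[tuple[str, str], str] = {}
    names: set[str] = set()
    for entry in catalog:
        if entry.rbd_name in names:
            raise CatalogError(f"duplicate catalog entry name {entry.rbd_name!r}")
        names.add(entry.rbd_name)
        for app, pattern in entry.match_patterns:
            key = (app, pattern.lower() if app == ANY_APPLICATION else pattern)
            if key in seen and seen[key] != entry.rbd_name:
                raise CatalogError(
                    f"ambiguous catalog: pattern {pattern!r} ({app}) in both "
                    f"{seen[key]!r} and {entry.rbd_name!r}"
                )
            seen[key] = entry.rbd_name
    return catalog


def save_catalog(catalog: Iterable[RBDCatalogEntry], path: Union[str, Path]) -> None:
    """Write a catalog to TSV (one row per match pattern)."""
    rows = []
    for entry in catalog:
        for app, pattern in sorted(entry.match_patterns):
            rows.append(
                {
                    "rbd_name": entry.rbd_name,
                    "group": entry.group,
                    "application": app,
                    "pattern": pattern,
                    "sequence_specific": entry.sequence_specific,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_catalog(path: Union[str, Path]) -> list[RBDCatalogEntry]:
    """Read a catalog TSV written by :func:`save_catalog` (or hand-edited).

    Raises :class:`CatalogError` if any pattern is claimed by two entries.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rbd_name", "group", "application", "pattern", "sequence_specific"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog file missing columns: {sorted(missing)}")
    entries = []
    for (name, group, specific), sub in df.groupby(
        ["rbd_name", "group", "sequence_specific"], sort=False
    ):
        entries.append(
            RBDCatalogEntry(
                rbd_name=str(name),
                group=int(group),
                match_patterns=frozenset(
                    (str(r.application), str(r.pattern)) for r in sub.itertuples()
                ),
                sequence_specific=str(specific).strip().lower() in ("true", "1", "yes"),
            )
        )
    return validate_catalog(entries)
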