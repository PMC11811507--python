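"""Disease marker lists and metabolite→enzyme maps.

Two per-disease gene-marker lists are partitioned into disease-specific
and shared sets; significant metabolites are mapped to the enzymes that
synthesise or degrade them via a frozen lookup table (a reproducible
stand-in for a live KEGG/HMDB extraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError

GROUP_A_ONLY = "A_specific"
GROUP_B_ONLY = "B_specific"
GROUP_SHARED = "shared"
MARKER_GROUPS = (GROUP_A_ONLY, GROUP_B_ONLY, GROUP_SHARED)

ENZYME_ROLES = ("biosynthesis", "degradation")
ENZYME_CLASSES = ("amino_acid_metabolism", "acylcarnitine_metabolism")

ENZYME_MAP_COLUMNS = (
    "metabolite_id",
    "enzyme_protein_id",
    "enzyme_gene_id",
    "role",
    "enzyme_class",
)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: trimmed, upper-cased."""
    return symbol.strip().upper()


def read_marker_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line marker list (``#`` comments allowed)."""
    symbols: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            sym = normalize_symbol(line)
            if sym in seen:
                warnings.warn(f"{path}: duplicate marker {sym!r} collapsed")
                continue
            seen.add(sym)
            symbols.append(sym)
    return symbols


def write_marker_list(symbols: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")
    return path


@dataclass(frozen=True)
class MarkerPartition:
    """Disease-A-only / disease-B-only / shared marker sets."""

    A_only: frozenset[str]
    B_only: frozenset[str]
    shared: frozenset[str]

    def group_of(self, marker: str) -> str | None:
        m = normalize_symbol(marker)
        if m in self.A_only:
            return GROUP_A_ONLY
        if m in self.B_only:
            return GROUP_B_ONLY
        if m in self.shared:
            return GROUP_SHARED
        return None

    def all_markers(self) -> frozenset[str]:
        return self.A_only | self.B_only | self.shared

    def sizes(self) -> dict[str, int]:
        return {
            GROUP_A_ONLY: len(self.A_only),
            GROUP_B_ONLY: len(self.B_only),
            GROUP_SHARED: len(self.shared),
        }

    def to_dict(self) -> dict[str, list[str]]:
        return {
            GROUP_A_ONLY: sorted(self.A_only),
            GROUP_B_ONLY: sorted(self.B_only),
            GROUP_SHARED: sorted(self.shared),
        }


def partition_markers(listA: Sequence[str], listB: Sequence[str]) -> MarkerPartition:
    """Split two marker lists into A-only, B-only and shared sets.

    Identifiers are normalised (trimmed, upper-cased); duplicates within a
    list collapse with a warning, since marker lists are treated as sets.
    """
    if not listA or not listB:
        raise ConfigurationError("marker lists must be non-empty")
    setA = _as_set(listA, "list A")
    setB = _as_set(listB, "list B")
    shared = setA & setB
    return MarkerPartition(
        A_only=frozenset(setA - shared),
        B_only=frozenset(setB - shared),
        shared=frozenset(shared),
    )


def _as_set(symbols: Sequence[str], label: str) -> frozenset[str]:
    normalized = [normalize_symbol(s) for s in symbols]
    if len(set(normalized)) != len(normalized):
        dups = sorted({s for s in normalized if normalized.count(s) > 1})
        warnings.warn(f"duplicate symbols in {label} collapsed: {dups}")
    return frozenset(normalized)


@dataclass
class EnzymeMap:
    """Metabolite → conversion-enzyme records.

    One row per (metabolite, enzyme protein, role) with the encoding gene
    and the enzyme's metabolic class (amino-acid vs acylcarnitine
    metabolism).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENZYME_MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"enzyme map lacks column(s): {missing}")
        t = self.table
        if t["enzyme_protein_id"].eq("").any() or t["enzyme_protein_id"].isna().any():
            raise FormatError("enzyme map contains an empty enzyme id")
        bad_role = t[~t["role"].isin(ENZYME_ROLES)]
        if len(bad_role):
            raise FormatError(
                f"unknown role {bad_role['role'].iloc[0]!r}; allowed: {ENZYME_ROLES}"
            )
        bad_cls = t[~t["enzyme_class"].isin(ENZYME_CLASSES)]
        if len(bad_cls):
            raise FormatError(
                f"unknown enzyme class {bad_cls['enzyme_class'].iloc[0]!r}; "
                f"allowed: {ENZYME_CLASSES}"
            )
        key = t[["metabolite_id", "enzyme_protein_id", "role"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate enzyme-map record: {dup}")

    # -- queries ----------------------------------------------------------
    def metabolites(self) -> set[str]:
        return set(self.table["metabolite_id"])

    def enzymes(self) -> set[str]:
        return set(self.table["enzyme_protein_id"])

    def class_of(self, enzyme_protein_id: str) -> str | None:
        rows = self.table[self.table["enzyme_protein_id"] == enzyme_protein_id]
        if rows.empty:
            return None
        return rows["enzyme_class"].iloc[0]

    def gene_of(self, enzyme_protein_id: str) -> str | None:
        rows = self.table[self.table["enzyme_protein_id"] == enzyme_protein_id]
        if rows.empty:
            return None
        return rows["enzyme_gene_id"].iloc[0]

    def validate_against_panel(self, metabolite_ids: Iterable[str]) -> None:
        vocab = set(metabolite_ids)
        unknown = sorted(self.metabolites() - vocab)
        if unknown:
            raise FormatError(
                f"enzyme map references metabolites outside the panel: {unknown}"
            )


def read_enzyme_map(path: str | Path) -> EnzymeMap:
    """Read the five-column enzyme-map TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return EnzymeMap(df)


def write_enzyme_map(emap: EnzymeMap, path: str | Path) -> Path:
    path = Path(path)
    emap.table.sort_values(list(ENZYME_MAP_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return path


def default_enzyme_map() -> EnzymeMap:
    """The enzyme map shipped with the package (synthetic stand-in)."""
    from importlib import resources

    with resources.as_file(
        resources.files("metaboreg") / "data" / "enzyme_map_synthetic.tsv"
    ) as p:
        return read_enzyme_map(p)


def enzymes_for_metabolites(
    significant: Iterable[str], emap: EnzymeMap
) -> tuple[pd.DataFrame, list[str]]:
    """Deduplicated union of conversion enzymes over significant metabolites.

    Returns ``(enzymes, unmapped)``: one row per enzyme protein with its
    gene, class, and the sorted metabolites it converts, plus the list of
    significant metabolites with no mapping (reported, never silently
    dropped).
    """
    sig = sorted(set(significant))
    hit = emap.table[emap.table["metabolite_id"].isin(sig)]
    unmapped = sorted(set(sig) - set(hit["metabolite_id"]))
    if hit.empty:
        empty = pd.DataFrame(
            columns=["enzyme_protein_id", "enzyme_gene_id", "enzyme_class",
                     "metabolites"]
        )
        return empty, unmapped
    grouped = (
        hit.groupby("enzyme_protein_id", sort=True)
        .agg(
            enzyme_gene_id=("enzyme_gene_id", "first"),
            enzyme_class=("enzyme_class", "first"),
            metabolites=("metabolite_id", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return grouped, unmapped
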