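"""Metabolite concentration panels: the container, readers/writers, validation.

The canonical layout is *wide*: one row per sample, a ``sample_id`` column,
a group column, then one numeric column per metabolite (concentrations in
µM).  Group labels are canonicalised to ``diseaseA`` / ``diseaseB`` /
``control`` via a configurable alias map (``PD`` → diseaseA, ``VP`` →
diseaseB by default, mirroring the two-parkinsonism study design this
package targets).  Metabolite classes (amino acid vs acylcarnitine) come
from a sidecar mapping or, by default, from the panel naming convention:
``C``-number names (C0, C2, …, C18:1) are acylcarnitines, everything else
is an amino acid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

GROUP_CONTROL = "control"
GROUP_A = "diseaseA"
GROUP_B = "diseaseB"
VALID_GROUPS = (GROUP_A, GROUP_B, GROUP_CONTROL)

CLASS_AMINO_ACID = "amino_acid"
CLASS_ACYLCARNITINE = "acylcarnitine"
VALID_CLASSES = (CLASS_AMINO_ACID, CLASS_ACYLCARNITINE)

#: Default aliases for group labels found in input tables (case-insensitive).
DEFAULT_GROUP_ALIASES: dict[str, str] = {
    "pd": GROUP_A,
    "parkinson": GROUP_A,
    "parkinsons": GROUP_A,
    "diseasea": GROUP_A,
    "a": GROUP_A,
    "vp": GROUP_B,
    "vascular": GROUP_B,
    "diseaseb": GROUP_B,
    "b": GROUP_B,
    "control": GROUP_CONTROL,
    "ctrl": GROUP_CONTROL,
    "healthy": GROUP_CONTROL,
}

_ACYLCARNITINE_RE = re.compile(r"^C\d")


def infer_metabolite_class(metabolite_id: str) -> str:
    """Classify a metabolite id by the targeted-panel naming convention.

    Acylcarnitines are named by acyl chain (``C0``, ``C5:1``, ``C16OH`` …);
    amino acids carry three-letter codes (``Ala``, ``Pro`` …).
    """
    return (
        CLASS_ACYLCARNITINE
        if _ACYLCARNITINE_RE.match(metabolite_id.strip())
        else CLASS_AMINO_ACID
    )


@dataclass
class MetaboliteProfileSet:
    """Samples × metabolites concentration matrix with group labels.

    Parameters
    ----------
    concentrations:
        DataFrame indexed by sample id, one column per metabolite (µM).
        Missing measurements are NaN, never zero.
    groups:
        Series mapping sample id → canonical group label.
    classes:
        Series mapping metabolite id → metabolite class.
    """

    concentrations: pd.DataFrame
    groups: pd.Series
    classes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.classes is None:
            self.classes = pd.Series(
                {m: infer_metabolite_class(m) for m in self.concentrations.columns},
                name="class",
            )
        self.groups = self.groups.reindex(self.concentrations.index)
        self.classes = self.classes.reindex(self.concentrations.columns)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.concentrations.index
        cols = self.concentrations.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate metabolite ids: {dups}")
        bad = self.groups[~self.groups.isin(VALID_GROUPS)]
        if len(bad):
            raise FormatError(
                f"unknown group label(s) {sorted(set(bad.dropna().astype(str)))} "
                f"for sample(s) {bad.index.tolist()}; allowed: {VALID_GROUPS}"
            )
        badc = self.classes[~self.classes.isin(VALID_CLASSES)]
        if len(badc):
            raise FormatError(
                f"unknown metabolite class for {badc.index.tolist()}; "
                f"allowed: {VALID_CLASSES}"
            )
        values = self.concentrations.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if (values < 0).any():
                rows, cols_ = np.nonzero(values < 0)
                loc = (idx[rows[0]], self.concentrations.columns[cols_[0]])
                raise FormatError(f"negative concentration at {loc}")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.concentrations.shape[1]

    def group_matrix(self, group: str) -> pd.DataFrame:
        """Concentration rows of one group (samples × metabolites)."""
        return self.concentrations.loc[self.groups == group]

    def metabolites_of_class(self, cls: str) -> list[str]:
        return list(self.classes[self.classes == cls].index)

    def equals(self, other: "MetaboliteProfileSet", rtol: float = 1e-9) -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if not self.groups.equals(other.groups):
            return False
        a = self.concentrations.to_numpy(dtype=float)
        b = other.concentrations.to_numpy(dtype=float)
        return bool(np.allclose(a, b, rtol=rtol, equal_nan=True))


def _text_header(path: Path, sep: str) -> list[str]:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        return next(csv.reader(fh, delimiter=sep))


def _canonical_group(raw: object, aliases: Mapping[str, str]) -> str | None:
    key = str(raw).strip().lower()
    if key in aliases:
        return aliases[key]
    if str(raw).strip() in VALID_GROUPS:
        return str(raw).strip()
    return None


def read_class_sidecar(path: str | Path) -> pd.Series:
    """Read a two-column ``metabolite_id<TAB>class`` sidecar file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["metabolite_id", "class"],
                     comment="#", dtype=str)
    df["metabolite_id"] = df["metabolite_id"].str.strip()
    df["class"] = df["class"].str.strip()
    bad = df[~df["class"].isin(VALID_CLASSES)]
    if len(bad):
        raise FormatError(
            f"{path}: unknown class {bad['class'].iloc[0]!r} on line "
            f"{bad.index[0] + 1}; allowed: {VALID_CLASSES}"
        )
    return df.set_index("metabolite_id")["class"]


def read_profiles(
    path: str | Path,
    format: str | None = None,
    group_column: str = "group",
    class_map: Mapping[str, str] | str | Path | None = None,
    group_aliases: Mapping[str, str] | None = None,
    sample_column: str = "sample_id",
) -> MetaboliteProfileSet:
    """Read a wide concentration table (CSV/TSV/XLSX) into a profile set.

    A transposed layout (metabolites as rows) is auto-detected when the
    group column appears as a row label instead of a column header.
    Non-numeric concentration cells raise :class:`FormatError` naming the
    offending row and column; empty cells become NaN (missing, not zero).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        header = _text_header(path, ",")
        raw = pd.read_csv(path, dtype=str)
    elif fmt == "tsv":
        header = _text_header(path, "\t")
        raw = pd.read_csv(path, sep="\t", dtype=str)
    elif fmt == "xlsx":
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True)
        header = [str(c) for c in next(wb.worksheets[0].iter_rows(
            min_row=1, max_row=1, values_only=True)) if c is not None]
        wb.close()
        raw = pd.read_excel(path, sheet_name=0, dtype=str)
    else:
        raise FormatError(f"unsupported format {fmt!r}; use csv, tsv or xlsx")
    # pandas renames duplicate headers (X, X.1), so check the raw header
    dup_header = sorted({h for h in header if header.count(h) > 1})
    if dup_header:
        raise FormatError(f"{path}: duplicated column(s): {dup_header}")

    first_col = raw.columns[0]
    if group_column not in raw.columns and raw[first_col].eq(group_column).any():
        # transposed layout: metabolites are rows, samples are columns
        raw = raw.set_index(first_col).T.reset_index(names=sample_column)
        raw.columns.name = None
    if group_column not in raw.columns:
        raise FormatError(f"{path}: group column {group_column!r} not found")
    if sample_column not in raw.columns:
        raise FormatError(f"{path}: sample column {sample_column!r} not found")

    aliases = dict(DEFAULT_GROUP_ALIASES)
    if group_aliases:
        aliases.update({k.strip().lower(): v for k, v in group_aliases.items()})

    sample_ids = raw[sample_column].astype(str).str.strip()
    if sample_ids.duplicated().any():
        dup = sample_ids[sample_ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    groups = []
    for i, g in enumerate(raw[group_column]):
        canon = _canonical_group(g, aliases)
        if canon is None:
            raise FormatError(
                f"{path}: unknown group label {g!r} for sample "
                f"{sample_ids.iloc[i]!r}; allowed (after aliasing): {VALID_GROUPS}"
            )
        groups.append(canon)

    met_cols = [c for c in raw.columns if c not in (sample_column, group_column)]
    if len(set(met_cols)) != len(met_cols):
        seen, dups = set(), []
        for c in met_cols:
            if c in seen:
                dups.append(c)
            seen.add(c)
        raise FormatError(f"{path}: duplicated metabolite column(s): {sorted(set(dups))}")

    conc = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for col in met_cols:
        cells = raw[col]
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = numeric.isna() & cells.notna() & (cells.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric concentration {cells.iloc[row]!r} in "
                f"column {col!r}, sample {sample_ids.iloc[row]!r}"
            )
        conc[col] = numeric.to_numpy(dtype=float)

    if class_map is None:
        classes = None
    elif isinstance(class_map, (str, Path)):
        classes = read_class_sidecar(class_map)
    else:
        classes = pd.Series(dict(class_map))
    if classes is not None:
        missing = [m for m in met_cols if m not in classes.index]
        if missing:
            raise FormatError(f"{path}: metabolites missing from class map: {missing}")
        classes = classes.reindex(met_cols)

    return MetaboliteProfileSet(
        concentrations=conc,
        groups=pd.Series(groups, index=conc.index, name="group"),
        classes=classes,
    )


def write_profiles(
    profiles: MetaboliteProfileSet,
    path: str | Path,
    format: str | None = None,
    group_column: str = "group",
    float_format: str = "%.12g",
) -> Path:
    """Write a profile set in the wide layout consumed by :func:`read_profiles`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    out = profiles.concentrations.copy()
    out.insert(0, group_column, profiles.groups)
    out.index.name = "sample_id"
    if fmt == "csv":
        out.to_csv(path, float_format=float_format)
    elif fmt == "tsv":
        out.to_csv(path, sep="\t", float_format=float_format)
    elif fmt == "xlsx":
        out.to_excel(path)
    else:
        raise FormatError(f"unsupported format {fmt!r}; use csv, tsv or xlsx")
    return path


def write_class_sidecar(profiles: MetaboliteProfileSet, path: str | Path) -> Path:
    path = Path(path)
    profiles.classes.rename("class").rename_axis("metabolite_id").to_csv(
        path, sep="\t", header=False
    )
    return path


def summarize_panel(profiles: MetaboliteProfileSet) -> dict:
    """Panel composition summary: counts per class, per group, missingness."""
    class_counts = profiles.classes.value_counts().to_dict()
    group_counts = profiles.groups.value_counts().to_dict()
    n_missing = int(profiles.concentrations.isna().to_numpy().sum())
    total = profiles.n_samples * profiles.n_metabolites
    return {
        "n_samples": profiles.n_samples,
        "n_metabolites": profiles.n_metabolites,
        "n_per_class": {c: int(class_counts.get(c, 0)) for c in VALID_CLASSES},
        "n_per_group": {g: int(group_counts.get(g, 0)) for g in VALID_GROUPS},
        "n_missing_cells": n_missing,
        "missing_fraction": (n_missing / total) if total else 0.0,
    }
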