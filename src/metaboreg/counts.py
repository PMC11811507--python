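"""Pathway-count matrices: marker × enzyme tallies with group/class margins."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .markers import EnzymeMap, MarkerPartition
from .templates import RegulatoryPath

UNASSIGNED = "unassigned"


@dataclass
class PathwayCountMatrix:
    """Marker × enzyme pathway counts plus marker-group / enzyme-class labels.

    ``counts`` is a non-negative integer DataFrame (rows = markers,
    columns = enzyme proteins); ``marker_group`` maps each row to
    {A_specific, B_specific, shared, unassigned} and ``enzyme_class`` each
    column to {amino_acid_metabolism, acylcarnitine_metabolism,
    unassigned}.
    """

    counts: pd.DataFrame
    marker_group: pd.Series
    enzyme_class: pd.Series

    def __post_init__(self) -> None:
        self.marker_group = self.marker_group.reindex(self.counts.index)
        self.enzyme_class = self.enzyme_class.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pathway counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def per_marker_by_class(self) -> pd.DataFrame:
        """Per marker, counts split by enzyme class (histogram content)."""
        out = self.counts.T.groupby(self.enzyme_class).sum().T
        out = out.reindex(sorted(out.columns), axis=1).fillna(0).astype(int)
        total = out.sum(axis=1)
        out = out.loc[total.sort_values(ascending=False, kind="stable").index]
        return out

    def per_enzyme_by_group(self) -> pd.DataFrame:
        """Per enzyme, counts split by marker group (specificity content)."""
        out = self.counts.groupby(self.marker_group).sum().T
        out = out.reindex(sorted(out.columns), axis=1).fillna(0).astype(int)
        return out.sort_index()


def count_paths(
    paths: Sequence[RegulatoryPath],
    marker_groups: MarkerPartition | None = None,
    enzyme_classes: EnzymeMap | None = None,
    dedupe: str = "paths",
) -> PathwayCountMatrix:
    """Tally enumerated paths into a marker × enzyme count matrix.

    ``dedupe='paths'`` counts every distinct path (the default);
    ``dedupe='pairs'`` counts each (marker, enzyme) pair at most once.
    Markers/enzymes without an annotation are tallied under
    ``unassigned`` with a warning.
    """
    if dedupe not in ("paths", "pairs"):
        raise ValueError(f"dedupe must be 'paths' or 'pairs', got {dedupe!r}")
    pairs = [(p.marker, p.enzyme) for p in paths]
    if dedupe == "pairs":
        pairs = sorted(set(pairs))
    markers = sorted({m for m, _ in pairs})
    enzymes = sorted({e for _, e in pairs})
    counts = pd.DataFrame(0, index=pd.Index(markers, name="marker"),
                          columns=pd.Index(enzymes, name="enzyme"), dtype=int)
    for m, e in pairs:
        counts.loc[m, e] += 1

    group = {}
    for m in markers:
        g = marker_groups.group_of(m) if marker_groups is not None else None
        if g is None:
            warnings.warn(f"marker {m!r} has no group annotation; 'unassigned'")
            g = UNASSIGNED
        group[m] = g
    cls = {}
    for e in enzymes:
        c = enzyme_classes.class_of(e) if enzyme_classes is not None else None
        if c is None:
            warnings.warn(f"enzyme {e!r} has no class annotation; 'unassigned'")
            c = UNASSIGNED
        cls[e] = c
    return PathwayCountMatrix(
        counts=counts,
        marker_group=pd.Series(group, name="marker_group", dtype=object),
        enzyme_class=pd.Series(cls, name="enzyme_class", dtype=object),
    )


def paths_to_table(paths: Sequence[RegulatoryPath]) -> pd.DataFrame:
    """One row per path: template, marker, enzyme, node chain, edge chain."""
    return pd.DataFrame(
        {
            "template": [p.template_id for p in paths],
            "marker": [p.marker for p in paths],
            "enzyme": [p.enzyme for p in paths],
            "n_edges": [len(p) for p in paths],
            "nodes": ["->".join(p.nodes) for p in paths],
            "edge_types": ["->".join(p.edge_types) for p in paths],
            "signs": ["->".join(p.signs) for p in paths],
        }
    )
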