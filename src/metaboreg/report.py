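"""Summary artifacts: per-marker histograms, per-enzyme group counts,
enzyme-specificity calls, and the run report bundle.

"Specificity" of an enzyme for a marker group is operationalised as a
dominant-group rule: the group contributing the most pathways wins the
call if its count is at least ``min_count`` and exceeds the runner-up by
a factor of at least ``min_margin``; ties and sub-threshold margins give
``mixed``.  The rule and its parameters are recorded in every run
manifest.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .counts import PathwayCountMatrix
from .errors import PipelineError
from .markers import MarkerPartition
from .screening import ScreeningResult

MIXED = "mixed"


@dataclass(frozen=True)
class EnzymeSpecificityCall:
    enzyme: str
    counts: dict  # marker group -> pathway count
    dominant_group: str  # a marker group, or "mixed"
    margin_ratio: float  # top count / max(1, second count)


def marker_histogram(matrix: PathwayCountMatrix) -> pd.DataFrame:
    """Per marker, pathway counts split by enzyme class, sorted by total.

    This is the machine-readable content behind the per-disease histogram
    figures: one row per marker, one column per enzyme class, plus a
    ``total`` column; rows in descending total order.
    """
    out = matrix.per_marker_by_class()
    out["total"] = out.sum(axis=1)
    return out


def classify_enzyme_specificity(
    matrix: PathwayCountMatrix,
    min_margin: float = 1.5,
    min_count: int = 1,
) -> list[EnzymeSpecificityCall]:
    """Dominant-marker-group call per enzyme (ties → ``mixed``)."""
    per_enzyme = matrix.per_enzyme_by_group()
    calls = []
    for enzyme, row in per_enzyme.iterrows():
        counts = {str(g): int(c) for g, c in row.items()}
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_group, top = ordered[0]
        second = ordered[1][1] if len(ordered) > 1 else 0
        tie = len(ordered) > 1 and ordered[1][1] == top
        ratio = top / max(1, second)
        if top >= min_count and not tie and ratio >= min_margin:
            dominant = top_group
        else:
            dominant = MIXED
        calls.append(
            EnzymeSpecificityCall(
                enzyme=str(enzyme), counts=counts,
                dominant_group=dominant, margin_ratio=ratio,
            )
        )
    return sorted(calls, key=lambda c: c.enzyme)


def specificity_table(calls: Sequence[EnzymeSpecificityCall]) -> pd.DataFrame:
    groups = sorted({g for c in calls for g in c.counts})
    rows = []
    for c in calls:
        row = {"enzyme": c.enzyme}
        row.update({g: c.counts.get(g, 0) for g in groups})
        row["dominant_group"] = c.dominant_group
        row["margin_ratio"] = c.margin_ratio
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    outdir: str | Path,
    screening: ScreeningResult | None = None,
    partition: MarkerPartition | None = None,
    matrix: PathwayCountMatrix | None = None,
    calls: Sequence[EnzymeSpecificityCall] | None = None,
    settings: dict | None = None,
    figures: bool = False,
) -> dict:
    """Write the report bundle (tables, manifest, optional figures).

    Every figure's underlying numbers are written as TSV first; figures
    are redrawn from those tables, so figure data and table data cannot
    diverge.  The manifest contains only run settings and content hashes
    (no timestamps), so re-running an identical configuration is
    byte-identical.
    """
    required = {"screening": screening, "partition": partition, "matrix": matrix}
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise PipelineError(f"render_report missing stage output(s): {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    screening.table.to_csv(outdir / "screening.tsv", sep="\t", index=False,
                           float_format="%.12g")
    written["screening"] = "screening.tsv"
    with open(outdir / "classification.json", "w", encoding="utf-8") as fh:
        json.dump(screening.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["classification"] = "classification.json"

    with open(outdir / "marker_partition.json", "w", encoding="utf-8") as fh:
        json.dump(partition.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["partition"] = "marker_partition.json"

    hist = marker_histogram(matrix)
    if hist.empty:
        (outdir / "marker_histograms.tsv").write_text(
            "# no pathways enumerated\n", encoding="utf-8"
        )
    else:
        hist.rename_axis("marker").to_csv(outdir / "marker_histograms.tsv", sep="\t")
    written["marker_histograms"] = "marker_histograms.tsv"

    per_enzyme = matrix.per_enzyme_by_group()
    if per_enzyme.empty:
        (outdir / "enzyme_group_counts.tsv").write_text(
            "# no pathways enumerated\n", encoding="utf-8"
        )
    else:
        per_enzyme.rename_axis("enzyme").to_csv(
            outdir / "enzyme_group_counts.tsv", sep="\t"
        )
    written["enzyme_group_counts"] = "enzyme_group_counts.tsv"

    if calls is None:
        calls = classify_enzyme_specificity(matrix)
    spec = specificity_table(calls)
    spec.to_csv(outdir / "specificity_calls.tsv", sep="\t", index=False,
                float_format="%.12g")
    written["specificity_calls"] = "specificity_calls.tsv"

    if figures:
        _draw_figures(outdir, hist, per_enzyme)
        written["figures"] = "figures/"

    manifest = {
        "settings": settings or {},
        "tables": written,
        "totals": {
            "n_paths": matrix.total,
            "n_markers": int(matrix.counts.shape[0]),
            "n_enzymes": int(matrix.counts.shape[1]),
        },
        "hashes": {
            name: _sha256(outdir / fname)
            for name, fname in written.items()
            if not fname.endswith("/")
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _draw_figures(outdir: Path, hist: pd.DataFrame, per_enzyme: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    for name, table in (("marker_histograms", hist.drop(columns=["total"],
                                                        errors="ignore")),
                        ("enzyme_group_counts", per_enzyme)):
        if table.empty:
            continue
        ax = table.plot.bar(figsize=(max(6, 0.4 * len(table)), 4), width=0.8)
        ax.set_ylabel("number of regulatory pathways")
        ax.figure.tight_layout()
        ax.figure.savefig(figdir / f"{name}.png", dpi=120)
        plt.close(ax.figure)
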