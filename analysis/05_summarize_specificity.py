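#!/usr/bin/env python
"""Aggregate pathway counts into the summary artifacts.

From the marker × enzyme pathway-count matrix, writes per-marker
histograms split by enzyme class, per-enzyme counts split by marker
group, and the enzyme-specificity calls (dominant marker group at margin
≥ 1.5) under results/report/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from metaboreg.counts import PathwayCountMatrix
from metaboreg.markers import MarkerPartition, default_enzyme_map
from metaboreg.report import (
    classify_enzyme_specificity,
    marker_histogram,
    specificity_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", type=Path,
                    default=Path("results/pathways/path_counts.tsv"))
    ap.add_argument("--partition", type=Path,
                    default=Path("results/markers/marker_partition.json"))
    ap.add_argument("--min-margin", type=float, default=1.5)
    ap.add_argument("--min-count", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.counts, sep="\t", index_col=0)
    pdict = json.loads(args.partition.read_text())
    part = MarkerPartition(
        frozenset(pdict["A_specific"]), frozenset(pdict["B_specific"]),
        frozenset(pdict["shared"]),
    )
    emap = default_enzyme_map()
    matrix = PathwayCountMatrix(
        counts,
        pd.Series({m: part.group_of(m) or "unassigned" for m in counts.index}),
        pd.Series({e: emap.class_of(e) or "unassigned" for e in counts.columns}),
    )

    hist = marker_histogram(matrix)
    hist.rename_axis("marker").to_csv(args.out / "marker_histograms.tsv", sep="\t")
    matrix.per_enzyme_by_group().rename_axis("enzyme").to_csv(
        args.out / "enzyme_group_counts.tsv", sep="\t"
    )
    calls = classify_enzyme_specificity(
        matrix, min_margin=args.min_margin, min_count=args.min_count
    )
    spec = specificity_table(calls)
    spec.to_csv(args.out / "specificity_calls.tsv", sep="\t", index=False,
                float_format="%.12g")

    print(f"{matrix.total} pathways over {len(calls)} enzymes")
    for group in ("A_specific", "B_specific", "shared", "mixed"):
        named = sorted(c.enzyme for c in calls if c.dominant_group == group)
        if named:
            print(f"  {group}: {', '.join(named)}")


if __name__ == "__main__":
    main()
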