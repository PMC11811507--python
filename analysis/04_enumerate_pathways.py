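#!/usr/bin/env python
"""Enumerate regulatory pathways from marker proteins to enzymes.

Applies the four pathway templates (direct protein-level regulation,
expression regulation of the enzyme gene, and both again through one
automatically discovered intermediate protein) to the knowledge graph,
and writes the path list plus the marker × enzyme count matrix under
results/pathways/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from metaboreg.counts import count_paths, paths_to_table
from metaboreg.kgraph import read_graph
from metaboreg.markers import MarkerPartition, default_enzyme_map
from metaboreg.templates import default_templates, enumerate_all_templates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--graph", type=Path, default=Path("results/inputs/graph.tsv"))
    ap.add_argument("--partition", type=Path,
                    default=Path("results/markers/marker_partition.json"))
    ap.add_argument("--enzymes", type=Path,
                    default=Path("results/markers/enzymes.tsv"))
    ap.add_argument("--max-intermediates", type=int, default=1)
    ap.add_argument("--dedupe", default="paths", choices=["paths", "pairs"])
    ap.add_argument("--out", type=Path, default=Path("results/pathways"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    graph = read_graph(args.graph)
    pdict = json.loads(args.partition.read_text())
    part = MarkerPartition(
        frozenset(pdict["A_specific"]), frozenset(pdict["B_specific"]),
        frozenset(pdict["shared"]),
    )
    enzymes = sorted(pd.read_csv(args.enzymes, sep="\t")["enzyme_protein_id"])
    templates = default_templates(args.max_intermediates)
    paths = enumerate_all_templates(
        graph, templates, sorted(part.all_markers()), enzymes,
        max_intermediates=args.max_intermediates,
    )
    paths_to_table(paths).to_csv(args.out / "paths.tsv", sep="\t", index=False)
    matrix = count_paths(paths, part, default_enzyme_map(), dedupe=args.dedupe)
    matrix.counts.rename_axis("marker").to_csv(args.out / "path_counts.tsv",
                                               sep="\t")

    per_template = paths_to_table(paths)["template"].value_counts().sort_index()
    print(f"{len(paths)} regulatory pathways from "
          f"{matrix.counts.shape[0]} markers to {matrix.counts.shape[1]} enzymes")
    for tid, n in per_template.items():
        print(f"  {tid}: {n}")


if __name__ == "__main__":
    main()
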