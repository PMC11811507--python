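#!/usr/bin/env python
"""Generate the study-condition inputs for the full analysis.

Writes under results/inputs/: the 9/9/17 three-group 44-metabolite
concentration panel (with the planted disease-shift structure), the
84/60 gene-marker lists sharing 22 symbols, and a typed knowledge graph
wiring those markers to the panel's conversion enzymes with planted
template pathways.
"""

import argparse
from pathlib import Path

from metaboreg.kgraph import write_graph
from metaboreg.markers import default_enzyme_map, partition_markers, write_marker_list
from metaboreg.profiles import summarize_panel, write_class_sidecar, write_profiles
from metaboreg.synthetic import (
    simulate_knowledge_graph,
    simulate_marker_lists,
    simulate_panel,
    study_graph_config,
    study_panel_config,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = simulate_panel(study_panel_config(seed=args.seed))
    write_profiles(panel, args.out / "panel.csv")
    write_class_sidecar(panel, args.out / "panel.classes.tsv")
    s = summarize_panel(panel)
    print(f"panel: {s['n_samples']} samples x {s['n_metabolites']} metabolites "
          f"({s['n_per_class']['amino_acid']} amino acids, "
          f"{s['n_per_class']['acylcarnitine']} acylcarnitines); "
          f"groups {s['n_per_group']}")

    list_a, list_b = simulate_marker_lists(84, 60, 22, seed=args.seed)
    write_marker_list(list_a, args.out / "markers_A.txt")
    write_marker_list(list_b, args.out / "markers_B.txt")
    part = partition_markers(list_a, list_b)
    print(f"markers: {len(list_a)} PD-like + {len(list_b)} VP-like, "
          f"{len(part.shared)} shared")

    enzymes = sorted(default_enzyme_map().enzymes())
    gcfg = study_graph_config(sorted(part.all_markers()), enzymes,
                              seed=args.seed, mean_paths_per_enzyme=4.0)
    graph = simulate_knowledge_graph(gcfg)
    write_graph(graph, args.out / "graph.tsv")
    print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges, "
          f"{len(gcfg.planted_paths)} planted pathways -> {args.out}")


if __name__ == "__main__":
    main()
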