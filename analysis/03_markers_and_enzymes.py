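#!/usr/bin/env python
"""Partition the disease marker lists and map significant metabolites to
their conversion enzymes.

Writes results/markers/: the A-only/B-only/shared marker partition and
the deduplicated enzyme table (with metabolic class and encoding gene)
for all metabolites called significant by the screening stage.
"""

import argparse
import json
from pathlib import Path

from metaboreg.markers import (
    default_enzyme_map,
    enzymes_for_metabolites,
    partition_markers,
    read_marker_list,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--classification", type=Path,
                    default=Path("results/screening/classification.json"))
    ap.add_argument("--out", type=Path, default=Path("results/markers"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    part = partition_markers(
        read_marker_list(args.inputs / "markers_A.txt"),
        read_marker_list(args.inputs / "markers_B.txt"),
    )
    with open(args.out / "marker_partition.json", "w", encoding="utf-8") as fh:
        json.dump(part.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"marker partition: {part.sizes()}")

    cls = json.loads(args.classification.read_text())
    significant = sorted(set(cls["shared"] + cls["A_specific"] + cls["B_specific"]))
    enzymes, unmapped = enzymes_for_metabolites(significant, default_enzyme_map())
    enzymes.to_csv(args.out / "enzymes.tsv", sep="\t", index=False)
    print(f"{len(significant)} significant metabolites -> "
          f"{len(enzymes)} conversion enzymes "
          f"({(enzymes['enzyme_class'] == 'amino_acid_metabolism').sum()} amino-acid, "
          f"{(enzymes['enzyme_class'] == 'acylcarnitine_metabolism').sum()} "
          f"acylcarnitine metabolism)")
    if unmapped:
        print(f"unmapped metabolites (no enzyme record): {unmapped}")


if __name__ == "__main__":
    main()
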