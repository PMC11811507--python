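#!/usr/bin/env python
"""Differential screening of the panel: each disease group vs control.

Reads results/inputs/panel.csv, applies Mann–Whitney + Kolmogorov–Smirnov
per metabolite with Benjamini–Hochberg FDR (q = 0.05) per test per
contrast, and writes the statistics table and the three-way metabolite
classification under results/screening/.
"""

import argparse
import json
from pathlib import Path

from metaboreg.profiles import read_profiles
from metaboreg.screening import screen_panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/inputs/panel.csv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--rule", default="both",
                    choices=["both", "either", "mw_only", "ks_only"])
    ap.add_argument("--out", type=Path, default=Path("results/screening"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = read_profiles(args.panel)
    res = screen_panel(panel, alpha=args.alpha, rule=args.rule)
    res.table.to_csv(args.out / "screening.tsv", sep="\t", index=False,
                     float_format="%.12g")
    summary = res.summary()
    with open(args.out / "classification.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    n = summary["n_significant"]
    print(f"significant at FDR<{args.alpha} (rule={args.rule}): "
          f"{n['diseaseA']} in disease A, {n['diseaseB']} in disease B, "
          f"{summary['n_shared']} shared")
    print(f"A-only: {summary['A_specific']}")
    print(f"B-only: {summary['B_specific']}")


if __name__ == "__main__":
    main()
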