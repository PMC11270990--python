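#!/usr/bin/env python
"""Summarize the structural descriptors of each ensemble.

Reads the descriptor tables written by 01_generate_ensembles.py and
reports, per linker and charge state, the circular mean of the
guanine-linker dihedral, the stacking-angle distribution and the
interligand-distance centre.  The dihedral populations should sit at the
per-linker minima (90 deg alkane, 15 deg alkene, 20/45 deg arene
neutral/cation) and distances near 5 A.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from samredox.report import summarize

BASE = Path("results/analysis")
ROWS = []


def main() -> None:
    for d in sorted(BASE.glob("*_*")):
        if not (d / "descriptors.csv").exists():
            continue
        linker, state = d.name.rsplit("_", 1)
        df = pd.read_csv(d / "descriptors.csv")
        dih = summarize(df["dihedral_deg"], "circular")
        stack = summarize(df["stacking_deg"], "linear", domain=(0.0, 90.0), bins=18)
        dist = summarize(df["neighbor_dist_A"], "linear")
        ROWS.append({
            "linker": linker, "state": state, "n": dih.n,
            "dihedral_circmean_deg": round(dih.mean, 2),
            "dihedral_mode_deg": round(dih.mode, 1),
            "stacking_mean_deg": round(stack.mean, 2),
            "distance_mean_A": round(dist.mean, 3),
            "distance_sd_A": round(dist.sd, 3),
        })
    table = pd.DataFrame(ROWS)
    table.to_csv(BASE / "descriptor_summary.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {BASE / 'descriptor_summary.csv'}")


if __name__ == "__main__":
    main()
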