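#!/usr/bin/env python
"""Generate the six synthetic SAM ensembles (3 linkers x 2 charge states).

Writes, per ensemble, a directory of XYZ frames with fragment map, direct
per-scenario vertical-gap tables and constrained-hole charge tables under
results/analysis/.  The neutral and cationic ensembles differ only in
their dihedral populations (the cationic thioarene twists to 45 deg) and
in which vertical gap they carry (VIE vs VAE).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from samredox.data_model import default_scenarios, write_scenarios, write_snapshot, write_tables
from samredox.descriptors import compute_descriptors, descriptor_frame
from samredox.pipeline import RunConfig, linker_params
from samredox.synthetic import build_sam, sample_charges, sample_energies

CONFIG = RunConfig(seed=1, frames=200, out_dir="results/analysis")


def main() -> None:
    out = Path(CONFIG.out_dir)
    scenarios = default_scenarios(0, 1)
    write_scenarios(scenarios, _mkdir(out) / "scenarios.json")
    for linker in CONFIG.linkers:
        for state in ("neutral", "cation"):
            params = linker_params(CONFIG, linker, state)
            snaps = build_sam(params)
            d = _mkdir(out / f"{linker}_{state}")
            for snap in snaps[:10]:  # a geometry sample; stages regenerate from seed
                write_snapshot(snap, d / f"frame_{snap.frame_index:04d}.xyz", d / "fragment_map.csv")
            desc = compute_descriptors(snaps)
            descriptor_frame(desc).to_csv(d / "descriptors.csv", index=False)
            stack = [r.stacking_angle for r in desc if r.ligand_id == 0]
            energies = []
            for scen in params.scenario_offsets:
                energies.extend(sample_energies(snaps, stack, params, scen))
            write_tables(energies, d / "energies.csv")
            if state == "neutral":
                charges = []
                for spec in scenarios.values():
                    charges.extend(sample_charges(s, spec, params) for s in snaps)
                write_tables(charges, d / "charges.csv")
            print(f"{linker}/{state}: {len(snaps)} frames, "
                  f"{len(energies)} energy records -> {d}")


def _mkdir(p: Path) -> Path:
    p.mkdir(parents=True, exist_ok=True)
    return p


if __name__ == "__main__":
    main()
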