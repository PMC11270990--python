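"""End-to-end orchestration: generate → descriptors → energies/charges →
redox → hole → report, for each linker chemistry and both charge states.

Seed management: the run's global seed never feeds a generator directly.
Each (linker, state) pair gets its own stream via
``SeedSequence(global_seed, spawn_key=(linker_index, state_index))``, whose
first 32-bit word (masked to 31 bits) becomes that stage's
``GeneratorParams.seed``.  Changing the global seed changes every stream;
changing one stage cannot perturb another.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    EnergyRecord,
    Snapshot,
    UsageError,
    default_scenarios,
    write_snapshot,
    write_tables,
)
from .descriptors import compute_descriptors, descriptor_frame
from .hole import fraction_matrix, hole_fractions
from .marcus import (
    default_calc_offsets,
    default_schemes,
    scenario_table,
    to_potential,
)
from .report import (
    build_report,
    descriptor_energy_join,
    summarize,
)
from .synthetic import (
    DEFAULT_SHE_REFERENCE,
    LINKERS,
    GeneratorParams,
    build_sam,
    default_params,
    sample_charges,
    sample_energies,
)

__all__ = ["RunConfig", "run_pipeline", "run_linker", "stage_seed"]

log = logging.getLogger("samredox")

_CONFIG_FIELDS = {
    "schema_version",
    "seed",
    "out_dir",
    "frames",
    "n_ligands_x",
    "n_ligands_y",
    "linkers",
    "angle_coupling",
    "energy_sd",
    "dihedral_spread",
    "distance_spread",
    "n_permutations",
    "she_reference",
    "write_geometries",
    "figures",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    frames: int = 200
    n_ligands_x: int = 2
    n_ligands_y: int = 2
    linkers: tuple[str, ...] = LINKERS
    angle_coupling: float = 0.01
    energy_sd: float = 0.3
    dihedral_spread: float = 12.0
    distance_spread: float = 0.3
    n_permutations: int = 999
    she_reference: float = DEFAULT_SHE_REFERENCE
    write_geometries: bool = False
    figures: bool = True
    log_level: str = "INFO"
    schema_version: int = 1

    def __post_init__(self) -> None:
        for linker in self.linkers:
            if linker not in LINKERS:
                raise UsageError(f"unknown linker {linker!r} in config")
        if self.frames < 1:
            raise UsageError("frames must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise UsageError("config must be a YAML mapping")
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        if "linkers" in raw:
            raw["linkers"] = tuple(raw["linkers"])
        return cls(**raw)

    def digest(self) -> str:
        body = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(body.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, linker: str, state: str) -> int:
    """Deterministic per-stage seed (31-bit) from the global seed."""
    li = LINKERS.index(linker)
    si = ("neutral", "cation").index(state)
    ss = np.random.SeedSequence(global_seed, spawn_key=(li, si))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def linker_params(config: RunConfig, linker: str, state: str) -> GeneratorParams:
    return default_params(
        linker,
        state,
        n_frames=config.frames,
        n_ligands_x=config.n_ligands_x,
        n_ligands_y=config.n_ligands_y,
        angle_coupling=config.angle_coupling,
        energy_sd=config.energy_sd,
        dihedral_spread=config.dihedral_spread,
        distance_spread=config.distance_spread,
        she_reference=config.she_reference,
        seed=stage_seed(config.seed, linker, state),
    )


def _reference_stacking(descriptors, reference_ligand: int = 0) -> list[float]:
    return [r.stacking_angle for r in descriptors if r.ligand_id == reference_ligand]


def generate_energy_tables(
    neutral: Sequence[Snapshot],
    cation: Sequence[Snapshot],
    stack_neutral: Sequence[float],
    stack_cation: Sequence[float],
    p_neutral: GeneratorParams,
    p_cation: GeneratorParams,
) -> tuple[dict, dict[str, list[EnergyRecord]]]:
    """Per-calc (vies, vaes) tables plus raw records per calc label."""
    calc_offsets = default_calc_offsets(p_neutral.scenario_offsets)
    pn = replace(p_neutral, scenario_offsets=calc_offsets)
    pc = replace(p_cation, scenario_offsets=calc_offsets)
    tables: dict[str, tuple[list[float], list[float]]] = {}
    records: dict[str, list[EnergyRecord]] = {}
    for calc in calc_offsets:
        vie_recs = sample_energies(neutral, stack_neutral, pn, calc)
        vae_recs = sample_energies(cation, stack_cation, pc, calc)
        tables[calc] = ([r.value for r in vie_recs], [r.value for r in vae_recs])
        records[calc] = vie_recs + vae_recs
    return tables, records


def run_linker(config: RunConfig, linker: str) -> dict:
    """All stages for one linker chemistry; returns the result sections."""
    p_n = linker_params(config, linker, "neutral")
    p_c = linker_params(config, linker, "cation")

    log.info("[%s] generating %d neutral + %d cation frames", linker, p_n.n_frames, p_c.n_frames)
    snaps_n = build_sam(p_n)
    snaps_c = build_sam(p_c)
    desc_n = compute_descriptors(snaps_n)
    desc_c = compute_descriptors(snaps_c)
    stack_n = _reference_stacking(desc_n)
    stack_c = _reference_stacking(desc_c)

    # direct per-scenario energies (the "big calculation" ground truth)
    direct: dict[str, list[EnergyRecord]] = {}
    for scen in p_n.scenario_offsets:
        direct[scen] = sample_energies(snaps_n, stack_n, p_n, scen) + sample_energies(
            snaps_c, stack_c, p_c, scen
        )

    # additive route: small independent calcs combined per scheme
    tables, calc_records = generate_energy_tables(
        snaps_n, snaps_c, stack_n, stack_c, p_n, p_c
    )
    redox = scenario_table(tables, default_schemes())
    for scen, row in redox.items():
        row["potential_V"] = to_potential(row["delta_e_red"], config.she_reference)

    # hole analysis on the neutral-trajectory frames
    scenarios = default_scenarios(0, 1) if p_n.n_ligands >= 2 else None
    holes = None
    if scenarios is not None:
        ensemble = []
        for scen in scenarios.values():
            for snap in snaps_n:
                delta = sample_charges(snap, scen, p_n)
                ensemble.append(hole_fractions(delta, snap, scen))
        holes = fraction_matrix(ensemble)

    # distribution summaries
    vie_values = [r.value for r in direct["I"] if r.kind == "VIE"]
    vae_values = [r.value for r in direct["I"] if r.kind == "VAE"]
    summaries = {
        "dihedral_neutral": summarize([r.dihedral for r in desc_n], "circular"),
        "dihedral_cation": summarize([r.dihedral for r in desc_c], "circular"),
        "stacking": summarize(stack_n, "linear", domain=(0.0, 90.0), bins=18),
        "distance": summarize([r.neighbor_distance for r in desc_n], "linear"),
        "VIE": summarize(vie_values, "linear"),
        "VAE": summarize(vae_values, "linear"),
    }
    for name, s in summaries.items():
        s.variable = name

    # structure-energy association (VIE side)
    vie_records = [r for recs in direct.values() for r in recs if r.kind == "VIE"]
    _, correlations = descriptor_energy_join(
        desc_n,
        vie_records,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, linker, "neutral") ^ 0x5EED,
    )

    return {
        "params_neutral": p_n,
        "params_cation": p_c,
        "snapshots_neutral": snaps_n,
        "snapshots_cation": snaps_c,
        "descriptors_neutral": desc_n,
        "descriptors_cation": desc_c,
        "energy_tables": tables,
        "calc_records": calc_records,
        "direct_records": direct,
        "redox": redox,
        "holes": holes,
        "summaries": summaries,
        "correlations": correlations,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage for every configured linker; write artifacts.

    Artifacts land under ``config.out_dir``: per-linker energy and
    descriptor CSVs, a redox CSV, holes CSV, ``report.json`` (+ figures),
    and ``provenance.json`` recording config hash, seed and tool version.
    A ``.partial`` marker exists while the run is incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()

    redox_all: dict[str, dict] = {}
    holes_all: dict[str, pd.DataFrame] = {}
    summaries_all: dict[str, dict] = {}
    corr_all: dict[str, dict] = {}
    redox_rows = []
    holes_rows = []

    for linker in config.linkers:
        res = run_linker(config, linker)
        redox_all[linker] = res["redox"]
        summaries_all[linker] = res["summaries"]
        corr_all[linker] = res["correlations"]

        ddf = descriptor_frame(res["descriptors_neutral"])
        ddf.to_csv(out / f"descriptors_{linker}_neutral.csv", index=False)
        recs = [r for rs in res["calc_records"].values() for r in rs]
        write_tables(sorted(recs, key=lambda r: (r.scenario, r.kind, r.frame_index)), out / f"energies_calcs_{linker}.csv")
        direct = [r for rs in res["direct_records"].values() for r in rs]
        write_tables(sorted(direct, key=lambda r: (r.scenario, r.kind, r.frame_index)), out / f"energies_scenarios_{linker}.csv")

        for scen, row in res["redox"].items():
            redox_rows.append(
                {
                    "linker": linker,
                    "scenario": scen,
                    "mean_vie_eV": row["mean_vie"],
                    "mean_vae_eV": row["mean_vae"],
                    "delta_e_red_eV": row["delta_e_red"],
                    "lambda_eV": row["lambda_reorg"],
                    "se_eV": row["se_delta"],
                    "potential_V": row["potential_V"],
                }
            )
        if res["holes"] is not None:
            holes_all[linker] = res["holes"]
            m = res["holes"]
            for scen in m.index:
                for frag, stat in m.columns:
                    if stat == "mean":
                        holes_rows.append(
                            {
                                "linker": linker,
                                "scenario": scen,
                                "fragment": frag,
                                "mean_fraction": float(m.loc[scen, (frag, "mean")]),
                                "se": float(m.loc[scen, (frag, "se")]),
                                "n": int(m.loc[scen, ("n", "")]),
                            }
                        )
        if config.write_geometries:
            geo = out / f"snapshots_{linker}_neutral"
            geo.mkdir(exist_ok=True)
            for snap in res["snapshots_neutral"]:
                write_snapshot(
                    snap,
                    geo / f"frame_{snap.frame_index:04d}.xyz",
                    geo / "fragment_map.csv",
                )

    pd.DataFrame(redox_rows).to_csv(out / "redox.csv", index=False)
    if holes_rows:
        pd.DataFrame(holes_rows).to_csv(out / "holes.csv", index=False)

    provenance = {
        "tool": "samredox",
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(config).items()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")

    report = build_report(
        out,
        redox=redox_all,
        holes=holes_all or None,
        summaries=summaries_all,
        correlations=corr_all,
        metadata={"seed": config.seed, "version": __version__, "config_digest": config.digest()},
        figures=config.figures,
    )
    marker.unlink(missing_ok=True)
    return report
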