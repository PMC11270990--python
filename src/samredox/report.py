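"""Distribution summaries, structure–energy correlation and the run report.

The structure–energy analysis compares the distributions of the three
geometric descriptors (guanine–linker dihedral, stacking angle,
interligand distance) with the vertical-gap ensembles, and quantifies the
stacking-angle/energy association per scenario with a Spearman rank
correlation whose p-value comes from a seeded permutation test.  Angular
variables use circular statistics; the centre of a distribution is
reported both as mean (circular mean for angles) and histogram mode, since
"centre" is estimator-dependent for skewed ensembles.

The report is a machine-readable JSON summary (the tested contract) plus
matplotlib figures (a convenience layer): a per-scenario potential bar
chart, a scenario × fragment hole heatmap, and distribution panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, EnergyRecord, UsageError
from .descriptors import descriptor_frame

__all__ = [
    "DistributionSummary",
    "summarize",
    "descriptor_energy_join",
    "spearman_permutation",
    "build_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

#: Fixed histogram domains per variable kind; angle histograms use 5° bins
#: over their natural domain for comparability across linkers and states.
ANGLE_BIN_WIDTH = 5.0


@dataclass
class DistributionSummary:
    variable: str
    kind: str  # "linear" | "circular"
    mean: float
    sd: float
    mode: float  # midpoint of the most occupied histogram bin
    bin_edges: list[float]
    counts: list[int]
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    values: Sequence[float],
    kind: str = "linear",
    bins: int = 36,
    domain: tuple[float, float] | None = None,
) -> DistributionSummary:
    """Summarize one ensemble of scalar values.

    ``kind="circular"`` treats values as degrees on (−180, 180] and uses
    the circular mean and circular SD; the histogram then spans the full
    circle (or ``domain`` if given) in fixed 5° bins.  Linear kinds use
    the data range unless a ``domain`` is supplied.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise UsageError("summarize needs at least one value")
    if bins < 1:
        raise UsageError("bins must be >= 1")
    if kind == "circular":
        mean = float(stats.circmean(v, high=180.0, low=-180.0))
        sd = float(stats.circstd(v, high=180.0, low=-180.0))
        if domain is None:
            domain = (-180.0, 180.0)
        edges = np.arange(domain[0], domain[1] + ANGLE_BIN_WIDTH / 2, ANGLE_BIN_WIDTH)
    elif kind == "linear":
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        lo, hi = domain if domain is not None else (float(v.min()), float(v.max()))
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
    else:
        raise UsageError(f"kind must be linear or circular, got {kind!r}")
    counts, edges = np.histogram(v, bins=edges)
    mode = float((edges[counts.argmax()] + edges[counts.argmax() + 1]) / 2.0)
    return DistributionSummary(
        variable="",
        kind=kind,
        mean=mean,
        sd=sd,
        mode=mode,
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
        n=int(v.size),
    )


# ---------------------------------------------------------------------------
# Structure–energy correlation
# ---------------------------------------------------------------------------


def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman ρ with a two-sided permutation p-value.

    p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_permutations + 1), permuting y
    against x with a seeded generator; ranks are computed once and
    permuted, so the cost is one correlation per permutation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise UsageError("need two equal-length samples of size >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry_c = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry_c))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry_c)
        if abs(float(np.mean(rx * perm))) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return rho, p


def descriptor_energy_join(
    descriptors,
    energies: Sequence[EnergyRecord],
    *,
    reference_ligand: int = 0,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Join descriptors with energies and correlate stacking angle vs gap.

    Energies are per-frame properties of the reference ligand, so the join
    key is (system_id, frame_index) against the reference ligand's
    descriptor rows.  Returns the inner-joined table plus, per scenario
    label, the Spearman ρ of stacking angle vs energy with its permutation
    p-value.
    """
    ddf = descriptors if isinstance(descriptors, pd.DataFrame) else descriptor_frame(descriptors)
    ddf = ddf[ddf["ligand_id"] == reference_ligand]
    edf = pd.DataFrame(
        [(r.system_id, r.frame_index, r.scenario, r.kind, r.value) for r in energies],
        columns=["system_id", "frame_index", "scenario", "kind", "value_eV"],
    )
    joined = ddf.merge(edf, on=["system_id", "frame_index"], how="inner")
    if joined.empty:
        raise DataError(
            f"empty join: {len(ddf)} descriptor rows vs {len(edf)} energy rows "
            "share no (system_id, frame_index) keys"
        )
    correlations: dict[str, dict] = {}
    for scen, grp in joined.groupby("scenario", sort=True):
        rho, p = spearman_permutation(
            grp["stacking_deg"], grp["value_eV"], n_permutations, seed
        )
        correlations[str(scen)] = {"rho": rho, "p_value": p, "n": int(len(grp))}
    return joined, correlations


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def build_report(
    out_dir: str | Path,
    redox: Mapping[str, Mapping[str, dict]] | None = None,
    holes: Mapping[str, pd.DataFrame] | None = None,
    summaries: Mapping[str, Mapping[str, DistributionSummary]] | None = None,
    correlations: Mapping[str, Mapping[str, dict]] | None = None,
    metadata: Mapping | None = None,
    figures: bool = True,
) -> Path:
    """Write report.json (and figures) from whichever sections are present.

    ``redox`` maps linker → scenario → result dict; ``holes`` maps
    linker → fraction matrix; ``summaries`` maps linker → variable →
    :class:`DistributionSummary`.  The JSON is deterministic (sorted keys,
    repr-exact floats) given identical inputs.
    """
    if redox is None and holes is None and summaries is None:
        raise UsageError("build_report needs at least one input section")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if metadata:
        payload["metadata"] = dict(metadata)
    if redox is not None:
        payload["redox"] = {
            linker: {scen: dict(res) for scen, res in table.items()}
            for linker, table in redox.items()
        }
    if holes is not None:
        payload["holes"] = {linker: _matrix_to_dict(m) for linker, m in holes.items()}
    if summaries is not None:
        payload["distributions"] = {
            linker: {var: s.to_dict() for var, s in block.items()}
            for linker, block in summaries.items()
        }
    if correlations is not None:
        payload["correlations"] = {
            linker: {scen: dict(c) for scen, c in block.items()}
            for linker, block in (correlations or {}).items()
        }

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    if figures:
        _write_figures(out_dir, redox, holes, summaries)
    return report_path


def _matrix_to_dict(matrix: pd.DataFrame) -> dict:
    # scenarios hold different fragment sets, so the stacked frame has NaN
    # holes; only a scenario's own fragments are serialized
    out = {}
    for scen in matrix.index:
        row = {}
        for frag, stat in matrix.columns:
            val = matrix.loc[scen, (frag, stat)]
            key = f"{frag}.{stat}" if stat else frag
            if isinstance(val, str):
                row[key] = val
            elif np.isfinite(val):
                row[key] = float(val)
        out[str(scen)] = row
    return out


def _write_figures(out_dir, redox, holes, summaries) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if redox:
        fig, ax = plt.subplots(figsize=(7, 4))
        linkers = sorted(redox)
        scen_labels = sorted({s for t in redox.values() for s in t})
        width = 0.8 / max(len(linkers), 1)
        for i, linker in enumerate(linkers):
            xs = np.arange(len(scen_labels)) + i * width
            ys = [redox[linker].get(s, {}).get("delta_e_red", np.nan) for s in scen_labels]
            ax.bar(xs, ys, width=width, label=linker)
        ax.set_xticks(np.arange(len(scen_labels)) + 0.4 - width / 2)
        ax.set_xticklabels(scen_labels)
        ax.set_xlabel("scenario")
        ax.set_ylabel(r"$\Delta E_{red}$ (eV)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "scenario_potentials.png", dpi=120)
        plt.close(fig)

    if holes:
        for linker, matrix in holes.items():
            frag_cols = [c for c in matrix.columns if c[1] == "mean"]
            data = matrix[frag_cols].to_numpy(float)
            fig, ax = plt.subplots(figsize=(6, 3.5))
            im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=1)
            ax.set_yticks(range(len(matrix.index)), matrix.index)
            ax.set_xticks(range(len(frag_cols)), [c[0] for c in frag_cols], rotation=45)
            fig.colorbar(im, ax=ax, label="mean hole fraction")
            ax.set_title(f"hole localization: {linker}")
            fig.tight_layout()
            fig.savefig(out_dir / f"hole_fractions_{linker}.png", dpi=120)
            plt.close(fig)

    if summaries:
        for linker, block in summaries.items():
            n = len(block)
            fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3))
            if n == 1:
                axes = [axes]
            for ax, (var, s) in zip(axes, sorted(block.items())):
                edges = np.asarray(s.bin_edges)
                ax.stairs(s.counts, edges, fill=True)
                ax.set_title(f"{var} ({linker})", fontsize=9)
            fig.tight_layout()
            fig.savefig(out_dir / f"distributions_{linker}.png", dpi=120)
            plt.close(fig)
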