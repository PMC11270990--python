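"""Hole localization from cation-minus-neutral atomic charges.

The spatial distribution of the hole after vertical ionization is read off
the per-atom charge differences Δq_i between the constrained-cation and
neutral states at the same geometry: the fraction of the hole on a
fragment is the fragment's Δq sum over the total.  Fractions are signed —
back-polarization shows up as negative fragment sums and is reported
as-is, never clipped, so conservation holds exactly and unphysical inputs
stay visible.

Gold is reported as one aggregate fragment (the QM gold region is a
handful of surface atoms); solvent, if present, lands in spillover along
with any other fragment outside the scenario's QM region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    GOLD_FRAGMENT,
    ChargeDelta,
    DataError,
    ScenarioSpec,
    Snapshot,
    UsageError,
    fragment_key,
)

__all__ = ["HoleFractions", "hole_fractions", "fraction_matrix", "localization_index"]

SPILLOVER = "spillover"


@dataclass
class HoleFractions:
    """Per-fragment hole fractions for one frame under one scenario."""

    scenario: str
    frame_index: int
    per_fragment: dict[str, float]  # fragment key -> fraction, QM region only
    spillover: float = 0.0
    system_id: str = ""

    @property
    def total(self) -> float:
        return sum(self.per_fragment.values()) + self.spillover


def hole_fractions(
    delta: ChargeDelta,
    snapshot: Snapshot,
    scenario: ScenarioSpec,
    *,
    per_atom_gold: bool = False,
    min_total: float = 0.5,
) -> HoleFractions:
    """Aggregate per-atom charge differences into fragment hole fractions.

    fraction(f) = Σ_{i ∈ f} Δq_i / Σ_i Δq_i.  Fragments outside the
    scenario's QM region (solvent included) are pooled into ``spillover``.
    A total Δq below ``min_total`` e means the pair of states does not
    describe a single hole and is rejected.
    """
    dq = np.asarray(delta.per_atom_delta, dtype=float)
    if dq.size != snapshot.n_atoms:
        raise UsageError(
            f"charge delta has {dq.size} atoms but snapshot has {snapshot.n_atoms}"
        )
    total = float(dq.sum())
    if total < min_total:
        raise DataError(
            f"total charge difference {total:.4f} e is below {min_total}; "
            "not a one-hole cation/neutral pair"
        )

    per_fragment: dict[str, float] = {}
    spill = 0.0
    for frag in snapshot.fragments():
        if frag == GOLD_FRAGMENT:
            idx = snapshot.gold_atoms()
        else:
            idx = snapshot.atoms_of(*frag)
        frac = float(dq[idx].sum()) / total
        if frag in scenario.qm_fragments:
            if frag == GOLD_FRAGMENT and per_atom_gold:
                for i in idx:
                    per_fragment[f"gold@{i}"] = float(dq[i]) / total
            else:
                per_fragment[fragment_key(*frag)] = frac
        else:
            spill += frac
    return HoleFractions(
        scenario=scenario.label,
        frame_index=delta.frame_index,
        per_fragment=per_fragment,
        spillover=spill,
        system_id=delta.system_id,
    )


def fraction_matrix(ensemble: Sequence[HoleFractions]) -> pd.DataFrame:
    """Scenario × fragment table of mean hole fractions with SEs.

    Rows are indexed by scenario label; columns are a MultiIndex of
    (fragment, stat) where stat ∈ {mean, se}; an extra ``localization``
    column holds the per-scenario localization index (largest mean
    fragment fraction).  All frames of a scenario must report the same
    fragment keys.
    """
    if not ensemble:
        raise UsageError("fraction_matrix needs a non-empty ensemble")
    by_scenario: dict[str, list[HoleFractions]] = {}
    for hf in ensemble:
        by_scenario.setdefault(hf.scenario, []).append(hf)

    rows = {}
    for label, frames in sorted(by_scenario.items()):
        keys = sorted(frames[0].per_fragment)
        for hf in frames:
            if sorted(hf.per_fragment) != keys:
                raise UsageError(
                    f"inconsistent fragment keys within scenario {label}: "
                    f"{sorted(hf.per_fragment)} vs {keys}"
                )
        mat = np.array(
            [[hf.per_fragment[k] for k in keys] + [hf.spillover] for hf in frames]
        )
        means = mat.mean(axis=0)
        n = mat.shape[0]
        ses = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
        row = {}
        for j, k in enumerate(keys + [SPILLOVER]):
            row[(k, "mean")] = means[j]
            row[(k, "se")] = ses[j]
        row[("localization", "index")] = float(means[:-1].max())
        row[("localization", "fragment")] = keys[int(means[:-1].argmax())]
        row[("n", "")] = n
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    df.index.name = "scenario"
    return df


def localization_index(matrix: pd.DataFrame, scenario: str) -> tuple[float, str]:
    """(largest mean fragment fraction, its fragment key) for one scenario."""
    return (
        float(matrix.loc[scenario, ("localization", "index")]),
        str(matrix.loc[scenario, ("localization", "fragment")]),
    )
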