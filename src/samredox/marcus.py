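"""Marcus linear-response redox estimates and the additive QM-region scheme.

Under the linear-response approximation the one-electron oxidation
quantity and reorganization energy follow from the two vertical-gap
ensembles:

    ΔE_red = (⟨VIE⟩ + ⟨VAE⟩) / 2
    λ      = (⟨VIE⟩ − ⟨VAE⟩) / 2

with ⟨VIE⟩ averaged over the neutral trajectory and ⟨VAE⟩ over the
cationic one.  Both gaps are stored as positive ionization-direction
energies (cation minus neutral at fixed geometry), so λ ≥ 0 in
well-behaved data.

Large QM regions are assembled from small independent calculations by the
additive scheme: the property of the big region is the reference
calculation plus signed differences of auxiliary calculations, assuming no
cooperativity between the added effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import DataError, EnergyRecord, RedoxResult, UsageError

__all__ = [
    "AdditiveScheme",
    "default_schemes",
    "default_calc_offsets",
    "linear_response",
    "to_potential",
    "additive_combine",
    "scenario_table",
    "split_energy_records",
]


@dataclass(frozen=True)
class AdditiveScheme:
    """One scenario's composition out of independent calculations.

    The combined value is ``values[reference_calc] + Σ sign·values[calc]``
    over ``terms``.  Calc ids are free-text labels resolved against the
    energy tables supplied to :func:`scenario_table`.
    """

    reference_calc: str
    terms: tuple[tuple[str, int], ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        ids = [self.reference_calc] + [c for c, _ in self.terms]
        if len(set(ids)) != len(ids):
            raise UsageError(f"duplicate calc ids in scheme: {ids}")
        for _, sign in self.terms:
            if sign not in (+1, -1):
                raise UsageError("term signs must be +1 or -1")

    @property
    def calc_ids(self) -> list[str]:
        return [self.reference_calc] + [c for c, _ in self.terms]


def default_schemes() -> dict[str, AdditiveScheme]:
    """The five default scenario compositions.

    Calc ids name the three underlying calculation families: ``lig_*`` is
    the single-ligand QM region (calc i) with the hole constrained to the
    nucleobase or the full ligand; ``pair_*`` the two-ligand region
    (calc iii) with one vs two nucleobases or ligands allowed; ``gold_*``
    the ligand + 4 Au region (calc ii) with gold blocked or allowed.
    These defaults are data, not code — pass your own schemes to override.
    """
    return {
        "I": AdditiveScheme("lig_nb", (), "hole on one nucleobase"),
        "II": AdditiveScheme(
            "lig_nb",
            (("pair_nb2", +1), ("pair_nb1", -1)),
            "two nucleobases via the two-ligand calc",
        ),
        "III": AdditiveScheme("lig_full", (), "hole over the full ligand"),
        "IV": AdditiveScheme(
            "lig_full",
            (("pair_lig2", +1), ("pair_lig1", -1)),
            "two full ligands via the two-ligand calc",
        ),
        "V": AdditiveScheme(
            "lig_full",
            (("gold_on", +1), ("gold_off", -1)),
            "ligand plus the four nearest gold atoms",
        ),
    }


def default_calc_offsets(scenario_offsets: Mapping[str, float]) -> dict[str, float]:
    """Synthetic-generator energy offsets per calc id.

    Inverts :func:`default_schemes` against per-scenario offsets so that
    combining the calcs reproduces each scenario's offset exactly:
    e.g. offset(V) = offset(III) + [offset(gold_on) − offset(gold_off)].
    """
    o = scenario_offsets
    return {
        "lig_nb": o["I"],
        "lig_full": o["III"],
        "pair_nb1": 0.0,
        "pair_nb2": o["II"] - o["I"],
        "pair_lig1": 0.0,
        "pair_lig2": o["IV"] - o["III"],
        "gold_off": 0.0,
        "gold_on": o["V"] - o["III"],
    }


def linear_response(vies: Sequence[float], vaes: Sequence[float]) -> RedoxResult:
    """Ensemble linear-response estimate from VIE and VAE samples (eV).

    Snapshots are equally weighted; standard errors are sample SD / √n,
    combined in quadrature for the half-sum:
    SE(ΔE_red) = ½·sqrt(SE_VIE² + SE_VAE²).
    """
    vie = np.asarray(list(vies), dtype=float)
    vae = np.asarray(list(vaes), dtype=float)
    if vie.size == 0 or vae.size == 0:
        raise UsageError("linear_response needs non-empty VIE and VAE lists")
    for name, arr in (("VIE", vie), ("VAE", vae)):
        bad = np.nonzero(~np.isfinite(arr))[0]
        if bad.size:
            raise DataError(f"non-finite {name} values at positions {bad.tolist()}")
    mean_vie = float(vie.mean())
    mean_vae = float(vae.mean())
    se_vie = float(vie.std(ddof=1) / math.sqrt(vie.size)) if vie.size > 1 else 0.0
    se_vae = float(vae.std(ddof=1) / math.sqrt(vae.size)) if vae.size > 1 else 0.0
    return RedoxResult(
        mean_vie=mean_vie,
        mean_vae=mean_vae,
        delta_e_red=(mean_vie + mean_vae) / 2.0,
        lambda_reorg=(mean_vie - mean_vae) / 2.0,
        se_vie=se_vie,
        se_vae=se_vae,
        se_delta=0.5 * math.hypot(se_vie, se_vae),
        n_vie=int(vie.size),
        n_vae=int(vae.size),
    )


def to_potential(delta_e_red: float | RedoxResult, she_reference: float) -> float:
    """Convert ΔE_red (eV, one electron) to a potential vs SHE (V).

    The one-electron vertical quantity in eV maps numerically onto an
    absolute potential in V; subtracting the absolute SHE potential
    (default 4.28 V elsewhere in the package) references it to SHE.
    """
    if she_reference < 0:
        raise UsageError("she_reference must be >= 0")
    value = delta_e_red.delta_e_red if isinstance(delta_e_red, RedoxResult) else float(delta_e_red)
    return value - she_reference


def additive_combine(values: Mapping[str, float], scheme: AdditiveScheme) -> float:
    """Combine per-calc values under one additive scheme (exact arithmetic)."""
    missing = [c for c in scheme.calc_ids if c not in values]
    if missing:
        raise UsageError(f"additive scheme references missing calc ids: {missing}")
    out = float(values[scheme.reference_calc])
    for calc, sign in scheme.terms:
        out += sign * float(values[calc])
    return out


def split_energy_records(
    records: Sequence[EnergyRecord],
) -> dict[str, dict[str, list[float]]]:
    """Group energy records as {label: {"VIE": [...], "VAE": [...]}}."""
    out: dict[str, dict[str, list[float]]] = {}
    for r in records:
        out.setdefault(r.scenario, {"VIE": [], "VAE": []})[r.kind].append(r.value)
    return out


def scenario_table(
    energy_tables: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    schemes: Mapping[str, AdditiveScheme],
) -> dict[str, dict]:
    """Per-scenario linear-response results via the additive scheme.

    ``energy_tables`` maps calc id → (vies, vaes).  Each calc is reduced
    with :func:`linear_response`; each scenario's ΔE_red, λ and mean gaps
    are then assembled with :func:`additive_combine`, and SEs combined in
    quadrature over the scheme terms.  The returned mapping also carries
    each scenario's difference from scenario I (``delta_vs_I``) when a
    scenario labelled "I" is present.
    """
    per_calc = {
        calc: linear_response(vies, vaes)
        for calc, (vies, vaes) in energy_tables.items()
    }
    table: dict[str, dict] = {}
    for label, scheme in schemes.items():
        missing = [c for c in scheme.calc_ids if c not in per_calc]
        if missing:
            raise UsageError(
                f"scenario {label}: missing energy tables for calcs {missing}"
            )
        delta = additive_combine(
            {c: per_calc[c].delta_e_red for c in scheme.calc_ids}, scheme
        )
        lam = additive_combine(
            {c: per_calc[c].lambda_reorg for c in scheme.calc_ids}, scheme
        )
        mean_vie = additive_combine(
            {c: per_calc[c].mean_vie for c in scheme.calc_ids}, scheme
        )
        mean_vae = additive_combine(
            {c: per_calc[c].mean_vae for c in scheme.calc_ids}, scheme
        )
        se = math.sqrt(
            per_calc[scheme.reference_calc].se_delta ** 2
            + sum(per_calc[c].se_delta ** 2 for c, _ in scheme.terms)
        )
        ref = per_calc[scheme.reference_calc]
        table[label] = {
            "delta_e_red": delta,
            "lambda_reorg": lam,
            "mean_vie": mean_vie,
            "mean_vae": mean_vae,
            "se_delta": se,
            "n_vie": ref.n_vie,
            "n_vae": ref.n_vae,
        }
    if "I" in table:
        base = table["I"]["delta_e_red"]
        for label in table:
            table[label]["delta_vs_I"] = table[label]["delta_e_red"] - base
    return table
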