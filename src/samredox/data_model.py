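"""Domain types and file IO for SAM redox post-processing.

Every stage of the pipeline speaks in terms of the types defined here:

* :class:`Snapshot` — one frame of one system in one charge state, with a
  per-atom fragment map assigning each atom to a ligand and a moiety
  (nucleobase, linker, gold or solvent).
* :class:`ScenarioSpec` — one of the five hole-delocalization scenarios
  (I–V): which fragments sit in the QM region and which may host the hole.
* :class:`EnergyRecord` — a single vertical energy gap (VIE on the neutral
  trajectory, VAE on the cationic one), in eV.
* :class:`ChargeDelta` — per-atom cation-minus-neutral charges for one
  snapshot under one constraint (the raw material of hole analysis).
* :class:`RedoxResult` — ensemble ⟨VIE⟩/⟨VAE⟩, the linear-response
  oxidation quantity ΔE_red and reorganization energy λ, with standard
  errors.

Units are fixed package-wide: coordinates in Å, energies in eV, charges in
units of the elementary charge e.  Atom indexing is 0-based in every
CSV/JSON artifact (PDB serials stay 1-based inside PDB files, per the PDB
standard).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOIETIES",
    "SCENARIO_LABELS",
    "GOLD_FRAGMENT",
    "FormatError",
    "UsageError",
    "DataError",
    "Snapshot",
    "ScenarioSpec",
    "EnergyRecord",
    "ChargeDelta",
    "RedoxResult",
    "fragment_key",
    "parse_fragment_key",
    "read_snapshot",
    "write_snapshot",
    "write_tables",
    "read_energy_table",
    "read_charge_table",
    "read_scenarios",
    "write_scenarios",
]

#: Valid moiety tokens in a fragment map.
MOIETIES = ("nucleobase", "linker", "gold", "solvent")

#: The five hole-delocalization scenario labels.
SCENARIO_LABELS = ("I", "II", "III", "IV", "V")

#: Canonical fragment identifier for the (aggregated) gold QM atoms.
GOLD_FRAGMENT = (-1, "gold")

#: Ligand id reserved for atoms that belong to no ligand (gold, solvent).
NO_LIGAND = -1

#: Default tolerance on the one-hole condition sum(Δq) = +1 e.
ONE_HOLE_TOL = 1e-3


class FormatError(ValueError):
    """A file violates its documented format."""


class UsageError(ValueError):
    """An operation was called with arguments outside its contract."""


class DataError(ValueError):
    """Input data are well-formed but physically or statistically invalid."""


def fragment_key(ligand_id: int, moiety: str) -> str:
    """Serialize a fragment identifier to its canonical string form.

    Gold maps to ``"gold"``; everything else to ``"L<ligand_id>:<moiety>"``.
    """
    if moiety == "gold":
        return "gold"
    return f"L{ligand_id}:{moiety}"


def parse_fragment_key(key: str) -> tuple[int, str]:
    """Inverse of :func:`fragment_key`."""
    if key == "gold":
        return GOLD_FRAGMENT
    if not key.startswith("L") or ":" not in key:
        raise FormatError(f"malformed fragment key {key!r}")
    lig, moiety = key[1:].split(":", 1)
    if moiety not in MOIETIES:
        raise FormatError(f"unknown moiety {moiety!r} in fragment key {key!r}")
    return int(lig), moiety


# ---------------------------------------------------------------------------
# Snapshot
# ---------------------------------------------------------------------------


@dataclass
class Snapshot:
    """One frame of one system in one charge state.

    Attributes
    ----------
    system_id:
        Free-text system identifier, e.g. ``"alkane"``.
    state:
        ``"neutral"`` or ``"cation"`` — which trajectory the frame belongs to.
    frame_index:
        0-based frame number within the trajectory.
    elements:
        Element symbol per atom, file order.
    coords:
        (n_atoms, 3) float array, Å.
    ligand_ids:
        Per-atom ligand index; −1 for gold and solvent atoms.
    moieties:
        Per-atom moiety token (see :data:`MOIETIES`).
    roles:
        Per-atom role tag, empty string for most atoms.  The four atoms of
        the guanine–linker dihedral carry ``dihedral_a`` … ``dihedral_d``
        (a, b on the nucleobase, c, d on the linker, with b–c the rotable
        bond); descriptor extraction requires them.
    """

    system_id: str
    state: str
    frame_index: int
    elements: list[str]
    coords: np.ndarray
    ligand_ids: np.ndarray
    moieties: list[str]
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.ligand_ids = np.asarray(self.ligand_ids, dtype=int)
        if not self.roles:
            self.roles = [""] * len(self.elements)
        self.validate()

    def validate(self) -> None:
        n = len(self.elements)
        if n < 1:
            raise FormatError("snapshot must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise FormatError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} elements"
            )
        if len(self.ligand_ids) != n or len(self.moieties) != n:
            raise FormatError(
                f"fragment map length ({len(self.ligand_ids)} ligand ids, "
                f"{len(self.moieties)} moieties) does not match atom count {n}"
            )
        if len(self.roles) != n:
            raise FormatError("roles length does not match atom count")
        if self.state not in ("neutral", "cation"):
            raise FormatError(f"unknown state {self.state!r}")
        if self.frame_index < 0:
            raise FormatError("frame_index must be >= 0")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("coordinates must be finite")
        for i, m in enumerate(self.moieties):
            if m not in MOIETIES:
                raise FormatError(f"unknown moiety token {m!r} at atom {i}")
            lig = int(self.ligand_ids[i])
            if m in ("gold", "solvent") and lig != NO_LIGAND:
                raise FormatError(
                    f"atom {i} is {m} but carries ligand_id {lig}; gold and "
                    f"solvent atoms must have ligand_id -1"
                )
            if m in ("nucleobase", "linker") and lig < 0:
                raise FormatError(
                    f"atom {i} is {m} but has no ligand_id (got {lig})"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def ligands(self) -> list[int]:
        """Sorted list of ligand ids present in the frame."""
        return sorted({int(l) for l in self.ligand_ids if l >= 0})

    def atoms_of(self, ligand_id: int, moiety: str | None = None) -> np.ndarray:
        """Indices of the atoms of one ligand (optionally one moiety)."""
        mask = self.ligand_ids == ligand_id
        if moiety is not None:
            mask &= np.array([m == moiety for m in self.moieties])
        return np.nonzero(mask)[0]

    def gold_atoms(self) -> np.ndarray:
        return np.nonzero([m == "gold" for m in self.moieties])[0]

    def fragments(self) -> list[tuple[int, str]]:
        """All (ligand_id, moiety) fragments present, gold aggregated."""
        frags: set[tuple[int, str]] = set()
        for lig, m in zip(self.ligand_ids, self.moieties):
            if m == "gold":
                frags.add(GOLD_FRAGMENT)
            elif m == "solvent":
                frags.add((NO_LIGAND, "solvent"))
            else:
                frags.add((int(lig), m))
        return sorted(frags)


# ---------------------------------------------------------------------------
# ScenarioSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """One hole-delocalization scenario.

    ``qm_fragments`` lists the fragments in the QM region as
    (ligand_id, moiety) pairs, with gold represented by
    :data:`GOLD_FRAGMENT`.  ``hole_allowed`` is the subset that may host the
    hole under the constrained-DFT constraint being emulated.
    """

    label: str
    qm_fragments: frozenset[tuple[int, str]]
    hole_allowed: frozenset[tuple[int, str]]

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise UsageError(f"unknown scenario label {self.label!r}")
        if not self.hole_allowed:
            raise UsageError("hole_allowed must be non-empty")
        if not self.hole_allowed <= self.qm_fragments:
            raise UsageError("hole_allowed must be a subset of qm_fragments")
        if self.label == "I":
            nb = [f for f in self.hole_allowed if f[1] == "nucleobase"]
            if len(self.hole_allowed) != 1 or len(nb) != 1:
                raise UsageError(
                    "scenario I must allow the hole on exactly one nucleobase"
                )
        if self.label == "V" and GOLD_FRAGMENT not in self.hole_allowed:
            raise UsageError("scenario V must allow the hole on gold")

    @property
    def includes_gold(self) -> bool:
        return GOLD_FRAGMENT in self.qm_fragments


def default_scenarios(reference_ligand: int = 0, neighbor_ligand: int = 1) -> dict[str, ScenarioSpec]:
    """The five canonical scenarios for a reference ligand and its neighbour.

    I   hole on the reference nucleobase only (QM region: one ligand);
    II  hole shared between two nucleobases (QM region: two ligands);
    III hole over the full reference ligand;
    IV  hole over two full ligands;
    V   hole over the reference ligand plus the nearest gold atoms.
    """
    r, s = reference_ligand, neighbor_ligand
    one = frozenset({(r, "nucleobase"), (r, "linker")})
    two = frozenset(
        {(r, "nucleobase"), (r, "linker"), (s, "nucleobase"), (s, "linker")}
    )
    with_gold = one | {GOLD_FRAGMENT}
    return {
        "I": ScenarioSpec("I", one, frozenset({(r, "nucleobase")})),
        "II": ScenarioSpec(
            "II", two, frozenset({(r, "nucleobase"), (s, "nucleobase")})
        ),
        "III": ScenarioSpec("III", one, one),
        "IV": ScenarioSpec("IV", two, two),
        "V": ScenarioSpec("V", with_gold, with_gold),
    }


# ---------------------------------------------------------------------------
# Energy / charge records and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyRecord:
    """One vertical gap, in eV, tied to a frame and a scenario/calc label."""

    system_id: str
    frame_index: int
    scenario: str
    kind: str  # "VIE" | "VAE"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("VIE", "VAE"):
            raise UsageError(f"kind must be VIE or VAE, got {self.kind!r}")


@dataclass
class ChargeDelta:
    """Per-atom cation-minus-neutral charges (e) for one frame."""

    system_id: str
    frame_index: int
    scenario: str
    per_atom_delta: np.ndarray

    def __post_init__(self) -> None:
        self.per_atom_delta = np.asarray(self.per_atom_delta, dtype=float)

    def check_one_hole(self, tol: float = ONE_HOLE_TOL) -> None:
        total = float(self.per_atom_delta.sum())
        if abs(total - 1.0) > tol:
            raise DataError(
                f"charge delta for frame {self.frame_index} sums to "
                f"{total:.6f} e, violating the one-hole condition (tol {tol})"
            )


@dataclass(frozen=True)
class RedoxResult:
    """Ensemble linear-response redox quantities for one calc or scenario.

    ``delta_e_red`` = (⟨VIE⟩ + ⟨VAE⟩)/2 is the one-electron oxidation
    quantity; ``lambda_reorg`` = (⟨VIE⟩ − ⟨VAE⟩)/2 the reorganization
    energy.  Standard errors are plain SE of the mean, propagated in
    quadrature for the half-sum.
    """

    mean_vie: float
    mean_vae: float
    delta_e_red: float
    lambda_reorg: float
    se_vie: float
    se_vae: float
    se_delta: float
    n_vie: int
    n_vae: int

    def __post_init__(self) -> None:
        lo = min(self.mean_vae, self.mean_vie)
        hi = max(self.mean_vae, self.mean_vie)
        if not (lo - 1e-9 <= self.delta_e_red <= hi + 1e-9):
            raise DataError("delta_e_red must lie between mean VAE and mean VIE")


# ---------------------------------------------------------------------------
# Geometry IO
# ---------------------------------------------------------------------------

_FRAGMAP_COLUMNS = ["atom_index", "ligand_id", "moiety", "role"]


def read_snapshot(
    path: str | Path,
    fragment_map_path: str | Path,
    *,
    system_id: str | None = None,
    state: str = "neutral",
    frame_index: int = 0,
) -> Snapshot:
    """Read a geometry (XYZ or PDB) plus its fragment map into a Snapshot.

    The fragment map is a CSV with columns ``atom_index, ligand_id, moiety``
    and an optional ``role`` column; rows must cover each atom exactly once,
    in any order.  Atom order follows the geometry file.
    """
    import MDAnalysis as mda

    path = Path(path)
    with _quiet_mda():
        u = mda.Universe(str(path))
    coords = u.atoms.positions.astype(float)
    try:
        elements = [str(e).capitalize() for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        elements = [str(n).capitalize() for n in u.atoms.names]

    fmap = pd.read_csv(fragment_map_path)
    missing = {"atom_index", "ligand_id", "moiety"} - set(fmap.columns)
    if missing:
        raise FormatError(f"fragment map lacks columns {sorted(missing)}")
    if len(fmap) != len(elements):
        raise FormatError(
            f"geometry has {len(elements)} atoms but fragment map has "
            f"{len(fmap)} rows"
        )
    fmap = fmap.sort_values("atom_index")
    if list(fmap["atom_index"]) != list(range(len(elements))):
        raise FormatError("fragment map atom_index must cover 0..n_atoms-1")
    roles = (
        fmap["role"].fillna("").astype(str).replace("nan", "").tolist()
        if "role" in fmap.columns
        else [""] * len(elements)
    )
    return Snapshot(
        system_id=system_id if system_id is not None else path.stem,
        state=state,
        frame_index=frame_index,
        elements=elements,
        coords=coords,
        ligand_ids=fmap["ligand_id"].to_numpy(int),
        moieties=fmap["moiety"].astype(str).tolist(),
        roles=roles,
    )


def write_snapshot(snapshot: Snapshot, path: str | Path, fragment_map_path: str | Path) -> None:
    """Write a snapshot as XYZ plus a fragment-map CSV (inverse of read)."""
    path = Path(path)
    lines = [str(snapshot.n_atoms), f"{snapshot.system_id} frame={snapshot.frame_index} state={snapshot.state}"]
    for el, (x, y, z) in zip(snapshot.elements, snapshot.coords):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        {
            "atom_index": np.arange(snapshot.n_atoms),
            "ligand_id": snapshot.ligand_ids,
            "moiety": snapshot.moieties,
            "role": snapshot.roles,
        }
    ).to_csv(fragment_map_path, index=False)


class _quiet_mda:
    """Suppress MDAnalysis element-guessing chatter."""

    def __enter__(self):
        import warnings

        self._ctx = warnings.catch_warnings()
        self._ctx.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._ctx.__exit__(*exc)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

ENERGY_COLUMNS = ["system_id", "frame_index", "scenario", "kind", "value_eV"]
CHARGE_COLUMNS = ["system_id", "frame_index", "scenario", "atom_index", "delta_e"]


def write_tables(records: Sequence[EnergyRecord] | Sequence[ChargeDelta], path: str | Path) -> None:
    """Write a homogeneous list of records as CSV with fixed column order.

    Energy tables use columns ``system_id, frame_index, scenario, kind,
    value_eV``; charge tables are long-format with ``system_id, frame_index,
    scenario, atom_index, delta_e``.  Floats are written at full precision,
    so a read-back reproduces them exactly.
    """
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise UsageError(f"mixed record kinds in one table: {sorted(k.__name__ for k in kinds)}")
    if not records:
        # kind unknowable: default to the energy header
        pd.DataFrame(columns=ENERGY_COLUMNS).to_csv(path, index=False)
        return
    if isinstance(records[0], EnergyRecord):
        df = pd.DataFrame(
            [
                (r.system_id, r.frame_index, r.scenario, r.kind, r.value)
                for r in records
            ],
            columns=ENERGY_COLUMNS,
        )
    elif isinstance(records[0], ChargeDelta):
        rows = []
        for r in records:
            for i, dq in enumerate(r.per_atom_delta):
                rows.append((r.system_id, r.frame_index, r.scenario, i, dq))
        df = pd.DataFrame(rows, columns=CHARGE_COLUMNS)
    else:
        raise UsageError(f"unsupported record type {type(records[0]).__name__}")
    df.to_csv(path, index=False)


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ENERGY_COLUMNS:
        raise FormatError(
            f"energy table columns {list(df.columns)} != {ENERGY_COLUMNS}"
        )
    return [
        EnergyRecord(str(r.system_id), int(r.frame_index), str(r.scenario), str(r.kind), float(r.value_eV))
        for r in df.itertuples()
    ]


def read_charge_table(path: str | Path) -> list[ChargeDelta]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CHARGE_COLUMNS:
        raise FormatError(
            f"charge table columns {list(df.columns)} != {CHARGE_COLUMNS}"
        )
    out: list[ChargeDelta] = []
    for (sys_id, frame, scen), grp in df.groupby(
        ["system_id", "frame_index", "scenario"], sort=True
    ):
        grp = grp.sort_values("atom_index")
        if list(grp["atom_index"]) != list(range(len(grp))):
            raise FormatError(
                f"charge table for frame {frame} has gaps in atom_index"
            )
        out.append(
            ChargeDelta(str(sys_id), int(frame), str(scen), grp["delta_e"].to_numpy(float))
        )
    return out


# ---------------------------------------------------------------------------
# ScenarioSpec JSON IO
# ---------------------------------------------------------------------------


def write_scenarios(scenarios: dict[str, ScenarioSpec], path: str | Path) -> None:
    payload = {
        label: {
            "qm_fragments": sorted(fragment_key(*f) for f in s.qm_fragments),
            "hole_allowed": sorted(fragment_key(*f) for f in s.hole_allowed),
        }
        for label, s in scenarios.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_scenarios(path: str | Path) -> dict[str, ScenarioSpec]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for label, body in payload.items():
        out[label] = ScenarioSpec(
            label,
            frozenset(parse_fragment_key(k) for k in body["qm_fragments"]),
            frozenset(parse_fragment_key(k) for k in body["hole_allowed"]),
        )
    return out
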