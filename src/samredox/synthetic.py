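"""Synthetic SAM ensembles with the statistical structure the analysis assumes.

The real inputs of this pipeline are QM/MM/COSMO vertical gaps and
constrained-DFT charge differences computed over MD snapshots of
guanine-thiolate monolayers on Au(100).  Those engines are out of scope;
this module generates stand-in ensembles whose *statistics* match what the
downstream stages assume, so every stage can be exercised and validated at
desk scale:

* idealized Au(100) slab + ligand grid geometries, with per-frame
  guanine–linker dihedrals drawn from a wrapped normal and
  nearest-neighbour nucleobase centroid distances drawn from a normal
  centred near 5 Å;
* VIE/VAE ensembles as ``centre(linker, kind) + scenario offset +
  angle_coupling × stacking angle + Gaussian noise``, with the noise shared
  across scenario labels for a given frame (common random numbers — the
  same snapshot re-evaluated under a different QM constraint), which makes
  the additive-scheme closure exact;
* per-atom charge differences with fragment-level hole fractions drawn
  from a Dirichlet centred on a per-scenario profile (e.g. ~75 % gold /
  ~25 % ligand in scenario V).

Everything is reproducible bit-for-bit from ``GeneratorParams.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    GOLD_FRAGMENT,
    ChargeDelta,
    EnergyRecord,
    ScenarioSpec,
    Snapshot,
    UsageError,
    default_scenarios,
)

__all__ = [
    "GeneratorParams",
    "LINKERS",
    "DEFAULT_SHE_REFERENCE",
    "default_params",
    "build_sam",
    "sample_energies",
    "sample_charges",
    "default_fragment_profile",
]

LINKERS = ("alkane", "alkene", "arene")

#: Absolute potential of the standard hydrogen electrode used to convert
#: ΔE_red (eV) to an oxidation potential (V).  Configurable everywhere it
#: is consumed; 4.28 V is a common literature value for the aqueous SHE.
DEFAULT_SHE_REFERENCE = 4.28

# Ensemble centres per linker chemistry.  Dihedral centres follow the
# minima of the relaxed guanine–linker scans that the MD ensembles track
# (90 deg thioalkane, 15 deg thioalkene, 45 deg cationic thioarene; the
# neutral thioarene populates a 10-30 deg band, emulated at 20 deg).
# VIE centres: ~6.0 / 6.5 / 5.5 eV for alkane / alkene / arene.
_DIHEDRAL_CENTER = {
    ("alkane", "neutral"): 90.0,
    ("alkane", "cation"): 90.0,
    ("alkene", "neutral"): 15.0,
    ("alkene", "cation"): 15.0,
    ("arene", "neutral"): 20.0,
    ("arene", "cation"): 45.0,
}
_VIE_CENTER = {"alkane": 6.0, "alkene": 6.5, "arene": 5.5}

# Default additive scenario offsets (eV) relative to scenario I; chosen so
# the downstream redox stage shows the mechanism signature: I ~ II > III >
# IV >> V (the potential collapses once the hole can reach gold).
DEFAULT_SCENARIO_OFFSETS = {"I": 0.0, "II": 0.0, "III": -0.1, "IV": -0.4, "V": -1.5}

_LINKER_BEADS = {"alkane": 4, "alkene": 3, "arene": 6}
_RING_ELEMENTS = ["C", "N", "C", "N", "C", "C", "N", "C", "N"]
_RING_RADIUS = 1.4  # Å, aromatic-ring scale

# internal RNG stream tags so the three generators never share draws
_STREAM_GEOM = 11
_STREAM_VIE = 21
_STREAM_VAE = 22
_STREAM_CHARGE = 31


@dataclass
class GeneratorParams:
    """Parameters of the synthetic ensemble generator.

    Angles in degrees, distances in Å, energies in eV, charges in e.
    """

    linker: str = "alkane"
    state: str = "neutral"
    n_ligands_x: int = 2
    n_ligands_y: int = 2
    n_frames: int = 200
    dihedral_center: float | None = None  # None -> per-linker default
    dihedral_spread: float = 12.0
    distance_center: float = 5.0
    distance_spread: float = 0.3
    vie_center: float | None = None  # None -> per-linker default
    vae_center: float | None = None  # None -> vie_center - 1.0
    energy_sd: float = 0.3
    angle_coupling: float = 0.01  # eV per degree of stacking angle
    scenario_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_OFFSETS)
    )
    hole_profile: dict[str, float] | None = None  # moiety -> fraction
    dirichlet_concentration: float = 200.0
    primary_share: float = 0.95  # nucleobase localization, scenario II
    pair_share: float = 0.55  # milder nucleobase preference, scenario IV
    charge_noise_sd: float = 0.005  # e, on atoms outside the hole region
    lattice_constant: float = 4.08  # Å, fcc gold
    she_reference: float = DEFAULT_SHE_REFERENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker not in LINKERS:
            raise UsageError(f"unknown linker {self.linker!r}; choose from {LINKERS}")
        if self.state not in ("neutral", "cation"):
            raise UsageError(f"state must be neutral or cation, got {self.state!r}")
        if self.n_ligands_x < 1 or self.n_ligands_y < 1:
            raise UsageError("ligand grid dimensions must be >= 1")
        if self.n_frames < 1:
            raise UsageError("n_frames must be >= 1")
        if self.dihedral_spread <= 0 or self.distance_spread <= 0:
            raise UsageError("spreads must be > 0")
        if self.energy_sd < 0:
            raise UsageError("energy_sd must be >= 0")
        if self.hole_profile is not None:
            vals = np.array(list(self.hole_profile.values()), dtype=float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise UsageError("hole_profile must be non-negative and sum to 1")

    @property
    def dihedral_center_deg(self) -> float:
        if self.dihedral_center is not None:
            return self.dihedral_center
        return _DIHEDRAL_CENTER[(self.linker, self.state)]

    @property
    def vie_center_eV(self) -> float:
        return self.vie_center if self.vie_center is not None else _VIE_CENTER[self.linker]

    @property
    def vae_center_eV(self) -> float:
        return self.vae_center if self.vae_center is not None else self.vie_center_eV - 1.0

    @property
    def n_ligands(self) -> int:
        return self.n_ligands_x * self.n_ligands_y

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        """Deterministic per-stream generator derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, *extra))
        )


def default_params(linker: str, state: str = "neutral", **overrides) -> GeneratorParams:
    """Study-condition defaults for one linker chemistry and charge state."""
    return replace(GeneratorParams(linker=linker, state=state), **overrides)


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Fold angles into (-180, 180]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    return w


def _ligand_atoms(linker: str, dihedral_deg: float, origin: np.ndarray):
    """Coarse ligand geometry: S anchor, linker beads, 9-atom ring proxy.

    The ring is built in the xz-plane and rotated about the (vertical)
    guanine–linker bond by the requested dihedral, so the measured torsion
    of the tagged atom quadruple equals ``dihedral_deg`` by construction.
    """
    m = _LINKER_BEADS[linker]
    elements: list[str] = ["S"]
    roles: list[str] = [""]
    moieties: list[str] = ["linker"]
    coords: list[np.ndarray] = [origin + np.array([0.0, 0.0, 1.8])]

    z_s = 1.8
    for k in range(1, m + 1):
        if k == m:
            x = 0.0  # top bead sits on the bond axis
        elif k == m - 1:
            x = 0.4  # the dihedral reference bead, off-axis toward +x
        else:
            x = 0.35 * (-1.0) ** k
        coords.append(origin + np.array([x, 0.0, z_s + 1.3 * k]))
        elements.append("C")
        if k == m:
            roles.append("dihedral_c")
        elif k == m - 1:
            roles.append("dihedral_d")
        else:
            roles.append("")
        moieties.append("linker")

    z_c = z_s + 1.3 * m
    anchor = origin + np.array([0.0, 0.0, z_c + 1.4])
    theta = math.radians(dihedral_deg)
    ct, st = math.cos(theta), math.sin(theta)
    for j in range(9):
        phi = math.radians(40.0 * j)
        u = _RING_RADIUS * math.sin(phi)
        v = _RING_RADIUS * (1.0 - math.cos(phi))
        coords.append(anchor + np.array([u * ct, u * st, v]))
        elements.append(_RING_ELEMENTS[j])
        if j == 0:
            roles.append("dihedral_b")
        elif j == 1:
            roles.append("dihedral_a")
        else:
            roles.append("")
        moieties.append("nucleobase")
    return elements, coords, moieties, roles


def build_sam(params: GeneratorParams) -> list[Snapshot]:
    """Generate an ensemble of idealized SAM snapshots.

    Each frame holds a fixed Au(100) surface mesh and an
    ``n_ligands_x × n_ligands_y`` grid of coarse ligands.  Per frame, the
    ligand grid pitch is drawn from ``N(distance_center, distance_spread)``
    (so nearest-neighbour nucleobase centroid distances follow that normal
    exactly), and each ligand's guanine–linker dihedral from a wrapped
    normal at ``dihedral_center``.
    """
    rng = params.rng(_STREAM_GEOM)
    nx, ny = params.n_ligands_x, params.n_ligands_y

    # fixed gold mesh: (100) surface nearest-neighbour pitch a/sqrt(2)
    g = params.lattice_constant / math.sqrt(2.0)
    extent = max(nx - 1, ny - 1) * params.distance_center + 2.0 * g
    n_mesh = max(2, int(math.ceil(extent / g)) + 1)
    gold_xy = [(g * ix - g, g * iy - g) for ix in range(n_mesh) for iy in range(n_mesh)]

    snapshots: list[Snapshot] = []
    for f in range(params.n_frames):
        pitch = rng.normal(params.distance_center, params.distance_spread)
        dihedrals = _wrap_deg(
            rng.normal(params.dihedral_center_deg, params.dihedral_spread, size=nx * ny)
        )
        elements: list[str] = []
        coords: list[np.ndarray] = []
        moieties: list[str] = []
        roles: list[str] = []
        ligand_ids: list[int] = []
        for x, y in gold_xy:
            elements.append("Au")
            coords.append(np.array([x, y, 0.0]))
            moieties.append("gold")
            roles.append("")
            ligand_ids.append(-1)
        lig = 0
        for ix in range(nx):
            for iy in range(ny):
                origin = np.array([ix * pitch, iy * pitch, 0.0])
                el, co, mo, ro = _ligand_atoms(params.linker, float(dihedrals[lig]), origin)
                elements.extend(el)
                coords.extend(co)
                moieties.extend(mo)
                roles.extend(ro)
                ligand_ids.extend([lig] * len(el))
                lig += 1
        snapshots.append(
            Snapshot(
                system_id=params.linker,
                state=params.state,
                frame_index=f,
                elements=elements,
                coords=np.array(coords),
                ligand_ids=np.array(ligand_ids),
                moieties=moieties,
                roles=roles,
            )
        )
    return snapshots


# ---------------------------------------------------------------------------
# Energy generation
# ---------------------------------------------------------------------------


def sample_energies(
    snapshots: Sequence[Snapshot],
    descriptors: Sequence[float],
    params: GeneratorParams,
    scenario: str,
) -> list[EnergyRecord]:
    """Emit one vertical gap per frame for one scenario (or calc) label.

    ``value = centre(kind, linker) + scenario_offsets[scenario]
    + angle_coupling × stacking_angle + N(0, energy_sd)``.

    ``descriptors`` is the per-frame stacking angle (degrees) of the
    reference ligand, aligned with ``snapshots``.  VIE is emitted for
    neutral-state snapshots, VAE for cationic ones.  The Gaussian noise
    stream depends only on (seed, kind, frame), never on the scenario
    label: re-labelling the constraint re-uses the same snapshot noise, so
    scenario differences are exactly their offset differences.
    """
    if len(descriptors) != len(snapshots):
        raise UsageError(
            f"{len(descriptors)} descriptors for {len(snapshots)} snapshots"
        )
    if scenario not in params.scenario_offsets:
        raise UsageError(
            f"scenario {scenario!r} not in scenario_offsets "
            f"{sorted(params.scenario_offsets)}"
        )
    offset = params.scenario_offsets[scenario]
    state = params.state
    kind = "VIE" if state == "neutral" else "VAE"
    center = params.vie_center_eV if kind == "VIE" else params.vae_center_eV
    stream = _STREAM_VIE if kind == "VIE" else _STREAM_VAE
    noise = params.rng(stream).normal(0.0, params.energy_sd, size=len(snapshots))
    records = []
    for i, (snap, angle) in enumerate(zip(snapshots, descriptors)):
        if snap.state != state:
            raise UsageError(
                f"snapshot frame {snap.frame_index} has state {snap.state!r} "
                f"but params.state is {state!r}"
            )
        value = center + offset + params.angle_coupling * float(angle) + noise[i]
        records.append(
            EnergyRecord(snap.system_id, snap.frame_index, scenario, kind, float(value))
        )
    return records


# ---------------------------------------------------------------------------
# Charge generation
# ---------------------------------------------------------------------------


def default_fragment_profile(
    scenario: ScenarioSpec, params: GeneratorParams
) -> dict[tuple[int, str], float]:
    """Mean hole fraction per allowed fragment for one scenario.

    Moiety totals come from ``params.hole_profile`` when given, otherwise
    from per-scenario defaults that emulate the constrained-DFT outcomes:
    scenario V puts ~75 % on gold with the remaining 25 % spread evenly
    over the reference ligand; vertical delocalization (III) puts roughly
    two-thirds on the nucleobase (55/45 for the conjugated alkene);
    horizontal sharing (II) localizes on a single nucleobase; two-ligand
    sharing (IV) is more equitable.  Within a moiety shared by several
    allowed fragments, the reference fragment (lowest ligand id) takes
    ``primary_share`` (scenario II) or ``pair_share`` (otherwise) of that
    moiety's mass; the rest is split evenly.
    """
    if params.hole_profile is not None:
        moiety_totals = dict(params.hole_profile)
    elif scenario.label == "I":
        moiety_totals = {"nucleobase": 1.0}
    elif scenario.label == "II":
        moiety_totals = {"nucleobase": 1.0}
    elif scenario.label == "III":
        if params.linker == "alkene":
            moiety_totals = {"nucleobase": 0.55, "linker": 0.45}
        else:
            moiety_totals = {"nucleobase": 2.0 / 3.0, "linker": 1.0 / 3.0}
    elif scenario.label == "IV":
        moiety_totals = {"nucleobase": 0.6, "linker": 0.4}
    else:  # V
        moiety_totals = {"gold": 0.75, "nucleobase": 0.125, "linker": 0.125}

    allowed_moieties = {m for _, m in scenario.hole_allowed}
    if set(moiety_totals) != allowed_moieties:
        raise UsageError(
            f"hole profile moieties {sorted(moiety_totals)} do not match the "
            f"moieties allowed in scenario {scenario.label} "
            f"({sorted(allowed_moieties)})"
        )

    share = params.primary_share if scenario.label == "II" else params.pair_share
    profile: dict[tuple[int, str], float] = {}
    for moiety, total in moiety_totals.items():
        frags = sorted(f for f in scenario.hole_allowed if f[1] == moiety)
        if len(frags) == 1:
            profile[frags[0]] = total
        else:
            profile[frags[0]] = total * share
            rest = total * (1.0 - share) / (len(frags) - 1)
            for fkey in frags[1:]:
                profile[fkey] = rest
    return profile


def sample_charges(
    snapshot: Snapshot,
    scenario: ScenarioSpec,
    params: GeneratorParams,
    fragment_profile: Mapping[tuple[int, str], float] | None = None,
) -> ChargeDelta:
    """Draw one per-atom charge-difference vector emulating constrained DFT.

    Fragment-level hole fractions are drawn from a Dirichlet centred on the
    fragment profile (concentration ``params.dirichlet_concentration``;
    ``inf`` degenerates to the profile itself), spread uniformly over each
    fragment's atoms.  Atoms outside ``hole_allowed`` receive small
    zero-mean Gaussian noise.  The final vector is renormalized so the
    total is exactly the one-hole charge +1 e.
    """
    profile = (
        dict(fragment_profile)
        if fragment_profile is not None
        else default_fragment_profile(scenario, params)
    )
    if set(profile) - set(scenario.hole_allowed):
        raise UsageError("fragment profile names fragments outside hole_allowed")
    rng = params.rng(_STREAM_CHARGE, snapshot.frame_index, _scenario_index(scenario.label))

    frags = sorted(f for f in profile if profile[f] > 0)
    means = np.array([profile[f] for f in frags], dtype=float)
    means = means / means.sum()
    conc = params.dirichlet_concentration
    if math.isinf(conc):
        fractions = means
    else:
        fractions = rng.dirichlet(conc * means)

    delta = np.zeros(snapshot.n_atoms)
    hole_atoms = np.zeros(snapshot.n_atoms, dtype=bool)
    for fkey, frac in zip(frags, fractions):
        idx = (
            snapshot.gold_atoms()
            if fkey == GOLD_FRAGMENT
            else snapshot.atoms_of(*fkey)
        )
        if len(idx) == 0:
            raise UsageError(f"snapshot has no atoms for fragment {fkey}")
        delta[idx] = frac / len(idx)
        hole_atoms[idx] = True
    if params.charge_noise_sd > 0:
        outside = ~hole_atoms
        delta[outside] = rng.normal(0.0, params.charge_noise_sd, size=int(outside.sum()))
    delta = delta / delta.sum()
    return ChargeDelta(snapshot.system_id, snapshot.frame_index, scenario.label, delta)


def _scenario_index(label: str) -> int:
    from .data_model import SCENARIO_LABELS

    return SCENARIO_LABELS.index(label)


def sample_charge_ensemble(
    snapshots: Sequence[Snapshot],
    scenario: ScenarioSpec,
    params: GeneratorParams,
) -> list[ChargeDelta]:
    """Convenience: one ChargeDelta per snapshot for one scenario."""
    return [sample_charges(s, scenario, params) for s in snapshots]
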