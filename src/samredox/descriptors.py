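"""Structural descriptors of the SAM: dihedral, stacking angle, distance.

Three per-frame geometric quantities drive the structure–energy analysis:

* the signed guanine–linker torsion (degrees, (−180, 180]), measured over
  the four role-tagged atoms ``dihedral_a..d`` of each ligand;
* the π-stacking angle between the nucleobase ring plane of a ligand and
  that of its nearest neighbour — the angle between least-squares plane
  normals, folded into [0, 90] so 0° means parallel (stacked) rings and
  90° perpendicular ones;
* the interligand distance — nucleobase heavy-atom centroid separation to
  the nearest neighbouring ligand, in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Snapshot, UsageError

__all__ = [
    "DescriptorRecord",
    "DegenerateGeometryError",
    "dihedral_angle",
    "stacking_angle",
    "plane_normal",
    "interligand_distance",
    "compute_descriptors",
    "descriptor_frame",
]

DESCRIPTOR_COLUMNS = [
    "system_id",
    "frame_index",
    "ligand_id",
    "dihedral_deg",
    "stacking_deg",
    "neighbor_id",
    "neighbor_dist_A",
]


class DegenerateGeometryError(ValueError):
    """Raised when points are too degenerate for a well-defined descriptor."""


@dataclass(frozen=True)
class DescriptorRecord:
    system_id: str
    frame_index: int
    ligand_id: int
    dihedral: float  # degrees, (-180, 180]
    stacking_angle: float  # degrees, [0, 90]
    neighbor_id: int
    neighbor_distance: float  # Å

    def __post_init__(self) -> None:
        if not (0.0 <= self.stacking_angle <= 90.0 + 1e-9):
            raise ValueError("stacking_angle must lie in [0, 90]")
        if self.neighbor_distance <= 0:
            raise ValueError("neighbor_distance must be > 0")
        if self.neighbor_id == self.ligand_id:
            raise ValueError("a ligand cannot be its own neighbour")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion about the p2–p3 axis, degrees in (−180, 180].

    Standard atan2 formulation: with b1 = p2−p1, b2 = p3−p2, b3 = p4−p3,
    the angle is atan2(|b2| b1·(b2×b3), (b1×b2)·(b2×b3)).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, name in ((p1, p2, "p1/p2"), (p2, p3, "p2/p3"), (p3, p4, "p3/p4")):
        if np.linalg.norm(b - a) < 1e-10:
            raise DegenerateGeometryError(f"coincident points {name}: {a} / {b}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError(
            f"collinear consecutive points among {p1}, {p2}, {p3}, {p4}"
        )
    angle = np.degrees(
        np.arctan2(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2))
    )
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def plane_normal(points) -> np.ndarray:
    """Unit normal of the least-squares plane through ≥3 points.

    The normal is the principal direction of smallest variance of the
    centroid-referenced coordinates (smallest-singular-value right vector);
    its overall sign is not meaningful.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise UsageError("plane fitting needs at least three 3-vectors")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise DegenerateGeometryError("points are collinear; no unique plane")
    return vt[2]


def stacking_angle(ring_a, ring_b) -> float:
    """Angle between best-fit plane normals of two rings, degrees in [0, 90]."""
    na = plane_normal(ring_a)
    nb = plane_normal(ring_b)
    c = abs(float(np.dot(na, nb)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _nucleobase_centroid(snapshot: Snapshot, ligand_id: int) -> np.ndarray:
    idx = snapshot.atoms_of(ligand_id, "nucleobase")
    heavy = [i for i in idx if snapshot.elements[i] != "H"]
    if not heavy:
        raise UsageError(f"ligand {ligand_id} has no nucleobase heavy atoms")
    return snapshot.coords[heavy].mean(axis=0)


def interligand_distance(snapshot: Snapshot, ligand_id: int) -> tuple[int, float]:
    """Nearest ligand by nucleobase heavy-atom centroid, with its distance (Å)."""
    ligands = snapshot.ligands()
    if len(ligands) < 2:
        raise UsageError("interligand distance needs at least two ligands")
    if ligand_id not in ligands:
        raise UsageError(f"ligand {ligand_id} not present in snapshot")
    ref = _nucleobase_centroid(snapshot, ligand_id)
    dists = {
        other: float(np.linalg.norm(_nucleobase_centroid(snapshot, other) - ref))
        for other in ligands
        if other != ligand_id
    }
    d_min = min(dists.values())
    # ties (square grids put two neighbours at the same pitch) break to the
    # lowest ligand id, so the partner is stable under rigid motions
    best_id = min(o for o, d in dists.items() if d <= d_min + 1e-6)
    return best_id, dists[best_id]


def _dihedral_atoms(snapshot: Snapshot, ligand_id: int) -> tuple[np.ndarray, ...]:
    idx = {}
    for i in snapshot.atoms_of(ligand_id):
        role = snapshot.roles[i]
        if role.startswith("dihedral_"):
            idx[role] = i
    needed = ("dihedral_a", "dihedral_b", "dihedral_c", "dihedral_d")
    missing = [r for r in needed if r not in idx]
    if missing:
        raise UsageError(
            f"ligand {ligand_id} lacks dihedral role tags {missing}; the "
            "fragment map must name the guanine-linker atom quadruple"
        )
    return tuple(snapshot.coords[idx[r]] for r in needed)


def ligand_descriptors(snapshot: Snapshot, ligand_id: int) -> DescriptorRecord:
    """All three descriptors for one ligand of one frame."""
    a, b, c, d = _dihedral_atoms(snapshot, ligand_id)
    dih = dihedral_angle(a, b, c, d)
    neighbor_id, dist = interligand_distance(snapshot, ligand_id)
    ring_ref = snapshot.coords[snapshot.atoms_of(ligand_id, "nucleobase")]
    ring_nb = snapshot.coords[snapshot.atoms_of(neighbor_id, "nucleobase")]
    stack = stacking_angle(ring_ref, ring_nb)
    return DescriptorRecord(
        snapshot.system_id,
        snapshot.frame_index,
        ligand_id,
        dih,
        stack,
        neighbor_id,
        dist,
    )


def compute_descriptors(snapshots, ligand_ids=None) -> list[DescriptorRecord]:
    """Descriptor records for every (frame, ligand) pair requested."""
    out: list[DescriptorRecord] = []
    for snap in snapshots:
        ids = snap.ligands() if ligand_ids is None else ligand_ids
        for lig in ids:
            out.append(ligand_descriptors(snap, lig))
    return out


def descriptor_frame(records) -> pd.DataFrame:
    """Descriptor records as a DataFrame with the documented column order."""
    return pd.DataFrame(
        [
            (
                r.system_id,
                r.frame_index,
                r.ligand_id,
                r.dihedral,
                r.stacking_angle,
                r.neighbor_id,
                r.neighbor_distance,
            )
            for r in records
        ],
        columns=DESCRIPTOR_COLUMNS,
    )
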