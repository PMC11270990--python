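"""Geometric descriptors against independent brute-force oracles."""

import math

import numpy as np
import pytest

from samredox.data_model import UsageError
from samredox.descriptors import (
    DegenerateGeometryError,
    compute_descriptors,
    dihedral_angle,
    interligand_distance,
    ligand_descriptors,
    plane_normal,
    stacking_angle,
)


def dihedral_oracle(p1, p2, p3, p4):
    """Rotate the p2-p3 bond onto z and measure the projected angle.

    Signed angle from the projection of (p1 - p2) to the projection of
    (p4 - p3) in the plane perpendicular to the bond, about the p2->p3
    direction.  Independent of the atan2 cross-product formulation used by
    the implementation.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    z = p3 - p2
    z = z / np.linalg.norm(z)
    a = np.array([1.0, 0.0, 0.0])
    if abs(z @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    x = np.cross(a, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    u, v = p1 - p2, p4 - p3
    ux, uy, vx, vy = u @ x, u @ y, v @ x, v @ y
    return math.degrees(math.atan2(ux * vy - uy * vx, ux * vx + uy * vy))


def random_rigid_motion(rng):
    """Uniform random rotation (QR of a Gaussian matrix) plus translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return q, t


def hexagon(radius=1.4):
    ang = np.radians(np.arange(6) * 60.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral_angle([1, 1, 0], [0, 1, 0], [0, -1, 0], [1, -1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        d = dihedral_angle([1, 1, 0], [0, 1, 0], [0, -1, 0], [-1, -1, 0])
        assert abs(d) == pytest.approx(180.0, abs=1e-12)

    def test_matches_rotation_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(101)
        n = 0
        while n < 1000:
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                d = dihedral_angle(*pts)
            except DegenerateGeometryError:
                continue
            o = dihedral_oracle(*pts)
            assert abs(((d - o + 180.0) % 360.0) - 180.0) < 1e-9
            n += 1

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError, match="coincident"):
            dihedral_angle([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_mirror_flips_sign_keeps_magnitude(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                d = dihedral_angle(*pts)
            except DegenerateGeometryError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            dm = dihedral_angle(*mirrored)
            if abs(abs(d) - 180.0) > 1e-6:  # +-180 is the same torsion
                assert dm == pytest.approx(-d, abs=1e-9)
            assert abs(dm) == pytest.approx(abs(d), abs=1e-9)


class TestStackingAngle:
    def test_parallel_translated_rings_give_zero(self):
        ring = hexagon()
        assert stacking_angle(ring, ring + [0, 0, 3.4]) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings_give_ninety(self):
        ring = hexagon()
        rot = ring @ _rot_x(90.0).T
        assert stacking_angle(ring, rot) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 60.0])
    def test_constructed_rotations_recovered(self, angle):
        ring = hexagon()
        rot = ring @ _rot_x(angle).T + np.array([0.0, 1.0, 4.0])
        assert stacking_angle(ring, rot) == pytest.approx(angle, abs=1e-9)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(6, 3))
            assert stacking_angle(a, b) == pytest.approx(stacking_angle(b, a), abs=1e-12)

    def test_angles_fold_into_0_90(self):
        ring = hexagon()
        rot = ring @ _rot_x(150.0).T
        assert stacking_angle(ring, rot) == pytest.approx(30.0, abs=1e-9)

    def test_collinear_points_raise(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            plane_normal(line)

    def test_too_few_points_rejected(self):
        with pytest.raises(UsageError):
            plane_normal(np.zeros((2, 3)))


class TestInterligandDistance:
    def test_two_ligands_five_angstrom(self, toy_snapshot):
        nid, d = interligand_distance(toy_snapshot, 0)
        assert nid == 1
        assert d == pytest.approx(5.0, abs=1e-12)

    def test_nearest_of_three(self):
        import copy

        snap = _grid_snapshot(offsets=[0.0, 4.0, 6.0, 9.0])
        nid, d = interligand_distance(snap, 0)
        assert nid == 1
        assert d == pytest.approx(4.0, abs=1e-12)

    def test_single_ligand_rejected(self):
        snap = _grid_snapshot(offsets=[0.0])
        with pytest.raises(UsageError, match="two ligands"):
            interligand_distance(snap, 0)

    def test_matches_exhaustive_pairwise_minimum(self):
        """200 random multi-ligand frames equal the brute-force oracle."""
        rng = np.random.default_rng(55)
        for _ in range(200):
            n_lig = rng.integers(2, 6)
            centers = rng.normal(scale=8.0, size=(n_lig, 3))
            snap = _cloud_snapshot(centers, rng)
            ref = int(rng.integers(n_lig))
            nid, d = interligand_distance(snap, ref)
            # oracle: exhaustive centroid pairwise minimum
            cents = [
                snap.coords[snap.atoms_of(l, "nucleobase")].mean(axis=0)
                for l in range(n_lig)
            ]
            dists = {
                l: np.linalg.norm(cents[l] - cents[ref])
                for l in range(n_lig) if l != ref
            }
            best = min(dists, key=dists.get)
            assert nid == best
            assert d == pytest.approx(dists[best], abs=1e-9)


class TestRigidMotionInvariance:
    def test_all_descriptors_invariant_under_rigid_motion(self, small_ensemble):
        """Rotating + translating a frame leaves all descriptors unchanged."""
        snap = small_ensemble[0]
        base = ligand_descriptors(snap, 0)
        rng = np.random.default_rng(17)
        for _ in range(100):
            q, t = random_rigid_motion(rng)
            moved = _with_coords(snap, snap.coords @ q.T + t)
            rec = ligand_descriptors(moved, 0)
            assert rec.dihedral == pytest.approx(base.dihedral, abs=1e-9)
            assert rec.stacking_angle == pytest.approx(base.stacking_angle, abs=1e-9)
            assert rec.neighbor_distance == pytest.approx(base.neighbor_distance, abs=1e-9)
            assert rec.neighbor_id == base.neighbor_id


def _rot_x(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _with_coords(snap, coords):
    from samredox.data_model import Snapshot

    return Snapshot(
        snap.system_id, snap.state, snap.frame_index, snap.elements,
        coords, snap.ligand_ids, snap.moieties, list(snap.roles),
    )


def _grid_snapshot(offsets):
    """Ligands whose 3-atom nucleobases sit at given x offsets."""
    from samredox.data_model import Snapshot

    elements, coords, ligand_ids, moieties = [], [], [], []
    for lig, x0 in enumerate(offsets):
        for dx, dy in [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]:
            elements.append("C")
            coords.append([x0 + dx, dy, 3.0])
            ligand_ids.append(lig)
            moieties.append("nucleobase")
    return Snapshot("grid", "neutral", 0, elements, np.array(coords),
                    np.array(ligand_ids), moieties)


def _cloud_snapshot(centers, rng):
    from samredox.data_model import Snapshot

    elements, coords, ligand_ids, moieties = [], [], [], []
    for lig, c in enumerate(centers):
        # symmetric offsets keep the centroid exactly at c
        for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]:
            elements.append("C")
            coords.append(c + np.array(off, dtype=float))
            ligand_ids.append(lig)
            moieties.append("nucleobase")
    return Snapshot("cloud", "neutral", 0, elements, np.array(coords),
                    np.array(ligand_ids), moieties)
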