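"""Statistical contracts of the synthetic ensemble generator."""

import math

import numpy as np
import pytest

from samredox.data_model import GOLD_FRAGMENT, UsageError, default_scenarios
from samredox.descriptors import compute_descriptors
from samredox.synthetic import (
    GeneratorParams,
    build_sam,
    default_fragment_profile,
    default_params,
    sample_charges,
    sample_energies,
)


class TestBuildSam:
    def test_single_ligand_grid(self):
        p = default_params("alkane", n_frames=1, n_ligands_x=1, n_ligands_y=1)
        (snap,) = build_sam(p)
        assert snap.ligands() == [0]
        assert len(snap.gold_atoms()) > 0

    def test_same_seed_bit_identical(self):
        p = default_params("alkene", n_frames=3, seed=42)
        a = build_sam(p)
        b = build_sam(p)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.coords, sb.coords)

    def test_different_seed_differs(self):
        a = build_sam(default_params("alkene", n_frames=2, seed=1))
        b = build_sam(default_params("alkene", n_frames=2, seed=2))
        assert not np.allclose(a[0].coords, b[0].coords)

    def test_invalid_grid_rejected(self):
        with pytest.raises(UsageError):
            default_params("alkane", n_ligands_x=0)

    def test_dihedral_center_recovered_at_500_frames(self):
        """Measured guanine-linker dihedrals centre at 90 deg for alkane."""
        p = default_params("alkane", n_frames=500, n_ligands_x=1,
                           n_ligands_y=2, seed=9)
        recs = compute_descriptors(build_sam(p), ligand_ids=[0])
        d = np.array([r.dihedral for r in recs])
        se = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean() - 90.0) < 3 * se

    def test_distance_center_recovered(self):
        p = default_params("arene", n_frames=400, seed=3)
        recs = compute_descriptors(build_sam(p), ligand_ids=[0])
        d = np.array([r.neighbor_distance for r in recs])
        se = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean() - p.distance_center) < 3 * se
        assert abs(d.std(ddof=1) - p.distance_spread) < 0.2 * p.distance_spread

    def test_cation_arene_uses_45_deg_centre(self):
        p = default_params("arene", state="cation")
        assert p.dihedral_center_deg == 45.0
        assert default_params("arene").dihedral_center_deg == 20.0


class TestSampleEnergies:
    def _noiseless(self, linker, state, **kw):
        return default_params(linker, state, n_frames=5, energy_sd=0.0,
                              angle_coupling=0.0, **kw)

    def test_degenerate_alkene_vie_is_exactly_center(self):
        p = self._noiseless("alkene", "neutral",
                            scenario_offsets={"I": 0.0})
        snaps = build_sam(p)
        recs = sample_energies(snaps, [0.0] * len(snaps), p, "I")
        assert all(r.kind == "VIE" for r in recs)
        assert all(r.value == pytest.approx(6.5, abs=1e-12) for r in recs)

    def test_offset_shifts_additively(self):
        p = self._noiseless("alkene", "neutral",
                            scenario_offsets={"V": -2.0})
        snaps = build_sam(p)
        recs = sample_energies(snaps, [0.0] * len(snaps), p, "V")
        assert all(r.value == pytest.approx(4.5, abs=1e-12) for r in recs)

    def test_unknown_scenario_rejected(self):
        p = self._noiseless("alkane", "neutral")
        snaps = build_sam(p)
        with pytest.raises(UsageError, match="W"):
            sample_energies(snaps, [0.0] * len(snaps), p, "W")

    def test_cation_state_emits_vae(self):
        p = self._noiseless("alkane", "cation")
        snaps = build_sam(p)
        recs = sample_energies(snaps, [0.0] * len(snaps), p, "I")
        assert {r.kind for r in recs} == {"VAE"}
        assert recs[0].value == pytest.approx(5.0)  # vie_center - 1.0

    def test_sample_sd_recovers_generator_sd(self):
        p = default_params("alkane", n_frames=2000, energy_sd=0.3,
                           angle_coupling=0.0, seed=21)
        snaps = build_sam(p)
        recs = sample_energies(snaps, [0.0] * len(snaps), p, "I")
        sd = np.std([r.value for r in recs], ddof=1)
        assert abs(sd - 0.3) < 0.03

    def test_noise_shared_across_scenarios(self):
        """Common random numbers: scenario difference is exactly the offset."""
        p = default_params("alkane", n_frames=50, seed=4)
        snaps = build_sam(p)
        stack = [10.0] * len(snaps)
        a = sample_energies(snaps, stack, p, "I")
        b = sample_energies(snaps, stack, p, "IV")
        gaps = {round(x.value - y.value, 12) for x, y in zip(b, a)}
        assert gaps == {round(p.scenario_offsets["IV"], 12)}


class TestSampleCharges:
    def test_degenerate_dirichlet_puts_everything_on_profile(self, scenarios):
        p = default_params("alkane", n_frames=1, seed=8,
                           dirichlet_concentration=math.inf,
                           charge_noise_sd=0.0)
        (snap,) = build_sam(p)
        delta = sample_charges(snap, scenarios["I"], p)
        nb = snap.atoms_of(0, "nucleobase")
        assert delta.per_atom_delta[nb].sum() == pytest.approx(1.0, abs=1e-12)
        others = np.setdiff1d(np.arange(snap.n_atoms), nb)
        assert np.allclose(delta.per_atom_delta[others], 0.0)

    def test_total_is_exactly_one_hole(self, small_ensemble, small_params, scenarios):
        for scen in scenarios.values():
            delta = sample_charges(small_ensemble[0], scen, small_params)
            assert delta.per_atom_delta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scenario_v_gold_fraction_near_075(self, scenarios):
        p = default_params("alkane", n_frames=500, seed=13)
        snaps = build_sam(p)
        gold = snaps[0].gold_atoms()
        fracs = np.array([
            sample_charges(s, scenarios["V"], p).per_atom_delta[gold].sum()
            for s in snaps
        ])
        se = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.75) < 3 * se

    def test_profile_moiety_mismatch_rejected(self, small_ensemble, scenarios):
        p = default_params("alkane", hole_profile={"gold": 1.0})
        with pytest.raises(UsageError, match="moieties"):
            sample_charges(small_ensemble[0], scenarios["I"], p)

    def test_determinism(self, small_ensemble, small_params, scenarios):
        a = sample_charges(small_ensemble[3], scenarios["V"], small_params)
        b = sample_charges(small_ensemble[3], scenarios["V"], small_params)
        np.testing.assert_array_equal(a.per_atom_delta, b.per_atom_delta)

    def test_alkene_vertical_split_is_55_45(self, scenarios):
        p = default_params("alkene")
        prof = default_fragment_profile(scenarios["III"], p)
        assert prof[(0, "nucleobase")] == pytest.approx(0.55)
        assert prof[(0, "linker")] == pytest.approx(0.45)

    def test_scenario_v_profile_splits_ligand_evenly(self, scenarios):
        p = default_params("alkane")
        prof = default_fragment_profile(scenarios["V"], p)
        assert prof[GOLD_FRAGMENT] == pytest.approx(0.75)
        assert prof[(0, "nucleobase")] == pytest.approx(0.125)
        assert prof[(0, "linker")] == pytest.approx(0.125)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"dihedral_spread": 0.0},
        {"distance_spread": -1.0},
        {"hole_profile": {"gold": 0.5, "nucleobase": 0.2}},
        {"linker": "thiol"},
        {"state": "anion"},
        {"n_frames": 0},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(UsageError):
            GeneratorParams(**kw)
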