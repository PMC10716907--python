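"""Ensemble preprocessing, geometry statistics and I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from qtdg import (
    ComparisonRecord,
    ConformerEnsemble,
    energy_window_filter,
    identity_check,
    kabsch_rmsd,
    lowest_energy_conformer,
    make_toy_molecule,
    min_heavy_rmsd,
    radius_of_gyration,
    rg_ratio,
    rmsd_summary,
    rmsd_vs_rotors_regression,
    rotatable_bond_count,
    strip_to_largest_fragment,
)
from qtdg.ensembles import heavy_coordinates


def _ensemble_from(mol, energies=None, jitter_seeds=()):
    """Butane-style ensemble: base conformer plus rigidly rotated copies."""
    m = Chem.Mol(mol)
    base = m.GetConformer(0).GetPositions()
    for i, seed in enumerate(jitter_seeds, start=1):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=rng).as_matrix()
        conf = Chem.Conformer(m.GetNumAtoms())
        moved = base @ rot.T + rng.normal(size=3)
        for j, xyz in enumerate(moved):
            conf.SetAtomPosition(j, xyz.tolist())
        conf.SetId(i)
        m.AddConformer(conf, assignId=False)
    return ConformerEnsemble(mol=m, energies=energies)


class TestFragmentStripping:
    def test_single_component_unchanged(self, butane):
        assert strip_to_largest_fragment(butane) is butane

    def test_counterion_dropped(self):
        salt = make_toy_molecule("salt_pair")
        kept = strip_to_largest_fragment(salt)
        assert len(Chem.GetMolFrags(kept)) == 1
        assert sum(a.GetAtomicNum() > 1 for a in kept.GetAtoms()) == 8

    def test_tie_broken_by_total_atom_count(self):
        # ethane (2 heavy, 8 total with H) vs acetylene (2 heavy, 4 total)
        combo = Chem.CombineMols(
            Chem.AddHs(Chem.MolFromSmiles("C#C")),
            Chem.AddHs(Chem.MolFromSmiles("CC")),
        )
        kept = strip_to_largest_fragment(combo)
        assert kept.GetNumAtoms() == 8

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            strip_to_largest_fragment(Chem.Mol())


class TestIdentityCheck:
    def test_self_identity(self, butane):
        assert identity_check(butane, butane)

    def test_constitutional_isomers_differ(self):
        assert not identity_check(
            Chem.MolFromSmiles("CCCC"), Chem.MolFromSmiles("CC(C)C")
        )

    def test_identity_is_connectivity_level(self, butane):
        moved = Chem.Mol(butane)
        conf = moved.GetConformer()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 5.0, p.y, p.z))
        assert identity_check(butane, moved)


class TestEnergyFilters:
    def test_window_threshold(self, butane):
        ens = _ensemble_from(butane, energies=[0.0, 3.0, 5.9, 6.1],
                             jitter_seeds=(1, 2, 3))
        kept = energy_window_filter(ens, window=6.0)
        assert kept.n_conformers == 3
        assert list(kept.energies) == [0.0, 3.0, 5.9]

    def test_zero_window_keeps_minimum(self, butane):
        ens = _ensemble_from(butane, energies=[1.0, 0.5, 0.9], jitter_seeds=(1, 2))
        kept = energy_window_filter(ens, window=0.0)
        assert kept.n_conformers == 1 and kept.energies[0] == 0.5

    def test_all_equal_energies_all_kept(self, butane):
        ens = _ensemble_from(butane, energies=[2.0, 2.0, 2.0], jitter_seeds=(1, 2))
        assert energy_window_filter(ens, window=1.0).n_conformers == 3

    def test_window_nesting(self, butane):
        ens = _ensemble_from(butane, energies=[0.0, 1.5, 4.0, 7.0],
                             jitter_seeds=(1, 2, 3))
        small = energy_window_filter(ens, window=2.0)
        large = energy_window_filter(ens, window=5.0)
        assert set(small.labels) <= set(large.labels)

    def test_missing_energies_rejected(self, butane):
        with pytest.raises(ValueError, match="energies"):
            energy_window_filter(_ensemble_from(butane), window=6.0)

    def test_lowest_energy_conformer(self, butane):
        ens = _ensemble_from(butane, energies=[2.0, 0.5, 1.1], jitter_seeds=(1, 2))
        assert lowest_energy_conformer(ens) == 1
        tie = _ensemble_from(butane, energies=[0.5, 0.5], jitter_seeds=(1,))
        assert lowest_energy_conformer(tie) == 0


class TestRmsd:
    def test_ensemble_containing_reference_is_zero(self, butane):
        ens = _ensemble_from(butane, jitter_seeds=(1, 2))
        ref = butane.GetConformer(0).GetPositions()
        assert min_heavy_rmsd(ens, ref) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_removed(self, butane):
        ens = _ensemble_from(butane)
        ref = butane.GetConformer(0).GetPositions()
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert min_heavy_rmsd(ens, ref @ rot.T) == pytest.approx(0.0, abs=1e-9)

    def test_kabsch_against_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(6, 3))
        b = a @ Rotation.random(random_state=rng).as_matrix().T + rng.normal(size=3)
        b += rng.normal(scale=0.1, size=b.shape)
        est, scipy_rssd = Rotation.align_vectors(
            a - a.mean(0), b - b.mean(0)
        )
        assert kabsch_rmsd(a, b) == pytest.approx(scipy_rssd / np.sqrt(6), rel=1e-6)

    def test_three_atom_displacement_closed_form(self):
        # one point of an equilateral pair displaced; optimal alignment found
        # by brute-force search over rotations as the oracle
        a = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0]])
        b = a.copy()
        b[2, 1] += 0.3
        best = np.inf
        for ang in np.linspace(0, 2 * np.pi, 7201):
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            ac = a - a.mean(0)
            bc = b - b.mean(0)
            best = min(best, np.sqrt(((ac @ rot - bc) ** 2).sum() / 3))
        assert kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-5)

    def test_atom_count_mismatch_rejected(self, butane):
        ens = _ensemble_from(butane)
        with pytest.raises(ValueError, match="atom count"):
            min_heavy_rmsd(ens, np.zeros((3, 3)))


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_atoms_two_angstrom_apart(self):
        assert radius_of_gyration([[0, 0, 0], [2.0, 0, 0]]) == pytest.approx(1.0)

    def test_unit_square(self):
        sq = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        assert radius_of_gyration(sq) == pytest.approx(np.sqrt(0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))

    @given(st.integers(0, 10**6))
    def test_rigid_invariance_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(5, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        rg = radius_of_gyration(pts)
        assert radius_of_gyration(pts @ rot.T + 1.5) == pytest.approx(rg, rel=1e-9)
        assert radius_of_gyration(pts * 3.0) == pytest.approx(3.0 * rg, rel=1e-9)

    def test_rg_ratio(self):
        a = [[0, 0, 0], [2.0, 0, 0]]
        b = [[0, 0, 0], [4.0, 0, 0]]
        assert rg_ratio(a, a) == pytest.approx(1.0)
        assert rg_ratio(a, b) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            rg_ratio(a, [[1.0, 1.0, 1.0]])


class TestRotatableBonds:
    @pytest.mark.parametrize("smiles,expected", [
        ("CC", 0),          # both carbons terminal
        ("CCCC", 1),        # the single C2-C3 rotor
        ("c1ccccc1", 0),    # ring bonds excluded
        ("CC(=O)NC", 0),    # amide C-N excluded, rest terminal
        ("CCOCC", 2),
    ])
    def test_definition(self, smiles, expected):
        assert rotatable_bond_count(Chem.MolFromSmiles(smiles)) == expected

    def test_butane_fixture_brute_force(self, butane):
        # enumerate bonds against the stated definition independently
        mol = butane
        count = 0
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtom(), bond.GetEndAtom()
            if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                continue
            heavy = lambda a: [n for n in a.GetNeighbors() if n.GetAtomicNum() > 1]
            if i.GetAtomicNum() <= 1 or j.GetAtomicNum() <= 1:
                continue
            if len(heavy(i)) < 2 or len(heavy(j)) < 2:
                continue
            count += 1
        assert rotatable_bond_count(mol) == count == 1


class TestSummaries:
    def _rec(self, rotors, rmsd):
        return ComparisonRecord("m", rotors, rmsd, 1.0, 1.0)

    def test_regression_closed_form(self):
        recs = [self._rec(0, 0.1), self._rec(2, 0.5), self._rec(4, 0.9)]
        slope, intercept = rmsd_vs_rotors_regression(recs)
        assert slope == pytest.approx(0.2)
        assert intercept == pytest.approx(0.1)

    def test_flat_and_two_point_cases(self):
        flat = [self._rec(0, 0.4), self._rec(3, 0.4)]
        assert rmsd_vs_rotors_regression(flat)[0] == pytest.approx(0.0)
        two = [self._rec(1, 0.2), self._rec(3, 0.8)]
        slope, intercept = rmsd_vs_rotors_regression(two)
        assert slope * 1 + intercept == pytest.approx(0.2)
        assert slope * 3 + intercept == pytest.approx(0.8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rmsd_vs_rotors_regression([self._rec(2, 0.1), self._rec(2, 0.2)])

    def test_rmsd_summary(self):
        recs = [self._rec(0, r) for r in (0.1, 0.3, 0.7)]
        out = rmsd_summary(recs, thresholds=(0.5,))
        assert out["median"] == pytest.approx(0.3)
        assert out["fraction_le_0.5"] == pytest.approx(2 / 3)
        single = rmsd_summary([self._rec(0, 0.4)], thresholds=(0.5,))
        assert single["median"] == single["mean"] == pytest.approx(0.4)

    def test_fractions_monotone_in_threshold(self):
        recs = [self._rec(0, r) for r in (0.05, 0.3, 0.45, 0.9, 1.4)]
        out = rmsd_summary(recs, thresholds=(0.2, 0.5, 1.0))
        fr = [out["fraction_le_0.2"], out["fraction_le_0.5"], out["fraction_le_1.0"]]
        assert fr == sorted(fr)
        assert all(0.0 <= f <= 1.0 for f in fr)


class TestIO:
    def test_sdf_round_trip(self, butane, tmp_path):
        ens = _ensemble_from(butane, energies=[0.0, 1.2], jitter_seeds=(5,))
        path = tmp_path / "ens.sdf"
        ens.to_sdf(path)
        back = ConformerEnsemble.from_sdf(path)
        assert back.n_conformers == 2
        assert back.energies == pytest.approx([0.0, 1.2])
        np.testing.assert_allclose(
            back.coordinates(0), ens.coordinates(0), atol=1e-4
        )
        assert Chem.MolToSmiles(Chem.RemoveHs(back.mol)) == Chem.MolToSmiles(
            Chem.RemoveHs(ens.mol)
        )

    def test_sidecar_energy_csv(self, butane, tmp_path):
        ens = _ensemble_from(butane, jitter_seeds=(5,))
        ens.labels = ["confA", "confB"]
        path = tmp_path / "ens.sdf"
        ens.to_sdf(path)
        csv = tmp_path / "energies.csv"
        csv.write_text("label,energy\nconfA,0.7\nconfB,0.1\n")
        back = ConformerEnsemble.from_sdf(path, energy_tag="absent", energy_csv=csv)
        assert back.energies == pytest.approx([0.7, 0.1])

    def test_xyz_multiframe_reader(self, butane, tmp_path):
        ens = _ensemble_from(butane, jitter_seeds=(5,))
        path = tmp_path / "traj.xyz"
        with open(path, "w") as fh:
            for c in range(2):
                coords = ens.coordinates(c)
                fh.write(f"{ens.mol.GetNumAtoms()}\nframe{c}\n")
                for atom, (x, y, z) in zip(ens.mol.GetAtoms(), coords):
                    fh.write(f"{atom.GetSymbol()} {x:.6f} {y:.6f} {z:.6f}\n")
        back = ConformerEnsemble.from_xyz(path)
        assert back.n_conformers == 2
        assert Chem.MolToSmiles(Chem.RemoveHs(back.mol)) == "CCCC"
        np.testing.assert_allclose(back.coordinates(1), ens.coordinates(1), atol=1e-5)

    def test_heavy_coordinates_mask(self, butane):
        heavy = heavy_coordinates(butane)
        assert heavy.shape == (4, 3)
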