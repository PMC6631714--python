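"""Domain types and file round-trips for sites, ligands and pose ensembles."""
import warnings

import numpy as np
import pandas as pd
import pytest

from gtmdock.io import (
    FileFormatError,
    read_node_table,
    read_poses,
    read_site,
    write_node_table,
    write_pose_table,
    write_poses_sdf,
    write_site_mol2,
)
from gtmdock.structures import Atom, Ligand, SiteModel, assign_hbond_roles


class TestAtomValidation:
    def test_rejects_nonfinite_coords(self):
        with pytest.raises(ValueError, match="non-finite"):
            Atom(0, "C", [0.0, np.nan, 0.0])

    def test_rejects_unknown_element(self):
        with pytest.raises(ValueError, match="unsupported element"):
            Atom(0, "Xx", [0, 0, 0])

    def test_bondi_radius_default(self):
        assert Atom(0, "H", [0, 0, 0]).vdw_radius == 1.2
        assert Atom(0, "C", [0, 0, 0]).vdw_radius == 1.7


class TestHBondRoles:
    def test_donor_is_the_hydrogen(self):
        atoms = [Atom(0, "N", [0, 0, 0]), Atom(1, "H", [1.0, 0, 0]),
                 Atom(2, "C", [-1.5, 0, 0]), Atom(3, "H", [-2.6, 0, 0])]
        assign_hbond_roles(atoms, [(0, 1, 1), (0, 2, 1), (2, 3, 1)])
        assert atoms[1].is_hbd and not atoms[3].is_hbd
        assert not atoms[0].is_hbd

    def test_nitrogen_with_hydrogen_is_not_acceptor(self):
        atoms = [Atom(0, "N", [0, 0, 0]), Atom(1, "H", [1.0, 0, 0]),
                 Atom(2, "O", [3.0, 0, 0])]
        assign_hbond_roles(atoms, [(0, 1, 1)])
        assert not atoms[0].is_hba
        assert atoms[2].is_hba

    def test_positively_charged_oxygen_excluded(self):
        atoms = [Atom(0, "O", [0, 0, 0], formal_charge=1)]
        assign_hbond_roles(atoms, [])
        assert not atoms[0].is_hba


def test_key_atom_order_is_frozen():
    atoms = [Atom(i, "C", [float(i), 0, 0]) for i in range(4)]
    site = SiteModel(atoms, key_atom_indices=(1, 3))
    with pytest.raises(ValueError, match="frozen"):
        site.with_key_atoms((3, 1))


def test_disconnected_ligand_warns_but_builds():
    atoms = [Atom(0, "C", [0, 0, 0]), Atom(1, "C", [5, 0, 0])]
    with pytest.warns(UserWarning, match="disconnected"):
        lig = Ligand("L", atoms, [])
    assert len(lig.atoms) == 2


class TestSiteMol2:
    def test_roundtrip_preserves_charges_bitexact(self, toy_system, tmp_path):
        site = toy_system[0]
        path = tmp_path / "site.mol2"
        write_site_mol2(site, path)
        back = read_site(path)
        assert len(back.atoms) == len(site.atoms)
        for a, b in zip(site.atoms, back.atoms):
            assert b.partial_charge == a.partial_charge
            assert a.element == b.element
        assert np.allclose(site.coords, back.coords, atol=5e-7)

    def test_reading_twice_is_identical(self, toy_system, tmp_path):
        path = tmp_path / "site.mol2"
        write_site_mol2(toy_system[0], path)
        s1, s2 = read_site(path), read_site(path)
        assert np.array_equal(s1.coords, s2.coords)
        assert [a.element for a in s1.atoms] == [a.element for a in s2.atoms]

    def test_zero_charges_accepted_with_warning(self, tmp_path):
        atoms = [Atom(i, "C", [3.0 * i, 0, 0]) for i in range(3)]
        site = SiteModel(atoms)
        path = tmp_path / "zero.mol2"
        write_site_mol2(site, path)
        with pytest.warns(UserWarning, match="zero"):
            back = read_site(path)
        assert len(back.atoms) == 3

    def test_three_atom_charges_preserved(self, tmp_path):
        charges = (0.4, -0.8, 0.4)
        atoms = [Atom(i, "C", [3.0 * i, 0, 0], partial_charge=q)
                 for i, q in enumerate(charges)]
        path = tmp_path / "tri.mol2"
        write_site_mol2(SiteModel(atoms), path)
        back = read_site(path)
        assert tuple(a.partial_charge for a in back.atoms) == charges

    def test_unparseable_file_raises_format_error(self, tmp_path):
        path = tmp_path / "garbage.mol2"
        path.write_text("this is not a mol2 file\n")
        with pytest.raises((FileFormatError, ValueError)):
            read_site(path)


def test_pdb_site_gets_fallback_charges(tmp_path):
    pdb = tmp_path / "site.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  O   ALA A   1       2.200   1.200   0.000  1.00  0.00           O\n"
        "END\n"
    )
    site = read_site(pdb)
    assert site.provenance["charges"].startswith("fallback:")
    assert any(a.partial_charge != 0.0 for a in site.atoms)


class TestPoseSDF:
    def test_roundtrip_energy_and_ids(self, toy_system, toy_pool, tmp_path):
        _, ligand, _, _ = toy_system
        poses = toy_pool.poses[:5]
        path = tmp_path / "p.sdf"
        write_poses_sdf(path, ligand, poses)
        back = read_poses(path)
        assert len(back) == 5
        assert [p.energy for p in back] == [p.energy for p in poses]
        assert [p.conformer_id for p in back] == [p.conformer_id for p in poses]
        assert np.allclose(back[0].coords, poses[0].coords, atol=5e-5)

    def test_missing_energy_tag_names_record(self, toy_system, toy_pool, tmp_path):
        _, ligand, _, _ = toy_system
        path = tmp_path / "p.sdf"
        write_poses_sdf(path, ligand, toy_pool.poses[:3], energy_tag="other")
        with pytest.raises(FileFormatError, match="record 0"):
            read_poses(path)

    def test_empty_file_warns_returns_empty(self, tmp_path):
        path = tmp_path / "empty.sdf"
        path.write_text("")
        with pytest.warns(UserWarning, match="no pose records"):
            assert read_poses(path) == []

    def test_atom_count_mismatch_is_hard_error(self, toy_system, toy_pool, tmp_path):
        _, ligand, _, _ = toy_system
        path = tmp_path / "p.sdf"
        write_poses_sdf(path, ligand, toy_pool.poses[:2])
        small = Ligand("X", [Atom(0, "C", [0, 0, 0]), Atom(1, "C", [1.5, 0, 0])],
                       [(0, 1, 1)])
        from gtmdock.structures import Pose

        extra = Pose(toy_pool.ligand_id, "odd", np.zeros((2, 3)), -1.0)
        write_poses_sdf(tmp_path / "extra.sdf", small, [extra])
        with open(path, "a") as fh:
            fh.write((tmp_path / "extra.sdf").read_text())
        with pytest.raises(FileFormatError, match="atoms"):
            read_poses(path)


class TestNodeTable:
    def _landscape(self, toy_system, toy_pool):
        from gtmdock.contact_fp import compute_cf_matrix
        from gtmdock.gtm import GTM
        from gtmdock.landscapes import PropertyLandscape

        site, ligand, _, schema = toy_system
        X = compute_cf_matrix(toy_pool.poses, ligand, site, schema)
        gtm = GTM(n_nodes=16, n_rbfs=4, random_state=0).fit(X)
        y = np.array([p.rmsd_to_native for p in toy_pool.poses])
        return PropertyLandscape(gtm).fit(X, y)

    def test_roundtrip_identical(self, toy_system, toy_pool, tmp_path):
        ls = self._landscape(toy_system, toy_pool)
        path = tmp_path / "nodes.csv"
        write_node_table(ls, path)
        df = read_node_table(path)
        assert len(df) == 16
        assert list(df.columns) == ["node_index", "grid_x", "grid_y", "density", "value"]
        finite = ~np.isnan(ls.node_values_)
        assert np.array_equal(df["value"].to_numpy()[finite], ls.node_values_[finite])
        # second write/read cycle is bit-identical
        path2 = tmp_path / "nodes2.csv"
        write_node_table(ls, path2)
        assert path.read_text() == path2.read_text()

    def test_undefined_value_leaves_empty_cell_with_density(self, tmp_path):
        from gtmdock.landscapes import PropertyLandscape

        R = np.zeros((2, 4))
        R[0, 0] = R[1, 0] = 1.0
        ls = PropertyLandscape(None).fit(R, np.array([1.0, 3.0]))
        path = tmp_path / "n.csv"
        write_node_table(ls, path)
        df = read_node_table(path)
        assert np.isnan(df["value"].iloc[1])
        assert df["density"].notna().all()

    def test_uncoloured_landscape_errors(self, tmp_path):
        from gtmdock.landscapes import PropertyLandscape

        with pytest.raises(ValueError, match="not coloured|fit"):
            write_node_table(PropertyLandscape(None), tmp_path / "x.csv")


def test_pose_table_has_native_flags(toy_pool, tmp_path):
    path = tmp_path / "poses.csv"
    write_pose_table(path, toy_pool)
    df = pd.read_csv(path)
    assert set(df.columns) == {"conformer_id", "energy", "rmsd", "native_like"}
    assert df["native_like"].sum() == sum(
        p.rmsd_to_native < 2.0 for p in toy_pool.poses)
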