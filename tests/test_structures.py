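"""Structure handling: PDB reading, contact maps, charges, B-DNA
lattices, rigid poses and clash detection."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from electrofold.structures import (PDBParseError, Pose, ProteinStructure,
                                    Residue, assign_charges,
                                    build_bdna_phosphates, build_contact_map,
                                    detect_clash, read_structure,
                                    transform_pose)


def _pdb_record(serial, name, res, chain, resseq, xyz):
    return (f"ATOM  {serial:5d}  {name:<3s} {res:>3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {name[0]:>2s}")


def make_fixture_pdb(n_models: int = 1, offset: float = 5.0) -> str:
    """Three residues (LYS, ASP, GLY) with 3/2/1 atoms; model m is
    shifted by (m-1)*offset along x."""
    residues = [("LYS", [("N", (0, 0, 0)), ("CA", (1.5, 0, 0)),
                         ("NZ", (3.0, 2.0, 0))]),
                ("ASP", [("CA", (4.0, 0, 0)), ("OD1", (5.0, 1.0, 0))]),
                ("GLY", [("CA", (7.0, 0, 0))])]
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for ri, (rname, atoms) in enumerate(residues, start=1):
            for aname, (x, y, z) in atoms:
                lines.append(_pdb_record(serial, aname, rname, "A", ri,
                                         (x + (m - 1) * offset, y, z)))
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestReadStructure:
    def test_empty_source_rejected(self):
        with pytest.raises(PDBParseError):
            read_structure("   \n")

    def test_three_residue_fixture_counts(self):
        prot = read_structure(make_fixture_pdb())
        assert prot.n_residues == 3
        assert [len(r.heavy_atoms) for r in prot.residues] == [3, 2, 1]
        assert [r.name for r in prot.residues] == ["LYS", "ASP", "GLY"]

    def test_model_selection_uses_requested_coordinates(self):
        txt = make_fixture_pdb(n_models=2, offset=5.0)
        m1 = read_structure(txt, model_id=1)
        m2 = read_structure(txt, model_id=2)
        assert np.allclose(m2.coords()[:, 0] - m1.coords()[:, 0], 5.0)
        assert np.allclose(m2.coords()[:, 1:], m1.coords()[:, 1:])

    def test_missing_model_lists_available(self):
        with pytest.raises(ValueError, match="available models"):
            read_structure(make_fixture_pdb(n_models=2), model_id=3)

    def test_malformed_record_names_line(self):
        txt = make_fixture_pdb()
        lines = txt.splitlines()
        lines[3] = lines[3][:30] + "  badcoord  " + lines[3][42:]
        with pytest.raises(PDBParseError, match="line 4"):
            read_structure("\n".join(lines))


def _point_structure(res_atoms):
    """Residues from lists of coordinate tuples."""
    residues = []
    for idx, atoms in enumerate(res_atoms, start=1):
        residues.append(Residue(index=idx, name="ALA",
                                heavy_atoms=np.array(atoms, dtype=float)))
    return ProteinStructure(residues)


class TestContactMap:
    def test_far_apart_residues_give_empty_map(self):
        s = _point_structure([[(0, 0, 0)], [(100, 0, 0)]])
        assert build_contact_map(s, cutoff=5.0, min_separation=1).pairs == {}

    def test_counts_atom_pairs_within_cutoff(self):
        # residues 1 and 3 share exactly two 4.0-A atom pairs at cutoff
        # 4.05 (the cross pairs are at sqrt(17) ~ 4.12 A)
        s = _point_structure([
            [(0, 0, 0), (1, 0, 0)],
            [(50, 50, 50)],
            [(0, 0, 4), (1, 0, 4)],
        ])
        cm = build_contact_map(s, cutoff=4.05, min_separation=2)
        assert cm.pairs == {(1, 3): 2}

    def test_min_separation_filters(self):
        s = _point_structure([
            [(0, 0, 0), (1, 0, 0)],
            [(50, 50, 50)],
            [(0, 0, 4), (1, 0, 4)],
        ])
        assert build_contact_map(s, cutoff=4.05, min_separation=3).pairs == {}

    def test_agrees_with_brute_force_distance_scan(self):
        rng = np.random.default_rng(11)
        res_atoms = [rng.uniform(0, 15, size=(3, 3)) * 1.0 for _ in range(7)]
        s = _point_structure([list(map(tuple, a)) for a in res_atoms])
        cm = build_contact_map(s, cutoff=5.0, min_separation=2)
        expected = {}
        for i in range(7):
            for j in range(i + 1, 7):
                if j - i < 2:
                    continue
                n = sum(
                    1
                    for a in res_atoms[i]
                    for b in res_atoms[j]
                    if np.linalg.norm(a - b) <= 5.0
                )
                if n:
                    expected[(i + 1, j + 1)] = n
        assert cm.pairs == expected

    def test_invariant_under_rigid_transform(self):
        prot = read_structure(make_fixture_pdb())
        cm1 = build_contact_map(prot, cutoff=5.0, min_separation=1)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = prot.transformed(rot, np.array([3.0, -7.0, 1.0]))
        cm2 = build_contact_map(moved, cutoff=5.0, min_separation=1)
        assert cm1.pairs == cm2.pairs


class TestCharges:
    def test_poly_ala_is_neutral(self):
        s = _point_structure([[(0, 0, 0)]] * 4)
        ch = assign_charges(s)
        assert set(ch.charges.values()) == {0}
        assert ch.net_charge == 0

    def test_kdg_chain_charges(self):
        residues = [Residue(1, "LYS", np.zeros((1, 3))),
                    Residue(2, "ASP", np.ones((1, 3))),
                    Residue(3, "GLY", 2 * np.ones((1, 3)))]
        ch = assign_charges(ProteinStructure(residues))
        assert [ch.charges[i] for i in (1, 2, 3)] == [+1, -1, 0]
        assert ch.net_charge == 0

    def test_net_charge_sums_lookup_table(self):
        names = ["LYS", "ARG", "LYS", "ARG", "LYS", "ASP", "GLU", "ALA", "HIS"]
        residues = [Residue(i + 1, n, np.array([[float(i), 0, 0]]))
                    for i, n in enumerate(names)]
        assert assign_charges(ProteinStructure(residues)).net_charge == +3

    def test_unknown_residue_warns_and_is_neutral(self):
        residues = [Residue(1, "XYZ", np.zeros((1, 3)))]
        with pytest.warns(UserWarning, match="unknown residue"):
            ch = assign_charges(ProteinStructure(residues))
        assert ch.charges[1] == 0

    def test_charge_site_is_charged_group_centroid(self):
        prot = read_structure(make_fixture_pdb())
        assign_charges(prot)
        assert np.allclose(prot.residues[0].charge_site, (3.0, 2.0, 0.0))  # NZ
        assert np.allclose(prot.residues[1].charge_site, (5.0, 1.0, 0.0))  # OD1


class TestBDNALattice:
    def test_phosphate_count_omits_5prime_terminals(self):
        assert build_bdna_phosphates(10).n_phosphates == 18

    def test_rise_between_intrastrand_neighbors(self):
        lat = build_bdna_phosphates(8)
        strand_a = lat.phosphates[:7]
        assert np.allclose(np.diff(strand_a[:, 2]), 3.38)

    def test_intrastrand_neighbor_distance_closed_form(self):
        lat = build_bdna_phosphates(8)
        expected = math.sqrt((2 * 8.91 * math.sin(math.radians(18))) ** 2
                             + 3.38 ** 2)
        d = np.linalg.norm(lat.phosphates[1] - lat.phosphates[0])
        assert d == pytest.approx(expected, abs=1e-9)

    def test_all_phosphates_on_cylinder(self):
        lat = build_bdna_phosphates(12, radius=9.5)
        r = np.linalg.norm(lat.phosphates[:, :2], axis=1)
        assert np.allclose(r, 9.5, atol=1e-6)

    def test_too_few_base_pairs_rejected(self):
        with pytest.raises(ValueError):
            build_bdna_phosphates(1)


class TestPoseAndClash:
    def test_identity_pose_preserves_coordinates(self):
        prot = read_structure(make_fixture_pdb())
        moved = transform_pose(prot, Pose(), axis=(0, 0, 1.0))
        assert np.allclose(moved.coords(), prot.coords())

    def test_translation_displaces_centroid_exactly(self):
        prot = read_structure(make_fixture_pdb())
        moved = transform_pose(prot, Pose(translation=10.0), axis=(0, 0, 1.0))
        assert moved.centroid()[2] - prot.centroid()[2] == pytest.approx(10.0)
        assert np.allclose(moved.centroid()[:2], prot.centroid()[:2])

    def test_rotation_preserves_internal_distances(self):
        prot = read_structure(make_fixture_pdb())
        pose = Pose(rotation=(33.0, 71.0, -150.0), translation=4.0)
        moved = transform_pose(prot, pose, axis=(1.0, 0, 0))
        d0 = np.linalg.norm(prot.coords()[:, None] - prot.coords()[None], axis=-1)
        d1 = np.linalg.norm(moved.coords()[:, None] - moved.coords()[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_unnormalized_axis_rejected(self):
        prot = read_structure(make_fixture_pdb())
        with pytest.raises(ValueError):
            transform_pose(prot, Pose(translation=1.0), axis=(0, 0, 2.0))

    def test_clash_far_and_near(self):
        lat = build_bdna_phosphates(6)
        far = _point_structure([[(200.0, 0, 0)]])
        assert detect_clash(far, lat) is False
        near = _point_structure([[tuple(lat.phosphates[0] + [1.0, 0, 0])]])
        assert detect_clash(near, lat, threshold=2.0) is True

    def test_clash_boundary_is_strict(self):
        lat = build_bdna_phosphates(6)
        at_threshold = _point_structure(
            [[tuple(lat.phosphates[0] + [2.0, 0, 0])]])
        assert detect_clash(at_threshold, lat, threshold=2.0) is False
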