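"""Geometry generation: nanotubes, functional groups, complexes, water boxes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosolv.geometry import random_rotation, rotation_about_axis
from nanosolv.io import read_frame, read_structure, write_structure
from nanosolv.structures import (
    RigidMolecule,
    SimulationBox,
    assign_charges,
    build_drug_surrogate,
    build_water_box,
    build_zigzag_cnt,
    functionalize,
    make_complex,
    make_tip3p_water,
    solvate,
    water_count_for_density,
    zigzag_radius,
)


def pairwise_distances(pos):
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)


class TestZigzagCNT:
    @pytest.mark.parametrize("n,n_cells", [(9, 5), (6, 2), (12, 3), (9, 1)])
    def test_atom_count_radius_topology(self, n, n_cells):
        cc = 1.455
        cnt = build_zigzag_cnt(n, n_cells, cc)
        assert cnt.n_atoms == 4 * n * n_cells
        radii = np.linalg.norm(cnt.positions[:, :2], axis=1)
        assert np.allclose(radii, zigzag_radius(n, cc), atol=1e-6)
        d = pairwise_distances(cnt.positions)
        np.fill_diagonal(d, np.inf)
        neighbours = (d < 1.1 * cc).sum(axis=1)
        # interior atoms have 3 ring neighbours; only the n end-ring atoms at
        # each open end have fewer
        assert neighbours.max() == 3
        assert (neighbours == 3).sum() == cnt.n_atoms - 2 * n

    def test_default_tube_matches_study_geometry(self):
        cnt = build_zigzag_cnt()
        assert cnt.n_atoms == 180
        assert zigzag_radius(9, 1.455) == pytest.approx(3.61, abs=0.01)
        assert np.allclose(cnt.positions[:, 2].mean(), 0.0, atol=1e-9)

    @pytest.mark.parametrize("kwargs", [dict(n=2), dict(n_cells=0),
                                        dict(cc_bond=1.0), dict(cc_bond=2.0)])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            build_zigzag_cnt(**{"n": 9, "n_cells": 5, "cc_bond": 1.455, **kwargs})


def _midwall_carbon(cnt):
    return int(np.argmin(np.abs(cnt.positions[:, 2])))


class TestFunctionalize:
    def test_hydroxyl_geometry(self):
        cnt = build_zigzag_cnt()
        mol = functionalize(cnt, "OH", _midwall_carbon(cnt))
        assert mol.n_atoms == 182
        o2, h3 = mol.labeled_position("O2"), mol.labeled_position("H3")
        c1 = mol.labeled_position("C1")
        assert np.linalg.norm(o2 - h3) == pytest.approx(0.999, abs=1e-9)
        assert np.linalg.norm(o2 - c1) == pytest.approx(1.476, abs=1e-9)

    def test_carboxyl_geometry(self):
        cnt = build_zigzag_cnt()
        mol = functionalize(cnt, "COOH", _midwall_carbon(cnt))
        assert mol.n_atoms == 184
        c1 = mol.labeled_position("C1")
        assert np.linalg.norm(c1 - mol.labeled_position("O6")) == pytest.approx(1.219, abs=1e-9)
        assert np.linalg.norm(c1 - mol.labeled_position("O2")) == pytest.approx(1.377, abs=1e-9)
        assert np.linalg.norm(
            mol.labeled_position("O2") - mol.labeled_position("H3")
        ) == pytest.approx(0.997, abs=1e-9)

    def test_group_points_outward(self):
        cnt = build_zigzag_cnt()
        site = _midwall_carbon(cnt)
        mol = functionalize(cnt, "OH", site)
        r_site = np.linalg.norm(cnt.positions[site][:2])
        assert np.linalg.norm(mol.labeled_position("O2")[:2]) > r_site + 1.0

    def test_double_functionalization_rejected(self):
        cnt = build_zigzag_cnt()
        site = _midwall_carbon(cnt)
        mol = functionalize(cnt, "OH", site)
        with pytest.raises(ValueError, match="sidewall"):
            functionalize(mol, "OH", site)

    def test_edge_atom_rejected(self):
        cnt = build_zigzag_cnt()
        edge = int(np.argmax(cnt.positions[:, 2]))
        with pytest.raises(ValueError, match="sidewall"):
            functionalize(cnt, "OH", edge)


class TestDrugSurrogate:
    def test_carbonyl_bond_length(self):
        drug = build_drug_surrogate()
        d = np.linalg.norm(
            drug.labeled_position("O4") - drug.labeled_position("C_carbonyl")
        )
        assert d == pytest.approx(1.228, abs=1e-9)

    def test_deterministic_fixture(self):
        a, b = build_drug_surrogate(), build_drug_surrogate()
        assert a.elements == b.elements
        assert np.array_equal(a.positions, b.positions)

    def test_tagged_sites_present(self):
        drug = build_drug_surrogate()
        assert "O4" in drug.labels and "N_py" in drug.labels
        assert drug.elements[drug.labels["N_py"]] == "N"


class TestAssignCharges:
    def test_mapped_sites_and_neutralization(self):
        drug = assign_charges(
            build_drug_surrogate(), {"O4": -0.821, "N_py": -0.640}, neutralize=True
        )
        assert drug.charges[drug.labels["O4"]] == pytest.approx(-0.821)
        assert drug.charges.sum() == pytest.approx(0.0, abs=1e-9)

    def test_formal_charge_respected(self):
        drug = assign_charges(
            build_drug_surrogate(), {"O4": -0.9}, neutralize=True, formal_charge=1.0
        )
        assert drug.charges.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_map_without_neutralize_keeps_zeros(self):
        drug = assign_charges(build_drug_surrogate(), {}, neutralize=False)
        assert np.all(drug.charges == 0.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            assign_charges(build_drug_surrogate(), {"Zz": 1.0})


@pytest.fixture(scope="module")
def carrier_oh():
    cnt = build_zigzag_cnt()
    return functionalize(cnt, "OH", _midwall_carbon(cnt))


class TestMakeComplex:
    def test_hydrogen_bond_pose_contact(self, carrier_oh, charged_drug):
        cx = make_complex(charged_drug, carrier_oh, "CO", 1.8)
        d = np.linalg.norm(cx.labeled_position("O4") - cx.labeled_position("H3"))
        assert d == pytest.approx(1.8, abs=1e-6)
        assert cx.n_atoms == carrier_oh.n_atoms + charged_drug.n_atoms

    def test_pyridine_pose_uses_nitrogen(self, carrier_oh, charged_drug):
        cx = make_complex(charged_drug, carrier_oh, "PY", 1.8)
        d = np.linalg.norm(cx.labeled_position("N_py") - cx.labeled_position("H3"))
        assert d == pytest.approx(1.8, abs=1e-6)

    def test_pi_stack_pose_on_pristine_tube(self, charged_drug):
        cnt = build_zigzag_cnt()
        cx = make_complex(charged_drug, cnt, "CO", 3.4)
        drug_pos = cx.positions[cnt.n_atoms:]
        # drug plane normal parallel to the radial direction (+x)
        centered = drug_pos - drug_pos.mean(axis=0)
        normal = np.linalg.svd(centered, full_matrices=False)[2][2]
        assert abs(abs(normal[0]) - 1.0) < 1e-6
        r_wall = np.linalg.norm(cnt.positions[:, :2], axis=1).max()
        assert drug_pos.mean(axis=0)[0] == pytest.approx(r_wall + 3.4, abs=1e-6)

    def test_clashing_contact_rejected(self, carrier_oh, charged_drug):
        with pytest.raises(ValueError, match="clash"):
            make_complex(charged_drug, carrier_oh, "CO", 0.1)

    def test_no_intermolecular_clash(self, carrier_oh, charged_drug):
        cx = make_complex(charged_drug, carrier_oh, "CO", 1.8)
        a = cx.positions[: carrier_oh.n_atoms]
        b = cx.positions[carrier_oh.n_atoms:]
        d = np.linalg.norm(a[:, None] - b[None], axis=-1)
        assert d.min() >= 1.0


class TestWaterBox:
    @pytest.mark.parametrize("edge,expected", [(50.0, 4149), (10.0, 33)])
    def test_closed_form_count(self, edge, expected):
        assert water_count_for_density(SimulationBox.cubic(edge), 0.993) == expected

    def test_density_matches_request(self, small_water_box):
        n = small_water_box.n_waters
        box = small_water_box.box
        realized = n * 18.015 / (6.02214076e23 * box.volume * 1e-24)
        target = water_count_for_density(box, 0.993) * 18.015 / (
            6.02214076e23 * box.volume * 1e-24
        )
        assert realized == pytest.approx(target, rel=1e-12)
        assert realized == pytest.approx(0.993, rel=0.02)  # rounding in a small box

    def test_seed_determinism(self):
        box = SimulationBox.cubic(14.0)
        a = build_water_box(box, seed=42)
        b = build_water_box(box, seed=42)
        assert np.array_equal(a.water_array(), b.water_array())
        c = build_water_box(box, seed=43)
        assert not np.array_equal(a.water_array(), c.water_array())

    def test_tip3p_internal_geometry(self, small_water_box):
        for w in small_water_box.waters[:5]:
            o, h1, h2 = w.positions
            assert np.linalg.norm(h1 - o) == pytest.approx(0.9572, abs=1e-9)
            assert np.linalg.norm(h2 - o) == pytest.approx(0.9572, abs=1e-9)
            cosang = np.dot(h1 - o, h2 - o) / 0.9572 ** 2
            assert np.degrees(np.arccos(cosang)) == pytest.approx(104.52, abs=1e-6)

    def test_no_initial_clashes(self, small_water_box):
        W = small_water_box.water_array().reshape(-1, 3)
        d = pairwise_distances(W)
        nw = small_water_box.n_waters
        mol = np.repeat(np.arange(nw), 3)
        inter = mol[:, None] != mol[None, :]
        assert d[inter].min() >= 0.5

    def test_too_small_box_rejected(self):
        with pytest.raises(ValueError):
            build_water_box(SimulationBox.cubic(2.0))


class TestSolvate:
    def test_no_solute_keeps_every_water(self, small_water_box):
        out = solvate(None, small_water_box)
        assert out.n_waters == small_water_box.n_waters

    def test_zero_cutoff_keeps_every_water(self, small_water_box, charged_drug):
        out = solvate(charged_drug, small_water_box, clash_cutoff=0.0)
        assert out.n_waters == small_water_box.n_waters

    def test_monotone_in_cutoff_with_bruteforce_oracle(self, small_water_box, charged_drug):
        solute = charged_drug.translated(-charged_drug.centroid())
        edges = small_water_box.box.edges_array()
        counts = []
        for cutoff in (1.0, 2.0, 2.6, 3.5):
            out = solvate(charged_drug, small_water_box, clash_cutoff=cutoff)
            # brute-force distance scan over every water/solute site pair
            keep = 0
            for w in small_water_box.waters:
                d = w.positions[:, None, :] - solute.positions[None, :, :]
                d -= edges * np.round(d / edges)
                if np.sqrt((d ** 2).sum(-1)).min() >= cutoff:
                    keep += 1
            assert out.n_waters == keep
            counts.append(out.n_waters)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotent(self, small_water_box, charged_drug):
        once = solvate(charged_drug, small_water_box, 2.6)
        twice = solvate(once.solute, once, 2.6)
        assert twice.n_waters == once.n_waters

    def test_oversized_solute_rejected(self, charged_drug):
        tiny = build_water_box(SimulationBox.cubic(4.0), density=0.993, seed=0)
        with pytest.raises(ValueError, match="fit"):
            solvate(charged_drug, tiny)


class TestRigidMoves:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        axis=st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3).filter(
            lambda a: sum(x * x for x in a) > 1e-4
        ),
        angle=st.floats(-np.pi, np.pi),
        shift=st.lists(st.floats(-20.0, 20.0), min_size=3, max_size=3),
    )
    def test_arbitrary_rigid_move_preserves_geometry(self, axis, angle, shift):
        drug = build_drug_surrogate()
        ref = pairwise_distances(drug.positions)
        moved = drug.rotated(rotation_about_axis(np.array(axis), angle))
        moved = moved.translated(np.array(shift))
        assert np.allclose(pairwise_distances(moved.positions), ref, atol=1e-10)

    def test_rotation_translation_preserve_internal_distances(self):
        rng = np.random.default_rng(5)
        drug = build_drug_surrogate()
        ref = pairwise_distances(drug.positions)
        for _ in range(25):
            rot = random_rotation(rng)
            moved = drug.rotated(rot).translated(rng.normal(size=3) * 10)
            assert np.allclose(pairwise_distances(moved.positions), ref, atol=1e-10)

    def test_rotation_matrix_is_orthonormal(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = rotation_about_axis(rng.normal(size=3), rng.uniform(-np.pi, np.pi))
            assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0)


class TestStructureIO:
    def test_xyz_roundtrip_cnt(self, tmp_path):
        cnt = build_zigzag_cnt()
        path = tmp_path / "cnt.xyz"
        write_structure(cnt, path)
        back = read_structure(path)
        assert back.elements == cnt.elements
        assert np.allclose(back.positions, cnt.positions, atol=1e-4)

    def test_pdb_roundtrip_system(self, tmp_path, solvated_drug):
        path = tmp_path / "sys.pdb"
        write_structure(solvated_drug, path)
        elements, coords, box = read_frame(path)
        n_expected = solvated_drug.solute.n_atoms + 3 * solvated_drug.n_waters
        assert len(elements) == n_expected
        assert box.edge_lengths == pytest.approx(solvated_drug.box.edge_lengths)
        flat = np.vstack(
            [solvated_drug.solute.positions]
            + [w.positions for w in solvated_drug.waters]
        )
        assert np.allclose(coords, flat, atol=5.1e-4)  # PDB prints 3 decimals

    def test_pdb_readable_by_mdanalysis(self, tmp_path):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        cnt = build_zigzag_cnt()
        path = tmp_path / "cnt.pdb"
        write_structure(cnt, path)
        u = MDAnalysis.Universe(str(path))
        assert len(u.atoms) == 180
        assert np.allclose(u.atoms.positions, cnt.positions, atol=5.1e-4)

    def test_pdb_extra_fields_ignored(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       1.000   2.000   3.000  1.00 12.34"
            "           O\nEND\n"
        )
        elements, coords, _ = read_frame(path)
        assert elements == ["O"]
        assert np.allclose(coords, [[1.0, 2.0, 3.0]])

    def test_bad_xyz_header_reports_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("notanumber\ncomment\n")
        with pytest.raises(ValueError, match=":1:"):
            read_frame(path)

    def test_truncated_xyz_rejected(self, tmp_path):
        path = tmp_path / "short.xyz"
        path.write_text("5\ncomment\nC 0 0 0\n")
        with pytest.raises(ValueError, match="truncated|expected"):
            read_frame(path)
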