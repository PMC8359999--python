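"""Ring construction, dihedral libraries and Z-matrix assembly."""

import numpy as np
import pytest

from puckermc.conformer_catalog import canonical_state, enumerate_catalog, find_label
from puckermc.ring_pucker import PuckeringState, forward_pucker, mean_plane_displacements
from puckermc.structure_builder import (
    DihedralLibrary,
    MoleculeSpec,
    RingClosureError,
    RingTemplate,
    SubstituentSpec,
    attach_substituents,
    build_dihedral_library,
    build_ring_geometry,
    dihedral_angle,
    endocyclic_dihedrals,
    read_library_files,
    read_var_file,
)
from .conftest import ALL_HETEROATOMS


def planar_state(n: int) -> PuckeringState:
    nq = 1 if n == 5 else 2
    nphi = 1 if n < 7 else 2
    return PuckeringState(n_atoms=n, q=np.zeros(nq), phi=np.zeros(nphi),
                          Q=0.0 if n == 6 else None,
                          theta=0.0 if n == 6 else None, planar=True)


class TestRingGeometry:
    def test_planar_hexagon_bonds(self):
        t = RingTemplate(6, "CH2")
        ring = build_ring_geometry(t, planar_state(6))
        d = np.linalg.norm(np.roll(ring.coords, -1, axis=0) - ring.coords, axis=1)
        assert np.allclose(d, 1.54, atol=5e-3)
        assert np.allclose(ring.coords[:, 2], 0.0, atol=1e-9)

    def test_chair_round_trip(self):
        t = RingTemplate(6, "O")
        st = canonical_state(find_label(6, "4C1"), 0.55)
        ring = build_ring_geometry(t, st)
        back = forward_pucker(mean_plane_displacements(ring))
        assert back.theta == pytest.approx(0.0, abs=0.5)
        assert back.q3 == pytest.approx(0.55, abs=5e-3)

    def test_seven_ring_twist_boat_plane(self):
        t = RingTemplate(7, "O")
        lab = next(l for l in enumerate_catalog(7) if l.family == "TB")
        ring = build_ring_geometry(t, canonical_state(lab, 0.6))
        back = forward_pucker(mean_plane_displacements(ring))
        assert back.q3 <= 0.01

    def test_amplitude_bound(self):
        t = RingTemplate(6, "O")
        st = canonical_state(find_label(6, "4C1"), 0.95)
        with pytest.raises(RingClosureError):
            build_ring_geometry(t, st)

    def test_ring_size_mismatch(self):
        with pytest.raises(ValueError):
            build_ring_geometry(RingTemplate(5, "O"), planar_state(6))

    @pytest.mark.parametrize("het", ALL_HETEROATOMS)
    def test_all_templates_all_labels_six_ring(self, het):
        t = RingTemplate(6, het)
        for lab in enumerate_catalog(6):
            st = canonical_state(lab, 0.55)
            ring = build_ring_geometry(t, st)
            d = np.linalg.norm(np.roll(ring.coords, -1, axis=0) - ring.coords,
                               axis=1)
            assert np.allclose(d, t.bond_lengths, atol=5e-3)
            back = forward_pucker(mean_plane_displacements(ring))
            assert np.allclose(back.q, st.q, atol=1e-3)


class TestEndocyclicDihedrals:
    def test_planar_ring_zero(self):
        ring = build_ring_geometry(RingTemplate(6, "CH2"), planar_state(6))
        assert np.allclose(endocyclic_dihedrals(ring), 0.0, atol=1e-6)

    def test_chair_alternating_symmetry(self):
        ring = build_ring_geometry(RingTemplate(6, "CH2"),
                                   canonical_state(find_label(6, "4C1"), 0.55))
        D = endocyclic_dihedrals(ring)
        assert len(D) == 3
        assert abs(D[0]) == pytest.approx(abs(D[1]), abs=1e-6)
        assert abs(D[1]) == pytest.approx(abs(D[2]), abs=1e-6)
        assert np.sign(D[0]) == -np.sign(D[1])
        assert np.sign(D[1]) == -np.sign(D[2])


class TestLibrary:
    @pytest.mark.parametrize("n,entries,per_entry",
                             [(5, 20, 2), (6, 38, 3), (7, 98, 4)])
    def test_build_counts(self, n, entries, per_entry):
        t = RingTemplate(n, "O")
        lib = build_dihedral_library(t, enumerate_catalog(n), 0.45)
        assert len(lib) == entries
        assert all(len(v) == per_entry for v in lib.entries.values())

    def test_chair_entry_matches_direct_build(self):
        t = RingTemplate(6, "CH2")
        lib = build_dihedral_library(t, enumerate_catalog(6), 0.55)
        ring = build_ring_geometry(t, canonical_state(find_label(6, "4C1"), 0.55))
        assert np.allclose(lib.entries["4C1"], endocyclic_dihedrals(ring))

    def test_entry_length_validation(self):
        with pytest.raises(ValueError):
            DihedralLibrary(template_key=(6, "O", 0),
                            entries={"x": np.array([1.0, 2.0])})


class TestLibraryFiles:
    def _write_pair(self, tmp_path, rows1, rows2):
        p1 = tmp_path / "N-5-H-0-D1.txt"
        p2 = tmp_path / "N-5-H-0-D2.txt"
        np.savetxt(p1, rows1, fmt="%.4f")
        np.savetxt(p2, rows2, fmt="%.4f")
        return [p1, p2]

    def test_round_trip(self, tmp_path):
        grid = np.arange(0.0, 360.0, 18.0)
        d1 = np.column_stack((grid, np.sin(np.radians(grid)) * 40))
        d2 = np.column_stack((grid, np.cos(np.radians(grid)) * 40))
        lib = read_library_files(self._write_pair(tmp_path, d1, d2))
        assert len(lib) == 20
        first = next(iter(lib.entries.values()))
        assert len(first) == 2
        assert first[0] == pytest.approx(0.0, abs=1e-3)
        assert first[1] == pytest.approx(40.0, abs=1e-3)

    def test_mismatched_rows(self, tmp_path):
        d1 = np.column_stack((np.arange(5.0), np.zeros(5)))
        d2 = np.column_stack((np.arange(4.0), np.zeros(4)))
        with pytest.raises(ValueError, match="row counts"):
            read_library_files(self._write_pair(tmp_path, d1, d2))

    def test_empty_file(self, tmp_path):
        paths = self._write_pair(tmp_path,
                                 np.column_stack((np.arange(3.0), np.zeros(3))),
                                 np.zeros((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            read_library_files(paths)

    def test_missing_dihedral_file(self, tmp_path):
        p = tmp_path / "N-6-H-0-Oxy-D1.txt"
        np.savetxt(p, np.column_stack((np.arange(3.0), np.zeros(3))))
        with pytest.raises(ValueError, match="missing|needs"):
            read_library_files([p])

    def test_non_numeric(self, tmp_path):
        p1 = tmp_path / "N-5-H-0-D1.txt"
        p1.write_text("0.0 abc\n")
        p2 = tmp_path / "N-5-H-0-D2.txt"
        p2.write_text("0.0 1.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_library_files([p1, p2])


class TestVarFiles:
    def test_read_var_file(self, tmp_path):
        p = tmp_path / "custom.var"
        p.write_text("# comment\nOH.d_CO = 1.41\n\nOH.a_HOC=108\n")
        assert read_var_file(p) == {"OH.d_CO": 1.41, "OH.a_HOC": 108.0}

    def test_bad_line(self, tmp_path):
        p = tmp_path / "bad.var"
        p.write_text("OH.d_CO 1.41\n")
        with pytest.raises(ValueError):
            read_var_file(p)


def _chair_ring(het="CH2"):
    t = RingTemplate(6, het)
    return t, build_ring_geometry(t, canonical_state(find_label(6, "4C1"), 0.55))


class TestAttach:
    def test_bare_cyclohexane(self):
        t, ring = _chair_ring()
        zm = attach_substituents(ring, t, [])
        assert zm.n_atoms == 18
        assert zm.variable_names("endocyclic") == ["D1", "D2", "D3"]
        assert zm.variable_names("rotamer") == []
        assert (zm.charge, zm.multiplicity) == (0, 1)

    def test_single_hydroxyl_rotamer(self):
        t = RingTemplate(5, "O")
        ring = build_ring_geometry(t, canonical_state(enumerate_catalog(5)[0], 0.4))
        zm = attach_substituents(ring, t, [SubstituentSpec(2, "OH", "up")])
        assert len(zm.variable_names("rotamer")) == 1
        assert zm.n_atoms == 14  # C4H8O2

    def test_glucose_counts(self):
        t, ring = _chair_ring("O")
        subs = [SubstituentSpec(1, "OH", "down"), SubstituentSpec(2, "OH", "down"),
                SubstituentSpec(3, "OH", "up"), SubstituentSpec(4, "OH", "down"),
                SubstituentSpec(5, "CH2OH", "up")]
        zm = attach_substituents(ring, t, subs)
        els, _ = zm.to_cartesian()
        assert sorted(set(els)) == ["C", "H", "O"]
        assert (els.count("C"), els.count("H"), els.count("O")) == (6, 12, 6)
        # 4 hydroxyls x 1 + hydroxymethyl x 2 rotatable bonds
        assert len(zm.variable_names("rotamer")) == 6

    def test_atom_count_conservation(self):
        # ring + het hydrogens + substituent atoms + filler hydrogens
        t, ring = _chair_ring("NH")
        zm = attach_substituents(ring, t, [SubstituentSpec(3, "F", "up")])
        # C5N ring + 1 N-H + F + 9 filler H
        assert zm.n_atoms == 6 + 1 + 1 + 9
        assert "HFLIP" in zm.variables

    def test_valence_overflow(self):
        t, ring = _chair_ring("O")
        subs = [SubstituentSpec(2, "OH", "up"), SubstituentSpec(2, "F", "up")]
        with pytest.raises(ValueError):
            attach_substituents(ring, t, subs)

    def test_heteroatom_position_closed(self):
        t, ring = _chair_ring("O")
        with pytest.raises(ValueError):
            attach_substituents(ring, t, [SubstituentSpec(6, "OH", "up")])

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            SubstituentSpec(2, "SeH", "up")

    def test_so2_oxygens_fixed(self):
        t, ring = _chair_ring("SO2")
        zm = attach_substituents(ring, t, [])
        els, _ = zm.to_cartesian()
        assert els.count("O") == 2
        assert zm.variable_names("rotamer") == []


class TestZMatrixValidity:
    def test_cartesian_round_trip(self):
        t, ring = _chair_ring("O")
        subs = [SubstituentSpec(2, "OH", "down"), SubstituentSpec(5, "CH2OH", "up")]
        zm = attach_substituents(ring, t, subs)
        els, xyz = zm.to_cartesian()
        # ring bond lengths preserved
        n = 6
        d = [np.linalg.norm(xyz[(k + 1) % n] - xyz[k]) for k in range(n)]
        assert np.allclose(d, t.bond_lengths, atol=5e-3)
        # endocyclic dihedrals re-extracted from Cartesian match variables
        for k in range(3):
            got = dihedral_angle(xyz[k], xyz[k + 1], xyz[k + 2], xyz[k + 3])
            assert got == pytest.approx(zm.variables[f"D{k + 1}"], abs=1e-3)
        # conversion convention: first atom at origin, second on +x
        assert np.allclose(xyz[0], 0.0)
        assert xyz[1][1] == pytest.approx(0.0, abs=1e-12)
        assert xyz[1][2] == pytest.approx(0.0, abs=1e-12)

    def test_rotamer_variable_moves_only_its_hydrogen(self):
        t, ring = _chair_ring("O")
        zm = attach_substituents(ring, t, [SubstituentSpec(2, "OH", "down")])
        _, before = zm.to_cartesian()
        zm.set_variable("R1", 60.0)
        _, after = zm.to_cartesian()
        moved = np.where(np.linalg.norm(after - before, axis=1) > 1e-9)[0]
        assert len(moved) == 1  # only the hydroxyl hydrogen

    def test_unknown_variable(self):
        t, ring = _chair_ring()
        zm = attach_substituents(ring, t, [])
        with pytest.raises(KeyError):
            zm.set_variable("R99", 10.0)


class TestMoleculeSpec:
    def test_duplicate_face_rejected(self):
        t = RingTemplate(6, "O")
        with pytest.raises(ValueError):
            MoleculeSpec(template=t, substituents=(
                SubstituentSpec(2, "OH", "up"), SubstituentSpec(2, "F", "up")))

    def test_position_range(self):
        t = RingTemplate(5, "O")
        with pytest.raises(ValueError):
            MoleculeSpec(template=t, substituents=(SubstituentSpec(9, "OH", "up"),))
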