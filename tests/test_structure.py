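"""Structure I/O, selection and assembly expansion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filageom import synthetic
from filageom.rigid import RigidTransform
from filageom.structure import (Atom, Chain, ChainLimitError, LookupError_,
                                ParseError, Residue, SelectionError, Selector,
                                Structure, apply_transform, expand_assembly,
                                read_structure, select_atoms,
                                transform_between_subunits, write_structure)


@pytest.fixture(scope="module")
def small_structure(protomer):
    return Structure(id="syn", chains=[protomer])


def all_coords(s: Structure) -> np.ndarray:
    return np.vstack([c.coords() for c in s.chains])


class TestReadWrite:
    @pytest.mark.parametrize("fmt,tol", [("pdb", 1e-3), ("mmcif", 1e-5)])
    def test_roundtrip_precision(self, tmp_path, small_structure, fmt, tol):
        path = tmp_path / f"model.{'pdb' if fmt == 'pdb' else 'cif'}"
        write_structure(small_structure, path, fmt)
        back = read_structure(path)
        assert np.abs(all_coords(back) - all_coords(small_structure)).max() \
            <= tol

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_structure(path)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "model.xyz"
        path.write_text("junk\n")
        with pytest.raises(Exception, match="format|suffix"):
            read_structure(path)

    def test_chain_limit_in_pdb_strict_mode(self, tmp_path, rng):
        chains = [Chain(f"C{i}", [Residue(1, "ALA", [
            Atom("CA", "C", rng.normal(size=3))])]) for i in range(63)]
        s = Structure(id="many", chains=chains)
        with pytest.raises(ChainLimitError):
            write_structure(s, tmp_path / "many.pdb", "pdb")
        # non-strict mode falls back to mmCIF silently
        write_structure(s, tmp_path / "many2.pdb", "pdb",
                        strict_chain_limit=False)
        assert len(read_structure(tmp_path / "many2.pdb",
                                  "mmcif").chains) == 63

    def test_waters_and_hydrogens_dropped(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1      11.000  12.000  13.000"
            "  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1      11.500  12.000  13.000"
            "  1.00  0.00           H\n"
            "ATOM      3  CA  ALA A   2      14.000  12.000  13.000"
            "  1.00  0.00           C\n"
            "HETATM    4  O   HOH A 101      20.000  20.000  20.000"
            "  1.00  0.00           O\n"
            "END\n")
        path = tmp_path / "w.pdb"
        path.write_text(pdb)
        s = read_structure(path)
        names = [a.name for c in s.chains for r in c.residues
                 for a in r.atoms]
        assert "H" not in names
        assert all(r.name != "HOH" for c in s.chains for r in c.residues)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1      10.000   0.000   0.000"
            "  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1      20.000   0.000   0.000"
            "  0.60  0.00           C\n"
            "ATOM      3  CA  ALA A   2       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      4  CA  ALA A   3       5.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        s = read_structure(path)
        res1 = s.chain("A").residue(1)
        assert len(res1.atoms) == 1
        assert res1.atoms[0].coords[0] == pytest.approx(20.0, abs=1e-3)


class TestSelection:
    def test_main_chain_count(self, small_structure):
        cs = select_atoms(small_structure, "chain P and name N,CA,C")
        n_res = len(small_structure.chain("P").residues)
        assert len(cs) == 3 * n_res
        assert set(cs.table["atom_name"]) == {"N", "CA", "C"}

    def test_selection_is_deterministic(self, small_structure):
        a = select_atoms(small_structure, "chain P and resi 5-20 and name CB")
        b = select_atoms(small_structure, "chain P and resi 5-20 and name CB")
        assert (a.table == b.table).all().all()
        assert np.array_equal(a.coords, b.coords)

    def test_absent_chain_is_lookup_error(self, small_structure):
        with pytest.raises(LookupError_, match="absent chain"):
            select_atoms(small_structure, "chain Z")

    def test_bad_syntax_raises(self, small_structure):
        with pytest.raises(SelectionError):
            select_atoms(small_structure, "chains P")

    def test_empty_selection_warns(self, small_structure):
        with pytest.warns(UserWarning, match="no atoms"):
            cs = select_atoms(small_structure, "chain P and resi 999")
        assert len(cs) == 0

    def test_glycine_has_no_cbeta(self, tmp_path):
        chain = Chain("A", [Residue(123, "GLY", [
            Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1.5, 0, 0]),
            Atom("C", "C", [2.2, 1.2, 0])])])
        s = Structure(id="g", chains=[chain])
        with pytest.warns(UserWarning, match="no atoms"):
            cs = select_atoms(s, "resi 123 and name CB")
        assert len(cs) == 0


class TestTransforms:
    def test_identity_and_translation(self, small_structure):
        t = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        moved = apply_transform(small_structure, t)
        delta = all_coords(moved) - all_coords(small_structure)
        assert np.allclose(delta, [1.0, 0.0, 0.0])

    def test_random_rotation_preserves_distances(self, small_structure, rng):
        t = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.normal(scale=10, size=3))
        a = all_coords(small_structure)[:60]
        b = all_coords(apply_transform(small_structure, t))[:60]
        da = np.linalg.norm(a[:, None] - a[None, :], axis=2)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=2)
        assert np.allclose(da, db, rtol=1e-9, atol=1e-9)


class TestExpandAssembly:
    def test_identity_op_duplicates_chain(self, small_structure):
        out = expand_assembly(small_structure, [RigidTransform.identity()], 1)
        assert len(out.chains) == 2
        assert np.allclose(out.chains[0].coords(), out.chains[1].coords())

    def test_two_chains_one_op_gives_four(self, protomer):
        import copy
        second = copy.deepcopy(protomer)
        second.chain_id = "Q"
        s = Structure(id="two", chains=[protomer, second])
        op = RigidTransform(np.eye(3), np.array([100.0, 0, 0]))
        out = expand_assembly(s, [op], 1)
        assert len(out.chains) == 4

    def test_screw_op_full_turn_azimuths(self, protomer):
        """12 applications of a 30-degree ring operator close one full
        turn of 13 chains."""
        s, _ = synthetic.build_helical_filament(
            protomer, rise=0.0, twist_deg=30.0, helical_radius=100.0, n=2)
        base = Structure(id="p", chains=[s.chains[0]])
        op = synthetic.screw_operator(30.0, 0.0)
        out = expand_assembly(base, [op], 12)
        assert len(out.chains) == 13
        az = sorted(
            float(np.degrees(np.arctan2(c.centroid()[1],
                                        c.centroid()[0]))) % 360
            for c in out.chains)
        gaps = np.diff(az + [az[0] + 360.0])
        # 13 chains at 30-degree steps: 12 single gaps and one double
        # (the 13th chain coincides with azimuth 0 after a full turn)
        assert sorted(np.round(gaps, 6).tolist()) == pytest.approx(
            [0.0] + [30.0] * 12, abs=1e-6)

    def test_generated_ids_record_provenance(self, small_structure):
        out = expand_assembly(small_structure,
                              [RigidTransform.identity()], 2)
        assert out.chain_ids == ["P", "P~0.1", "P~0.2"]


class TestTransformBetweenSubunits:
    def test_translation_related_chains(self, protomer):
        s, _ = synthetic.build_helical_filament(
            protomer, rise=48.0, twist_deg=0.0, n=2)
        t, rmsd = transform_between_subunits(s, "S0", "S1")
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert t.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_numbering_is_error(self, protomer):
        import copy
        other = copy.deepcopy(protomer)
        other.chain_id = "Q"
        for res in other.residues:
            res.seq_id += 1000
        s = Structure(id="d", chains=[protomer, other])
        with pytest.raises(Exception, match="common"):
            transform_between_subunits(s, "P", "Q")
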