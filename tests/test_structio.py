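"""Structure I/O, target preparation, parameter assignment."""

import numpy as np
import pytest

from seedgrow import build_fragment
from seedgrow.errors import ParseError, StructureError, TypingError
from seedgrow.fragments import FragmentSpec
from seedgrow.structio import (assign_parameters, prepare_target,
                               read_structure, write_structure)

PDB_3ATOM = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.543   7.243  -4.800  1.00  0.00           C
END
"""

PDB_TWO_CHAINS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY B   1       8.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  GLY B   1       9.458   0.000   0.000  1.00  0.00           C
ATOM      7  C   GLY B   1      10.009   1.420   0.000  1.00  0.00           C
ATOM      8  O   GLY B   1       9.251   2.390   0.000  1.00  0.00           O
HETATM    9  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""

MOL2_3ATOM = """\
@<TRIPOS>MOLECULE
test
3 0 1 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
     1 N      0.0000  0.0000  0.0000 N.4    1 ALA1   -0.3000
     2 CA     1.4580  0.0000  0.0000 C.3    1 ALA1    0.1000
     3 C      2.0090  1.4200  0.0000 C.2    1 ALA1    0.2000
"""


class TestReadWrite:
    def test_pdb_identity(self, tmp_path):
        path = tmp_path / "a.pdb"
        path.write_text(PDB_3ATOM)
        s = read_structure(path)
        assert s.n_atoms == 3
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]
        assert s.atoms[0].coord == pytest.approx([11.104, 6.134, -6.504])
        assert all(a.charge is None for a in s.atoms)

    def test_mol2_charges_carried(self, tmp_path):
        path = tmp_path / "a.mol2"
        path.write_text(MOL2_3ATOM)
        s = read_structure(path)
        assert [a.charge for a in s.atoms] == [-0.3, 0.1, 0.2]
        assert [a.element for a in s.atoms] == ["N", "C", "C"]

    def test_two_chains_order_preserved(self, tmp_path):
        path = tmp_path / "b.pdb"
        path.write_text(PDB_TWO_CHAINS)
        s = read_structure(path)
        assert [a.chain_id for a in s.atoms[:8]] == ["A"] * 4 + ["B"] * 4

    @pytest.mark.parametrize("fmt", ["pdb", "mol2"])
    def test_round_trip_preserves_coords_and_order(self, tmp_path, fmt, h3_seq):
        s = build_fragment(FragmentSpec(start=2, residues="RT", n_cap="acetyl"),
                           h3_seq)
        path = tmp_path / f"frag.{fmt}"
        write_structure(s, path)
        s2 = read_structure(path)
        assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
        # PDB precision is 3 decimals
        assert np.allclose(s2.coords(), s.coords(), atol=2e-3)

    def test_malformed_mol2_names_line(self, tmp_path):
        path = tmp_path / "bad.mol2"
        path.write_text("@<TRIPOS>MOLECULE\nx\n2 0\nSMALL\nQ\n"
                        "@<TRIPOS>ATOM\n1 N notanumber 0 0 N.3\n")
        with pytest.raises(ParseError) as err:
            read_structure(path)
        assert "bad.mol2" in str(err.value)


class TestPrepareTarget:
    def test_keeps_first_protein_chain_and_drops_waters(self, tmp_path):
        path = tmp_path / "t.pdb"
        path.write_text(PDB_TWO_CHAINS)
        s = prepare_target(read_structure(path))
        chains = {a.chain_id for a in s.atoms}
        assert chains == {"A"}
        assert all(a.residue_name != "HOH" for a in s.atoms)

    def test_single_chain_unchanged_except_added_h(self, tmp_path):
        path = tmp_path / "t.pdb"
        path.write_text(PDB_3ATOM)
        s = prepare_target(read_structure(path))
        heavy = [a for a in s.atoms if not a.is_hydrogen]
        assert [a.name for a in heavy] == ["N", "CA", "C"]

    def test_water_only_structure_rejected(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        with pytest.raises(StructureError):
            prepare_target(read_structure(path))

    def test_idempotent(self, tmp_path):
        path = tmp_path / "t.pdb"
        path.write_text(PDB_TWO_CHAINS)
        once = prepare_target(read_structure(path))
        twice = prepare_target(once)
        assert [a.name for a in twice.atoms] == [a.name for a in once.atoms]
        assert np.allclose(twice.coords(), once.coords(), atol=1e-9)

    def test_all_atoms_parameterized(self, tmp_path):
        path = tmp_path / "t.pdb"
        path.write_text(PDB_TWO_CHAINS)
        s = prepare_target(read_structure(path))
        assert s.is_parameterized()


class TestAssignParameters:
    def test_carbonyl_oxygen_table_row(self, capped_ar_fragment):
        o = next(a for a in capped_ar_fragment.atoms
                 if a.name == "O" and a.residue_name == "ALA")
        assert (o.vdw_radius, o.well_depth) == (1.6612, 0.21)

    def test_capped_dipeptide_fully_typable(self, h3_seq):
        s = build_fragment(FragmentSpec(start=7, residues="AR", n_cap="acetyl"),
                           h3_seq)
        s = assign_parameters(s)  # no TypingError
        assert s.is_parameterized()

    def test_net_charge_of_neutral_dipeptide(self, h3_seq):
        # TA window: both residues neutral, caps neutral
        s = assign_parameters(
            build_fragment(FragmentSpec(start=6, residues="TA", n_cap="acetyl"),
                           h3_seq))
        assert s.net_charge() == pytest.approx(0.0, abs=0.01)

    def test_arg_dipeptide_net_plus_one(self, capped_ar_fragment):
        assert capped_ar_fragment.net_charge() == pytest.approx(1.0, abs=0.01)

    def test_mol2_charges_take_precedence(self, tmp_path):
        path = tmp_path / "c.mol2"
        path.write_text(MOL2_3ATOM)
        s = assign_parameters(read_structure(path))
        assert [a.charge for a in s.atoms] == [-0.3, 0.1, 0.2]

    def test_unknown_residue_rejected(self, tmp_path):
        path = tmp_path / "u.pdb"
        path.write_text(
            "ATOM      1 ZN    ZN A   1       0.000   0.000   0.000"
            "  1.00  0.00          ZN\nEND\n")
        with pytest.raises(TypingError):
            assign_parameters(read_structure(path))
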