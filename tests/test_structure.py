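"""Structure parsing, filtering, numbering and round-trip behaviour."""

import numpy as np
import pytest

from abdev.structure import (NumberingMap, StructureError, apply_numbering,
                             extract_chain_sequence, kabat_region,
                             load_numbering_csv, read_compact_chain_csv,
                             read_structure, write_compact_chain_csv, write_pdb)
from conftest import build_structure

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00 20.00           C  \n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1      11.000  12.000  13.000  0.60 20.00           C  \n"
    "ATOM      2  CA BALA A   1      11.500  12.000  13.000  0.40 21.00           C  \n"
    "END\n"
)

MULTI_PDB = (
    "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N  \n"
    "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 11.00           C  \n"
    "ATOM      3  CA  SER A   2       5.000   0.000   0.000  1.00 12.00           C  \n"
    "ATOM      4  CA  ASN A   3       9.000   0.000   0.000  1.00 13.00           C  \n"
    "HETATM    5  O   HOH A 101      20.000  20.000  20.000  1.00 30.00           O  \n"
    "HETATM    6 ZN    ZN A 102      25.000  25.000  25.000  1.00 30.00          ZN  \n"
    "END\n"
)

MSE_PDB = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C  \n"
    "HETATM    2  CA  MSE A   2       4.000   0.000   0.000  1.00 10.00           C  \n"
    "HETATM    3 SE   MSE A   2       5.500   0.000   0.000  1.00 10.00          SE  \n"
    "ATOM      4  CA  GLY A   3       8.000   0.000   0.000  1.00 10.00           C  \n"
    "END\n"
)


def test_minimal_single_atom_record(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(MINIMAL_PDB)
    st = read_structure(p)
    assert len(st.chains) == 1
    assert len(st.chains[0].residues) == 1
    assert st.n_atoms == 1
    atom = st.chains[0].residues[0].atoms[0]
    assert atom.element == "C"
    assert atom.vdw_radius == pytest.approx(1.70)
    np.testing.assert_allclose(atom.coords, [11.0, 12.0, 13.0])


def test_altloc_highest_occupancy_keeps_a_copy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    st = read_structure(p, altloc_policy="highest_occupancy")
    assert st.n_atoms == 1
    atom = st.chains[0].residues[0].atoms[0]
    assert atom.occupancy == pytest.approx(0.6)
    assert atom.coords[0] == pytest.approx(11.0)


def test_filters_are_monotone_and_water_specific(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_PDB)
    everything = read_structure(p, drop_waters=False, drop_hetero=False)
    no_water = read_structure(p, drop_waters=True, drop_hetero=False)
    default = read_structure(p)
    assert everything.n_atoms == 6
    assert no_water.n_atoms == 5  # exactly the HOH residue removed
    assert default.n_atoms == 4   # HOH and ZN removed
    assert {r.name for r in no_water.iter_residues()} == {"ALA", "SER", "ASN", "ZN"}


def test_unparseable_and_missing_files_raise(tmp_path):
    with pytest.raises(StructureError, match="no such file"):
        read_structure(tmp_path / "absent.pdb")
    empty = tmp_path / "only_water.pdb"
    empty.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O  \nEND\n")
    with pytest.raises(StructureError, match="empty structure"):
        read_structure(empty)


def test_sequence_extraction_and_modified_residue_alias(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_PDB)
    st = read_structure(p)
    assert extract_chain_sequence(st, "A") == "ASN"
    with pytest.raises(StructureError, match="no chain"):
        extract_chain_sequence(st, "Z")

    p2 = tmp_path / "mse.pdb"
    p2.write_text(MSE_PDB)
    aliased = read_structure(p2, use_modified_aliases=True)
    strict = read_structure(p2, use_modified_aliases=False, drop_hetero=False)
    assert extract_chain_sequence(aliased, "A") == "AMG"
    assert extract_chain_sequence(strict, "A") == "AXG"


def test_pdb_round_trip_preserves_identity_coords_bfactors(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_PDB)
    st = read_structure(p, drop_waters=False, drop_hetero=False)
    out = tmp_path / "out.pdb"
    write_pdb(st, out)
    st2 = read_structure(out, drop_waters=False, drop_hetero=False)
    keys1 = [r.key for r in st.iter_residues()]
    keys2 = [r.key for r in st2.iter_residues()]
    assert keys1 == keys2
    np.testing.assert_allclose(st.coords(), st2.coords(), atol=1e-3)
    b1 = [a.b_factor for _, a in st.iter_atoms()]
    b2 = [a.b_factor for _, a in st2.iter_atoms()]
    np.testing.assert_allclose(b1, b2, atol=1e-2)


def test_compact_chain_csv_round_trip(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_PDB)
    st = read_structure(p)
    out = tmp_path / "chain_A.csv"
    write_compact_chain_csv(st, "A", out)
    st2 = read_compact_chain_csv([out], "again")
    assert [r.key for r in st2.iter_residues()] == [r.key for r in st.iter_residues()]
    np.testing.assert_allclose(st2.coords(), st.coords(), atol=5e-3)
    assert [a.vdw_radius for _, a in st2.iter_atoms()] == \
           [a.vdw_radius for _, a in st.iter_atoms()]


def test_apply_numbering_direct_assignment_and_empty_map():
    st = build_structure([("H", 97, "W", [("CA", "C", (0, 0, 0), 1.7)]),
                          ("H", 98, "L", [("CA", "C", (4, 0, 0), 1.7)])])
    before = st.coords().copy()
    annotated = apply_numbering(st, NumberingMap({("H", 97, ""): ("H97", "CDR3")}))
    res = annotated.find_residue("H", 97)
    assert (res.scheme_label, res.region) == ("H97", "CDR3")
    assert annotated.find_residue("H", 98).region == "other"
    np.testing.assert_array_equal(annotated.coords(), before)

    st2 = build_structure([("H", 1, "Q", [("CA", "C", (0, 0, 0), 1.7)])])
    apply_numbering(st2, NumberingMap({}))
    assert st2.find_residue("H", 1).region == "other"


def test_apply_numbering_strict_vs_lenient():
    st = build_structure([("H", 97, "W", [("CA", "C", (0, 0, 0), 1.7)])])
    bad = NumberingMap({("H", 999, ""): ("H999", "other")})
    with pytest.raises(StructureError, match="not present"):
        apply_numbering(st, bad, strict=True)
    apply_numbering(st, bad, strict=False)  # lenient: ignored


def test_kabat_region_boundaries():
    # heavy: CDR3 spans 95-102, so W97 / Y99 are CDR3; light CDR3 89-97 holds W93
    assert kabat_region("heavy", 97) == "CDR3"
    assert kabat_region("heavy", 99) == "CDR3"
    assert kabat_region("light", 93) == "CDR3"
    assert kabat_region("heavy", 31) == "CDR1"
    assert kabat_region("heavy", 35) == "CDR1"
    assert kabat_region("heavy", 36) == "FR2"
    assert kabat_region("heavy", 50) == "CDR2"
    assert kabat_region("light", 24) == "CDR1"
    assert kabat_region("light", 56) == "CDR2"
    assert kabat_region("light", 88) == "FR3"
    assert kabat_region("heavy", 150) == "constant"


def test_numbering_csv_loader(tmp_path):
    csv = tmp_path / "map.csv"
    csv.write_text("chain,resnum,icode,aa,scheme_label,region\n"
                   "H,97,,W,H97,CDR3\nH,100,A,G,H100A,CDR3\n")
    numbering = load_numbering_csv(csv)
    assert numbering.entries[("H", 97, "")] == ("H97", "CDR3")
    assert numbering.entries[("H", 100, "A")] == ("H100A", "CDR3")
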