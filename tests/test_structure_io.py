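"""Structure and pocket-list I/O: heavy-atom contract, ligand filtering,
altloc resolution, and the two pocket formats."""

import numpy as np
import pytest

from prank.structure_io import (
    CrossReferenceError,
    EmptyStructureError,
    PocketFormatError,
    PocketPrediction,
    load_structure,
    parse_fpocket_output,
    parse_generic_pockets,
    write_generic_pockets,
    write_rescored,
)
from prank.scoring import RankedPocket


def _atom_line(record, serial, name, resname, chain, resseq, x, y, z,
               occ=1.0, b=20.0, altloc=" ", element=None):
    element = element or name[0]
    pname = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {pname}{altloc}{resname:>3s} {chain}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def _write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_load_structure_filters_waters_hydrogens_and_small_hetatms(tmp_path):
    lines = []
    for i in range(10):
        lines.append(_atom_line("ATOM", i + 1, "CA", "GLY", "A", i + 1,
                                float(3 * i), 0, 0))
    lines.append(_atom_line("ATOM", 11, "H", "GLY", "A", 1, 0, 1, 0, element="H"))
    lines.append(_atom_line("HETATM", 12, "O", "HOH", "W", 100, 50, 50, 50))
    # 2-atom group: fails the default >=5 heavy atom ligand filter
    lines.append(_atom_line("HETATM", 13, "C1", "XAA", "L", 200, 40, 0, 0))
    lines.append(_atom_line("HETATM", 14, "C2", "XAA", "L", 200, 41, 0, 0))
    # 6-atom group: passes
    for j in range(6):
        lines.append(_atom_line("HETATM", 15 + j, f"C{j+1}", "XBB", "L", 300,
                                30.0 + j, 5, 0))
    st = load_structure(_write_pdb(tmp_path / "t.pdb", lines))
    assert len(st.atoms) == 10
    assert all(a.element != "H" for a in st.atoms)
    assert len(st.ligands) == 1 and st.ligands[0].group_name == "XBB"
    assert len(st.ligands[0].atoms) == 6
    np.testing.assert_allclose(st.ligands[0].center,
                               np.mean([[30 + j, 5, 0] for j in range(6)], axis=0))


def test_load_structure_min_ligand_atoms_configurable(tmp_path):
    lines = [_atom_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0)]
    lines += [_atom_line("HETATM", 2 + j, f"C{j+1}", "XAA", "L", 10,
                         10.0 + j, 0, 0) for j in range(3)]
    path = _write_pdb(tmp_path / "t.pdb", lines)
    assert len(load_structure(path).ligands) == 0
    assert len(load_structure(path, min_ligand_atoms=3).ligands) == 1


def test_load_structure_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        _atom_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0, occ=0.4, altloc="A"),
        _atom_line("ATOM", 2, "CA", "GLY", "A", 1, 9, 9, 9, occ=0.6, altloc="B"),
        _atom_line("ATOM", 3, "CB", "GLY", "A", 1, 1, 1, 1, occ=0.5, altloc="A"),
        _atom_line("ATOM", 4, "CB", "GLY", "A", 1, 2, 2, 2, occ=0.5, altloc="B"),
    ]
    st = load_structure(_write_pdb(tmp_path / "t.pdb", lines))
    by_name = {a.name: a for a in st.atoms}
    np.testing.assert_allclose(by_name["CA"].coords, [9, 9, 9])   # higher occ
    np.testing.assert_allclose(by_name["CB"].coords, [1, 1, 1])   # tie -> first


def test_load_structure_empty_and_unparseable(tmp_path):
    only_water = [_atom_line("HETATM", 1, "O", "HOH", "W", 1, 0, 0, 0)]
    with pytest.raises(EmptyStructureError):
        load_structure(_write_pdb(tmp_path / "w.pdb", only_water))


@pytest.fixture
def ten_atom_structure(tmp_path):
    lines = [_atom_line("ATOM", i + 1, "CA", "GLY", "A", i + 1,
                        float(3 * i), 0, 0) for i in range(10)]
    return load_structure(_write_pdb(tmp_path / "s.pdb", lines))


class TestFpocketOutput:
    def _make_dir(self, tmp_path, files):
        d = tmp_path / "out"
        (d / "pockets").mkdir(parents=True)
        for name, text in files.items():
            (d / "pockets" / name).write_text(text)
        return d

    def test_parses_ranks_scores_and_centroid(self, tmp_path, ten_atom_structure):
        p1 = "\n".join([
            "HEADER 0  - Pocket Score : 1.25",
            "HEADER 5  - Volume : 310.5",
            _atom_line("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0),
            _atom_line("ATOM", 2, "CA", "GLY", "A", 2, 3, 0, 0),
        ])
        p2 = _atom_line("ATOM", 5, "CA", "GLY", "A", 5, 12, 0, 0)
        d = self._make_dir(tmp_path, {"pocket1_atm.pdb": p1,
                                      "pocket2_atm.pdb": p2})
        pockets = parse_fpocket_output(d, ten_atom_structure)
        assert [p.original_rank for p in pockets] == [1, 2]
        assert pockets[0].original_score == 1.25
        assert pockets[0].volume == 310.5
        np.testing.assert_allclose(pockets[0].center, [1.5, 0, 0])

    def test_missing_pockets_dir_errors(self, tmp_path, ten_atom_structure):
        with pytest.raises(PocketFormatError):
            parse_fpocket_output(tmp_path, ten_atom_structure)

    def test_unknown_serial_errors_with_offender(self, tmp_path,
                                                 ten_atom_structure):
        bad = _atom_line("ATOM", 99, "CA", "GLY", "A", 99, 0, 0, 0)
        d = self._make_dir(tmp_path, {"pocket1_atm.pdb": bad})
        with pytest.raises(CrossReferenceError, match="99"):
            parse_fpocket_output(d, ten_atom_structure)


class TestGenericPockets:
    def test_round_trip_preserves_everything(self, tmp_path, ten_atom_structure):
        pockets = [
            PocketPrediction("a", 1, frozenset({1, 2, 3}), np.array([1.0, 2.0, 3.0]),
                             original_score=0.5, volume=120.0),
            PocketPrediction("b", 2, frozenset({4, 5}), np.array([4.5, 0.0, 0.0])),
        ]
        path = tmp_path / "p.csv"
        write_generic_pockets(pockets, path)
        back = parse_generic_pockets(path, ten_atom_structure)
        for orig, rt in zip(pockets, back):
            assert rt.pocket_id == orig.pocket_id
            assert rt.original_rank == orig.original_rank
            assert rt.member_atom_serials == orig.member_atom_serials
            np.testing.assert_allclose(rt.center, orig.center)
            assert rt.volume == orig.volume

    def test_explicit_center_wins_over_centroid(self, tmp_path,
                                                ten_atom_structure):
        path = tmp_path / "p.csv"
        path.write_text("pocket_id,rank,score,volume,atom_serials,cx,cy,cz\n"
                        "a,1,,,1;2,7.0,8.0,9.0\n")
        (pocket,) = parse_generic_pockets(path, ten_atom_structure)
        np.testing.assert_allclose(pocket.center, [7, 8, 9])

    def test_missing_center_uses_centroid(self, tmp_path, ten_atom_structure):
        path = tmp_path / "p.csv"
        path.write_text("pocket_id,rank,atom_serials\na,1,1;2\n")
        (pocket,) = parse_generic_pockets(path, ten_atom_structure)
        np.testing.assert_allclose(pocket.center, [1.5, 0, 0], atol=1e-9)

    @pytest.mark.parametrize("body,err", [
        ("a,1,1;2\nb,3,3;4\n", "contiguous"),          # ranks 1,3
        ("a,1,1;2\na,2,3;4\n", "duplicate"),           # duplicate id
    ])
    def test_format_errors(self, tmp_path, ten_atom_structure, body, err):
        path = tmp_path / "p.csv"
        path.write_text("pocket_id,rank,atom_serials\n" + body)
        with pytest.raises(PocketFormatError, match=err):
            parse_generic_pockets(path, ten_atom_structure)


class TestWriteRescored:
    def _ranked(self, pid, orig, new, score):
        pocket = PocketPrediction(pid, orig, frozenset({1}), np.zeros(3))
        return RankedPocket(pocket=pocket, pscore=score, new_rank=new, n_points=3)

    def test_sorted_by_new_rank(self, tmp_path):
        ranked = [self._ranked("a", 1, 2, 5.0), self._ranked("b", 2, 1, 7.0)]
        path = tmp_path / "r.csv"
        write_rescored(ranked, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "pocket_id,original_rank,new_rank,pscore,n_inner_points"
        assert lines[1].startswith("b,2,1,7.0")
        assert lines[2].startswith("a,1,2,5.0")

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "r.csv"
        write_rescored([], path)
        assert path.read_text().strip() == \
            "pocket_id,original_rank,new_rank,pscore,n_inner_points"
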