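"""Structure parsing, pLDDT extraction, correspondence and pocket geometry."""

import numpy as np
import pytest

from rass.exceptions import CorrespondenceError, InputError, SelectionError
from rass.structure_io import (
    ReferencePair,
    build_correspondence,
    define_pocket,
    extract_plddt,
    fetch_structure,
    read_structure,
    write_structure,
)
from rass.synthetic import make_hinge_conformer

from conftest import pdb_line, write_pdb_text


def _three_residue_pdb(tmp_path, b=(10.0, 20.0, 30.0)):
    lines = []
    serial = 1
    for ri, bf in enumerate(b, start=1):
        for name, dx in (("N", 0.0), ("CA", 1.5), ("C", 3.0), ("O", 4.0)):
            lines.append(
                pdb_line(
                    serial,
                    name,
                    (ri * 10.0 + dx, 1.0, 2.0),
                    res_id=ri,
                    b=bf,
                    element=name[0],
                )
            )
            serial += 1
    path = tmp_path / "three.pdb"
    write_pdb_text(path, lines)
    return path


def test_read_minimal_pdb(tmp_path):
    model = read_structure(_three_residue_pdb(tmp_path))
    assert model.n_residues() == 3
    assert set(model.atoms.atom_name) == {"N", "CA", "C", "O"}
    assert not model.atoms.hetero.any()


def test_write_read_roundtrip_precision(tmp_path, hinge_pair):
    apo, _, _ = hinge_pair
    out = tmp_path / "apo.pdb"
    write_structure(apo, out)
    again = read_structure(out)
    assert len(again.atoms) == len(apo.atoms)
    delta = np.abs(again.atoms.coord - apo.atoms.coord).max()
    assert delta <= 1e-3  # PDB fixed-width precision


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    lines = [
        pdb_line(1, "N", (0.0, 0.0, 0.0), element="N"),
        pdb_line(2, "CA", (1.0, 0.0, 0.0), alt="A", occ=0.40),
        pdb_line(3, "CA", (9.0, 9.0, 9.0), alt="B", occ=0.60),
        pdb_line(4, "C", (2.0, 0.0, 0.0)),
        pdb_line(5, "O", (3.0, 0.0, 0.0), element="O"),
    ]
    path = tmp_path / "alt.pdb"
    write_pdb_text(path, lines)
    model = read_structure(path)
    ca = model.atoms[model.atoms.atom_name == "CA"]
    assert len(ca) == 1  # single conformer retained
    assert np.allclose(ca.coord[0], [9.0, 9.0, 9.0])  # the 0.60-occupancy one


def test_missing_chain_is_selection_error(tmp_path):
    path = _three_residue_pdb(tmp_path)
    with pytest.raises(SelectionError, match="chain"):
        read_structure(path, chain="Z")


def test_extract_plddt_uniform_and_mixed(tmp_path):
    model = read_structure(_three_residue_pdb(tmp_path, b=(90.0, 90.0, 90.0)))
    assert np.array_equal(extract_plddt(model), [90.0, 90.0, 90.0])
    model = read_structure(_three_residue_pdb(tmp_path, b=(50.0, 90.0, 50.0)))
    assert np.array_equal(extract_plddt(model), [50.0, 90.0, 50.0])


def test_extract_plddt_out_of_range_warns_and_reports_as_is(tmp_path):
    model = read_structure(_three_residue_pdb(tmp_path, b=(120.0, 90.0, 90.0)))
    with pytest.warns(UserWarning, match="outside"):
        vals = extract_plddt(model)
    assert vals[0] == 120.0


def test_extract_plddt_skips_residue_without_ca(tmp_path):
    lines = [
        pdb_line(1, "CA", (0.0, 0.0, 0.0), res_id=1, b=80.0),
        pdb_line(2, "N", (5.0, 0.0, 0.0), res_id=2, element="N", b=70.0),  # no CA
        pdb_line(3, "CA", (10.0, 0.0, 0.0), res_id=3, b=60.0),
    ]
    path = tmp_path / "noca.pdb"
    write_pdb_text(path, lines)
    model = read_structure(path)
    with pytest.warns(UserWarning, match="no CA"):
        vals = extract_plddt(model)
    assert np.array_equal(vals, [80.0, 60.0])


def test_correspondence_identical_models(hinge_pair):
    apo, _, _ = hinge_pair
    corr = build_correspondence(apo, apo)
    assert len(corr) == apo.n_residues()
    assert corr.keys_a == corr.keys_b
    assert corr.n_dropped_a == corr.n_dropped_b == 0


def test_correspondence_with_missing_residues(hinge_pair):
    apo, _, _ = hinge_pair
    truncated = read = apo.atoms[(apo.atoms.res_id < 5) | (apo.atoms.res_id > 10)]
    from rass.structure_io import StructureModel

    b = StructureModel(id="trunc", atoms=truncated)
    corr = build_correspondence(apo, b)
    matched_ids = {k[0] for k in corr.keys_a}
    assert matched_ids == set(range(1, 61)) - set(range(5, 11))
    assert corr.n_dropped_a == 6


def test_correspondence_numbering_offset(hinge_pair):
    apo, _, _ = hinge_pair
    shifted = apo.atoms.copy()
    shifted.res_id = shifted.res_id + 100
    from rass.structure_io import StructureModel

    b = StructureModel(id="shift", atoms=shifted)
    with pytest.raises(CorrespondenceError):
        build_correspondence(apo, b)
    corr = build_correspondence(apo, b, offset_b=100)
    assert len(corr) == apo.n_residues()
    assert all(kb[0] == ka[0] + 100 for ka, kb in zip(corr.keys_a, corr.keys_b))


def test_correspondence_symmetry(hinge_pair):
    apo, holo, _ = hinge_pair
    ab = build_correspondence(apo, holo)
    ba = build_correspondence(holo, apo)
    assert list(zip(ab.keys_a, ab.keys_b)) == [(b, a) for a, b in zip(ba.keys_a, ba.keys_b)]


def test_correspondence_minimum_matched():
    small = make_hinge_conformer(10)
    with pytest.raises(CorrespondenceError, match="minimum"):
        build_correspondence(small, small)  # default floor of 30
    corr = build_correspondence(small, small, min_matched=5)
    assert len(corr) == 10


def _pocket_fixture(tmp_path, lig_x):
    """5 CA-only residues on the x axis at 0,10,20,30,40; ligand at lig_x."""
    lines = [
        pdb_line(i + 1, "CA", (10.0 * i, 0.0, 0.0), res_id=i + 1) for i in range(5)
    ]
    lines.append(
        pdb_line(
            6, "C1", (lig_x, 0.0, 0.0), res_id=99, res_name="LIG", record="HETATM"
        )
    )
    path = tmp_path / "pocket.pdb"
    write_pdb_text(path, lines)
    return read_structure(path)


def test_pocket_boundary_inclusive(tmp_path):
    # ligand exactly 4.5 A from residue 1 (at x=0): included
    holo = _pocket_fixture(tmp_path, lig_x=-4.5)
    pocket = define_pocket(holo, ligand="LIG", cutoff=4.5)
    assert pocket == frozenset({(1, "")})


def test_pocket_far_ligand_empty_set(tmp_path):
    holo = _pocket_fixture(tmp_path, lig_x=-20.0)
    assert define_pocket(holo, ligand="LIG", cutoff=4.5) == frozenset()


def test_pocket_matches_brute_force_distances(tmp_path, hinge_pair):
    _, holo, _ = hinge_pair
    pocket = define_pocket(holo, ligand="LIG", cutoff=4.5)
    # brute force: all protein-heavy x ligand-heavy pairs
    prot = holo.protein_atoms
    lig = holo.hetero_atoms
    expected = set()
    for i in range(len(prot)):
        d = np.linalg.norm(lig.coord - prot.coord[i], axis=1).min()
        if d <= 4.5:
            expected.add((int(prot.res_id[i]), str(prot.ins_code[i])))
    assert pocket == frozenset(expected)
    assert len(pocket) > 0


def test_pocket_ligand_not_found(tmp_path):
    holo = _pocket_fixture(tmp_path, lig_x=-4.5)
    with pytest.raises(SelectionError, match="not found"):
        define_pocket(holo, ligand="XYZ")


def test_reference_pair_restricts_pocket_to_correspondence(hinge_pair):
    apo, holo, _ = hinge_pair
    pair = ReferencePair.from_models(apo, holo, ligand="LIG")
    assert pair.pocket is not None and len(pair.pocket) > 0
    assert pair.pocket <= set(pair.correspondence.keys_b)


def test_fetch_requires_explicit_opt_in(tmp_path):
    with pytest.raises(InputError, match="downloads are disabled"):
        fetch_structure("1ABC", tmp_path, allow_download=False)
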