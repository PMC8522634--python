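"""Tests for PDB parsing, salt-bridge detection and charge-reversal logic."""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pytest

from ampmosaic import (
    AtomRecord,
    charge_reversal_report,
    find_salt_bridges,
    parse_pdb_atoms,
)
from ampmosaic.structure import (
    PdbParseError,
    parse_mutation,
    write_pdb_atoms,
)

from conftest import oracle_salt_bridges


def _atom(chain, resname, resnum, name, x, y, z) -> AtomRecord:
    return AtomRecord(chain, resname, resnum, name, x, y, z)


def _interface(distance: float) -> list[AtomRecord]:
    """Minimal two-chain Lys/Asp interface at a given NZ–OD1 distance."""
    return [
        _atom("B", "LYS", 78, "NZ", 0.0, 0.0, 0.0),
        _atom("B", "LYS", 78, "CA", 1.5, 0.0, 0.0),
        _atom("A", "ASP", 22, "OD1", distance, 0.0, 0.0),
        _atom("A", "ASP", 22, "CB", distance + 1.5, 0.0, 0.0),
    ]


def test_parse_two_atom_fixture():
    text = (
        "ATOM      1  NZ  LYS B  78      11.104  13.207   9.500  1.00  0.00\n"
        "ATOM      2  OD1 ASP A  22      14.104  13.207   9.500  1.00  0.00\n"
        "END\n"
    )
    atoms = parse_pdb_atoms(io.StringIO(text))
    assert len(atoms) == 2
    assert atoms[0] == _atom("B", "LYS", 78, "NZ", 11.104, 13.207, 9.5)
    assert atoms[1].atom_name == "OD1"


def test_hetatm_anisou_and_altloc_skipped():
    text = (
        "HETATM    1  O   HOH A 201      10.000  10.000  10.000  1.00  0.00\n"
        "ANISOU    1  NZ  LYS B  78     1000   1000   1000      0      0      0\n"
        "ATOM      2  NZ BLYS B  78      11.000  12.000  13.000  1.00  0.00\n"
        "ATOM      3  NZ ALYS B  78       1.000   2.000   3.000  1.00  0.00\n"
    )
    atoms = parse_pdb_atoms(io.StringIO(text))
    assert len(atoms) == 1  # only the altLoc 'A' ATOM survives
    assert atoms[0].x == 1.0


def test_malformed_coordinate_reports_line_number():
    text = "ATOM      1  NZ  LYS B  78      xx.xxx  13.207   9.500\n"
    with pytest.raises(PdbParseError, match="line 1"):
        parse_pdb_atoms(io.StringIO(text))


def test_writer_parser_roundtrip(tmp_path):
    """100 generated atoms survive write -> parse unchanged."""
    rng = np.random.default_rng(55)
    resnames = ["LYS", "ARG", "ASP", "GLU", "ALA", "HIS"]
    names = {"LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1",
             "ALA": "CB", "HIS": "ND1"}
    atoms = []
    for i in range(100):
        res = resnames[int(rng.integers(0, len(resnames)))]
        atoms.append(
            _atom(
                "AB"[int(rng.integers(0, 2))], res, int(rng.integers(1, 400)),
                names[res],
                *(float(np.round(v, 3)) for v in rng.uniform(-99, 99, 3)),
            )
        )
    path = tmp_path / "fixture.pdb"
    write_pdb_atoms(atoms, path)
    with open(path) as fh:
        back = parse_pdb_atoms(fh)
    assert back == atoms


def test_roundtrip_agrees_with_biopython_parser(tmp_path):
    """Cross-check the fixed-column writer/parser against Bio.PDB."""
    from Bio.PDB import PDBParser

    atoms = _interface(3.0)
    path = tmp_path / "iface.pdb"
    write_pdb_atoms(atoms, path)
    model = PDBParser(QUIET=True).get_structure("x", str(path))[0]
    ours = {(a.chain_id, a.residue_number, a.atom_name): (a.x, a.y, a.z) for a in atoms}
    theirs = {}
    for chain in model:
        for res in chain:
            for atom in res:
                theirs[(chain.id, res.id[1], atom.get_name())] = tuple(
                    float(v) for v in atom.coord
                )
    assert set(ours) == set(theirs)
    for key, xyz in ours.items():
        assert np.allclose(theirs[key], xyz, atol=1e-3)


def test_contact_at_three_angstroms():
    contacts = find_salt_bridges(_interface(3.0), "A", "B")
    assert len(contacts) == 1
    c = contacts[0]
    assert c.cation == ("B", "LYS", 78, "NZ")
    assert c.anion == ("A", "ASP", 22, "OD1")
    assert c.distance == pytest.approx(3.0)


def test_no_contact_beyond_cutoff():
    assert find_salt_bridges(_interface(8.0), "A", "B") == []


def test_missing_chain_lists_available():
    with pytest.raises(ValueError, match="available"):
        find_salt_bridges(_interface(3.0), "A", "Z")


def test_matches_all_pairs_oracle():
    """Random 50-atom two-chain fixtures (120 instances): the detected
    contact set equals the brute-force all-pairs search."""
    rng = np.random.default_rng(61)
    resnames = ["LYS", "ARG", "HIS", "ASP", "GLU", "GLY"]
    atom_names = {
        "LYS": ["NZ", "CA"], "ARG": ["NH1", "NH2", "NE", "CZ"],
        "HIS": ["ND1", "NE2", "CB"], "ASP": ["OD1", "OD2", "CG"],
        "GLU": ["OE1", "OE2"], "GLY": ["CA"],
    }
    for trial in range(120):
        atoms = []
        for i in range(50):
            res = resnames[int(rng.integers(0, len(resnames)))]
            name = atom_names[res][int(rng.integers(0, len(atom_names[res])))]
            atoms.append(
                _atom(
                    "AB"[int(rng.integers(0, 2))], res,
                    int(rng.integers(1, 40)), name,
                    *(float(v) for v in rng.uniform(0, 15, 3)),
                )
            )
        cutoff = float(rng.uniform(3.0, 6.0))
        got = {
            (c.cation, c.anion) for c in find_salt_bridges(atoms, "A", "B", cutoff)
        }
        assert got == oracle_salt_bridges(atoms, "A", "B", cutoff)


def test_symmetry_and_threshold_monotonicity():
    atoms = _interface(3.9) + [
        _atom("A", "ARG", 30, "NH1", 0.0, 3.5, 0.0),
        _atom("B", "GLU", 90, "OE2", 0.0, 0.5, 0.0),
    ]
    ab = find_salt_bridges(atoms, "A", "B", 4.0)
    ba = find_salt_bridges(atoms, "B", "A", 4.0)
    assert ab == ba  # symmetric in chain order
    near = {(c.cation, c.anion) for c in find_salt_bridges(atoms, "A", "B", 3.5)}
    far = {(c.cation, c.anion) for c in find_salt_bridges(atoms, "A", "B", 4.0)}
    assert near <= far


def test_histidine_contacts_flagged():
    atoms = [
        _atom("B", "HIS", 10, "ND1", 0.0, 0.0, 0.0),
        _atom("A", "GLU", 5, "OE1", 3.2, 0.0, 0.0),
    ]
    contacts = find_salt_bridges(atoms, "A", "B")
    assert contacts[0].histidine_cation is True


def test_charge_reversal_for_lysine_to_glutamate():
    """K78E converts the K78–D22 attraction into a like-charge repulsion."""
    contacts = find_salt_bridges(_interface(3.0), "A", "B")
    report = charge_reversal_report(contacts, "K78E")
    assert "attractive -> repulsive" in report
    assert "LYS78" in report and "ASP22" in report


def test_charge_reversal_edge_cases():
    contacts = find_salt_bridges(_interface(3.0), "A", "B")
    assert charge_reversal_report(contacts, "K99E") == ""  # untouched residue
    assert "attractive -> attractive" in charge_reversal_report(contacts, "K78R")
    with pytest.raises(ValueError):
        parse_mutation("not-a-mutation")


def test_transducin_interface_contact_if_structure_available():
    """Optional integration check on the 2.0 A transducin heterotrimer
    (PDB 1GOT): the Gbeta Lys78 – Galpha Asp22 salt bridge is detected.
    Runs only when a local copy of the coordinates is present."""
    path = Path(__file__).parent / "data" / "1got.pdb"
    if not path.exists():
        pytest.skip("1GOT coordinates not available locally")
    with open(path) as fh:
        atoms = parse_pdb_atoms(fh)
    contacts = find_salt_bridges(atoms, "A", "B", 4.0)
    pairs = {
        (c.cation[1], c.cation[2], c.anion[1], c.anion[2]) for c in contacts
    }
    assert ("LYS", 78, "ASP", 22) in pairs
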