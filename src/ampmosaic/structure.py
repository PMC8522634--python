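"""Inter-chain salt-bridge detection on PDB-format coordinates.

In a heterotrimeric G-protein, the Gβ β-propeller contacts the
N-terminal helix of Gα; a lysine on the propeller surface can form an
intermolecular salt bridge with an aspartate of that helix, and a
charge-reversing substitution (K→E) at the lysine converts the
attraction into repulsion, destabilising Gα–Gβγ reassembly.  This
module makes that argument computable: parse ATOM records, enumerate
cation–carboxylate atom pairs across two chains within a distance
cutoff, and report how a residue substitution changes each contact's
electrostatic character.

The salt-bridge criterion is the conventional one: charged-group heavy
atoms (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2, protonation unknown, so His
contacts are flagged; Asp OD1/OD2; Glu OE1/OE2) within 4.0 Å by
default.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

CATION_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}
ANION_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Formal side-chain charge by 3-letter residue name (else 0).
RESIDUE_CHARGE = {"LYS": +1, "ARG": +1, "HIS": +1, "ASP": -1, "GLU": -1}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_name: str  # 3-letter
    residue_number: int
    atom_name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("empty atom_name")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("non-finite coordinate")


@dataclass(frozen=True)
class SaltBridgeContact:
    """One cation–carboxylate heavy-atom pair across the interface."""

    cation: tuple[str, str, int, str]  # (chain, resname, resnum, atom)
    anion: tuple[str, str, int, str]
    distance: float
    histidine_cation: bool = False  # protonation-dependent, flagged

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be > 0")
        if self.cation[1] not in CATION_ATOMS:
            raise ValueError(f"{self.cation[1]} is not a cationic residue")
        if self.anion[1] not in ANION_ATOMS:
            raise ValueError(f"{self.anion[1]} is not an anionic residue")


class PdbParseError(ValueError):
    pass


def parse_pdb_atoms(stream: TextIO | Iterable[str]) -> list[AtomRecord]:
    """Parse fixed-column ATOM records from PDB-format text.

    Columns follow the PDB v3 dialect: atom name 13–16, altLoc 17,
    resName 18–20, chainID 22, resSeq 23–26, x/y/z 31–54.  HETATM and
    ANISOU lines are ignored; alternate locations other than blank or
    'A' are skipped.  A malformed numeric field raises
    :class:`PdbParseError` naming the line number.
    """
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.startswith("ATOM"):
            continue
        altloc = line[16:17]
        if altloc not in (" ", "", "A"):
            continue
        try:
            atoms.append(
                AtomRecord(
                    chain_id=line[21:22].strip(),
                    residue_name=line[17:20].strip(),
                    residue_number=int(line[22:26]),
                    atom_name=line[12:16].strip(),
                    x=float(line[30:38]),
                    y=float(line[38:46]),
                    z=float(line[46:54]),
                )
            )
        except ValueError as exc:
            raise PdbParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    return atoms


def write_pdb_atoms(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write atoms as valid fixed-column ATOM records (fixture writer)."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {i:>5d} {name:<4s} {a.residue_name:>3s} {a.chain_id:1s}"
                f"{a.residue_number:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"  1.00  0.00\n"
            )
        fh.write("END\n")


def find_salt_bridges(
    atoms: Sequence[AtomRecord],
    chain_a: str,
    chain_b: str,
    max_dist: float = 4.0,
) -> list[SaltBridgeContact]:
    """All inter-chain cation–carboxylate pairs within ``max_dist`` Å.

    Pairs are taken in both directions (cation on either chain), sorted
    by distance ascending, and the result is symmetric in chain order.
    Raises if either chain is absent, listing the chains present.
    """
    chains_present = {a.chain_id for a in atoms}
    for chain in (chain_a, chain_b):
        if chain not in chains_present:
            raise ValueError(
                f"chain {chain!r} not in structure; available: "
                f"{sorted(chains_present)}"
            )

    def _select(chain: str, table: dict[str, tuple[str, ...]]) -> list[AtomRecord]:
        return [
            a
            for a in atoms
            if a.chain_id == chain
            and a.residue_name in table
            and a.atom_name in table[a.residue_name]
        ]

    contacts: list[SaltBridgeContact] = []
    for cat_chain, an_chain in ((chain_a, chain_b), (chain_b, chain_a)):
        for cat in _select(cat_chain, CATION_ATOMS):
            for an in _select(an_chain, ANION_ATOMS):
                d = math.dist((cat.x, cat.y, cat.z), (an.x, an.y, an.z))
                if d <= max_dist:
                    contacts.append(
                        SaltBridgeContact(
                            cation=(cat.chain_id, cat.residue_name,
                                    cat.residue_number, cat.atom_name),
                            anion=(an.chain_id, an.residue_name,
                                   an.residue_number, an.atom_name),
                            distance=d,
                            histidine_cation=cat.residue_name == "HIS",
                        )
                    )
    contacts.sort(key=lambda c: (c.distance, c.cation, c.anion))
    return contacts


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation(mutation: str) -> tuple[str, int, str]:
    """Parse 'K78E' -> ('LYS', 78, 'GLU')."""
    m = _MUTATION_RE.match(mutation.strip().upper())
    if not m or m.group(1) not in _ONE_TO_THREE or m.group(3) not in _ONE_TO_THREE:
        raise ValueError(f"cannot parse mutation string {mutation!r}")
    return _ONE_TO_THREE[m.group(1)], int(m.group(2)), _ONE_TO_THREE[m.group(3)]


def _pair_character(charge_a: int, charge_b: int) -> str:
    if charge_a * charge_b < 0:
        return "attractive"
    if charge_a * charge_b > 0:
        return "repulsive"
    return "neutral"


def charge_reversal_report(
    contacts: Sequence[SaltBridgeContact], mutation: str
) -> str:
    """Describe how *mutation* (e.g. ``K78E``) changes each involved contact.

    For every contact whose cation or anion residue matches the mutated
    residue number and type, reports the electrostatic character before
    and after the substitution per the formal charge table (K/R/H: +1,
    D/E: -1, else 0).  Contacts not involving the residue are omitted;
    an empty report means the mutation touches no detected bridge.
    """
    from_res, resnum, to_res = parse_mutation(mutation)
    to_charge = RESIDUE_CHARGE.get(to_res, 0)
    lines: list[str] = []
    for c in contacts:
        for side, partner in ((c.cation, c.anion), (c.anion, c.cation)):
            if side[1] == from_res and side[2] == resnum:
                before = _pair_character(
                    RESIDUE_CHARGE.get(side[1], 0),
                    RESIDUE_CHARGE.get(partner[1], 0),
                )
                after = _pair_character(
                    to_charge, RESIDUE_CHARGE.get(partner[1], 0)
                )
                lines.append(
                    f"{side[1]}{side[2]} (chain {side[0]}) -- "
                    f"{partner[1]}{partner[2]} (chain {partner[0]}) at "
                    f"{c.distance:.2f} A: {before} -> {after} under {mutation}"
                )
    return "\n".join(lines)


def write_contacts_tsv(
    contacts: Iterable[SaltBridgeContact], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cation_chain\tcation_res\tcation_num\tcation_atom\t"
            "anion_chain\tanion_res\tanion_num\tanion_atom\t"
            "distance_A\this_flagged\n"
        )
        for c in contacts:
            fh.write(
                "\t".join(
                    [
                        c.cation[0], c.cation[1], str(c.cation[2]), c.cation[3],
                        c.anion[0], c.anion[1], str(c.anion[2]), c.anion[3],
                        f"{c.distance:.3f}", "1" if c.histidine_cation else "0",
                    ]
                )
                + "\n"
            )
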