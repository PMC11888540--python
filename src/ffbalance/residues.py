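"""Amino-acid naming tables shared by atom classification and fixtures.

Sidechain connectivity is encoded as (parent, child) bonded pairs rooted
at CA, using PDB v3 atom names.  Histidine is shipped as the neutral
N-delta tautomer; protonation variants are handled through the alias
table.
"""

from __future__ import annotations

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: protonation/tautomer variants -> canonical residue name
RESIDUE_ALIASES = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
    "CYM": "CYS", "CYX": "CYS", "TYM": "TYR",
    "ARN": "ARG",
}

STANDARD_RESIDUES = set(ONE_TO_THREE.values())

#: residues whose sidechain is ionized at neutral pH (the variants that
#: neutralize them are mapped back by name, so they are checked by the
#: *file* residue name, not the canonical one)
CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIP", "HSP", "CYM", "TYM"}

#: formal sidechain charge used by the toy-topology generator
FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

WATER_RESIDUES = {"SOL", "WAT", "HOH", "TIP3", "TIP4", "TIP5", "SPC", "T4P", "T3P"}
ION_RESIDUES = {"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "MG2", "ZN", "CAL", "LI"}

#: main-chain caps; their atoms follow the backbone rule
CAP_RESIDUES = {"ACE", "NME", "NMA", "NHE"}

#: backbone atom names common to all residues (heavy + polar/alpha H),
#: including terminal variants
BACKBONE_ATOMS = {
    "N", "H", "HN", "CA", "HA", "HA1", "HA2", "HA3", "C", "O",
    "OXT", "OC1", "OC2", "O1", "O2", "H1", "H2", "H3", "HT1", "HT2", "HT3",
}

BACKBONE_HEAVY_ATOMS = {"N", "CA", "C", "O", "OXT", "OC1", "OC2", "O1", "O2"}

#: sidechain bonded pairs rooted at CA (PDB v3 names, hydrogens included)
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
    "SER": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"), ("OG", "HG")],
    "THR": [("CA", "CB"), ("CB", "HB"), ("CB", "OG1"), ("OG1", "HG1"),
            ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")],
    "CYS": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "SG"), ("SG", "HG")],
    "VAL": [("CA", "CB"), ("CB", "HB"),
            ("CB", "CG1"), ("CG1", "HG11"), ("CG1", "HG12"), ("CG1", "HG13"),
            ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")],
    "LEU": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"), ("CG", "HG"),
            ("CG", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
            ("CG", "CD2"), ("CD2", "HD21"), ("CD2", "HD22"), ("CD2", "HD23")],
    "ILE": [("CA", "CB"), ("CB", "HB"),
            ("CB", "CG2"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
            ("CB", "CG1"), ("CG1", "HG12"), ("CG1", "HG13"),
            ("CG1", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13")],
    "MET": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"), ("CG", "SD"),
            ("SD", "CE"), ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3")],
    "PHE": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CG", "CD2"), ("CD2", "HD2"),
            ("CD1", "CE1"), ("CE1", "HE1"), ("CD2", "CE2"), ("CE2", "HE2"),
            ("CE1", "CZ"), ("CZ", "HZ")],
    "TYR": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CG", "CD2"), ("CD2", "HD2"),
            ("CD1", "CE1"), ("CE1", "HE1"), ("CD2", "CE2"), ("CE2", "HE2"),
            ("CE1", "CZ"), ("CZ", "OH"), ("OH", "HH")],
    "TRP": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "HE1"), ("CD2", "CE2"),
            ("CD2", "CE3"), ("CE3", "HE3"), ("CE2", "CZ2"), ("CZ2", "HZ2"),
            ("CE3", "CZ3"), ("CZ3", "HZ3"), ("CZ3", "CH2"), ("CH2", "HH2")],
    "ASP": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"),
            ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22")],
    "GLN": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"),
            ("CD", "OE1"), ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22")],
    "LYS": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"),
            ("CG", "CD"), ("CD", "HD2"), ("CD", "HD3"),
            ("CD", "CE"), ("CE", "HE2"), ("CE", "HE3"),
            ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "ARG": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"),
            ("CG", "CD"), ("CD", "HD2"), ("CD", "HD3"),
            ("CD", "NE"), ("NE", "HE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("NH1", "HH11"), ("NH1", "HH12"),
            ("CZ", "NH2"), ("NH2", "HH21"), ("NH2", "HH22")],
    "HIS": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "ND1"), ("ND1", "HD1"), ("CG", "CD2"), ("CD2", "HD2"),
            ("ND1", "CE1"), ("CE1", "HE1"), ("CD2", "NE2")],
    "PRO": [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"),
            ("CB", "CG"), ("CG", "HG2"), ("CG", "HG3"),
            ("CG", "CD"), ("CD", "HD2"), ("CD", "HD3"), ("CD", "N")],
}

ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def canonical_residue(name: str) -> str:
    """Map protonation variants onto the canonical three-letter name."""
    name = name.upper()
    return RESIDUE_ALIASES.get(name, name)


def element_of(atom_name: str) -> str:
    """Infer element from a PDB-style atom name (leading digits stripped)."""
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first == "M":  # virtual site of four-site water
        return "M"
    return first


def is_hydrogen(atom_name: str) -> bool:
    return element_of(atom_name) == "H"


def sidechain_atoms(resname: str) -> list[str]:
    """Sidechain atom names (CA excluded) in deterministic order."""
    seen: list[str] = []
    for a, b in SIDECHAIN_BONDS[canonical_residue(resname)]:
        for name in (a, b):
            if name not in ("CA", "N") and name not in seen:
                seen.append(name)
    return seen
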