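"""Residue-specific psi backbone-torsion force-constant refinement.

The psi dihedral of residue i is N(i)-CA(i)-C(i)-N(i+1).  Refinement
presets rewrite the force constant k of the multiplicity-1 periodic
correction term on that quadruple for chosen residue types, leaving the
phase, the multiplicity and every other dihedral untouched:

* STQ: serine, threonine and glutamine go from the base 2.0 kJ/mol to
  1.0 kJ/mol, damping an over-helical bias for these residues.
* STQ' (STQ_PRIME): same for S/T, but glutamine is set to the
  intermediate 1.5 kJ/mol, which balances helicity in polyglutamine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .residues import canonical_residue
from .topology import (
    DihedralTerm,
    ForceFieldTopology,
    Molecule,
    TopologyError,
)

__all__ = [
    "TorsionPreset",
    "PsiMatch",
    "find_psi_dihedrals",
    "set_psi_force_constant",
    "diff_torsions",
]


@dataclass(frozen=True)
class TorsionPreset:
    """Residue -> k_psi (kJ/mol) map for the multiplicity-1 psi term."""

    name: str
    k_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.k_map.values()):
            raise ValueError("k_psi values must be positive")

    @classmethod
    def base(cls) -> "TorsionPreset":
        return cls("BASE", {"SER": 2.0, "THR": 2.0, "GLN": 2.0})

    @classmethod
    def stq(cls) -> "TorsionPreset":
        return cls("STQ", {"SER": 1.0, "THR": 1.0, "GLN": 1.0})

    @classmethod
    def stq_prime(cls) -> "TorsionPreset":
        return cls("STQ_PRIME", {"SER": 1.0, "THR": 1.0, "GLN": 1.5})

    @classmethod
    def custom(cls, k_map: dict[str, float]) -> "TorsionPreset":
        return cls("custom", {canonical_residue(r): k for r, k in k_map.items()})


@dataclass
class PsiMatch:
    molecule: str
    term: DihedralTerm
    residue_index: int
    residue_name: str


def _backbone_index_map(mol: Molecule) -> dict[int, dict[str, int]]:
    """residue index -> {backbone atom name -> 1-based atom index}."""
    out: dict[int, dict[str, int]] = {}
    for atom in mol.atoms:
        if atom.atom_name.upper() in ("N", "CA", "C"):
            out.setdefault(atom.residue_index, {})[atom.atom_name.upper()] = atom.index
    return out


def find_psi_dihedrals(
    topo: ForceFieldTopology, residues: Iterable[str]
) -> list[PsiMatch]:
    """Locate psi dihedral terms for the requested residue types.

    Matching goes through atom names across consecutive residues, so it
    is independent of the ordering of terms in the file.  A residue of a
    requested type lacking backbone atoms is a hard error; C-terminal
    residues have no psi and are skipped.
    """
    wanted = {canonical_residue(r) for r in residues}
    matches: list[PsiMatch] = []
    for mol in topo.molecules.values():
        backbone = _backbone_index_map(mol)
        if not backbone:
            continue
        residue_names = {a.residue_index: a.residue_name for a in mol.atoms}
        res_indices = sorted(backbone)
        by_quad = {}
        for term in mol.dihedrals:
            key = term.atom_indices
            by_quad.setdefault(key, []).append(term)
            by_quad.setdefault(key[::-1], []).append(term)
        for ri in res_indices:
            resname = residue_names.get(ri, "")
            if canonical_residue(resname) not in wanted:
                continue
            if ri + 1 not in backbone or "N" not in backbone[ri + 1]:
                continue  # C-terminal: no psi
            bb = backbone[ri]
            missing = [n for n in ("N", "CA", "C") if n not in bb]
            if missing:
                raise TopologyError(
                    f"molecule {mol.name!r} residue {ri} ({resname}): "
                    f"missing backbone atom(s) {missing}"
                )
            quad = (bb["N"], bb["CA"], bb["C"], backbone[ri + 1]["N"])
            for term in by_quad.get(quad, []):
                matches.append(PsiMatch(mol.name, term, ri, resname))
    return matches


def set_psi_force_constant(
    topo: ForceFieldTopology, preset: TorsionPreset
) -> ForceFieldTopology:
    """Rewrite k of the n=1 psi term per the preset; idempotent.

    The phase and multiplicity are read from the base topology and
    preserved; other multiplicities on the same quadruple and all other
    dihedrals are untouched.  A matched psi quadruple without an n=1
    periodic term is a hard error: the correction term being refined
    must exist in the base files.
    """
    new = topo.copy()
    matches = find_psi_dihedrals(new, preset.k_map.keys())
    seen_quads: dict[tuple[str, int], bool] = {}
    for m in matches:
        key = (m.molecule, m.residue_index)
        if m.term.is_periodic and m.term.multiplicity == 1:
            m.term.force_constant = preset.k_map[canonical_residue(m.residue_name)]
            seen_quads[key] = True
        else:
            seen_quads.setdefault(key, False)
    bad = [k for k, ok in seen_quads.items() if not ok]
    if bad:
        raise TopologyError(
            "no multiplicity-1 periodic psi term found for residue(s): "
            + ", ".join(f"{mol} residue {ri}" for mol, ri in bad)
        )
    return new


def diff_torsions(
    topo_a: ForceFieldTopology, topo_b: ForceFieldTopology
) -> list[dict]:
    """List every dihedral whose (k, n, delta) differ between topologies.

    Topologies must be structurally identical (same molecules, same
    dihedral count and quadruples in the same order).
    """
    if set(topo_a.molecules) != set(topo_b.molecules):
        raise TopologyError("topologies have different molecule sets")
    diffs: list[dict] = []
    for name, mol_a in topo_a.molecules.items():
        mol_b = topo_b.molecules[name]
        if len(mol_a.dihedrals) != len(mol_b.dihedrals) or len(mol_a.atoms) != len(
            mol_b.atoms
        ):
            raise TopologyError(
                f"molecule {name!r}: structurally different topologies"
            )
        residue_of = {a.index: (a.residue_index, a.residue_name) for a in mol_a.atoms}
        for da, db in zip(mol_a.dihedrals, mol_b.dihedrals):
            if da.atom_indices != db.atom_indices:
                raise TopologyError(
                    f"molecule {name!r}: dihedral quadruples do not line up"
                )
            if (
                da.force_constant != db.force_constant
                or da.multiplicity != db.multiplicity
                or da.phase_deg != db.phase_deg
                or da.params != db.params
            ):
                ri, rn = residue_of.get(da.atom_indices[1], (None, "?"))
                diffs.append(
                    {
                        "molecule": name,
                        "atom_indices": da.atom_indices,
                        "residue_index": ri,
                        "residue_name": rn,
                        "k_a": da.force_constant,
                        "k_b": db.force_constant,
                        "multiplicity": da.multiplicity,
                        "phase_deg": da.phase_deg,
                    }
                )
    return diffs
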