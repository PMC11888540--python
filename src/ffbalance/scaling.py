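"""Selective protein-water Lennard-Jones scaling.

Strengthening protein-water dispersion by a uniform factor gamma on the
combined epsilon of protein-atom/water-oxygen pairs is a standard cure
for over-compact disordered ensembles.  This module implements the
selective variants of that idea: scaling only backbone heavy atoms, only
sidechain atoms (glycine excluded, since it has no sidechain), or only
sidechains of uncharged residues.  Selectivity is realized by atom-type
cloning, because the topology dialect expresses pair overrides per
type-pair: any type shared between targeted and untargeted atoms is
duplicated (identical parameters) and the targeted atoms re-typed, then
one ``[ nonbond_params ]`` override per targeted type is emitted against
the water oxygen type with epsilon = gamma * combination-rule epsilon.

Only the water oxygen carries LJ in the four-site water model this
lineage of force fields uses, so overrides against OW are sufficient.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

from .residues import (
    BACKBONE_ATOMS,
    BACKBONE_HEAVY_ATOMS,
    CAP_RESIDUES,
    CHARGED_RESIDUES,
    ION_RESIDUES,
    STANDARD_RESIDUES,
    WATER_RESIDUES,
    canonical_residue,
    is_hydrogen,
)
from .topology import (
    AtomRecord,
    AtomTypeRecord,
    ForceFieldTopology,
    Molecule,
    NonbondedOverride,
    TopologyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomClass",
    "ScalingMode",
    "ScalingScheme",
    "classify_atom",
    "select_scaling_targets",
    "combine_lj",
    "apply_water_scaling",
    "repartition_hydrogen_masses",
    "find_water_oxygen_type",
]


class AtomClass(enum.Enum):
    BACKBONE = "backbone"
    SIDECHAIN = "sidechain"
    WATER = "water"
    ION = "ion"
    OTHER = "other"


class ScalingMode(enum.Enum):
    ALL = "all"
    BACKBONE = "backbone"
    SIDECHAIN_ALL = "sidechain"
    SIDECHAIN_UNCHARGED = "sidechain-uncharged"


#: default set of ionized residues excluded by SIDECHAIN_UNCHARGED; includes
#: the doubly protonated His and deprotonated Cys/Tyr variant names
DEFAULT_CHARGED_RESIDUES = frozenset(CHARGED_RESIDUES)


@dataclass
class ScalingScheme:
    """Which atoms get scaled water interactions, and by how much.

    gamma is the multiplier on the combined LJ epsilon; 1.10 is the
    conventional "10% stronger protein-water attraction".
    """

    mode: ScalingMode = ScalingMode.ALL
    gamma: float = 1.10
    water_oxygen_type: str | None = None
    charged_residues: frozenset[str] = DEFAULT_CHARGED_RESIDUES
    clone_suffix: str = "_ws"

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = ScalingMode(self.mode)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _is_protein_residue(resname: str) -> bool:
    return canonical_residue(resname) in STANDARD_RESIDUES or resname.upper() in CAP_RESIDUES


def classify_atom(atom: AtomRecord) -> AtomClass:
    """Assign an atom to backbone/sidechain/water/ion.

    Every atom of a protein residue is backbone xor sidechain; cap
    residues (ACE/NME) count as backbone.  Unrecognized residues map to
    OTHER with a warning so they are never silently scaled.
    """
    resname = atom.residue_name.upper()
    if resname in WATER_RESIDUES:
        return AtomClass.WATER
    if resname in ION_RESIDUES:
        return AtomClass.ION
    if resname in CAP_RESIDUES:
        return AtomClass.BACKBONE
    if canonical_residue(resname) in STANDARD_RESIDUES:
        if atom.atom_name.upper() in BACKBONE_ATOMS:
            return AtomClass.BACKBONE
        return AtomClass.SIDECHAIN
    logger.warning(
        "unrecognized residue %r (atom %s): classified OTHER, never scaled",
        atom.residue_name,
        atom.atom_name,
    )
    return AtomClass.OTHER


def find_water_oxygen_type(topo: ForceFieldTopology) -> str:
    """Locate the LJ-carrying oxygen type of the water molecule."""
    for mol in topo.molecules.values():
        if not mol.atoms or not all(
            a.residue_name.upper() in WATER_RESIDUES for a in mol.atoms
        ):
            continue
        for atom in mol.atoms:
            atype = topo.atom_types[atom.type_name]
            if atype.epsilon > 0 and atom.atom_name.upper().startswith("O"):
                return atom.type_name
    raise TopologyError("no recognized water molecule with an LJ-carrying oxygen")


def select_scaling_targets(
    topo: ForceFieldTopology, scheme: ScalingScheme
) -> set[tuple[str, int]]:
    """Return the (molecule name, atom index) pairs the scheme targets.

    BACKBONE selects backbone heavy atoms only; the SIDECHAIN modes select
    all sidechain atoms, hydrogens included, excluding glycine (which has
    none) and, for SIDECHAIN_UNCHARGED, excluding ionized residues.
    """
    charged = {r.upper() for r in scheme.charged_residues}
    targets: set[tuple[str, int]] = set()
    for mol in topo.molecules.values():
        for atom in mol.atoms:
            cls = classify_atom(atom)
            if cls not in (AtomClass.BACKBONE, AtomClass.SIDECHAIN):
                continue
            if scheme.mode is ScalingMode.ALL:
                targets.add((mol.name, atom.index))
            elif scheme.mode is ScalingMode.BACKBONE:
                if cls is AtomClass.BACKBONE and not is_hydrogen(atom.atom_name):
                    targets.add((mol.name, atom.index))
            else:
                if cls is not AtomClass.SIDECHAIN:
                    continue
                if canonical_residue(atom.residue_name) == "GLY":
                    continue
                if (
                    scheme.mode is ScalingMode.SIDECHAIN_UNCHARGED
                    and atom.residue_name.upper() in charged
                ):
                    continue
                targets.add((mol.name, atom.index))
    return targets


def combine_lj(
    type_a: AtomTypeRecord, type_b: AtomTypeRecord, rule: str = "lorentz_berthelot"
) -> tuple[float, float]:
    """Combination-rule (sigma, epsilon) for an unlike pair."""
    if type_a.sigma < 0 or type_b.sigma < 0 or type_a.epsilon < 0 or type_b.epsilon < 0:
        raise ValueError("negative LJ parameters")
    eps = math.sqrt(type_a.epsilon * type_b.epsilon)
    if rule == "lorentz_berthelot":
        sigma = 0.5 * (type_a.sigma + type_b.sigma)
    elif rule == "geometric":
        sigma = math.sqrt(type_a.sigma * type_b.sigma)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return sigma, eps


def _clone_name(topo: ForceFieldTopology, base: str, suffix: str) -> str:
    name = base + suffix
    if name in topo.atom_types:
        raise TopologyError(
            f"clone name collision: atom type {name!r} already exists"
        )
    return name


def apply_water_scaling(
    topo: ForceFieldTopology,
    scheme: ScalingScheme,
    force: bool = False,
) -> ForceFieldTopology:
    """Emit gamma-scaled pair overrides against the water oxygen.

    The input topology is never modified.  In the result, every targeted
    atom interacts with the water oxygen through an override whose
    epsilon is exactly ``gamma`` times the combination-rule value;
    protein-protein, water-water and untargeted-protein-water
    interactions are bitwise unchanged (charges and masses untouched).
    """
    new = topo.copy()
    ow = scheme.water_oxygen_type or find_water_oxygen_type(new)
    if ow not in new.atom_types:
        raise TopologyError(f"water oxygen type {ow!r} not in [ atomtypes ]")
    targets = select_scaling_targets(new, scheme)
    if not targets:
        raise TopologyError(
            f"scaling scheme {scheme.mode.value!r} selects no protein atoms"
        )

    # types used by targeted vs untargeted atoms anywhere in the system
    targeted_types: set[str] = set()
    untargeted_types: set[str] = set()
    for mol in new.molecules.values():
        for atom in mol.atoms:
            if (mol.name, atom.index) in targets:
                targeted_types.add(atom.type_name)
            else:
                untargeted_types.add(atom.type_name)

    clone_of: dict[str, str] = {}
    for tname in sorted(targeted_types & untargeted_types):
        parent = new.atom_types[tname]
        cname = _clone_name(new, tname, scheme.clone_suffix)
        new.atom_types[cname] = AtomTypeRecord(
            name=cname,
            mass=parent.mass,
            charge=parent.charge,
            sigma=parent.sigma,
            epsilon=parent.epsilon,
            at_num=parent.at_num,
            ptype=parent.ptype,
        )
        clone_of[tname] = cname
        logger.info("cloned atom type %s -> %s", tname, cname)
    for mol in new.molecules.values():
        for atom in mol.atoms:
            if (mol.name, atom.index) in targets and atom.type_name in clone_of:
                atom.type_name = clone_of[atom.type_name]

    scaled_types = sorted((targeted_types - untargeted_types) | set(clone_of.values()))
    ow_rec = new.atom_types[ow]
    for tname in scaled_types:
        sigma, eps = combine_lj(new.atom_types[tname], ow_rec, new.combination_rule)
        existing = new.lookup_override(tname, ow)
        if existing is not None:
            if not force:
                raise TopologyError(
                    f"pre-existing override on ({tname}, {ow}); pass force=True to replace"
                )
            logger.warning("replacing pre-existing override on (%s, %s)", tname, ow)
        new.add_override(
            NonbondedOverride(
                type_a=tname, type_b=ow, sigma=sigma, epsilon=scheme.gamma * eps
            ),
            replace=True,
        )
        logger.info(
            "override %s-%s: sigma=%.6g nm epsilon=%.6g kJ/mol (gamma=%.4g)",
            tname, ow, sigma, scheme.gamma * eps, scheme.gamma,
        )
    return new


# ---------------------------------------------------------------------------
# hydrogen mass repartitioning

def _bond_partners(mol: Molecule) -> dict[int, list[int]]:
    partners: dict[int, list[int]] = {}
    for bond in mol.bonds:
        i, j = bond.atom_indices
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)
    return partners


def repartition_hydrogen_masses(
    topo: ForceFieldTopology, h_mass: float = 1.5
) -> ForceFieldTopology:
    """Set every protein hydrogen's mass to ``h_mass`` (amu).

    The mass difference is taken from the hydrogen's unique bonded heavy
    atom, so each molecule's total mass is conserved exactly.  Water and
    ions are untouched.
    """
    if h_mass <= 0:
        raise ValueError("h_mass must be positive")
    new = topo.copy()
    for mol in new.molecules.values():
        if not any(_is_protein_residue(a.residue_name) for a in mol.atoms):
            continue
        partners = _bond_partners(mol)
        by_index = {a.index: a for a in mol.atoms}
        for atom in mol.atoms:
            if not is_hydrogen(atom.atom_name):
                continue
            heavy = [
                j for j in partners.get(atom.index, ())
                if not is_hydrogen(by_index[j].atom_name)
            ]
            if len(heavy) != 1:
                raise TopologyError(
                    f"molecule {mol.name!r}: hydrogen {atom.atom_name} "
                    f"(index {atom.index}) bonded to {len(heavy)} heavy atoms"
                )
            delta = h_mass - atom.mass
            heavy_atom = by_index[heavy[0]]
            if heavy_atom.mass - delta <= 0:
                raise TopologyError(
                    f"molecule {mol.name!r}: repartitioning would drive "
                    f"{heavy_atom.atom_name} (index {heavy_atom.index}) to "
                    f"non-positive mass"
                )
            atom.mass = h_mass
            heavy_atom.mass -= delta
    return new
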