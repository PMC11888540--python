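"""Data model and reader/writer for the GROMACS topology dialect.

Covers the subset of the dialect that force-field refinement workflows
touch: ``[ defaults ]``, ``[ atomtypes ]``, ``[ nonbond_params ]``,
``[ moleculetype ]`` with ``[ atoms ]``, ``[ bonds ]``, ``[ pairs ]``,
``[ angles ]`` and ``[ dihedrals ]``, plus ``[ system ]`` and
``[ molecules ]``.  Any other section (settles, exclusions, virtual
sites, position restraints, dihedraltypes, ...) is preserved verbatim
and re-emitted on write, so a parse -> transform -> write cycle never
drops information it does not understand.

All indices are kept 1-based, as in the dialect itself.
"""

from __future__ import annotations

import copy
import math
import os
from dataclasses import dataclass, field

__all__ = [
    "AtomTypeRecord",
    "AtomRecord",
    "BondedTerm",
    "DihedralTerm",
    "NonbondedOverride",
    "Molecule",
    "ForceFieldTopology",
    "TopologyError",
    "Violation",
    "parse_topology",
    "parse_topology_file",
    "write_topology",
    "write_topology_file",
    "validate_topology",
]

#: sections parsed into the structured model; everything else passes through
_MOLECULE_PARSED = {"atoms", "bonds", "pairs", "angles", "dihedrals"}

# funct codes whose dihedral parameters are (phase, k, multiplicity)
_PERIODIC_DIHEDRAL_FUNCTS = {1, 4, 9}


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


@dataclass
class AtomTypeRecord:
    """One ``[ atomtypes ]`` entry: LJ well depth/size and default mass/charge."""

    name: str
    mass: float
    charge: float
    sigma: float  # nm
    epsilon: float  # kJ/mol
    at_num: int | None = None
    ptype: str = "A"

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise TopologyError(f"atom type {self.name!r}: negative mass")
        if self.sigma < 0 or self.epsilon < 0:
            raise TopologyError(f"atom type {self.name!r}: negative LJ parameter")


@dataclass
class AtomRecord:
    """One ``[ atoms ]`` entry of a molecule (1-based ``index``)."""

    index: int
    type_name: str
    residue_index: int
    residue_name: str
    atom_name: str
    charge: float
    mass: float
    charge_group: int = 0


@dataclass
class BondedTerm:
    """Bond/pair/angle entry: atom indices, funct code, raw trailing params."""

    atom_indices: tuple[int, ...]
    funct: int
    params: tuple[float, ...] = ()


@dataclass
class DihedralTerm:
    """A ``[ dihedrals ]`` entry.

    For periodic functs (1, 4, 9) the proper-torsion energy is
    ``k * (1 + cos(n*phi - delta))`` with ``phase_deg`` = delta and
    ``multiplicity`` = n.  Other functs keep their parameters in
    ``params`` untouched.
    """

    atom_indices: tuple[int, int, int, int]
    funct: int
    phase_deg: float | None = None
    force_constant: float | None = None
    multiplicity: int | None = None
    params: tuple[float, ...] = ()

    @property
    def is_periodic(self) -> bool:
        return self.funct in _PERIODIC_DIHEDRAL_FUNCTS and self.force_constant is not None


@dataclass
class NonbondedOverride:
    """A ``[ nonbond_params ]`` pair override; the (a, b) key is unordered."""

    type_a: str
    type_b: str
    sigma: float
    epsilon: float
    funct: int = 1

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.type_a, self.type_b))


@dataclass
class Molecule:
    """A ``[ moleculetype ]`` block with its bonded-term tables.

    ``extra_sections`` preserves unparsed per-molecule sections (settles,
    exclusions, virtual sites, ...) in file order as raw lines.
    """

    name: str
    nrexcl: int = 3
    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[BondedTerm] = field(default_factory=list)
    pairs: list[BondedTerm] = field(default_factory=list)
    angles: list[BondedTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    extra_sections: list[tuple[str, list[str]]] = field(default_factory=list)

    def atom_by_index(self, index: int) -> AtomRecord:
        atom = self.atoms[index - 1]
        if atom.index != index:  # sparse/reordered files
            for a in self.atoms:
                if a.index == index:
                    return a
            raise TopologyError(f"molecule {self.name!r}: no atom with index {index}")
        return atom

    def total_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def total_mass(self) -> float:
        return sum(a.mass for a in self.atoms)


@dataclass
class ForceFieldTopology:
    """Full parsed topology: types, pair overrides, molecules, system."""

    atom_types: dict[str, AtomTypeRecord] = field(default_factory=dict)
    overrides: dict[frozenset[str], NonbondedOverride] = field(default_factory=dict)
    molecules: dict[str, Molecule] = field(default_factory=dict)
    nbfunc: int = 1
    comb_rule: int = 2
    gen_pairs: str = "no"
    fudge_lj: float = 1.0
    fudge_qq: float = 1.0
    system_name: str = ""
    molecule_counts: list[tuple[str, int]] = field(default_factory=list)
    header_sections: list[tuple[str, list[str]]] = field(default_factory=list)
    water_model_tag: str = ""

    @property
    def combination_rule(self) -> str:
        """'lorentz_berthelot' (comb-rule 2) or 'geometric' (comb-rule 1/3)."""
        return "lorentz_berthelot" if self.comb_rule == 2 else "geometric"

    def lookup_override(self, a: str, b: str) -> NonbondedOverride | None:
        return self.overrides.get(frozenset((a, b)))

    def add_override(self, ov: NonbondedOverride, replace: bool = False) -> None:
        if ov.key in self.overrides and not replace:
            raise TopologyError(
                f"duplicate nonbonded override for pair ({ov.type_a}, {ov.type_b})"
            )
        self.overrides[ov.key] = ov

    def copy(self) -> "ForceFieldTopology":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parsing

def _strip(line: str) -> str:
    return line.split(";", 1)[0].strip()


def _logical_lines(text: str, include_dir: str | None) -> list[str]:
    """Expand #include by literal inlining; drop comments and blanks."""
    out: list[str] = []
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("#include"):
            target = stripped.split(None, 1)[1].strip().strip('"<>')
            path = os.path.join(include_dir, target) if include_dir else target
            if not os.path.exists(path):
                raise TopologyError(f"#include file not found: {target}")
            with open(path) as fh:
                out.extend(_logical_lines(fh.read(), os.path.dirname(path)))
            continue
        if stripped.startswith("#"):  # other preprocessor lines dropped
            continue
        line = _strip(raw)
        if line:
            out.append(line)
    return out


def _parse_atomtype(tokens: list[str]) -> AtomTypeRecord:
    # Dialect variants:
    #   name                mass charge ptype sigma eps      (6 tokens)
    #   name at.num         mass charge ptype sigma eps      (7 tokens)
    #   name btype at.num   mass charge ptype sigma eps      (8 tokens)
    ptype_pos = next(
        (i for i, t in enumerate(tokens) if t in ("A", "S", "V", "D")), None
    )
    if ptype_pos is None or ptype_pos < 3 or len(tokens) < ptype_pos + 3:
        raise TopologyError(f"unparseable atomtypes line: {' '.join(tokens)}")
    name = tokens[0]
    at_num = None
    for tok in tokens[1 : ptype_pos - 2]:
        try:
            at_num = int(tok)
        except ValueError:
            pass
    return AtomTypeRecord(
        name=name,
        at_num=at_num,
        mass=float(tokens[ptype_pos - 2]),
        charge=float(tokens[ptype_pos - 1]),
        ptype=tokens[ptype_pos],
        sigma=float(tokens[ptype_pos + 1]),
        epsilon=float(tokens[ptype_pos + 2]),
    )


def parse_topology(text: str, include_dir: str | None = None) -> ForceFieldTopology:
    """Parse a topology stream into a :class:`ForceFieldTopology`.

    Raises :class:`TopologyError` on unresolved atom types or duplicate
    nonbonded override pairs.
    """
    topo = ForceFieldTopology()
    lines = _logical_lines(text, include_dir)

    section = None
    current_mol: Molecule | None = None
    current_extra: list[str] | None = None

    for line in lines:
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            current_extra = None
            if section in ("defaults", "atomtypes", "nonbond_params", "system",
                           "molecules"):
                current_mol = None  # top-level sections end any molecule block
            elif section == "moleculetype":
                current_mol = None  # name arrives on the next line
            elif current_mol is not None and section not in _MOLECULE_PARSED:
                current_extra = []
                current_mol.extra_sections.append((section, current_extra))
            elif current_mol is None and section not in (
                "defaults",
                "atomtypes",
                "nonbond_params",
                "system",
                "molecules",
            ):
                current_extra = []
                topo.header_sections.append((section, current_extra))
            continue

        tokens = line.split()
        if section == "defaults":
            topo.nbfunc = int(tokens[0])
            topo.comb_rule = int(tokens[1])
            if len(tokens) > 2:
                topo.gen_pairs = tokens[2]
            if len(tokens) > 3:
                topo.fudge_lj = float(tokens[3])
            if len(tokens) > 4:
                topo.fudge_qq = float(tokens[4])
        elif section == "atomtypes":
            rec = _parse_atomtype(tokens)
            topo.atom_types[rec.name] = rec
        elif section == "nonbond_params":
            ov = NonbondedOverride(
                type_a=tokens[0],
                type_b=tokens[1],
                funct=int(tokens[2]),
                sigma=float(tokens[3]),
                epsilon=float(tokens[4]),
            )
            topo.add_override(ov)
        elif section == "moleculetype":
            current_mol = Molecule(name=tokens[0], nrexcl=int(tokens[1]))
            topo.molecules[current_mol.name] = current_mol
        elif section == "atoms" and current_mol is not None:
            type_name = tokens[1]
            atype = topo.atom_types.get(type_name)
            charge = float(tokens[6]) if len(tokens) > 6 else (
                atype.charge if atype else 0.0
            )
            mass = float(tokens[7]) if len(tokens) > 7 else (
                atype.mass if atype else 0.0
            )
            current_mol.atoms.append(
                AtomRecord(
                    index=int(tokens[0]),
                    type_name=type_name,
                    residue_index=int(tokens[2]),
                    residue_name=tokens[3],
                    atom_name=tokens[4],
                    charge_group=int(tokens[5]),
                    charge=charge,
                    mass=mass,
                )
            )
        elif section == "bonds" and current_mol is not None:
            current_mol.bonds.append(
                BondedTerm(
                    atom_indices=(int(tokens[0]), int(tokens[1])),
                    funct=int(tokens[2]) if len(tokens) > 2 else 1,
                    params=tuple(float(t) for t in tokens[3:]),
                )
            )
        elif section == "pairs" and current_mol is not None:
            current_mol.pairs.append(
                BondedTerm(
                    atom_indices=(int(tokens[0]), int(tokens[1])),
                    funct=int(tokens[2]) if len(tokens) > 2 else 1,
                    params=tuple(float(t) for t in tokens[3:]),
                )
            )
        elif section == "angles" and current_mol is not None:
            current_mol.angles.append(
                BondedTerm(
                    atom_indices=tuple(int(t) for t in tokens[:3]),
                    funct=int(tokens[3]) if len(tokens) > 3 else 1,
                    params=tuple(float(t) for t in tokens[4:]),
                )
            )
        elif section == "dihedrals" and current_mol is not None:
            idx = tuple(int(t) for t in tokens[:4])
            funct = int(tokens[4]) if len(tokens) > 4 else 9
            params = tuple(float(t) for t in tokens[5:])
            if funct in _PERIODIC_DIHEDRAL_FUNCTS and len(params) >= 3:
                term = DihedralTerm(
                    atom_indices=idx,
                    funct=funct,
                    phase_deg=params[0],
                    force_constant=params[1],
                    multiplicity=int(round(params[2])),
                )
                if term.multiplicity < 1:
                    raise TopologyError(
                        f"dihedral {idx}: multiplicity must be >= 1"
                    )
            else:
                term = DihedralTerm(atom_indices=idx, funct=funct, params=params)
            current_mol.dihedrals.append(term)
        elif section == "system":
            topo.system_name = line
        elif section == "molecules":
            topo.molecule_counts.append((tokens[0], int(tokens[1])))
        elif current_extra is not None:
            current_extra.append(line)

    if not topo.atom_types:
        raise TopologyError("no [ atomtypes ] section found")
    if not topo.molecules:
        raise TopologyError("no [ moleculetype ] block found")

    for mol in topo.molecules.values():
        for atom in mol.atoms:
            if atom.type_name not in topo.atom_types:
                raise TopologyError(
                    f"molecule {mol.name!r} atom {atom.index} ({atom.atom_name}) "
                    f"references unknown atom type {atom.type_name!r}"
                )
    return topo


def parse_topology_file(path: str | os.PathLike) -> ForceFieldTopology:
    path = os.fspath(path)
    with open(path) as fh:
        return parse_topology(fh.read(), include_dir=os.path.dirname(path))


# ---------------------------------------------------------------------------
# writing

def _fmt(x: float) -> str:
    """Floats with 12 significant digits: compact, round-trips losslessly
    at the model's comparison tolerance."""
    return f"{x:.12g}"


def write_topology(topo: ForceFieldTopology) -> str:
    """Serialize to the dialect; parse(write(t)) is semantically identical."""
    out: list[str] = []
    out.append("[ defaults ]")
    out.append(
        f"{topo.nbfunc} {topo.comb_rule} {topo.gen_pairs} "
        f"{_fmt(topo.fudge_lj)} {_fmt(topo.fudge_qq)}"
    )
    out.append("")
    out.append("[ atomtypes ]")
    for rec in topo.atom_types.values():
        at_num = "" if rec.at_num is None else f" {rec.at_num}"
        out.append(
            f"{rec.name}{at_num} {_fmt(rec.mass)} {_fmt(rec.charge)} "
            f"{rec.ptype} {_fmt(rec.sigma)} {_fmt(rec.epsilon)}"
        )
    out.append("")
    if topo.overrides:
        out.append("[ nonbond_params ]")
        for ov in topo.overrides.values():
            out.append(
                f"{ov.type_a} {ov.type_b} {ov.funct} {_fmt(ov.sigma)} {_fmt(ov.epsilon)}"
            )
        out.append("")
    for name, raw in topo.header_sections:
        out.append(f"[ {name} ]")
        out.extend(raw)
        out.append("")
    for mol in topo.molecules.values():
        out.append("[ moleculetype ]")
        out.append(f"{mol.name} {mol.nrexcl}")
        out.append("")
        out.append("[ atoms ]")
        for a in mol.atoms:
            out.append(
                f"{a.index} {a.type_name} {a.residue_index} {a.residue_name} "
                f"{a.atom_name} {a.charge_group} {_fmt(a.charge)} {_fmt(a.mass)}"
            )
        out.append("")
        for label, terms in (
            ("bonds", mol.bonds),
            ("pairs", mol.pairs),
            ("angles", mol.angles),
        ):
            if terms:
                out.append(f"[ {label} ]")
                for t in terms:
                    idx = " ".join(str(i) for i in t.atom_indices)
                    par = " ".join(_fmt(p) for p in t.params)
                    out.append(f"{idx} {t.funct} {par}".rstrip())
                out.append("")
        if mol.dihedrals:
            out.append("[ dihedrals ]")
            for d in mol.dihedrals:
                idx = " ".join(str(i) for i in d.atom_indices)
                if d.is_periodic:
                    out.append(
                        f"{idx} {d.funct} {_fmt(d.phase_deg)} "
                        f"{_fmt(d.force_constant)} {d.multiplicity}"
                    )
                else:
                    par = " ".join(_fmt(p) for p in d.params)
                    out.append(f"{idx} {d.funct} {par}".rstrip())
            out.append("")
        for name, raw in mol.extra_sections:
            out.append(f"[ {name} ]")
            out.extend(raw)
            out.append("")
    if topo.system_name:
        out.append("[ system ]")
        out.append(topo.system_name)
        out.append("")
    if topo.molecule_counts:
        out.append("[ molecules ]")
        for name, count in topo.molecule_counts:
            out.append(f"{name} {count}")
        out.append("")
    return "\n".join(out)


def write_topology_file(topo: ForceFieldTopology, path: str | os.PathLike) -> None:
    """Atomic write: temp file in the target directory, then rename."""
    path = os.fspath(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(write_topology(topo))
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# validation

@dataclass
class Violation:
    record: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.record}: [{self.rule}] {self.message}"


def validate_topology(topo: ForceFieldTopology) -> list[Violation]:
    """Check model invariants; empty list means the topology is consistent."""
    report: list[Violation] = []
    for name, rec in topo.atom_types.items():
        if rec.mass < 0 or rec.sigma < 0 or rec.epsilon < 0:
            report.append(
                Violation(f"atomtype {name}", "nonnegative", "mass/sigma/epsilon < 0")
            )
    for ov in topo.overrides.values():
        for t in (ov.type_a, ov.type_b):
            if t not in topo.atom_types:
                report.append(
                    Violation(
                        f"nonbond_params ({ov.type_a},{ov.type_b})",
                        "resolvable-types",
                        f"unknown atom type {t!r}",
                    )
                )
    for mol in topo.molecules.values():
        seen: set[int] = set()
        for atom in mol.atoms:
            if atom.index in seen:
                report.append(
                    Violation(
                        f"{mol.name}/atom {atom.index}",
                        "unique-index",
                        "duplicate atom index",
                    )
                )
            seen.add(atom.index)
            if atom.type_name not in topo.atom_types:
                report.append(
                    Violation(
                        f"{mol.name}/atom {atom.index} ({atom.atom_name})",
                        "resolvable-type",
                        f"unknown atom type {atom.type_name!r}",
                    )
                )
        q = mol.total_charge()
        if abs(q - round(q)) > 1e-6:
            report.append(
                Violation(
                    f"molecule {mol.name}",
                    "integer-charge",
                    f"net charge {q:.6f} e is not integral",
                )
            )
        n_atoms = len(mol.atoms)
        for kind, terms in (
            ("bond", mol.bonds),
            ("pair", mol.pairs),
            ("angle", mol.angles),
            ("dihedral", mol.dihedrals),
        ):
            for t in terms:
                for i in t.atom_indices:
                    if not 1 <= i <= n_atoms:
                        report.append(
                            Violation(
                                f"{mol.name}/{kind} {t.atom_indices}",
                                "index-range",
                                f"atom index {i} out of range",
                            )
                        )
    for name, count in topo.molecule_counts:
        if name not in topo.molecules:
            report.append(
                Violation(
                    f"molecules entry {name}",
                    "declared-molecule",
                    "no matching [ moleculetype ]",
                )
            )
        if count < 0:
            report.append(
                Violation(f"molecules entry {name}", "count", "negative count")
            )
    return report


def topologies_semantically_equal(
    a: ForceFieldTopology, b: ForceFieldTopology, rtol: float = 1e-9
) -> bool:
    """True when two topologies carry the same records with equal values."""

    def close(x: float | None, y: float | None) -> bool:
        if x is None or y is None:
            return x is y
        return math.isclose(x, y, rel_tol=rtol, abs_tol=1e-12)

    if set(a.atom_types) != set(b.atom_types):
        return False
    for name, ra in a.atom_types.items():
        rb = b.atom_types[name]
        if not all(
            close(getattr(ra, f), getattr(rb, f))
            for f in ("mass", "charge", "sigma", "epsilon")
        ):
            return False
    if set(a.overrides) != set(b.overrides):
        return False
    for key, ova in a.overrides.items():
        ovb = b.overrides[key]
        if not (close(ova.sigma, ovb.sigma) and close(ova.epsilon, ovb.epsilon)):
            return False
    if set(a.molecules) != set(b.molecules):
        return False
    for name, ma in a.molecules.items():
        mb = b.molecules[name]
        if len(ma.atoms) != len(mb.atoms) or len(ma.dihedrals) != len(mb.dihedrals):
            return False
        for aa, ab in zip(ma.atoms, mb.atoms):
            if (aa.index, aa.type_name, aa.atom_name, aa.residue_name) != (
                ab.index,
                ab.type_name,
                ab.atom_name,
                ab.residue_name,
            ):
                return False
            if not (close(aa.charge, ab.charge) and close(aa.mass, ab.mass)):
                return False
        for da, db in zip(ma.dihedrals, mb.dihedrals):
            if da.atom_indices != db.atom_indices or da.funct != db.funct:
                return False
            if not (
                close(da.phase_deg, db.phase_deg)
                and close(da.force_constant, db.force_constant)
                and da.multiplicity == db.multiplicity
            ):
                return False
    return a.molecule_counts == b.molecule_counts
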