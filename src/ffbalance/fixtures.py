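"""Synthetic generators: toy topologies, ideal geometries, stochastic
trajectories.

These make every transformation and observable testable offline.  Toy
topologies use *generic* per-element parameters, not real force-field
values: tests assert relations (ratios, deltas, conservation), never
absolute energies.  Published topology files remain fully supported
inputs to every transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .residues import (
    ELEMENT_MASS,
    FORMAL_CHARGE,
    ONE_TO_THREE,
    SIDECHAIN_BONDS,
    element_of,
)
from .topology import (
    AtomRecord,
    AtomTypeRecord,
    BondedTerm,
    DihedralTerm,
    ForceFieldTopology,
    Molecule,
)
from .observables import Trajectory

__all__ = [
    "FixtureSpec",
    "make_toy_topology",
    "ideal_helix_coords",
    "extended_coords",
    "gaussian_chain",
    "rigid_tumbling_trajectory",
    "tumbling_vectors",
    "wobble_vectors",
    "cone_s2",
]


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    sequence: str
    seed: int = 0
    noise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letter(s): {bad}")


# ---------------------------------------------------------------------------
# toy topology

_GENERIC_TYPES = {
    # name: (mass, sigma nm, epsilon kJ/mol)
    "Cg": ("C", 0.340, 0.360),
    "Ng": ("N", 0.325, 0.711),
    "Og": ("O", 0.296, 0.880),
    "Sg": ("S", 0.356, 1.046),
    "Hg": ("H", 0.107, 0.0657),
}
_BASE_CHARGE = {"C": 0.10, "N": -0.40, "O": -0.50, "S": -0.20, "H": 0.15}
_TYPE_OF_ELEMENT = {el: name for name, (el, _, _) in _GENERIC_TYPES.items()}

#: the psi correction term every residue of the toy base force field carries
BASE_K_PSI = 2.0  # kJ/mol


def _water_molecule() -> Molecule:
    mol = Molecule(name="SOL", nrexcl=2)
    entries = [
        ("OW", "OWt", 15.999, 0.0),
        ("HW1", "HWt", 1.008, 0.5564),
        ("HW2", "HWt", 1.008, 0.5564),
        ("MW", "MWt", 0.0, -1.1128),
    ]
    for i, (name, typ, mass, q) in enumerate(entries, start=1):
        mol.atoms.append(
            AtomRecord(
                index=i, type_name=typ, residue_index=1, residue_name="SOL",
                atom_name=name, charge=q, mass=mass, charge_group=1,
            )
        )
    # rigid four-site geometry and its virtual site are pass-through lines
    mol.extra_sections.append(("settles", ["1 1 0.09572 0.15139"]))
    mol.extra_sections.append(
        ("virtual_sites3", ["4 1 2 3 1 0.128012065 0.128012065"])
    )
    mol.extra_sections.append(
        ("exclusions", ["1 2 3 4", "2 1 3 4", "3 1 2 4", "4 1 2 3"])
    )
    return mol


def make_toy_topology(sequence: str, n_water: int = 1) -> ForceFieldTopology:
    """Reduced but chemically plausible topology for a peptide sequence.

    Every residue carries full PDB-v3 atom naming (hydrogens included),
    per-element generic LJ types, residue charges summing to the formal
    charge, a multiplicity-1 psi correction term at the base k = 2.0
    kJ/mol plus an untouched multiplicity-3 psi term and phi terms, and
    a four-site water moleculetype whose LJ lives on the oxygen only.
    """
    spec = FixtureSpec(sequence)
    topo = ForceFieldTopology(
        nbfunc=1, comb_rule=2, gen_pairs="yes", fudge_lj=0.5, fudge_qq=0.8333,
        system_name=f"toy peptide {sequence}",
        water_model_tag="tip4p-like",
    )
    for name, (el, sigma, eps) in _GENERIC_TYPES.items():
        topo.atom_types[name] = AtomTypeRecord(
            name=name, mass=ELEMENT_MASS[el], charge=0.0, sigma=sigma, epsilon=eps
        )
    topo.atom_types["OWt"] = AtomTypeRecord("OWt", 15.999, 0.0, 0.31644, 0.7749)
    topo.atom_types["HWt"] = AtomTypeRecord("HWt", 1.008, 0.0, 0.0, 0.0)
    topo.atom_types["MWt"] = AtomTypeRecord("MWt", 0.0, 0.0, 0.0, 0.0)

    mol = Molecule(name="Protein", nrexcl=3)
    index = 0
    #: residue index -> {atom name -> atom index}
    name_to_index: list[dict[str, int]] = []
    for ri, letter in enumerate(spec.sequence, start=1):
        resname = ONE_TO_THREE[letter]
        atoms: list[str] = ["N"]
        if resname != "PRO":
            atoms.append("H")
        atoms.append("CA")
        atoms.extend(["HA2", "HA3"] if resname == "GLY" else ["HA"])
        for a, b in SIDECHAIN_BONDS[resname]:
            for nm in (a, b):
                if nm not in atoms:
                    atoms.append(nm)
        atoms.extend(["C", "O"])
        local: dict[str, int] = {}
        charges = {}
        for nm in atoms:
            el = element_of(nm)
            charges[nm] = _BASE_CHARGE[el]
        correction = (FORMAL_CHARGE.get(resname, 0) - sum(charges.values())) / len(atoms)
        for nm in atoms:
            index += 1
            local[nm] = index
            el = element_of(nm)
            mol.atoms.append(
                AtomRecord(
                    index=index,
                    type_name=_TYPE_OF_ELEMENT[el],
                    residue_index=ri,
                    residue_name=resname,
                    atom_name=nm,
                    charge=charges[nm] + correction,
                    mass=ELEMENT_MASS[el],
                    charge_group=ri,
                )
            )
        name_to_index.append(local)

    # bonds: backbone, sidechain, inter-residue peptide bond
    def add_bond(i: int, j: int, x_h: bool) -> None:
        b0, k = (0.109, 310000.0) if x_h else (0.147, 250000.0)
        mol.bonds.append(BondedTerm(atom_indices=(i, j), funct=1, params=(b0, k)))

    for ri, local in enumerate(name_to_index):
        resname = ONE_TO_THREE[spec.sequence[ri]]
        if "H" in local:
            add_bond(local["N"], local["H"], True)
        add_bond(local["N"], local["CA"], False)
        for ha in ("HA", "HA2", "HA3"):
            if ha in local:
                add_bond(local["CA"], local[ha], True)
        add_bond(local["CA"], local["C"], False)
        add_bond(local["C"], local["O"], False)
        for a, b in SIDECHAIN_BONDS[resname]:
            i, j = local[a], local[b]
            add_bond(i, j, element_of(a) == "H" or element_of(b) == "H")
        if ri + 1 < len(name_to_index):
            add_bond(local["C"], name_to_index[ri + 1]["N"], False)

    # angle terms on every bonded triple (generic parameters)
    adjacency: dict[int, set[int]] = {}
    for bond in mol.bonds:
        i, j = bond.atom_indices
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)
    for j in sorted(adjacency):
        nbrs = sorted(adjacency[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                mol.angles.append(
                    BondedTerm(
                        atom_indices=(nbrs[a], j, nbrs[b]),
                        funct=1,
                        params=(109.5, 300.0),
                    )
                )

    # 1-4 pairs (graph distance exactly 3)
    n_atoms = len(mol.atoms)
    dist = {i: {i: 0} for i in range(1, n_atoms + 1)}
    for start in range(1, n_atoms + 1):
        frontier = {start}
        for d in range(1, 4):
            frontier = {
                k for f in frontier for k in adjacency.get(f, ())
            } - set(dist[start])
            for k in frontier:
                dist[start][k] = d
    for i in range(1, n_atoms + 1):
        for j, d in sorted(dist[i].items()):
            if d == 3 and i < j:
                mol.pairs.append(BondedTerm(atom_indices=(i, j), funct=1))

    # torsions: psi (n=1 correction + n=3 background) and phi terms
    for ri, local in enumerate(name_to_index):
        if ri + 1 < len(name_to_index):
            quad = (
                local["N"], local["CA"], local["C"], name_to_index[ri + 1]["N"]
            )
            mol.dihedrals.append(
                DihedralTerm(atom_indices=quad, funct=1, phase_deg=0.0,
                             force_constant=BASE_K_PSI, multiplicity=1)
            )
            mol.dihedrals.append(
                DihedralTerm(atom_indices=quad, funct=1, phase_deg=180.0,
                             force_constant=0.4, multiplicity=3)
            )
        if ri > 0:
            prev = name_to_index[ri - 1]
            mol.dihedrals.append(
                DihedralTerm(
                    atom_indices=(prev["C"], local["N"], local["CA"], local["C"]),
                    funct=1, phase_deg=180.0, force_constant=1.2, multiplicity=2,
                )
            )

    topo.molecules["Protein"] = mol
    topo.molecules["SOL"] = _water_molecule()
    topo.molecule_counts = [("Protein", 1), ("SOL", n_water)]
    return topo


def random_configuration(
    topo: ForceFieldTopology, seed: int = 0, spread: float = 2.0, min_sep: float = 0.12
) -> np.ndarray:
    """Deterministic random coordinates (nm) for a topology's expanded
    system, with a minimum pair separation enforced by resampling."""
    from .energy import _expanded_instances

    rng = np.random.default_rng(seed)
    n = sum(len(m.atoms) for m in _expanded_instances(topo))
    coords = np.zeros((n, 3))
    placed = 0
    while placed < n:
        cand = rng.uniform(0, spread, size=3)
        if placed == 0 or np.min(
            np.linalg.norm(coords[:placed] - cand, axis=1)
        ) >= min_sep:
            coords[placed] = cand
            placed += 1
    return coords


# ---------------------------------------------------------------------------
# ideal backbone geometries

_BOND = {"N-CA": 0.1458, "CA-C": 0.1525, "C-N": 0.1329, "C-O": 0.1229}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.9, "CA-C-O": 120.8}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d relative to a-b-c."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_chain(n_res: int, phi: float, psi: float, omega: float = 180.0,
                    sequence: str | None = None) -> Trajectory:
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    pos: list[np.ndarray] = []
    names: list[str] = []
    res_idx: list[int] = []
    n_prev = np.array([0.0, 0.0, 0.0])
    ca_prev = n_prev + np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    c_prev = ca_prev + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(n_prev, ca_prev, c_prev)]
    for _ in range(1, n_res):
        n_i = _place(n_prev, ca_prev, c_prev, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_i = _place(ca_prev, c_prev, n_i, _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        c_i = _place(c_prev, n_i, ca_i, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        backbone.append((n_i, ca_i, c_i))
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
    for ri, (n_i, ca_i, c_i) in enumerate(backbone, start=1):
        o_i = _place(n_i, ca_i, c_i, _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        pos.extend([n_i, ca_i, c_i, o_i])
        names.extend(["N", "CA", "C", "O"])
        res_idx.extend([ri] * 4)
    res_names = [
        ONE_TO_THREE[sequence[r - 1]] if sequence else "ALA" for r in res_idx
    ]
    return Trajectory(
        coords=np.array(pos)[None],
        atom_names=names,
        residue_indices=np.array(res_idx),
        residue_names=res_names,
    )


def ideal_helix_coords(n_res: int, sequence: str | None = None) -> Trajectory:
    """Backbone N/CA/C/O of an ideal alpha-helix (phi=-57, psi=-47)."""
    return _backbone_chain(n_res, phi=-57.0, psi=-47.0, sequence=sequence)


def extended_coords(n_res: int, sequence: str | None = None) -> Trajectory:
    """Fully extended backbone (phi=psi=180)."""
    return _backbone_chain(n_res, phi=180.0, psi=180.0, sequence=sequence)


# ---------------------------------------------------------------------------
# stochastic ensembles

def gaussian_chain(
    n_beads: int, bond_length: float, n_chains: int = 1, seed: int = 0
) -> np.ndarray:
    """Freely jointed chains, (n_chains, n_beads, 3); asymptotically
    <R_g^2> = n * b^2 / 6."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_chains, n_beads - 1, 3))
    norms = np.linalg.norm(steps, axis=2, keepdims=True)
    steps = np.where(norms > 0, steps / norms, steps) * bond_length
    coords = np.zeros((n_chains, n_beads, 3))
    coords[:, 1:] = np.cumsum(steps, axis=1)
    return coords


def _random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat)


def rigid_tumbling_trajectory(
    frame: Trajectory | np.ndarray, n_frames: int, seed: int = 0
) -> Trajectory:
    """Apply uniform (Haar) random global rotations to one frame."""
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    rng = np.random.default_rng(seed)
    if isinstance(frame, Trajectory):
        base = frame.coords[0]
        meta = frame
    else:
        base = np.asarray(frame, dtype=float)
        meta = None
    center = base.mean(axis=0)
    rots = _random_rotations(n_frames, rng)
    frames = np.stack([r.apply(base - center) for r in rots])
    if meta is not None:
        return Trajectory(
            coords=frames,
            atom_names=meta.atom_names,
            residue_indices=meta.residue_indices,
            residue_names=meta.residue_names,
            masses=meta.masses,
        )
    n = base.shape[0]
    return Trajectory(
        coords=frames,
        atom_names=[f"X{i}" for i in range(1, n + 1)],
        residue_indices=np.arange(1, n + 1),
        residue_names=["UNK"] * n,
    )


def tumbling_vectors(
    base_vectors: np.ndarray, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Rigid-body unit-vector series: fixed internal geometry under
    global tumbling; (n_frames, M, 3)."""
    rng = np.random.default_rng(seed)
    base = np.asarray(base_vectors, dtype=float)
    base = base / np.linalg.norm(base, axis=1, keepdims=True)
    rots = _random_rotations(n_frames, rng)
    return np.stack([r.apply(base) for r in rots])


def wobble_vectors(
    mean_vectors: np.ndarray,
    cone_semiangle_deg: float,
    n_frames: int,
    seed: int = 0,
) -> np.ndarray:
    """Diffusion-in-a-cone vector series under global tumbling.

    Each residue's vector is drawn uniformly within a cone of the given
    semi-angle about its mean direction (the equilibrium distribution of
    cone diffusion), independently per frame, then a global random
    rotation is applied.  At theta = 0 this reduces to rigid tumbling.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean_vectors, dtype=float)
    mean = mean / np.linalg.norm(mean, axis=1, keepdims=True)
    m = mean.shape[0]
    cos_t = np.cos(np.deg2rad(cone_semiangle_deg))
    # orthonormal frames around each mean vector
    helper = np.where(np.abs(mean[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(mean, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mean, e1)
    cos_b = 1.0 - rng.uniform(size=(n_frames, m)) * (1.0 - cos_t)
    sin_b = np.sqrt(1.0 - cos_b**2)
    az = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, m))
    vecs = (
        cos_b[..., None] * mean[None]
        + sin_b[..., None] * (np.cos(az)[..., None] * e1[None]
                              + np.sin(az)[..., None] * e2[None])
    )
    rots = _random_rotations(n_frames, rng)
    return np.stack([r.apply(v) for r, v in zip(rots, vecs)])


def cone_s2(cone_semiangle_deg: float) -> float:
    """Closed-form order parameter of uniform diffusion in a cone:
    S = cos(theta) (1 + cos(theta)) / 2, returned squared."""
    c = np.cos(np.deg2rad(cone_semiangle_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)
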