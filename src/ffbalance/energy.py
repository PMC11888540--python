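"""Cutoff-free single-point energy oracle.

Direct double-sum Lennard-Jones and Coulomb plus periodic proper
dihedrals, with exclusions derived from the bonded lists (graph distance
<= nrexcl) and 1-4 interactions re-added through the ``[ pairs ]`` table
scaled by the fudge factors of the ``[ defaults ]`` directive.

This evaluator exists to *verify parameter transformations* — e.g. that
a gamma = 1 scaling is energy-neutral, or that a refined topology shifts
only the intended torsion term.  It deliberately has no periodic
boundary conditions, no cutoffs and no PME, so its absolute numbers are
not comparable to a simulation engine's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scaling import combine_lj
from .topology import ForceFieldTopology, Molecule, TopologyError

__all__ = [
    "KE_COULOMB",
    "Configuration",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "dihedral_energy",
    "dihedral_angle",
    "total_energy",
]

#: Coulomb constant 1/(4 pi eps0) in kJ/mol * nm / e^2
KE_COULOMB = 138.935458

_MIN_SEPARATION = 1e-6  # nm


@dataclass
class Configuration:
    """Cartesian coordinates (nm) for one expanded system of a topology."""

    coordinates: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")


def lj_pair_energy(sigma: float, epsilon: float, r: float) -> float:
    """12-6 potential 4*eps*[(sigma/r)^12 - (sigma/r)^6], kJ/mol."""
    if r <= 0:
        raise ValueError("r must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def coulomb_pair_energy(q_a: float, q_b: float, r: float) -> float:
    if r <= 0:
        raise ValueError("r must be positive")
    return KE_COULOMB * q_a * q_b / r


def dihedral_energy(k: float, n: int, delta_deg: float, phi_deg: float) -> float:
    """Periodic proper torsion k*(1 + cos(n*phi - delta)), kJ/mol."""
    if n < 1:
        raise ValueError("multiplicity must be >= 1")
    return k * (1.0 + np.cos(np.deg2rad(n * phi_deg - delta_deg)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points (IUPAC sign)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# system expansion helpers

def _expanded_instances(topo: ForceFieldTopology) -> list[Molecule]:
    counts = topo.molecule_counts or [(name, 1) for name in topo.molecules]
    instances: list[Molecule] = []
    for name, count in counts:
        if name not in topo.molecules:
            raise TopologyError(f"[ molecules ] entry {name!r} has no moleculetype")
        instances.extend([topo.molecules[name]] * count)
    return instances


def _exclusion_pairs(mol: Molecule) -> set[tuple[int, int]]:
    """0-based intra-molecule pairs within nrexcl bonds of each other."""
    n = len(mol.atoms)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for bond in mol.bonds:
        i, j = bond.atom_indices[0] - 1, bond.atom_indices[1] - 1
        adjacency[i].add(j)
        adjacency[j].add(i)
    excluded: set[tuple[int, int]] = set()
    for start in range(n):
        frontier = {start}
        seen = {start}
        for _ in range(mol.nrexcl):
            frontier = {k for f in frontier for k in adjacency[f]} - seen
            seen |= frontier
            for other in frontier:
                excluded.add((min(start, other), max(start, other)))
    return excluded


def _pair_tables(topo: ForceFieldTopology, type_names: list[str]):
    """(sigma, epsilon) lookup matrices over the distinct types present."""
    t = len(type_names)
    sig = np.zeros((t, t))
    eps = np.zeros((t, t))
    rule = topo.combination_rule
    for i, a in enumerate(type_names):
        for j, b in enumerate(type_names):
            ov = topo.lookup_override(a, b)
            if ov is not None:
                sig[i, j], eps[i, j] = ov.sigma, ov.epsilon
            else:
                sig[i, j], eps[i, j] = combine_lj(
                    topo.atom_types[a], topo.atom_types[b], rule
                )
    return sig, eps


def total_energy(
    topo: ForceFieldTopology,
    config: Configuration | np.ndarray,
    terms: tuple[str, ...] = ("lj", "coulomb", "dihedral"),
) -> dict[str, float]:
    """Per-term energies (kJ/mol) of one configuration of the full system.

    The system is the topology's ``[ molecules ]`` expansion (each
    moleculetype once if that section is absent); coordinates must list
    atoms in that order.  Raises on overlapping interacting atoms.
    """
    if isinstance(config, Configuration):
        coords = config.coordinates
    else:
        coords = Configuration(np.asarray(config)).coordinates
    instances = _expanded_instances(topo)
    n_total = sum(len(m.atoms) for m in instances)
    if coords.shape[0] != n_total:
        raise ValueError(
            f"configuration has {coords.shape[0]} atoms, topology expands to {n_total}"
        )

    type_names = sorted({a.type_name for m in instances for a in m.atoms})
    type_index = {t: i for i, t in enumerate(type_names)}
    t_idx = np.fromiter(
        (type_index[a.type_name] for m in instances for a in m.atoms),
        dtype=int,
        count=n_total,
    )
    charges = np.fromiter(
        (a.charge for m in instances for a in m.atoms), dtype=float, count=n_total
    )

    # pairwise distances and masks
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = np.triu_indices(n_total, k=1)
    include = np.zeros((n_total, n_total), dtype=bool)
    include[iu] = True

    offset = 0
    exclusion_cache: dict[int, set[tuple[int, int]]] = {}
    pair_lists: list[tuple[int, int]] = []  # global 0-based 1-4 pairs
    dihedral_list: list[tuple[tuple[int, int, int, int], float, float, int]] = []
    for mol in instances:
        excl = exclusion_cache.get(id(mol))
        if excl is None:
            excl = _exclusion_pairs(mol)
            exclusion_cache[id(mol)] = excl
        for i, j in excl:
            include[offset + i, offset + j] = False
            include[offset + j, offset + i] = False
        for p in mol.pairs:
            pair_lists.append((offset + p.atom_indices[0] - 1, offset + p.atom_indices[1] - 1))
        for d in mol.dihedrals:
            if d.is_periodic:
                dihedral_list.append(
                    (
                        tuple(offset + k - 1 for k in d.atom_indices),
                        d.force_constant,
                        d.phase_deg,
                        d.multiplicity,
                    )
                )
        offset += len(mol.atoms)

    interacting = include | np.zeros_like(include)
    for gi, gj in pair_lists:
        interacting[gi, gj] = True
        interacting[gj, gi] = True
    too_close = (r < _MIN_SEPARATION) & interacting & ~np.eye(n_total, dtype=bool)
    if np.any(np.triu(too_close, k=1)):
        i, j = np.argwhere(np.triu(too_close, k=1))[0]
        raise ValueError(f"overlapping interacting atoms {i + 1} and {j + 1}")

    energies: dict[str, float] = {}
    r_safe = np.where(r > 0, r, np.inf)

    if "lj" in terms or "coulomb" in terms:
        sig_tab, eps_tab = _pair_tables(topo, type_names)
        sig = sig_tab[t_idx[:, None], t_idx[None, :]]
        eps = eps_tab[t_idx[:, None], t_idx[None, :]]
        sr6 = (sig / r_safe) ** 6
        e_lj_mat = 4.0 * eps * (sr6 * sr6 - sr6)
        e_qq_mat = KE_COULOMB * charges[:, None] * charges[None, :] / r_safe
        if "lj" in terms:
            e = float(e_lj_mat[include].sum())
            e += topo.fudge_lj * sum(float(e_lj_mat[i, j]) for i, j in pair_lists)
            energies["lj"] = e
        if "coulomb" in terms:
            e = float(e_qq_mat[include].sum())
            e += topo.fudge_qq * sum(float(e_qq_mat[i, j]) for i, j in pair_lists)
            energies["coulomb"] = e

    if "dihedral" in terms:
        e = 0.0
        for (ia, ib, ic, id_), k, delta, n in dihedral_list:
            phi = dihedral_angle(coords[ia], coords[ib], coords[ic], coords[id_])
            e += dihedral_energy(k, n, delta, phi)
        energies["dihedral"] = e

    energies["total"] = sum(energies.values())
    return energies
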