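"""Coordinate I/O at the trajectory-reader boundary.

PDB handling delegates to biotite; multi-frame XYZ files use a plain
reader/writer.  All in-memory coordinates are nm; PDB files are
angstrom on disk, XYZ files written here are nm (stated in the comment
line).
"""

from __future__ import annotations

import os

import numpy as np

from .observables import Trajectory

__all__ = ["read_pdb", "write_pdb", "read_xyz", "write_xyz", "read_trajectory"]


def read_pdb(path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a Trajectory (nm)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(os.fspath(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float) / 10.0
    arr = stack[0] if coords.ndim == 3 else stack
    if coords.ndim == 2:
        coords = coords[None]
    return Trajectory(
        coords=coords,
        atom_names=list(arr.atom_name),
        residue_indices=np.asarray(arr.res_id, dtype=int),
        residue_names=list(arr.res_name),
    )


def write_pdb(traj: Trajectory, path) -> None:
    """Write all frames of a Trajectory as PDB models (angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coords[f] * 10.0
        arr.atom_name = np.array(traj.atom_names)
        arr.res_id = traj.residue_indices
        arr.res_name = np.array(traj.residue_names)
        arr.chain_id = np.array(["A"] * n)
        arr.element = np.array(
            [a.lstrip("0123456789")[0].upper() for a in traj.atom_names]
        )
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    tmp = os.fspath(path) + ".tmp"
    pdb.write(tmp)
    os.replace(tmp, os.fspath(path))


def read_xyz(path) -> Trajectory:
    """Multi-frame XYZ (coordinates in nm; atom labels are names)."""
    frames: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        coords = np.empty((n, 3))
        frame_names = []
        for k, ln in enumerate(block):
            tok = ln.split()
            frame_names.append(tok[0])
            coords[k] = [float(x) for x in tok[1:4]]
        if not names:
            names = frame_names
        frames.append(coords)
        i += 2 + n
        while i < len(lines) and not lines[i].strip():
            break
    return Trajectory(
        coords=np.stack(frames),
        atom_names=names,
        residue_indices=np.arange(1, len(names) + 1),
        residue_names=["UNK"] * len(names),
    )


def write_xyz(traj: Trajectory, path) -> None:
    out: list[str] = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        out.append(f"frame {f} (coordinates in nm)")
        for name, xyz in zip(traj.atom_names, traj.coords[f]):
            out.append(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("\n".join(out) + "\n")
    os.replace(tmp, os.fspath(path))


def read_trajectory(path) -> Trajectory:
    path = os.fspath(path)
    if path.lower().endswith(".pdb"):
        return read_pdb(path)
    if path.lower().endswith(".xyz"):
        return read_xyz(path)
    raise ValueError(f"unsupported coordinate format: {path}")
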