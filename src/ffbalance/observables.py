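"""Validation observables over coordinate trajectories and shift tables.

All coordinates are in nm.  The implementations favour closed-form
verifiability: vacuum Debye scattering (no hydration shell or excluded
volume), a Kabsch-Sander hydrogen-bond DSSP for helicity, and the iRED
eigenmode decomposition for backbone amide S2 order parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "Trajectory",
    "ObservableSeries",
    "radius_of_gyration",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsf",
    "debye_saxs",
    "GuinierResult",
    "guinier_rg",
    "dssp_assign",
    "helix_fraction",
    "read_shift_table",
    "secondary_shift_delta",
    "ired_s2",
    "agreement_rmsd",
    "ATOMIC_F0",
]


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates with atom metadata."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    atom_names: list[str]
    residue_indices: np.ndarray  # (n_atoms,), 1-based
    residue_names: list[str]
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        n = self.coords.shape[1]
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if not (len(self.atom_names) == len(self.residue_indices) == len(self.residue_names) == n):
            raise ValueError("metadata length mismatch with coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, residue_index: int, atom_name: str) -> int | None:
        for i, (ri, an) in enumerate(zip(self.residue_indices, self.atom_names)):
            if ri == residue_index and an == atom_name:
                return i
        return None

    def select(self, atom_names: Sequence[str]) -> np.ndarray:
        wanted = set(atom_names)
        return np.array(
            [i for i, n in enumerate(self.atom_names) if n in wanted], dtype=int
        )


@dataclass
class ObservableSeries:
    """Labelled numeric series (per residue, per q, per frame...)."""

    labels: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels and values must have equal length")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape[0] != self.values.shape[0]:
                raise ValueError("uncertainty length mismatch")

    def to_frame(self) -> pd.DataFrame:
        data = {"label": self.labels, "value": self.values}
        if self.uncertainty is not None:
            data["uncertainty"] = self.uncertainty
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# geometry

def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the center of mass, nm."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(frame.shape[0])
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * frame).sum(axis=0) / total
    d2 = ((frame - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / total))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) mapping centered mobile onto
    centered reference, by SVD of the covariance matrix."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _check_nondegenerate(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("need >= 3 atoms for superposition")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("collinear/degenerate selection")


def kabsch_rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: np.ndarray | None = None,
    align: bool = True,
) -> float:
    """Least-squares RMSD (nm) after optimal rigid superposition.

    With ``align=False`` no superposition is performed (raw RMSD)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError("frames differ in shape")
    if align:
        _check_nondegenerate(a)
        _check_nondegenerate(b)
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot = kabsch_rotation(a, b)
        a = a @ rot.T
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsf(traj: Trajectory, selection: np.ndarray | None = None) -> ObservableSeries:
    """Per-atom RMS fluctuation about the mean structure (nm) after
    per-frame superposition onto that mean."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    frames = traj.coords[:, sel, :].copy()
    _check_nondegenerate(frames[0])
    ref = frames[0] - frames[0].mean(axis=0)
    for _ in range(2):  # align to first, then to the running mean
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            x = frames[f] - frames[f].mean(axis=0)
            rot = kabsch_rotation(x, ref)
            aligned[f] = x @ rot.T
        ref = aligned.mean(axis=0)
        frames = aligned
    fluct = np.sqrt(((frames - ref) ** 2).sum(axis=2).mean(axis=0))
    return ObservableSeries(labels=sel, values=fluct, units="nm")


# ---------------------------------------------------------------------------
# SAXS

#: q -> 0 atomic scattering factors (electron counts); the small-angle
#: regime treated here is insensitive to the Gaussian falloff
ATOMIC_F0 = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}


def _resolve_form_factors(
    frame: np.ndarray,
    form_factors,
    atom_names: Sequence[str] | None,
) -> np.ndarray:
    n = frame.shape[0]
    if form_factors is None:
        return np.ones(n)
    if np.isscalar(form_factors):
        return np.full(n, float(form_factors))
    if isinstance(form_factors, dict):
        if atom_names is None:
            raise ValueError("element form factors require atom names")
        from .residues import element_of

        return np.array([form_factors[element_of(a)] for a in atom_names])
    ff = np.asarray(form_factors, dtype=float)
    if ff.shape[0] != n:
        raise ValueError("form factor array length mismatch")
    return ff


def debye_saxs(
    frame: np.ndarray,
    q_grid: np.ndarray,
    form_factors=None,
    atom_names: Sequence[str] | None = None,
) -> ObservableSeries:
    """Orientationally averaged vacuum scattering intensity by the Debye
    double sum I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij)."""
    frame = np.asarray(frame, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    f = _resolve_form_factors(frame, form_factors, atom_names)
    if frame.shape[0] == 1:
        return ObservableSeries(labels=q, values=np.full(q.shape, f[0] ** 2), units="e^2")
    rij = pdist(frame)
    # product of form factors over the same condensed ordering as pdist
    n = frame.shape[0]
    iu = np.triu_indices(n, k=1)
    fprod = f[iu[0]] * f[iu[1]]
    # sin(qr)/(qr) with the q->0 / r->0 limit of 1 handled by np.sinc
    qr = q[:, None] * rij[None, :]
    sinc = np.sinc(qr / np.pi)
    intensity = (f**2).sum() + 2.0 * (fprod[None, :] * sinc).sum(axis=1)
    return ObservableSeries(labels=q, values=intensity, units="e^2")


class GuinierResult(NamedTuple):
    rg: float
    i0: float
    q_max: float
    n_points: int


def guinier_rg(curve: ObservableSeries, qrg_max: float = 1.3) -> GuinierResult:
    """Radius of gyration from the Guinier regime of a scattering curve.

    Linear fit of ln I against q^2; R_g = sqrt(-3 * slope).  The fit
    window is iterated until the largest included q satisfies
    q * R_g <= qrg_max self-consistently.
    """
    q = np.asarray(curve.labels, dtype=float)
    intensity = np.asarray(curve.values, dtype=float)
    order = np.argsort(q)
    q, intensity = q[order], intensity[order]

    def fit(mask: np.ndarray) -> tuple[float, float]:
        if mask.sum() < 5:
            raise ValueError("fewer than 5 points in the Guinier window")
        if np.any(intensity[mask] <= 0):
            raise ValueError("non-positive intensities in the Guinier window")
        slope, icpt = np.polyfit(q[mask] ** 2, np.log(intensity[mask]), 1)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; no decaying regime")
        return float(slope), float(icpt)

    mask = np.zeros_like(q, dtype=bool)
    mask[: max(5, min(10, len(q)))] = True
    slope, icpt = fit(mask)
    rg = float(np.sqrt(-3.0 * slope))
    for _ in range(100):
        new_mask = q * rg <= qrg_max
        if new_mask.sum() < 5:
            new_mask = np.zeros_like(mask)
            new_mask[:5] = True
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        slope, icpt = fit(mask)
        rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(rg=rg, i0=float(np.exp(icpt)), q_max=float(q[mask].max()),
                         n_points=int(mask.sum()))


# ---------------------------------------------------------------------------
# DSSP secondary structure

_HB_CUTOFF = -0.5  # kcal/mol
_HB_Q1Q2_F = 0.084 * 332.0  # Kabsch-Sander electrostatic prefactor, kcal*A/mol


def _hbond_matrix(
    n_coords: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    o: np.ndarray,
    h: np.ndarray | None,
) -> np.ndarray:
    """A[i, j] True when CO of residue i accepts the NH of residue j."""
    nres = n_coords.shape[0]
    if h is None:
        h = np.full_like(n_coords, np.nan)
        # amide H placed 0.1 nm from N along the previous residue's O->C direction
        co_dir = c[:-1] - o[:-1]
        co_dir /= np.linalg.norm(co_dir, axis=1)[:, None]
        h[1:] = n_coords[1:] + 0.1 * co_dir

    def dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return 10.0 * np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)  # Angstrom

    r_on = dist(o, n_coords)
    r_oh = dist(o, h)
    r_cn = dist(c, n_coords)
    r_ch = dist(c, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = _HB_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    energy = np.where(np.isfinite(energy), energy, 0.0)
    accept = energy < _HB_CUTOFF
    i_idx, j_idx = np.meshgrid(np.arange(nres), np.arange(nres), indexing="ij")
    accept &= np.abs(i_idx - j_idx) >= 2  # no bond with self or sequence neighbour
    return accept


def dssp_assign(
    traj: Trajectory, frame: int = 0, include_310_as_helix: bool = False
) -> str:
    """Per-residue secondary structure for one frame: H/G/I/E/C.

    Kabsch-Sander hydrogen-bond energies (cutoff -0.5 kcal/mol) define
    n-turns and bridges; two consecutive 4-turns make an alpha-helix.
    The amide H is taken from the trajectory when present, otherwise
    placed along the preceding carbonyl C=O direction.
    """
    res_ids = sorted(set(traj.residue_indices.tolist()))
    nres = len(res_ids)
    coords = traj.coords[frame]

    def bb(name: str, required: bool = True) -> np.ndarray | None:
        out = np.full((nres, 3), np.nan)
        ok = True
        for k, ri in enumerate(res_ids):
            idx = traj.atom_index(ri, name)
            if idx is None:
                ok = False
            else:
                out[k] = coords[idx]
        if not ok:
            if required:
                raise ValueError(f"missing backbone {name} atom(s) for DSSP")
            return None
        return out

    n_c = bb("N")
    ca = bb("CA")
    c = bb("C")
    o = bb("O")
    h = bb("H", required=False)
    accept = _hbond_matrix(n_c, ca, c, o, h)

    def turn(n: int) -> np.ndarray:
        t = np.zeros(nres, dtype=bool)
        for i in range(nres - n):
            t[i] = accept[i, i + n]
        return t

    t3, t4, t5 = turn(3), turn(4), turn(5)
    ss = np.array(["C"] * nres, dtype="<U1")

    def mark(tn: np.ndarray, span: int, code: str) -> None:
        for i in range(1, nres - span):
            if tn[i - 1] and tn[i]:
                for k in range(i, i + span):
                    if ss[k] == "C":
                        ss[k] = code

    mark(t4, 4, "H")
    # beta bridges/ladders (both partners marked E)
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            para = (accept[i - 1, j] and accept[j, i + 1]) or (
                accept[j - 1, i] and accept[i, j + 1]
            )
            anti = (accept[i, j] and accept[j, i]) or (
                accept[i - 1, j + 1] and accept[j - 1, i + 1]
            )
            if para or anti:
                for k in (i, j):
                    if ss[k] == "C":
                        ss[k] = "E"
    mark(t3, 3, "G")
    mark(t5, 5, "I")
    if include_310_as_helix:
        ss[ss == "G"] = "H"
    return "".join(ss)


def helix_fraction(
    traj: Trajectory, include_310: bool = False
) -> tuple[ObservableSeries, list[str]]:
    """Fraction of frames each residue is assigned alpha-helix (H).

    Returns the per-residue fractions and the raw per-frame assignment
    strings.  3-10 helix counts toward the fraction only when
    ``include_310`` is set.
    """
    res_ids = sorted(set(traj.residue_indices.tolist()))
    assignments = [
        dssp_assign(traj, f, include_310_as_helix=include_310)
        for f in range(traj.n_frames)
    ]
    counts = np.zeros(len(res_ids))
    for ss in assignments:
        counts += np.frombuffer(ss.encode(), dtype="S1") == b"H"
    frac = counts / traj.n_frames
    return (
        ObservableSeries(labels=np.array(res_ids), values=frac, units="fraction"),
        assignments,
    )


# ---------------------------------------------------------------------------
# chemical shifts

def read_shift_table(path) -> pd.DataFrame:
    """Read a plain-text shift table: residue index, [residue name,]
    C-alpha shift, C-beta shift (ppm); '#' comments; NaN allowed for
    glycine C-beta."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    if df.shape[1] == 4:
        df.columns = ["residue_index", "residue_name", "ca", "cb"]
    elif df.shape[1] == 3:
        df.columns = ["residue_index", "ca", "cb"]
        df["residue_name"] = ""
    else:
        raise ValueError("expected 3 or 4 whitespace-separated columns")
    df["residue_index"] = df["residue_index"].astype(int)
    df[["ca", "cb"]] = df[["ca", "cb"]].apply(pd.to_numeric, errors="coerce")
    if not df["residue_index"].is_monotonic_increasing:
        raise ValueError("residue indices must be monotone increasing")
    return df[["residue_index", "residue_name", "ca", "cb"]]


def secondary_shift_delta(
    observed: pd.DataFrame, random_coil: pd.DataFrame
) -> ObservableSeries:
    """Helicity-discriminating secondary shift difference per residue:
    (dCa_obs - dCa_coil) - (dCb_obs - dCb_coil), ppm.

    Positive values indicate helical, negative beta-sheet propensity.
    Glycine (no C-beta) contributes its C-alpha secondary shift alone.
    """
    obs = observed.sort_values("residue_index").reset_index(drop=True)
    coil = random_coil.sort_values("residue_index").reset_index(drop=True)
    merged = obs.merge(
        coil, on="residue_index", how="outer", suffixes=("_obs", "_rc"), indicator=True
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        raise ValueError(
            "residue mismatch between observed and random-coil tables: "
            + ", ".join(str(r) for r in bad["residue_index"].tolist())
        )
    name_obs = merged["residue_name_obs"].astype(str)
    name_rc = merged["residue_name_rc"].astype(str)
    named = (name_obs != "") & (name_rc != "")
    clash = merged[named & (name_obs != name_rc)]
    if len(clash):
        raise ValueError(
            "residue name mismatch at indices: "
            + ", ".join(str(r) for r in clash["residue_index"].tolist())
        )
    d_ca = merged["ca_obs"] - merged["ca_rc"]
    d_cb = merged["cb_obs"] - merged["cb_rc"]
    delta = (d_ca - d_cb.fillna(0.0)).to_numpy()
    gly_flag = d_cb.isna().to_numpy()
    return ObservableSeries(
        labels=merged["residue_index"].to_numpy(),
        values=delta,
        uncertainty=None,
        units="ppm;ca_only=" + ",".join(
            str(i) for i in merged["residue_index"][gly_flag].tolist()
        ),
    )


# ---------------------------------------------------------------------------
# iRED order parameters

def _p2_covariance(vectors: np.ndarray) -> np.ndarray:
    dots = np.einsum("fmi,fni->fmn", vectors, vectors)
    return ((3.0 * dots**2 - 1.0) / 2.0).mean(axis=0)


def _s2_from_matrix(m: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(m)  # ascending
    # the 5 largest-eigenvalue modes carry overall reorientation; the
    # remainder are internal: S2_i = 1 - sum_internal lam_m |m_i|^2
    internal = slice(0, max(m.shape[0] - 5, 0))
    s2 = 1.0 - (lam[internal][None, :] * vec[:, internal] ** 2).sum(axis=1)
    return np.clip(s2, 0.0, 1.0)


def ired_s2(vectors: np.ndarray, n_blocks: int = 1) -> ObservableSeries:
    """iRED order parameters from per-residue unit-vector time series.

    ``vectors`` is (n_frames, n_residues, 3).  The M x M matrix of
    time-averaged P2(u_i . u_j) is eigendecomposed; the five largest
    modes represent overall reorientation and the remaining (internal)
    modes are subtracted from 1 to give S2, clipped to [0, 1].  With
    ``n_blocks`` > 1 the frames are split into contiguous blocks and the
    mean and standard deviation across blocks are reported.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 3 or v.shape[2] != 3:
        raise ValueError("vectors must be (n_frames, n_residues, 3)")
    if v.shape[0] < 10:
        raise ValueError("need at least 10 frames")
    if v.shape[1] < 2:
        raise ValueError("need at least 2 residues")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite vectors")
    if v.shape[1] < 6:
        warnings.warn(
            "fewer than 6 residues: separating 5 reorientational modes is "
            "ill-defined", stacklevel=2
        )
    norms = np.linalg.norm(v, axis=2, keepdims=True)
    v = v / norms
    labels = np.arange(1, v.shape[1] + 1)
    if n_blocks <= 1:
        s2 = _s2_from_matrix(_p2_covariance(v))
        return ObservableSeries(labels=labels, values=s2, units="S2")
    blocks = np.array_split(v, n_blocks, axis=0)
    per_block = np.stack([_s2_from_matrix(_p2_covariance(b)) for b in blocks])
    return ObservableSeries(
        labels=labels,
        values=per_block.mean(axis=0),
        uncertainty=per_block.std(axis=0, ddof=1),
        units="S2",
    )


# ---------------------------------------------------------------------------
# agreement statistic

def agreement_rmsd(sim: ObservableSeries, exp: ObservableSeries) -> float:
    """Root-mean-square deviation between matched simulated and
    experimental series: sqrt(sum (x_sim - x_exp)^2 / N)."""
    if sim.labels.shape != exp.labels.shape or not np.array_equal(
        sim.labels, exp.labels
    ):
        raise ValueError("series labels do not match")
    diff = sim.values - exp.values
    return float(np.sqrt((diff**2).mean()))
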