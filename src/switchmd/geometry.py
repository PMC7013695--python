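"""Geometry kernels shared by every trajectory metric.

Dihedrals, centroids, Kabsch superposition, RMSD/RMSF, residue-pair
minimum-distance matrices and helix axes.  All angles are degrees in
(-180, 180]; all distances Angstrom.  Every metric is invariant under a
global rigid motion of the frame (the superposition-dependent ones by
construction).

Centers of mass are *unweighted* geometric centroids of the stated atom
selection: the coupling metric is defined over C-alpha atoms only, where
mass weighting is a no-op, and side-chain centroids are kept unweighted
for reproducibility without mass tables.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import (DegenerateInputError, GeometryError, MappingError,
                     MissingAtomError, UnsupportedResidueError)
from .io import Frame, Trajectory
from .numbering import ResidueMap

#: gamma atom completing the chi1 dihedral N-CA-CB-gamma, by residue type
CHI1_GAMMA_ATOM = {
    "ILE": "CG1", "VAL": "CG1", "SER": "OG", "THR": "OG1", "CYS": "SG",
}
_CHI1_UNSUPPORTED = {"GLY", "ALA"}


@dataclasses.dataclass(frozen=True)
class Selection:
    """An ordered, validated atom selection over a trajectory."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise GeometryError(f"empty selection {self.label!r}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def from_atoms(cls, traj: Trajectory,
                   atoms: Iterable[tuple[str, int, str]],
                   label: str = "") -> "Selection":
        idx = []
        for chain, rid, name in atoms:
            try:
                idx.append(traj.atom_index(chain, rid, name))
            except KeyError as exc:
                raise MissingAtomError(str(exc)) from None
        return cls(np.array(idx), label)

    @classmethod
    def ca_of(cls, traj: Trajectory,
              residues: Iterable[tuple[str, int]],
              label: str = "") -> "Selection":
        return cls.from_atoms(traj, [(c, r, "CA") for c, r in residues], label)


@dataclasses.dataclass
class DistanceSeries:
    """A per-frame scalar distance with its time base."""

    label: str
    times: np.ndarray   # ns
    values: np.ndarray  # Angstrom

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DegenerateInputError("times and values differ in length")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Torsion angle of four points, degrees in (-180, 180].

    Sign follows the IUPAC convention (clockwise positive when viewed from
    p2 towards p3).  Accepts batched inputs with shape (..., 3); raises
    GeometryError when any of p1p2p3 or p2p3p4 is collinear (or two
    consecutive points coincide), since the torsion is then undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or \
       np.any(np.linalg.norm(n2, axis=-1) < 1e-10) or np.any(b2n < 1e-10):
        raise GeometryError("degenerate dihedral: collinear or coincident points")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None]), axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)  # half-open (-180, 180]
    if ang.ndim == 0:
        return float(ang)
    return ang


def chi1(frame: Frame, residue: tuple[str, int]) -> float:
    """First side-chain torsion N-CA-CB-gamma of a residue, degrees."""
    chain, rid = residue
    traj = frame.trajectory
    try:
        res_name = traj.residue_name(chain, rid)
    except KeyError:
        raise MissingAtomError(f"no residue {chain}/{rid}") from None
    if res_name in _CHI1_UNSUPPORTED:
        raise UnsupportedResidueError(
            f"{res_name} {chain}/{rid} has no chi1 (no gamma atom)")
    gamma = CHI1_GAMMA_ATOM.get(res_name, "CG")
    pts = []
    for name in ("N", "CA", "CB", gamma):
        if not traj.has_atom(chain, rid, name):
            raise MissingAtomError(
                f"residue {res_name} {chain}/{rid} lacks atom {name}")
        pts.append(frame.coords[traj.atom_index(chain, rid, name)])
    return dihedral(*pts)


def chi1_series(traj: Trajectory, residue: tuple[str, int]) -> np.ndarray:
    """chi1 over all frames, vectorised."""
    chain, rid = residue
    res_name = traj.residue_name(chain, rid)
    if res_name in _CHI1_UNSUPPORTED:
        raise UnsupportedResidueError(
            f"{res_name} {chain}/{rid} has no chi1 (no gamma atom)")
    gamma = CHI1_GAMMA_ATOM.get(res_name, "CG")
    try:
        idx = [traj.atom_index(chain, rid, n) for n in ("N", "CA", "CB", gamma)]
    except KeyError as exc:
        raise MissingAtomError(str(exc)) from None
    p = traj.coords[:, idx, :]
    return np.atleast_1d(dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3]))


# ---------------------------------------------------------------------------
# Centroids and distances
# ---------------------------------------------------------------------------

def com(frame: Frame, selection: Selection) -> np.ndarray:
    """Unweighted centroid of a selection in one frame."""
    return frame.coords[selection.indices].mean(axis=0)


def com_distance_series(traj: Trajectory, sel_a: Selection,
                        sel_b: Selection, label: str = "") -> DistanceSeries:
    """Per-frame Euclidean distance between two selection centroids."""
    ca = traj.coords[:, sel_a.indices, :].mean(axis=1)
    cb = traj.coords[:, sel_b.indices, :].mean(axis=1)
    d = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(label or f"{sel_a.label}-{sel_b.label}",
                          traj.times, d)


def residue_min_distance_matrix(frame: Frame,
                                residues_a: Sequence[tuple[str, int]],
                                residues_b: Sequence[tuple[str, int]],
                                contact_cutoff: float = 3.0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum heavy-atom distance between residue pairs, plus the contact
    mask (distance <= 3.0 A, the conventional contact-map threshold).

    Hydrogens are excluded throughout because they are frequently absent
    from PDB coordinate dumps.
    """
    traj = frame.trajectory
    groups_a = [frame.coords[traj.residue_indices(c, r)] for c, r in residues_a]
    groups_b = [frame.coords[traj.residue_indices(c, r)] for c, r in residues_b]
    for (c, r), g in zip(list(residues_a) + list(residues_b),
                         groups_a + groups_b):
        if len(g) == 0:
            raise MissingAtomError(f"residue {c}/{r} has no heavy atoms")
    mat = np.empty((len(groups_a), len(groups_b)))
    for i, ga in enumerate(groups_a):
        for j, gb in enumerate(groups_b):
            mat[i, j] = cdist(ga, gb).min()
    return mat, mat <= contact_cutoff


def time_averaged_min_distance_matrix(traj: Trajectory,
                                      residues_a, residues_b,
                                      window: slice | None = None,
                                      contact_cutoff: float = 3.0
                                      ) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-frame minimum distances over a frame window, then
    threshold — so a contact is a pair whose *mean* closest approach stays
    within the cutoff over the window."""
    window = window or slice(None)
    frames = range(*window.indices(traj.n_frames))
    if len(frames) == 0:
        raise DegenerateInputError("empty frame window")
    acc = None
    for i in frames:
        m, _ = residue_min_distance_matrix(traj.frame(i), residues_a,
                                           residues_b, contact_cutoff)
        acc = m if acc is None else acc + m
    mean = acc / len(frames)
    return mean, mean <= contact_cutoff


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def _check_fit_points(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise GeometryError("superposition needs >=3 fit atoms")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8:
        raise GeometryError("fit atoms are collinear")


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns (R, t) with ``mobile @ R.T + t`` superposed; proper rotation
    (det +1) enforced via scipy's Kabsch implementation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    _check_fit_points(mobile)
    _check_fit_points(reference)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t


def superpose(mobile: Frame | np.ndarray, reference: Frame | np.ndarray,
              fit_selection: Selection
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superpose a mobile frame onto a reference on the fit selection.

    Returns (transformed coordinates of *all* atoms, rotation matrix,
    translation vector).
    """
    mob = mobile.coords if isinstance(mobile, Frame) else np.asarray(mobile, float)
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference, float)
    idx = fit_selection.indices
    R, t = kabsch(mob[idx], ref[idx])
    return mob @ R.T + t, R, t


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    d = np.asarray(coords_a, float) - np.asarray(coords_b, float)
    return float(np.sqrt((d * d).sum(axis=-1).mean()))


def rmsd_series(traj: Trajectory, fit_selection: Selection,
                measure_selection: Selection | None = None,
                reference: int = 0) -> DistanceSeries:
    """Per-frame RMSD of the measure selection after least-squares fitting
    each frame to the reference frame on the fit selection."""
    measure = measure_selection or fit_selection
    ref = traj.coords[reference]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        moved, _, _ = superpose(traj.coords[i], ref, fit_selection)
        out[i] = rmsd(moved[measure.indices], ref[measure.indices])
    return DistanceSeries(f"rmsd[{measure.label or fit_selection.label}]",
                          traj.times, out)


def rmsf(traj: Trajectory, fit_selection: Selection,
         atoms: Selection | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-average
    position, after superposing every frame onto the time-average structure
    (two-pass: fit to frame 0, average, re-fit to the average)."""
    if traj.n_frames < 2:
        raise DegenerateInputError("RMSF needs >=2 frames")
    atoms = atoms or fit_selection
    fitted = np.empty_like(traj.coords)
    ref = traj.coords[0]
    for i in range(traj.n_frames):
        fitted[i], _, _ = superpose(traj.coords[i], ref, fit_selection)
    mean = fitted.mean(axis=0)
    for i in range(traj.n_frames):
        fitted[i], _, _ = superpose(fitted[i], mean, fit_selection)
    mean = fitted.mean(axis=0)
    disp = fitted[:, atoms.indices, :] - mean[atoms.indices]
    return np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Helix axes and the TM6 kink
# ---------------------------------------------------------------------------

def helix_axis(frame: Frame, residues: Sequence[tuple[str, int]]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of a consecutive C-alpha run (>=5 residues).

    Returns (unit axis, centroid); the axis is oriented from the first
    towards the last residue of the run.
    """
    if len(residues) < 5:
        raise GeometryError("helix axis needs >=5 consecutive C-alpha atoms")
    traj = frame.trajectory
    sel = Selection.ca_of(traj, residues, "helix")
    pts = frame.coords[sel.indices]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def tm6_kink(frame: Frame, rmap: ResidueMap,
             split_below: int = 48, split_above: int = 49,
             first: int = 30, last: int = 60) -> float:
    """Bending angle of TM6 at the CWxP motif, degrees in [0, 180).

    Angle between the principal axes of the sub-helices 6.30-6.47 and
    6.49-6.60 (clipped to the mapped span); the split sits at the toggle
    tryptophan W6.48 where agonist-bound receptors kink TM6.
    """
    lower = rmap.helix_residues(6, first, split_below - 1)
    upper = rmap.helix_residues(6, split_above, last)
    if len(lower) < 5 or len(upper) < 5:
        raise MappingError(
            f"TM6 segments too short for kink: {len(lower)} / {len(upper)} residues")
    ax_lo, _ = helix_axis(frame, lower)
    ax_hi, _ = helix_axis(frame, upper)
    cosang = float(np.clip(np.dot(ax_lo, ax_hi), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def tm6_kink_series(traj: Trajectory, rmap: ResidueMap, **kwargs) -> np.ndarray:
    return np.array([tm6_kink(traj.frame(i), rmap, **kwargs)
                     for i in range(traj.n_frames)])
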