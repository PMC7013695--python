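"""Activation and coupling hallmark metrics ("molecular switches").

Class-A GPCR activation leaves residue-level fingerprints: the chi1
rotamer states of the toggle tryptophan W6.48, the transmission switch
F6.44, H6.55 and the NPxxY tyrosine Y7.53; breakage of the TM3-TM6 ionic
lock R3.50-E6.30; approach of Y5.58 to Y7.53; and a drift of the G-protein
alpha5 helix towards the receptor core.  This module computes those
metrics from the geometry kernels and classifies the receptor-G-protein
coupling tendency from the fitted distance trend line.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, MappingError, MissingAtomError
from .geometry import (DistanceSeries, Selection, chi1_series,
                       com_distance_series)
from .io import Frame, Trajectory
from .numbering import ResidueMap

logger = logging.getLogger(__name__)

#: the four switch residues whose chi1 the battery tracks by default
DEFAULT_SWITCH_LABELS = ("6.48", "6.44", "6.55", "7.53")

#: receptor C-alpha probes for the receptor-alpha5 coupling distance
COUPLING_RECEPTOR_LABELS = ("7.53", "2.46", "3.46", "5.54", "6.40")

#: guanidinium nitrogens / carboxylate oxygens defining the ionic lock
_ARG_N = ("NE", "NH1", "NH2")
_GLU_O = ("OE1", "OE2")

_POLAR_ELEMENTS = {"N", "O"}


def rotamer_classify(chi1_deg: float | np.ndarray) -> str | np.ndarray:
    """Bin a chi1 angle into gauche-/gauche+/trans.

    Half-open bins: gauche- for (-120, 0], gauche+ for (0, 120], trans
    otherwise (so exactly -120 is trans).  Vectorised over arrays.
    """
    a = np.asarray(chi1_deg, dtype=float)
    out = np.full(a.shape, "trans", dtype=object)
    out[(a > -120.0) & (a <= 0.0)] = "gauche-"
    out[(a > 0.0) & (a <= 120.0)] = "gauche+"
    if out.ndim == 0:
        return str(out[()])
    return out


@dataclasses.dataclass
class SwitchSeries:
    """Per-frame chi1 and rotamer state of one switch residue."""

    residue_label: str
    times: np.ndarray
    chi1: np.ndarray
    state: np.ndarray

    def __post_init__(self):
        if not (len(self.times) == len(self.chi1) == len(self.state)):
            raise DegenerateInputError("switch series length mismatch")


@dataclasses.dataclass
class CouplingTrend:
    """OLS trend of the receptor-alpha5 distance and its classification.

    ``approaching`` if slope < -threshold, ``receding`` if slope >
    +threshold, else ``flat``.  The threshold (default 0.0005 A/ns, i.e.
    0.5 A of drift over a microsecond) guards against classifying noise as
    a trend.
    """

    slope: float            # A/ns
    intercept: float        # A
    threshold: float        # A/ns
    stderr: float = float("nan")
    r_value: float = float("nan")

    @property
    def classification(self) -> str:
        if self.slope < -self.threshold:
            return "approaching"
        if self.slope > self.threshold:
            return "receding"
        return "flat"


def switch_timeseries(traj: Trajectory, rmap: ResidueMap,
                      labels: Iterable[str] = DEFAULT_SWITCH_LABELS
                      ) -> dict[str, SwitchSeries]:
    """chi1 time series + rotamer states for the named switch residues."""
    out = {}
    for label in labels:
        residue = rmap.resolve(label)
        angles = chi1_series(traj, residue)
        out[label] = SwitchSeries(label, traj.times, angles,
                                  rotamer_classify(angles))
    return out


def ionic_lock_distance(frame: Frame, rmap: ResidueMap) -> float:
    """Minimum R3.50 guanidinium-N to E6.30 carboxylate-O distance (the
    TM3-TM6 ionic lock; ~3 A when formed in the inactive state)."""
    traj = frame.trajectory
    arg = rmap.resolve("3.50")
    glu = rmap.resolve("6.30")
    npts, opts = [], []
    for name in _ARG_N:
        if traj.has_atom(*arg, name):
            npts.append(frame.coords[traj.atom_index(*arg, name)])
    for name in _GLU_O:
        if traj.has_atom(*glu, name):
            opts.append(frame.coords[traj.atom_index(*glu, name)])
    if not npts:
        raise MissingAtomError(f"R3.50 {arg} lacks guanidinium nitrogens")
    if not opts:
        raise MissingAtomError(f"E6.30 {glu} lacks carboxylate oxygens")
    return float(cdist(np.array(npts), np.array(opts)).min())


def ionic_lock_series(traj: Trajectory, rmap: ResidueMap) -> DistanceSeries:
    vals = [ionic_lock_distance(traj.frame(i), rmap)
            for i in range(traj.n_frames)]
    return DistanceSeries("R3.50-E6.30", traj.times, np.array(vals))


def tm5_tm7_distance(frame: Frame, rmap: ResidueMap) -> float:
    """C-alpha distance between Y5.58 (TM5) and Y7.53 (TM7); large when
    TM6 is straight (inactive-like), small when the helices pack together
    in the active state."""
    traj = frame.trajectory
    pts = []
    for label in ("5.58", "7.53"):
        chain, rid = rmap.resolve(label)
        if not traj.has_atom(chain, rid, "CA"):
            raise MissingAtomError(f"{label} ({chain}/{rid}) lacks CA")
        pts.append(frame.coords[traj.atom_index(chain, rid, "CA")])
    return float(np.linalg.norm(pts[0] - pts[1]))


def tm5_tm7_series(traj: Trajectory, rmap: ResidueMap) -> DistanceSeries:
    vals = [tm5_tm7_distance(traj.frame(i), rmap)
            for i in range(traj.n_frames)]
    return DistanceSeries("Y5.58-Y7.53", traj.times, np.array(vals))


def coupling_selections(traj: Trajectory, rmap: ResidueMap,
                        alpha5_residues: Sequence[tuple[str, int]],
                        receptor_labels: Sequence[str] = COUPLING_RECEPTOR_LABELS
                        ) -> tuple[Selection, Selection]:
    """The two C-alpha probe selections of the coupling distance: five
    intracellular receptor residues and the C-terminal five alpha5
    residues of the G-alpha subunit."""
    rec = Selection.ca_of(traj, [rmap.resolve(l) for l in receptor_labels],
                          "receptor-probe")
    g = Selection.ca_of(traj, alpha5_residues, "alpha5-probe")
    return rec, g


def coupling_distance_series(traj: Trajectory, rmap: ResidueMap,
                             alpha5_residues: Sequence[tuple[str, int]]
                             ) -> DistanceSeries:
    rec, g = coupling_selections(traj, rmap, alpha5_residues)
    return com_distance_series(traj, rec, g, "receptor-alpha5")


def coupling_trend(series: DistanceSeries,
                   threshold: float = 0.0005,
                   window: slice | None = None) -> CouplingTrend:
    """Fit the best-fit (ordinary least squares) line through the
    receptor-alpha5 distance-vs-time points and classify its sign."""
    sl = window or slice(None)
    t = series.times[sl]
    d = series.values[sl]
    if len(t) < 2 or float(np.ptp(t)) == 0.0:
        raise DegenerateInputError(
            "coupling trend needs >=2 frames with time variance")
    fit = stats.linregress(t, d)
    return CouplingTrend(slope=float(fit.slope), intercept=float(fit.intercept),
                         threshold=float(threshold), stderr=float(fit.stderr),
                         r_value=float(fit.rvalue))


def _sidechain_centroid(frame: Frame, chain: str, rid: int) -> np.ndarray:
    traj = frame.trajectory
    idx = traj.residue_indices(chain, rid, heavy_only=True, sidechain_only=True)
    if len(idx) == 0:
        # Gly has no side chain; fall back to the C-alpha position
        logger.warning("residue %s/%s has no side-chain heavy atoms; "
                       "using CA", chain, rid)
        warnings.warn(f"residue {chain}/{rid} has no side chain; using CA",
                      stacklevel=2)
        idx = traj.residue_indices(chain, rid, heavy_only=True)
        idx = idx[traj.atom_names[idx].astype(str) == "CA"]
        if len(idx) == 0:
            raise MissingAtomError(f"residue {chain}/{rid} lacks CA fallback")
    return frame.coords[idx].mean(axis=0)


def interface_residue_distances(traj: Trajectory,
                                pairs: Sequence[tuple[tuple[str, int],
                                                      tuple[str, int]]],
                                window: slice | None = None
                                ) -> dict[tuple, tuple[float, float]]:
    """Side-chain-centroid distance per residue pair: time mean +/- sd over
    the window (e.g. ICL3 R233 vs the G-alpha contact residues)."""
    sl = window or slice(None)
    frames = range(*sl.indices(traj.n_frames))
    if len(frames) == 0:
        raise DegenerateInputError("empty frame window")
    out = {}
    for (res_a, res_b) in pairs:
        d = np.array([
            np.linalg.norm(_sidechain_centroid(traj.frame(i), *res_a)
                           - _sidechain_centroid(traj.frame(i), *res_b))
            for i in frames
        ])
        out[(tuple(res_a), tuple(res_b))] = (float(d.mean()), float(d.std()))
    return out


def hbond_present(frame: Frame, donor_residue: tuple[str, int],
                  acceptor_residue: tuple[str, int],
                  cutoff: float = 3.5
                  ) -> tuple[bool, tuple[str, str, float]]:
    """Heavy-atom hydrogen-bond check between two residues.

    True if any polar-heavy (N/O) atom pair across the residues sits within
    the cutoff (default 3.5 A); returns the minimising pair.  No angular
    term: hydrogens are routinely absent from the input coordinates.
    """
    traj = frame.trajectory
    out_pairs = []
    for res in (donor_residue, acceptor_residue):
        idx = traj.residue_indices(*res, heavy_only=True)
        polar = idx[np.isin(traj.elements[idx].astype(str),
                            list(_POLAR_ELEMENTS))]
        if len(polar) == 0:
            return False, ("", "", float("inf"))
        out_pairs.append(polar)
    da, aa = out_pairs
    d = cdist(frame.coords[da], frame.coords[aa])
    i, j = np.unravel_index(np.argmin(d), d.shape)
    best = (str(traj.atom_names[da[i]]), str(traj.atom_names[aa[j]]),
            float(d[i, j]))
    return bool(d[i, j] <= cutoff), best
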