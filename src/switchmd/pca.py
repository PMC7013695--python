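"""C-alpha principal component analysis and covariance-matrix overlap.

Essential-dynamics style PCA: frames are least-squares superposed onto
their average structure (two passes: fit to frame 0, average, re-fit to
the average), the 3N x 3N coordinate covariance of an analysis selection
is accumulated *non-mass-weighted*, and frames are projected onto the
leading eigenvectors.  Simulations are compared through the normalised
covariance overlap

    overlap(A, B) = 1 - sqrt( tr((A^1/2 - B^1/2)^2) / (tr A + tr B) )

which is 1 for identical matrices and 0 when the sampled subspaces are
mutually orthogonal.  Matrix square roots come from the symmetric
eigendecomposition with negative eigenvalues clipped to zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError, GeometryError
from .geometry import Selection, superpose
from .io import Trajectory

_EIG_CLIP = -1e-8


@dataclasses.dataclass
class CovarianceResult:
    """Coordinate covariance of an analysis selection plus everything
    needed to project further frames into the same subspace."""

    matrix: np.ndarray          # (3N, 3N), A^2
    mean: np.ndarray            # (3N,) mean structure of the analysis atoms
    reference: np.ndarray       # (n_atoms, 3) fitted average full structure
    fit_selection: Selection
    analysis_selection: Selection
    n_frames: int


@dataclasses.dataclass
class PCAResult:
    mean_structure: np.ndarray   # (3N,)
    eigenvalues: np.ndarray      # descending, A^2, clipped at 0
    eigenvectors: np.ndarray     # (3N, 3N), columns orthonormal
    projections: np.ndarray      # (frames, components), A
    times: np.ndarray
    extreme_frames: tuple[int, int] = (0, 0)  # argmin/argmax along PC1

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot == 0:
            raise DegenerateInputError("zero total variance")
        return self.eigenvalues / tot


def _superpose_all(traj: Trajectory, fit_selection: Selection
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass fit of every frame: to frame 0, then to the average.

    Returns (fitted coordinates, the average structure used as the final
    fitting target) — re-fitting any original frame onto that target
    reproduces its fitted coordinates exactly, which keeps later
    projections in the covariance's coordinate system.
    """
    fitted = np.empty_like(traj.coords)
    ref = traj.coords[0]
    for i in range(traj.n_frames):
        fitted[i], _, _ = superpose(traj.coords[i], ref, fit_selection)
    target = fitted.mean(axis=0)
    for i in range(traj.n_frames):
        fitted[i], _, _ = superpose(traj.coords[i], target, fit_selection)
    return fitted, target


def build_covariance(traj: Trajectory, fit_selection: Selection,
                     analysis_selection: Selection | None = None
                     ) -> CovarianceResult:
    """Non-mass-weighted covariance of the analysis C-alpha coordinates
    about their time mean, after superposition on the fit selection."""
    if traj.n_frames < 2:
        raise DegenerateInputError("covariance needs >=2 frames")
    analysis = analysis_selection or fit_selection
    fitted, target = _superpose_all(traj, fit_selection)
    x = fitted[:, analysis.indices, :].reshape(traj.n_frames, -1)
    mean = x.mean(axis=0)
    dx = x - mean
    cov = dx.T @ dx / traj.n_frames
    return CovarianceResult(cov, mean, target,
                            fit_selection, analysis, traj.n_frames)


def pca_project(cov: CovarianceResult, traj: Trajectory,
                window: slice | None = None,
                n_components: int | None = None) -> PCAResult:
    """Eigendecompose a covariance and project (a window of) a trajectory
    onto the principal components.

    The window (frame slice) mirrors analyses restricted to the late,
    equilibrated part of a simulation.  Frames are re-superposed onto the
    covariance's reference structure so projections live in the same
    coordinate system the covariance was built in.
    """
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals.size and evals.min() < _EIG_CLIP * max(1.0, abs(evals.max())):
        raise GeometryError("covariance matrix is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    sl = window or slice(None)
    frames = range(*sl.indices(traj.n_frames))
    if len(frames) == 0:
        raise DegenerateInputError("projection window outside trajectory")
    k = n_components or len(evals)
    proj = np.empty((len(frames), k))
    times = np.empty(len(frames))
    for row, i in enumerate(frames):
        fitted, _, _ = superpose(traj.coords[i], cov.reference,
                                 cov.fit_selection)
        x = fitted[cov.analysis_selection.indices].ravel() - cov.mean
        proj[row] = x @ evecs[:, :k]
        times[row] = traj.times[i]
    extremes = (int(np.argmin(proj[:, 0])), int(np.argmax(proj[:, 0])))
    return PCAResult(cov.mean.copy(), evals, evecs, proj, times, extremes)


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(mat)
    evals = np.clip(evals, 0.0, None)
    return (evecs * np.sqrt(evals)) @ evecs.T


def covariance_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised covariance overlap of two PSD matrices, in [0, 1].

    1 when the matrices are identical; 0 when the sampled subspaces are
    totally orthogonal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GeometryError(f"covariance shape mismatch: {a.shape} vs {b.shape}")
    tra, trb = float(np.trace(a)), float(np.trace(b))
    if tra + trb <= 0:
        raise DegenerateInputError("both covariances have zero trace")
    d = _psd_sqrt(a) - _psd_sqrt(b)
    num = max(float(np.trace(d @ d)), 0.0)
    return float(np.clip(1.0 - np.sqrt(num / (tra + trb)), 0.0, 1.0))


@dataclasses.dataclass
class OverlapMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def as_dict(self) -> dict:
        return {"labels": self.labels, "values": self.values.tolist()}


def overlap_matrix(covariances: dict[str, np.ndarray] | list,
                   labels: list[str] | None = None) -> OverlapMatrix:
    """Pairwise normalised covariance overlaps across simulations."""
    if isinstance(covariances, dict):
        labels = list(covariances)
        mats = [covariances[l] for l in labels]
    else:
        mats = list(covariances)
        labels = labels or [f"traj{i}" for i in range(len(mats))]
    n = len(mats)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = covariance_overlap(mats[i], mats[j])
    return OverlapMatrix(labels, out)
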