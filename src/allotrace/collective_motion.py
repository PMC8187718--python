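"""Essential-dynamics PCA of positional fluctuations and porcupine vectors.

The covariance matrix of Cα fluctuations about an iteratively refined mean
(rigid-body motion removed by least-squares fitting) is diagonalized; the
leading eigenvectors are the dominant collective motions. Eigenvalues are
Å² internally and reported in nm² (÷100) at the output boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_superpose
from .structure_io import Selection, Trajectory, resolve_selection

__all__ = ["ModeSet", "PorcupineField", "fit_to_mean", "build_covariance",
           "eigendecompose", "pca", "porcupine"]


@dataclass
class ModeSet:
    """Leading eigenpairs of the positional covariance matrix."""

    mean_structure: np.ndarray  # (n_sel, 3), Å
    eigenvalues: np.ndarray  # all 3n eigenvalues, descending, Å²
    eigenvectors: np.ndarray  # (3n, n_modes_kept), orthonormal columns
    n_modes_kept: int
    atom_indices: np.ndarray = field(default=None)  # selection indices into the topology

    @property
    def eigenvalues_nm2(self) -> np.ndarray:
        """Eigenvalues in nm² (1 nm² = 100 Å²)."""
        return self.eigenvalues / 100.0


@dataclass
class PorcupineField:
    """Filtered per-atom displacement arrows along one collective mode."""

    anchors: np.ndarray  # (k, 3) mean positions of retained atoms, Å
    vectors: np.ndarray  # (k, 3) displacements, Å
    atom_indices: np.ndarray  # retained selection-atom positions
    filter_cutoff: float  # Å


def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        selection = "calpha"
    if isinstance(selection, str):
        selection = resolve_selection(traj.topology, selection)
    return selection.indices


def fit_to_mean(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose frames onto their mean until the mean converges.

    Returns (fitted coordinates, converged mean). Removes rigid-body
    translation/rotation so the covariance captures internal motion only.
    Fitting needs ≥ 3 atoms; below that, frames are mean-centred only.
    """
    coords = np.asarray(coords, dtype=float).copy()
    n_frames, n_atoms, _ = coords.shape
    if n_atoms < 3:
        mean = coords.mean(axis=0)
        return coords, mean
    mean = coords[0].copy()
    for _ in range(max_iter):
        for f in range(n_frames):
            sup = kabsch_superpose(coords[f], mean)
            coords[f] = sup.apply(coords[f])
        new_mean = coords.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    return coords, mean


def build_covariance(
    traj: Trajectory, selection="calpha", fit: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance matrix (3n × 3n, Å²) of selected-atom fluctuations about the mean.

    Frames are least-squares fitted to the iteratively refined mean first
    (``fit=False`` skips the rigid-body removal, e.g. for < 3 atoms).
    Returns (covariance, mean structure, fitted frame coordinates).
    """
    idx = _selection_indices(traj, selection)
    if traj.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    coords = traj.frames[:, idx, :].copy()
    if fit and idx.size >= 3:
        coords, mean = fit_to_mean(coords)
    else:
        mean = coords.mean(axis=0)
    flat = coords.reshape(traj.n_frames, -1) - mean.reshape(1, -1)
    cov = flat.T @ flat / traj.n_frames
    cov = 0.5 * (cov + cov.T)
    return cov, mean, coords


def eigendecompose(covariance: np.ndarray, n_modes: int = 5, atom_indices=None,
                   mean_structure=None) -> ModeSet:
    """Top ``n_modes`` eigenpairs of a symmetric covariance matrix, descending."""
    c = np.asarray(covariance, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(1.0, float(np.abs(c).max()))
    if np.abs(c - c.T).max() > 1e-8 * scale:
        raise ValueError("covariance matrix is not symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (c + c.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    n_modes = min(n_modes, vals.size)
    mean = None if mean_structure is None else np.asarray(mean_structure, dtype=float)
    return ModeSet(
        mean_structure=mean,
        eigenvalues=vals,
        eigenvectors=vecs[:, :n_modes],
        n_modes_kept=n_modes,
        atom_indices=None if atom_indices is None else np.asarray(atom_indices),
    )


def pca(traj: Trajectory, selection="calpha", n_modes: int = 5) -> ModeSet:
    """Convenience: build_covariance + eigendecompose on one trajectory."""
    idx = _selection_indices(traj, selection)
    cov, mean, _ = build_covariance(traj, selection)
    return eigendecompose(cov, n_modes=n_modes, atom_indices=idx, mean_structure=mean)


def porcupine(
    modes: ModeSet, traj: Trajectory, mode: int = 1, cutoff: float = 4.0, selection="calpha"
) -> PorcupineField:
    """Per-atom displacement arrows spanning the extremes of one mode.

    The trajectory is projected onto the mode (1-based index); the
    displacement field is the eigenvector scaled by (max − min) projection,
    mapped to one 3-vector per selected atom. Arrows shorter than ``cutoff``
    (default 4 Å) are discarded.
    """
    if mode < 1 or mode > modes.n_modes_kept:
        raise ValueError(f"mode {mode} outside kept range 1..{modes.n_modes_kept}")
    idx = modes.atom_indices if modes.atom_indices is not None else _selection_indices(traj, selection)
    coords, mean = fit_to_mean(traj.frames[:, idx, :].copy())
    flat = coords.reshape(traj.n_frames, -1) - mean.reshape(1, -1)
    vec = modes.eigenvectors[:, mode - 1]
    proj = flat @ vec
    span = float(proj.max() - proj.min())
    disp = (span * vec).reshape(-1, 3)
    mag = np.linalg.norm(disp, axis=1)
    keep = mag >= cutoff
    return PorcupineField(
        anchors=mean[keep],
        vectors=disp[keep],
        atom_indices=np.flatnonzero(keep),
        filter_cutoff=float(cutoff),
    )
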