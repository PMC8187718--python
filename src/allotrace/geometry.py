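"""Superposition, RMSD, 2D-RMSD matrices, dihedrals, residue distances.

Superposition is least-squares optimal (Kabsch via SVD, reflection
corrected); all RMSD reporting is pairwise-superposed. Units: Å, degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Selection, Structure, Trajectory, resolve_selection

__all__ = [
    "SuperpositionResult",
    "RmsdMatrix",
    "kabsch_superpose",
    "rmsd_series",
    "rmsd_matrix_2d",
    "dihedral",
    "min_residue_distance",
    "sidechain_dihedral_series",
    "SIDECHAIN_DIHEDRALS",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: x ↦ rotation @ (x − mobile centroid) + reference centroid."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdMatrix:
    """All-pairs superposed RMSD between frames of two trajectories (Å)."""

    values: np.ndarray  # (n_A, n_B), Å
    axis_A: np.ndarray
    axis_B: np.ndarray

    @property
    def values_nm(self) -> np.ndarray:
        return self.values / 10.0

    def to_tsv(self, path) -> None:
        header = "\t".join(str(b) for b in self.axis_B)
        np.savetxt(path, self.values, delimiter="\t", header=header, comments="# ")

    def to_png(self, path, unit: str = "nm") -> None:
        """Render the matrix as a colour map (frame × frame, blue→red)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        values = self.values_nm if unit == "nm" else self.values
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(values, origin="lower", aspect="auto", cmap="jet",
                       extent=[self.axis_B[0], self.axis_B[-1],
                               self.axis_A[0], self.axis_A[-1]])
        fig.colorbar(im, ax=ax, label=f"RMSD ({unit})")
        ax.set_xlabel("frame B")
        ax.set_ylabel("frame A")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _check_points(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{label}: expected (n, 3) coordinates, got {x.shape}")
    return x


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Kabsch algorithm via SVD with determinant sign correction; weights
    default to uniform. Requires ≥ 3 non-collinear points.
    """
    mobile = _check_points(mobile, "mobile")
    reference = _check_points(reference, "reference")
    if mobile.shape[0] != reference.shape[0]:
        raise ValueError(f"point-count mismatch: {mobile.shape[0]} vs {reference.shape[0]}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    # covariance of the two point clouds
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if np.allclose(s, 0.0):
        raise ValueError("degenerate point set (all points coincident)")
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - y) ** 2, axis=1))))
    translation = cr - rot @ cm
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def _as_selection(traj: Trajectory, selection: Selection | str | None) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    if isinstance(selection, str):
        selection = resolve_selection(traj.topology, selection)
    return selection.indices


def rmsd_series(
    traj: Trajectory, reference_frame: int = 0, selection: Selection | str | None = None
) -> np.ndarray:
    """Per-frame superposed RMSD (Å) against a reference frame of the same trajectory."""
    idx = _as_selection(traj, selection)
    ref = traj.frames[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_superpose(traj.frames[f][idx], ref).rmsd
    return out


def rmsd_matrix_2d(
    traj_A: Trajectory, traj_B: Trajectory, selection: Selection | str | None = None
) -> RmsdMatrix:
    """All-pairs superposed RMSD between frames of two trajectories.

    Each (i, j) pair is superposed independently — entries measure mutual
    structural similarity, not distance to a common reference.
    """
    idx_a = _as_selection(traj_A, selection)
    idx_b = _as_selection(traj_B, selection)
    if idx_a.size != idx_b.size:
        raise ValueError(
            f"selection resolves to {idx_a.size} atoms in A but {idx_b.size} in B"
        )
    a = traj_A.frames[:, idx_a, :]
    b = traj_B.frames[:, idx_b, :]
    values = np.empty((traj_A.n_frames, traj_B.n_frames))
    same = traj_A is traj_B and np.array_equal(idx_a, idx_b)
    for i in range(traj_A.n_frames):
        j0 = i if same else 0
        for j in range(j0, traj_B.n_frames):
            values[i, j] = kabsch_superpose(a[i], b[j]).rmsd
        if same:
            values[i, i] = 0.0
            values[i + 1:, i] = values[i, i + 1:]
    times_a = traj_A.frame_times if traj_A.frame_times is not None else np.arange(traj_A.n_frames)
    times_b = traj_B.frame_times if traj_B.frame_times is not None else np.arange(traj_B.n_frames)
    return RmsdMatrix(values=values, axis_A=np.asarray(times_a), axis_B=np.asarray(times_b))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention (cis = 0°).

    Range (−180, 180]. Raises on degenerate geometry (collinear triples or
    coincident consecutive points).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, label in ((b1, b2, "p1-p2-p3"), (b2, b3, "p2-p3-p4")):
        if np.linalg.norm(a) < 1e-10 or np.linalg.norm(b) < 1e-10:
            raise ValueError("coincident consecutive points in dihedral")
        if np.linalg.norm(np.cross(a, b)) < 1e-10 * np.linalg.norm(a) * np.linalg.norm(b):
            raise ValueError(f"collinear points {label}: dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


#: Side-chain torsion quadruples for the charged residues tracked in the
#: TMD–NBD communication analysis (His: Cα-Cβ-Cγ-Cδ2, Arg: Cδ-Nε-Cζ-Nη2,
#: Glu: Cβ-Cγ-Cδ-Oε1).
SIDECHAIN_DIHEDRALS = {
    "HIS": ("CA", "CB", "CG", "CD2"),
    "ARG": ("CD", "NE", "CZ", "NH2"),
    "GLU": ("CB", "CG", "CD", "OE1"),
}


def sidechain_dihedral_series(
    traj: Trajectory, residue_id: int, atom_names: tuple[str, str, str, str] | None = None
) -> np.ndarray:
    """Per-frame side-chain torsion (degrees) for one residue.

    The atom quadruple defaults to the residue type's entry in
    :data:`SIDECHAIN_DIHEDRALS`.
    """
    top = traj.topology
    idx = top.residue_atom_indices(residue_id)
    if not idx:
        raise ValueError(f"residue {residue_id} not found in topology")
    resname = top.atoms[idx[0]].residue_name
    if atom_names is None:
        if resname not in SIDECHAIN_DIHEDRALS:
            raise ValueError(f"no default dihedral atoms for residue type {resname}")
        atom_names = SIDECHAIN_DIHEDRALS[resname]
    by_name = {top.atoms[i].name: i for i in idx}
    try:
        quad = [by_name[n] for n in atom_names]
    except KeyError as exc:
        raise ValueError(f"residue {residue_id} ({resname}) is missing atom {exc}") from None
    return np.array([
        dihedral(*(traj.frames[f][i] for i in quad)) for f in range(traj.n_frames)
    ])


_HEAVY = ("C", "N", "O", "S", "P")

#: Heavy atoms of the ionizable groups used for salt-bridge distances.
CHARGED_GROUP_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def _residue_coords(
    frame: np.ndarray, topology: Structure, residue_id: int, atom_subset: str
) -> np.ndarray:
    idx = topology.residue_atom_indices(residue_id)
    if not idx:
        raise ValueError(f"residue {residue_id} not found in topology")
    atoms = [topology.atoms[i] for i in idx]
    if atom_subset == "all":
        keep = idx
    elif atom_subset == "heavy":
        keep = [i for i, a in zip(idx, atoms) if not a.name.startswith("H") and a.element != "H"]
    elif atom_subset == "charged-group":
        resname = atoms[0].residue_name
        group = CHARGED_GROUP_ATOMS.get(resname)
        if group is None:
            raise ValueError(f"residue {residue_id} ({resname}) has no ionizable group")
        keep = [i for i, a in zip(idx, atoms) if a.name in group]
        if not keep:
            raise ValueError(f"residue {residue_id} ({resname}) is missing its ionizable-group atoms")
    else:
        raise ValueError(f"unknown atom_subset '{atom_subset}' (use all|heavy|charged-group)")
    if not keep:
        raise ValueError(f"residue {residue_id}: no atoms left under subset '{atom_subset}'")
    return frame[keep]


def min_residue_distance(
    frame: np.ndarray,
    topology: Structure,
    residue_A: int,
    residue_B: int,
    atom_subset: str = "heavy",
) -> float:
    """Minimum pairwise distance (Å) between two residues' selected atoms."""
    a = _residue_coords(frame, topology, residue_A, atom_subset)
    b = _residue_coords(frame, topology, residue_B, atom_subset)
    return float(cdist(a, b).min())
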