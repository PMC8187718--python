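"""Interhelical opening angles and helix bend (kink) angles.

The interhelical opening angle uses three anchor Cα atoms — one at the
C-terminus of the first helix, one in the connecting loop, one at the
N-terminus of the second helix — and measures the angle between the two
loop-to-helix vectors. Bend angles compare least-squares axes of the
helical segments flanking a pivot residue (HELANAL-style local kink).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TestResult, replica_aggregate, two_sample_test
from .structure_io import Structure, Trajectory

__all__ = ["HelixAxis", "AngleSeries", "interhelical_angle", "interhelical_angle_series",
           "helix_axis", "bend_angle_at", "bend_angle_series", "angle_statistics"]


@dataclass
class HelixAxis:
    """A fitted helix axis: a point on it, a unit direction (N→C), and fit RMS."""

    point: np.ndarray  # (3,), Å
    direction: np.ndarray  # unit 3-vector
    residue_range: tuple[int, int]
    fit_rms: float  # Å, perpendicular scatter of smoothed trace about the line


@dataclass
class AngleSeries:
    """Per-frame angle values (degrees) for one replica."""

    values: np.ndarray
    replica_id: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float | None:
        if self.values.size < 2:
            return None
        return float(np.std(self.values, ddof=1))


def _ca_position(frame: np.ndarray, topology: Structure, residue_id: int) -> np.ndarray:
    for i in topology.residue_atom_indices(residue_id):
        if topology.atoms[i].name == "CA":
            return frame[i]
    raise ValueError(f"residue {residue_id}: no CA atom in topology")


def interhelical_angle(
    frame: np.ndarray,
    topology: Structure,
    res_cterm: int = 571,
    res_loop: int = 574,
    res_nterm: int = 577,
) -> float:
    """Opening angle (degrees) at the loop anchor between the two helix anchors.

    Defaults are the MRP1 helix-10/ECL5/helix-11 anchors (I571, N574, I577).
    """
    a = _ca_position(frame, topology, res_cterm)
    b = _ca_position(frame, topology, res_loop)
    c = _ca_position(frame, topology, res_nterm)
    v1 = a - b
    v2 = c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-8 or n2 < 1e-8:
        raise ValueError("coincident anchor residues: angle undefined")
    cosang = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interhelical_angle_series(
    traj: Trajectory, res_cterm: int = 571, res_loop: int = 574, res_nterm: int = 577,
    replica_id: int | None = None,
) -> AngleSeries:
    vals = np.array([
        interhelical_angle(traj.frames[f], traj.topology, res_cterm, res_loop, res_nterm)
        for f in range(traj.n_frames)
    ])
    return AngleSeries(values=vals, replica_id=replica_id)


def _ca_trace(frame: np.ndarray, topology: Structure, first: int, last: int) -> np.ndarray:
    pts = []
    for rid in range(first, last + 1):
        try:
            pts.append(_ca_position(frame, topology, rid))
        except ValueError:
            continue
    return np.asarray(pts, dtype=float)


def helix_axis(frame: np.ndarray, topology: Structure, residue_range: tuple[int, int]) -> HelixAxis:
    """Axis of a helical segment, oriented N→C terminus.

    Uses the bisector construction: at each interior Cα the bisector of the
    two bond vectors points at the helix axis, and cross products of
    consecutive bisectors lie along it — exact on ideal helical geometry at
    any segment length, which a raw principal-component line fit is not
    (the unbalanced spiral phase tilts it by several degrees on short
    windows). Near-degenerate traces (straight or zig-zag, where the cross
    products vanish) fall back to the least-squares line.
    """
    first, last = residue_range
    pts = _ca_trace(frame, topology, first, last)
    if pts.shape[0] < 4:
        raise ValueError(f"helix axis needs ≥ 4 Cα atoms in {first}-{last}, found {pts.shape[0]}")
    chain_dir = pts[-1] - pts[0]
    # estimate the twist per residue from consecutive bond-vector bisectors
    bis = []
    for i in range(1, len(pts) - 1):
        v = (pts[i - 1] - pts[i]) + (pts[i + 1] - pts[i])
        n = np.linalg.norm(v)
        if n > 1e-10:
            bis.append(v / n)
    twists = [
        float(np.arccos(np.clip(b1 @ b2, -1.0, 1.0))) for b1, b2 in zip(bis[:-1], bis[1:])
    ]
    twist = float(np.mean(twists)) if twists else 0.0
    if 0.35 < twist < 2.8:
        # 4-tap symmetric smoothing [a b b a] nulling the spiral frequency
        # exactly: a·cos(1.5·twist) + b·cos(0.5·twist) = 0
        a = np.cos(0.5 * twist)
        b = -np.cos(1.5 * twist)
        w = np.array([a, b, b, a])
        w = w / w.sum()
        line_pts = np.array([w @ pts[i:i + 4] for i in range(len(pts) - 3)])
    else:
        # straight or zig-zag trace: no spiral to cancel
        line_pts = pts
    centred = line_pts - line_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction @ chain_dir < 0:
        direction = -direction
    centroid = pts.mean(axis=0)
    # residual: spread of radial distances about the mean radius (0 for an
    # ideal helix, grows with coordinate noise)
    perp = (pts - centroid) - np.outer((pts - centroid) @ direction, direction)
    radii = np.linalg.norm(perp, axis=1)
    fit_rms = float(np.std(radii))
    return HelixAxis(point=centroid, direction=direction, residue_range=(first, last),
                     fit_rms=fit_rms)


def bend_angle_at(
    frame: np.ndarray, topology: Structure, pivot_residue: int, window: int = 6
) -> float:
    """Kink angle (degrees, [0, 180]) between the helix axes flanking a pivot.

    The N-side axis fits residues pivot−window … pivot−1, the C-side axis
    residues pivot+1 … pivot+window; the angle between their N→C directions
    is 0 for a straight helix.
    """
    ax_n = helix_axis(frame, topology, (pivot_residue - window, pivot_residue - 1))
    ax_c = helix_axis(frame, topology, (pivot_residue + 1, pivot_residue + window))
    cosang = np.clip(ax_n.direction @ ax_c.direction, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def bend_angle_series(
    traj: Trajectory, pivot_residue: int, window: int = 6, replica_id: int | None = None
) -> AngleSeries:
    vals = np.array([
        bend_angle_at(traj.frames[f], traj.topology, pivot_residue, window)
        for f in range(traj.n_frames)
    ])
    return AngleSeries(values=vals, replica_id=replica_id)


def angle_statistics(
    series_A: list[AngleSeries], series_B: list[AngleSeries], test: str = "mann-whitney",
    stride: int = 1,
) -> dict:
    """Replica-level mean ± SD per condition plus a two-sample distribution test.

    Per-condition summaries aggregate replica means (SD over replica means,
    n−1 denominator, absent for one replica); the test pools frames across
    replicas, optionally strided to thin autocorrelated samples.
    """
    if not series_A or not series_B:
        raise ValueError("each condition needs at least one replica series")
    for s in series_A + series_B:
        if s.values.size == 0:
            raise ValueError("empty angle series")
    agg_a = replica_aggregate([s.values for s in series_A])
    agg_b = replica_aggregate([s.values for s in series_B])
    pooled_a = np.concatenate([s.values[::stride] for s in series_A])
    pooled_b = np.concatenate([s.values[::stride] for s in series_B])
    result: TestResult = two_sample_test(pooled_a, pooled_b, method=test)
    return {
        "mean_A": agg_a[0], "sd_A": agg_a[1],
        "mean_B": agg_b[0], "sd_B": agg_b[1],
        "test": result,
    }
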