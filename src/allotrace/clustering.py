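"""GROMOS (Daura) conformational clustering of trajectory frames.

All-pairs superposed RMSD on a selection; the frame with the most
neighbours within the cutoff seeds each cluster, it and its neighbours are
removed, and the loop repeats. Clusters are renumbered 1, 2, … by
descending size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structure_io import Selection, Trajectory, resolve_selection

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "gromos_cluster", "cluster_timeline",
           "average_occupancies"]


@dataclass
class ClusterResult:
    """Per-frame labels (1 = largest cluster), occupancies, centroid frames."""

    labels: np.ndarray  # (n_frames,), int, 1-based
    occupancy: np.ndarray  # per-cluster fraction of frames, descending
    representatives: np.ndarray  # per-cluster centroid frame index
    cutoff: float  # Å

    @property
    def n_clusters(self) -> int:
        return int(self.occupancy.size)


def pairwise_rmsd_matrix(traj: Trajectory, selection: Selection | str | None = None) -> np.ndarray:
    """Symmetric all-pairs superposed RMSD (Å) between frames of one trajectory."""
    if isinstance(selection, str):
        selection = resolve_selection(traj.topology, selection)
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    if idx.size == 0:
        raise ValueError("empty selection")
    coords = traj.frames[:, idx, :]
    n = traj.n_frames
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kabsch_superpose(coords[i], coords[j]).rmsd
    return d


def gromos_cluster(
    traj: Trajectory,
    selection: Selection | str | None = None,
    cutoff: float = 3.0,
) -> ClusterResult:
    """Greedy neighbour-count clustering at an RMSD ``cutoff`` (Å, default 3).

    Ties in neighbour count are broken toward the lowest frame index, so the
    result is deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = pairwise_rmsd_matrix(traj, selection)
    n = d.shape[0]
    neighbours = d <= cutoff  # includes self
    remaining = np.ones(n, dtype=bool)
    labels = np.zeros(n, dtype=int)
    reps: list[int] = []
    sizes: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbours[centre] & remaining)
        cluster += 1
        labels[members] = cluster
        reps.append(centre)
        sizes.append(members.size)
        remaining[members] = False
    # renumber by descending size; ties keep discovery order (stable)
    order = np.argsort(-np.asarray(sizes), kind="stable")
    remap = np.empty(cluster, dtype=int)
    remap[order] = np.arange(1, cluster + 1)
    labels = remap[labels - 1]
    occupancy = np.asarray(sizes, dtype=float)[order] / n
    representatives = np.asarray(reps, dtype=int)[order]
    return ClusterResult(labels=labels, occupancy=occupancy,
                         representatives=representatives, cutoff=float(cutoff))


def cluster_timeline(
    result: ClusterResult, frame_times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(time, cluster index) series for timeline plots."""
    n = result.labels.size
    times = np.asarray(frame_times, dtype=float) if frame_times is not None else np.arange(n, dtype=float)
    if times.shape != (n,):
        raise ValueError("frame_times length must equal number of frames")
    return times, result.labels.copy()


def average_occupancies(results: list[ClusterResult], n_clusters: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean ± SD of per-replica occupancy vectors after size-rank alignment.

    Cluster k of each replica is aligned to cluster k of the others (both are
    rank-k by size); shorter vectors are zero-padded. SD uses the n−1
    denominator and is NaN for a single replica.
    """
    if not results:
        raise ValueError("no cluster results given")
    width = n_clusters or max(r.n_clusters for r in results)
    mat = np.zeros((len(results), width))
    for i, r in enumerate(results):
        k = min(width, r.n_clusters)
        mat[i, :k] = r.occupancy[:k]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(results) > 1 else np.full(width, np.nan)
    return mean, sd
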