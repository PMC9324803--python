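"""Pairwise Calpha-RMSD matrix and GROMOS conformational clustering.

The GROMOS algorithm peels clusters off iteratively: among unassigned
frames, the one with the most neighbors within the cutoff becomes the next
cluster center and is removed together with its neighbors; ties in neighbor
count go to the lowest frame index.  Cluster ids follow discovery order, and
the medoid (member minimizing summed intra-cluster distance, lowest index on
ties) is recomputed within each final cluster — downstream single-point
analyses always consume the medoid.

The default cutoff is 2.0 A Calpha RMSD; matrices are stored dense, so
trajectories should be strided to a few thousand frames at most before
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Trajectory
from .structure_metrics import superpose

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "rmsd_matrix",
    "gromos_cluster",
    "medoid_frame",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 2.0


@dataclass
class DistanceMatrix:
    """Symmetric all-against-all RMSD matrix (Angstrom, zero diagonal)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0.0, atol=1e-6):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster id in discovery order
    sizes: list[int]
    centers: list[int]  # peeling centers (max-neighbor frames)
    medoids: list[int]  # recomputed within each final cluster
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def rmsd_matrix(traj: Trajectory, selection: Sequence[int] | None = None) -> DistanceMatrix:
    """Pairwise superposed RMSD between all frame pairs over ``selection``."""
    if traj.n_frames < 2:
        raise ValueError("rmsd_matrix needs at least 2 frames")
    n = traj.n_frames
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(traj.frames[i], traj.frames[j], selection).rmsd
            values[i, j] = values[j, i] = r
    return DistanceMatrix(values)


def gromos_cluster(matrix: DistanceMatrix | np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> ClusterResult:
    """GROMOS neighbor-peeling clustering of a distance matrix."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dm = matrix.values if isinstance(matrix, DistanceMatrix) else DistanceMatrix(matrix).values
    n = dm.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    within = dm <= cutoff
    np.fill_diagonal(within, False)
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    sizes: list[int] = []
    centers: list[int] = []
    cluster_id = 0
    while unassigned.any():
        neighbor_counts = (within & unassigned).sum(axis=1)
        neighbor_counts[~unassigned] = -1
        center = int(np.argmax(neighbor_counts))  # argmax takes lowest index on ties
        members = np.nonzero(unassigned & (within[center] | (np.arange(n) == center)))[0]
        labels[members] = cluster_id
        unassigned[members] = False
        sizes.append(len(members))
        centers.append(center)
        cluster_id += 1
    medoids = [
        medoid_frame(np.nonzero(labels == c)[0], dm) for c in range(cluster_id)
    ]
    assert sum(sizes) == n
    return ClusterResult(labels, sizes, centers, medoids, float(cutoff))


def medoid_frame(members: Sequence[int], matrix: DistanceMatrix | np.ndarray) -> int:
    """Member minimizing summed distance to the other members (ties: lowest)."""
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("empty member set")
    dm = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix)
    sub = dm[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])
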