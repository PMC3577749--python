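"""Pairwise-RMSD single-linkage clustering of trajectory frames.

Single linkage at a cutoff is realized as the connected components of the
threshold graph with an edge wherever the fitted RMSD is *strictly* below
the cutoff.  The cutoff-selection rule accepts the smallest candidate that
yields fewer than ``max_clusters`` clusters or a largest cluster holding at
most ``max_top_fraction`` percent of the frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import PepdimerError
from .geometry import rmsd_after_fit
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "single_linkage_cluster",
    "select_cutoff",
    "representative_structure",
]


@dataclass
class DistanceMatrix:
    """Symmetric frame-to-frame RMSD matrix (Å) with a selection tag."""

    d: np.ndarray
    subset_tag: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-8):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster id, 0..n_clusters-1, by size desc
    populations: np.ndarray  # % of frames per cluster, descending
    representatives: np.ndarray  # medoid frame index per cluster
    cutoff: float
    n_clusters: int


def pairwise_rmsd_matrix(
    traj: Trajectory,
    subset: Sequence[int],
    stride: int = 1,
    subset_tag: str = "",
) -> DistanceMatrix:
    """All-pairs fitted RMSD over ``subset`` atoms, frames subsampled at
    ``stride`` (the ensemble convention is one frame per 240 ps)."""
    idx = np.asarray(subset, dtype=int)
    frames = traj.coords[::stride]
    n = frames.shape[0]
    if n < 2:
        raise PepdimerError("need at least 2 frames to build a distance matrix")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rmsd_after_fit(frames[i], frames[j], idx, idx)
    return DistanceMatrix(d=d, subset_tag=subset_tag)


def _labels_by_size(raw_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel components by descending size; ties by smallest member index."""
    ids, counts = np.unique(raw_labels, return_counts=True)
    first_member = np.array([int(np.argmax(raw_labels == c)) for c in ids])
    order = np.lexsort((first_member, -counts))
    remap = {int(ids[k]): rank for rank, k in enumerate(order)}
    labels = np.array([remap[int(c)] for c in raw_labels], dtype=int)
    sizes = counts[order]
    return labels, sizes


def single_linkage_cluster(m: DistanceMatrix, cutoff: float) -> ClusterResult:
    """Connected components of the graph with edges where d < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adj = csr_matrix(m.d < cutoff)
    _, raw = connected_components(adj, directed=False)
    labels, sizes = _labels_by_size(raw)
    populations = 100.0 * sizes / m.n
    reps = np.array(
        [
            representative_structure(m, np.where(labels == c)[0])
            for c in range(len(sizes))
        ],
        dtype=int,
    )
    return ClusterResult(
        labels=labels,
        populations=populations,
        representatives=reps,
        cutoff=cutoff,
        n_clusters=len(sizes),
    )


def select_cutoff(
    m: DistanceMatrix,
    candidates: Sequence[float],
    max_clusters: int = 10,
    max_top_fraction: float = 30.0,
) -> tuple[float, ClusterResult]:
    """Smallest candidate cutoff whose clustering satisfies the rule:
    fewer than ``max_clusters`` clusters OR largest cluster holding no more
    than ``max_top_fraction`` percent of the population.

    Falls back to the last candidate (with a warning) if none qualifies.
    """
    if len(candidates) == 0:
        raise ValueError("candidate cutoff list is empty")
    cands = sorted(candidates)
    last = None
    for c in cands:
        result = single_linkage_cluster(m, c)
        last = (c, result)
        if result.n_clusters < max_clusters or result.populations[0] <= max_top_fraction:
            return c, result
    logger.warning(
        "no candidate cutoff satisfied the <%d clusters / <=%g%% rule; "
        "falling back to %g Å",
        max_clusters,
        max_top_fraction,
        cands[-1],
    )
    assert last is not None
    return last


def representative_structure(m: DistanceMatrix, members: Sequence[int]) -> int:
    """Medoid: member minimizing summed distance to the other members.
    Ties break toward the lowest frame index."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("cluster is empty")
    sub = m.d[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])
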