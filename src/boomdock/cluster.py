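"""Docked-pose ensemble clustering (Daura/GROMOS) and score summaries.

After rigid-body docking, the first N poses of each complex are merged into
one ensemble and clustered on pairwise RMSD with a fixed cutoff (0.3 nm by
convention); the central structure of the most populated cluster is carried
forward as the representative conformation.  Docked scores themselves are
inputs (engine output); the only score arithmetic here is averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import fitted_rmsd, rmsd as raw_rmsd
from .structio import Atom, PoseEnsemble, Residue

#: Angstrom per nanometre; RMSD values are reported in nm.
A_PER_NM = 10.0


@dataclass
class RMSDMatrix:
    """Symmetric matrix of pairwise pose RMSD values, in nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("RMSD values must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Cluster:
    members: frozenset[int]
    center: int

    def __post_init__(self):
        self.members = frozenset(self.members)
        if self.center not in self.members:
            raise ValueError("cluster center must be a member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cutoff: float
    ties: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        sizes = [c.size for c in self.clusters]
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("clusters must be ordered by non-increasing size")


def pairwise_rmsd(
    ensemble: PoseEnsemble,
    fit: bool = True,
    selection: Callable[[Residue, Atom], bool] | None = None,
) -> RMSDMatrix:
    """All-vs-all pose RMSD in nm.

    ``fit=True`` superposes each pair by least squares (Kabsch) over the
    selection before measuring; ``fit=False`` measures raw coordinates.  The
    default selection is all atoms.
    """
    if ensemble.count < 2:
        raise ValueError("need at least 2 frames to compute pairwise RMSD")
    if selection is None:
        coords = ensemble.frames
    else:
        mask = np.array([selection(res, atom)
                         for res, atom in ensemble.topology.iter_atoms()], dtype=bool)
        if not mask.any():
            raise ValueError("atom selection is empty")
        coords = ensemble.frames[:, mask, :]
    m = ensemble.count
    values = np.zeros((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            if fit:
                d = fitted_rmsd(coords[j], coords[i])
            else:
                d = raw_rmsd(coords[j], coords[i])
            values[i, j] = values[j, i] = d / A_PER_NM
    return RMSDMatrix(values=values)


def gromos_cluster(matrix: RMSDMatrix, cutoff: float = 0.3) -> ClusterResult:
    """Daura/GROMOS clustering of an RMSD matrix.

    Repeatedly take the pose with the most remaining neighbours within the
    cutoff (neighbour: RMSD <= cutoff; ties broken toward the lower pose
    index), emit that pose plus its neighbours as a cluster with the pose as
    center, remove them, and iterate until no pose remains.  Clusters are
    returned by descending size; groups of equal-size clusters are recorded
    in ``ties``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = matrix.values
    remaining = set(range(matrix.n))
    clusters: list[Cluster] = []
    while remaining:
        idx = sorted(remaining)
        best, best_count = None, -1
        for i in idx:
            count = sum(1 for j in idx if j != i and v[i, j] <= cutoff)
            if count > best_count:  # lower index wins ties (idx is sorted)
                best, best_count = i, count
        members = {best} | {j for j in idx if j != best and v[best, j] <= cutoff}
        clusters.append(Cluster(members=frozenset(members), center=best))
        remaining -= members
    clusters.sort(key=lambda c: (-c.size, c.center))
    ties: list[list[int]] = []
    i = 0
    while i < len(clusters):
        group = [i]
        while i + len(group) < len(clusters) and clusters[i + len(group)].size == clusters[i].size:
            group.append(i + len(group))
        if len(group) > 1:
            ties.append(group)
        i += len(group)
    return ClusterResult(clusters=clusters, cutoff=cutoff, ties=ties)


def representative(result: ClusterResult) -> int:
    """Center pose index of the most populated cluster.

    On a size tie the cluster whose center has the smallest pose index wins
    (the tie itself is visible in ``result.ties``).
    """
    if not result.clusters:
        raise ValueError("empty cluster result")
    top_size = result.clusters[0].size
    candidates = [c for c in result.clusters if c.size == top_size]
    return min(c.center for c in candidates)


def summarize_scores(scores: Sequence[float]) -> float:
    """Arithmetic mean of docked scores (reported to 1 decimal in tables)."""
    if len(scores) == 0:
        raise ValueError("no scores to summarize")
    return float(np.mean(np.asarray(scores, dtype=float)))


def cluster_report(result: ClusterResult) -> dict:
    """JSON-ready report of a clustering run."""
    return {
        "cutoff": result.cutoff,
        "clusters": [
            {"center": c.center, "members": sorted(c.members), "size": c.size}
            for c in result.clusters
        ],
        "ties": result.ties,
    }
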