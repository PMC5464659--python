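"""GROMOS (Daura) conformational clustering at a Cα-RMSD cutoff.

The greedy algorithm: the structure with the most neighbours within the
cutoff becomes a cluster center; it and its neighbours are removed; repeat.
Ties on neighbour count are broken toward the lowest structure index so the
result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory
from .conformation import superposed_rmsd

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "cluster_summary",
    "extract_structures",
    "MAX_DENSE_STRUCTURES",
]

# A dense float64 matrix for the study-scale 40,000 structures is ~12 GB;
# refuse above this count unless the caller explicitly overrides.
MAX_DENSE_STRUCTURES = 20_000


@dataclass
class ClusterResult:
    assignments: np.ndarray   # structure index -> cluster id (1-based)
    centers: np.ndarray       # one structure index per cluster
    cutoff: float             # nm
    counts: np.ndarray        # members per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def extract_structures(
    traj: Trajectory, stride: int = 1, selection: np.ndarray | None = None
) -> np.ndarray:
    """Every stride-th frame's coordinates for a selection (default: all).

    Returns an array of shape (ceil(n_frames / stride), n_sel, 3).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    return traj.coordinates[::stride][:, np.asarray(selection, int), :].copy()


def pairwise_rmsd_matrix(
    structures: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all structure pairs (nm)."""
    structures = np.asarray(structures, dtype=float)
    n = structures.shape[0]
    if n < 2:
        raise ValueError("need at least 2 structures")
    if structures.ndim != 3 or structures.shape[2] != 3:
        raise ValueError("structures must have shape (n, n_atoms, 3)")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = superposed_rmsd(
                structures[i], structures[j], weights
            )
    return mat


def gromos_cluster(
    matrix: np.ndarray, cutoff: float = 0.25, allow_large: bool = False
) -> ClusterResult:
    """Greedy neighbour clustering of a pairwise-RMSD matrix.

    ``cutoff`` is in nm (0.25 nm = the conventional 2.5 Å Cα criterion).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if n > MAX_DENSE_STRUCTURES and not allow_large:
        raise MemoryError(
            f"{n} structures exceed the dense-matrix guard "
            f"({MAX_DENSE_STRUCTURES}); pass allow_large=True to proceed"
        )
    neighbours = matrix < cutoff
    np.fill_diagonal(neighbours, True)  # a structure neighbours itself
    remaining = np.ones(n, dtype=bool)
    assignments = np.zeros(n, dtype=int)
    centers: list[int] = []
    counts: list[int] = []
    cluster_id = 0
    while remaining.any():
        cluster_id += 1
        counts_now = (neighbours & remaining[None, :]).sum(axis=1)
        counts_now[~remaining] = -1
        center = int(np.argmax(counts_now))  # argmax takes the lowest index on ties
        members = neighbours[center] & remaining
        assignments[members] = cluster_id
        centers.append(center)
        counts.append(int(members.sum()))
        remaining &= ~members
    return ClusterResult(
        assignments=assignments,
        centers=np.array(centers, dtype=int),
        cutoff=float(cutoff),
        counts=np.array(counts, dtype=int),
    )


def cluster_summary(result: ClusterResult | np.ndarray, total: int) -> pd.DataFrame:
    """Size/percentage table per cluster; percentages to one decimal
    (round-half-even), computed as 100 * count / total.
    """
    counts = result.counts if isinstance(result, ClusterResult) else np.asarray(result)
    if int(counts.sum()) != int(total):
        raise ValueError(f"cluster counts sum to {counts.sum()}, expected {total}")
    percentages = np.array(
        [float(np.format_float_positional(100.0 * c / total, precision=1,
                                          unique=False, fractional=True))
         for c in counts]
    )
    return pd.DataFrame(
        {
            "cluster": np.arange(1, len(counts) + 1),
            "count": counts.astype(int),
            "percentage": percentages,
        }
    )
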