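"""Independent brute-force oracles used to validate the implementations.

Each oracle deliberately avoids the code path it checks: periodic distances
enumerate all 27 images, clustering replays the greedy definition with plain
loops, and the superposition oracle scans rotations on an Euler grid refined
to 1 degree resolution.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_min_image_distance(a: np.ndarray, b: np.ndarray,
                             box: np.ndarray) -> float:
    """Minimum distance over all 27 periodic images of b."""
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * box
        best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def all_image_distances(a: np.ndarray, b: np.ndarray,
                        box: np.ndarray) -> list[float]:
    return [
        float(np.linalg.norm(a - (b + np.array(s) * box)))
        for s in itertools.product((-1, 0, 1), repeat=3)
    ]


def gromos_brute(matrix: np.ndarray, cutoff: float):
    """Literal restatement of the greedy neighbour-clustering definition."""
    n = matrix.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_center, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(
                1 for j in unassigned if i == j or matrix[i, j] < cutoff
            )
            if count > best_count:
                best_center, best_count = i, count
        members = {
            j for j in unassigned
            if j == best_center or matrix[best_center, j] < cutoff
        }
        clusters.append((best_center, frozenset(members)))
        unassigned -= members
    return clusters


def _euler_rotations(step_deg: float,
                     center=(0.0, 0.0, 0.0), span=180.0) -> np.ndarray:
    """Batch of rotation matrices on a zyz Euler grid around ``center``."""
    def axis_range(c, full):
        lo, hi = c - span, c + span
        n = max(1, int(round((hi - lo) / step_deg)))
        return np.deg2rad(np.linspace(lo, hi, n, endpoint=False))

    a = axis_range(center[0], 360)
    b = np.deg2rad(
        np.linspace(
            max(0.0, center[1] - span), min(180.0, center[1] + span),
            max(1, int(round(min(180.0, 2 * span) / step_deg))),
        )
    )
    c = axis_range(center[2], 360)
    A, B, C = np.meshgrid(a, b, c, indexing="ij")
    ca, sa = np.cos(A).ravel(), np.sin(A).ravel()
    cb, sb = np.cos(B).ravel(), np.sin(B).ravel()
    cc, sc = np.cos(C).ravel(), np.sin(C).ravel()
    R = np.empty((len(ca), 3, 3))
    # z(a) @ y(b) @ z(c)
    R[:, 0, 0] = ca * cb * cc - sa * sc
    R[:, 0, 1] = -ca * cb * sc - sa * cc
    R[:, 0, 2] = ca * sb
    R[:, 1, 0] = sa * cb * cc + ca * sc
    R[:, 1, 1] = -sa * cb * sc + ca * cc
    R[:, 1, 2] = sa * sb
    R[:, 2, 0] = -sb * cc
    R[:, 2, 1] = sb * sc
    R[:, 2, 2] = cb
    return R


def _grid_best(mobile: np.ndarray, reference: np.ndarray,
               rotations: np.ndarray) -> tuple[float, np.ndarray]:
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    rotated = np.einsum("rij,nj->rni", rotations, x)
    rmsd = np.sqrt(np.mean(np.sum((rotated - y) ** 2, axis=2), axis=1))
    k = int(np.argmin(rmsd))
    return float(rmsd[k]), rotations[k]


def rotation_grid_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rotations via a 4-degree global Euler scan followed
    by exhaustive 1-degree local refinement (final resolution 1 degree)."""
    coarse = _euler_rotations(4.0)
    best, R = _grid_best(mobile, reference, coarse)
    # recover Euler angles of the coarse winner and refine around them
    beta = float(np.degrees(np.arccos(np.clip(R[2, 2], -1, 1))))
    if abs(R[2, 2]) < 0.999999:
        alpha = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
        gamma = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    else:
        alpha = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
        gamma = 0.0
    fine = _euler_rotations(1.0, center=(alpha, beta, gamma), span=5.0)
    refined, _ = _grid_best(mobile, reference, fine)
    return min(best, refined)
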