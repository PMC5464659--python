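"""Rigid-body superposition, RMSD/RMSF series, and mass-density profiles.

RMSD and RMSF default to the peptide backbone (N, CA, C); conformational
clustering elsewhere uses Cα only. Superposition weights default to atomic
masses. Density profiles are time-averaged mass histograms along the membrane
normal (z), normalised by the time-averaged bin volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Topology, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "MetricSeries",
    "DensityProfile",
    "kabsch_superpose",
    "apply_transform",
    "superposed_rmsd",
    "rmsd_series",
    "rmsf",
    "density_profile",
    "profile_overlap",
]


class DegenerateGeometryError(ValueError):
    """Point sets with no rotational information (e.g. collinear)."""


@dataclass
class MetricSeries:
    times: np.ndarray          # ps; frame times (RMSD) or zeros (RMSF)
    values: np.ndarray         # nm
    selection: str = ""
    kind: str = "rmsd"         # "rmsd" | "rmsf"


@dataclass
class DensityProfile:
    bin_centers: np.ndarray    # nm, along z
    density: np.ndarray        # amu / nm^3
    group: str = ""
    bin_width: float = 0.0


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD.
    The rotation is proper (reflections excluded).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()

    mu_m = wn @ mobile
    mu_r = wn @ reference
    X = mobile - mu_m
    Y = reference - mu_r

    # collinearity check: rank of the weighted covariance of either set
    if np.linalg.matrix_rank(X.T @ (X * wn[:, None]), tol=1e-12) < 2:
        raise DegenerateGeometryError("mobile points are collinear or coincident")

    H = (X * wn[:, None]).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m

    diff = X @ R.T - Y
    rmsd = float(np.sqrt(np.sum(wn * np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def apply_transform(points: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(points) @ rotation.T + translation


def superposed_rmsd(a: np.ndarray, b: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """Minimum RMSD between two point sets over rigid motions."""
    return kabsch_superpose(a, b, weights)[2]


def _weights_for(topology: Topology, selection: np.ndarray,
                 mass_weighted: bool) -> np.ndarray:
    return topology.masses[selection] if mass_weighted else np.ones(len(selection))


def rmsd_series(
    traj: Trajectory,
    reference: Frame | int = 0,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Per-frame RMSD to a reference after optimal superposition."""
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection")
    if isinstance(reference, int):
        ref = traj.coordinates[reference][selection]
    else:
        ref = reference.coordinates[selection]
    w = _weights_for(traj.topology, selection, mass_weighted)
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        values[i] = kabsch_superpose(traj.coordinates[i][selection], ref, w)[2]
    return MetricSeries(times=traj.times.copy(), values=values, kind="rmsd")


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = True,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    With ``superpose=True`` every frame is first fitted onto the mean
    structure and the mean is recomputed once (one iteration), which removes
    global rigid-body motion.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection")
    coords = traj.coordinates[:, selection, :].copy()
    if superpose:
        w = _weights_for(traj.topology, selection, mass_weighted)
        mean = coords.mean(axis=0)
        for _ in range(2):  # fit -> new mean -> refit once
            for i in range(coords.shape[0]):
                R, t, _ = kabsch_superpose(coords[i], mean, w)
                coords[i] = apply_transform(coords[i], R, t)
            mean = coords.mean(axis=0)
    mean = coords.mean(axis=0)
    disp2 = np.sum((coords - mean) ** 2, axis=2)
    values = np.sqrt(disp2.mean(axis=0))
    return MetricSeries(times=np.zeros(len(selection)), values=values, kind="rmsf")


def density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    n_bins: int = 100,
    frame_range: tuple[int, int] | None = None,
    group: str = "",
) -> DensityProfile:
    """Time-averaged mass density along z for one atom group.

    ``frame_range`` is a half-open (start, stop) window of frame indices, so
    "first/last 100 ns" style windows are plain slices. Binning spans the
    time-averaged box height; coordinates are wrapped into [0, Lz).
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty group selection")
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"bad frame range ({lo}, {hi})")
    boxes = traj.boxes[lo:hi]
    lz = boxes[:, 2].mean()
    area = (boxes[:, 0] * boxes[:, 1]).mean()
    edges = np.linspace(0.0, lz, n_bins + 1)
    masses = traj.topology.masses[selection]
    hist = np.zeros(n_bins)
    for i in range(lo, hi):
        z = np.mod(traj.coordinates[i][selection, 2], traj.boxes[i, 2])
        z = np.clip(z, 0, lz * (1 - 1e-12))
        hist += np.histogram(z, bins=edges, weights=masses)[0]
    hist /= hi - lo
    bin_volume = area * (lz / n_bins)
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=hist / bin_volume,
        group=group,
        bin_width=lz / n_bins,
    )


def profile_overlap(p1: DensityProfile, p2: DensityProfile) -> float:
    """Overlap coefficient of two normalised profiles: sum min(p1, p2).

    1 for identical shapes, 0 for disjoint support.
    """
    if p1.bin_centers.shape != p2.bin_centers.shape or not np.allclose(
        p1.bin_centers, p2.bin_centers
    ):
        raise ValueError("profiles must share identical binning")
    a = p1.density / p1.density.sum()
    b = p2.density / p2.density.sum()
    return float(np.minimum(a, b).sum())
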