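"""Leaflet assignment, grid-based area per lipid, and acyl-chain order parameters.

Area per lipid (APL) uses a nearest-projected-atom grid tessellation: the
leaflet's head atoms (plus any peptide atoms within a z-slab around the head
plane) are projected onto the xy plane, each cell of an n x n grid is awarded
to its laterally nearest atom under periodic boundaries, and a lipid's area is
its cell count times the cell area. Cells won by peptide atoms accumulate into
a protein-occupied area, so per leaflet the lipid areas plus the protein area
tile the box exactly.

Per-lipid areas are stratified into the three distance regions around the
embedded peptide: core (closest head-peptide distance <= 0.5 nm), intermediate
(0.5-1.0 nm] and remote (> 1.0 nm).

The deuterium order parameter per acyl carbon is
S_CD = <(3 cos^2 theta - 1)/2> with theta the angle between the C-H vector and
the bilayer normal; for united-atom chains the two methylene hydrogens are
reconstructed perpendicular to the C(i-1)->C(i+1) axis. Values are reported as
-S_CD (the experimental plotting convention, positive for ordered chains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .core import Frame, Topology, Trajectory, min_image_distance

__all__ = [
    "DegenerateMembraneError",
    "assign_leaflets",
    "grid_apl",
    "stratify_apl",
    "apl_table",
    "region_of_distance",
    "OrderParameterProfile",
    "order_parameters",
    "s_cd_from_vectors",
    "periodic_voronoi_areas",
    "DEFAULT_REGION_BOUNDS",
]

DEFAULT_REGION_BOUNDS = (0.5, 1.0)  # nm; paper-scale 5 A and 10 A
REGIONS = ("core", "intermediate", "remote")


class DegenerateMembraneError(ValueError):
    """All head atoms coplanar with the midplane; leaflets undefined."""


def assign_leaflets(
    frame: Frame, topology: Topology, head_indices: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Split lipids into top/bottom leaflets at the head-atom midplane.

    Returns ``{"top": head_idx_array, "bottom": head_idx_array}`` (indices of
    head atoms; z exactly at the midplane counts as top).
    """
    if head_indices is None:
        head_indices = topology.lipid_head_indices()
    head_indices = np.asarray(head_indices, dtype=int)
    if len(head_indices) < 2:
        raise ValueError("need at least 2 lipids to define leaflets")
    z = frame.coordinates[head_indices, 2]
    mid = z.mean()
    if np.allclose(z, mid, atol=1e-9):
        raise DegenerateMembraneError("all head atoms lie at the midplane")
    top = head_indices[z >= mid]
    bottom = head_indices[z < mid]
    return {"top": top, "bottom": bottom}


def grid_apl(
    frame: Frame,
    leaflet_heads: np.ndarray,
    grid: int = 200,
    protein_indices: np.ndarray | None = None,
    protein_slab: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Grid-tessellation area per lipid for one leaflet of one frame.

    Returns ``(areas, protein_area)`` with one area (nm^2) per head atom in
    ``leaflet_heads`` order. Peptide atoms compete for cells only within
    ``protein_slab`` nm of the leaflet's mean head z (GRIDMAT-style), so
    mid-membrane atoms cannot steal head-plane area.
    """
    if grid < 50:
        raise ValueError("grid must be at least 50 x 50")
    leaflet_heads = np.asarray(leaflet_heads, dtype=int)
    if len(leaflet_heads) == 0:
        raise ValueError("empty leaflet")
    lx, ly = frame.box[0], frame.box[1]
    heads_xy = np.mod(frame.coordinates[leaflet_heads, :2], [lx, ly])
    points = heads_xy
    n_heads = len(leaflet_heads)
    if protein_indices is not None and len(protein_indices) > 0:
        z0 = frame.coordinates[leaflet_heads, 2].mean()
        prot = np.asarray(protein_indices, dtype=int)
        keep = np.abs(frame.coordinates[prot, 2] - z0) <= protein_slab
        prot_xy = np.mod(frame.coordinates[prot[keep], :2], [lx, ly])
        if len(prot_xy):
            points = np.vstack([heads_xy, prot_xy])
    # half-open cell centres; KD-tree with periodic boxsize
    cx = (np.arange(grid) + 0.5) * (lx / grid)
    cy = (np.arange(grid) + 0.5) * (ly / grid)
    centers = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    tree = cKDTree(points, boxsize=[lx, ly])
    _, owner = tree.query(centers, k=1)
    cell_area = (lx * ly) / (grid * grid)
    counts = np.bincount(owner, minlength=len(points))
    areas = counts[:n_heads] * cell_area
    protein_area = float(counts[n_heads:].sum() * cell_area)
    return areas, protein_area


def region_of_distance(d: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Region label per distance; bounds are closed on the upper edge."""
    lo, hi = bounds
    out = np.full(np.shape(d), "remote", dtype="<U12")
    d = np.asarray(d, dtype=float)
    out[d <= hi] = "intermediate"
    out[d <= lo] = "core"
    return out


def stratify_apl(
    areas: np.ndarray,
    frame: Frame,
    leaflet_heads: np.ndarray,
    peptide_indices: np.ndarray,
    bounds: tuple[float, float] = DEFAULT_REGION_BOUNDS,
    lateral: bool = False,
) -> pd.DataFrame:
    """Label each lipid's area with its distance region around the peptide.

    The distance is the minimum-image distance from the lipid head atom to the
    nearest peptide atom - 3D by default, xy-only with ``lateral=True``.
    """
    peptide_indices = np.asarray(peptide_indices, dtype=int)
    if len(peptide_indices) == 0:
        raise ValueError("empty peptide selection")
    leaflet_heads = np.asarray(leaflet_heads, dtype=int)
    heads = frame.coordinates[leaflet_heads]
    pep = frame.coordinates[peptide_indices]
    d = min_image_distance(
        heads[:, None, :], pep[None, :, :], frame.box, lateral=lateral
    ).min(axis=1)
    return pd.DataFrame(
        {
            "head_index": leaflet_heads,
            "area": np.asarray(areas, dtype=float),
            "distance": d,
            "region": region_of_distance(d, bounds),
        }
    )


def apl_table(
    traj: Trajectory,
    peptide_selection: np.ndarray | None,
    grid: int = 200,
    bounds: tuple[float, float] = DEFAULT_REGION_BOUNDS,
    lateral: bool = False,
    frame_range: tuple[int, int] | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Per-lipid per-frame APL with leaflet and region labels over a trajectory.

    Without a peptide selection every lipid is labelled remote (pure
    membrane). Aggregate with pandas, e.g.
    ``table.groupby(["leaflet", "region"]).area.agg(["mean", "std"])``.
    """
    topo = traj.topology
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    head_idx = topo.lipid_head_indices()
    rows = []
    for f in range(lo, hi, stride):
        frame = traj.frame(f)
        leaflets = assign_leaflets(frame, topo, head_idx)
        for leaflet, heads in leaflets.items():
            areas, protein_area = grid_apl(
                frame, heads, grid=grid, protein_indices=peptide_selection
            )
            if peptide_selection is not None and len(peptide_selection):
                part = stratify_apl(
                    areas, frame, heads, peptide_selection, bounds, lateral
                )
            else:
                part = pd.DataFrame(
                    {
                        "head_index": heads,
                        "area": areas,
                        "distance": np.inf,
                        "region": "remote",
                    }
                )
            part.insert(0, "frame", f)
            part.insert(1, "leaflet", leaflet)
            part["protein_area"] = protein_area
            rows.append(part)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# independent per-lipid area oracle: periodic Voronoi tessellation
# ---------------------------------------------------------------------------

def periodic_voronoi_areas(points_xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Exact per-point Voronoi cell areas under periodic boundaries.

    Tiles the 3 x 3 periodic images, builds a scipy Voronoi diagram and
    measures the central-copy polygons with the shoelace formula. Serves as
    the reference the grid tessellation converges to.
    """
    points_xy = np.mod(np.asarray(points_xy, dtype=float), box_xy)
    n = len(points_xy)
    shifts = [
        (dx * box_xy[0], dy * box_xy[1])
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
    ]
    tiled = np.concatenate([points_xy + s for s in shifts], axis=0)
    central_offset = shifts.index((0.0, 0.0)) * n
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central_offset + i]]
        if -1 in region or len(region) == 0:
            raise ValueError("unbounded Voronoi cell in central copy")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


# ---------------------------------------------------------------------------
# deuterium order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterProfile:
    chain: str
    carbon_index: np.ndarray      # 1-based position along the chain (interior)
    minus_s_cd: np.ndarray        # reported -S_CD per carbon
    n_samples: np.ndarray


def s_cd_from_vectors(vectors: np.ndarray,
                      normal: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """S_CD = <(3 cos^2 theta - 1)/2> over an array of C-H vectors (..., 3)."""
    vectors = np.asarray(vectors, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    cos_t = np.sum(vectors * normal, axis=-1) / np.linalg.norm(vectors, axis=-1)
    return float(np.mean(0.5 * (3.0 * cos_t**2 - 1.0)))


def _methylene_h_vectors(prev_c: np.ndarray, this_c: np.ndarray,
                         next_c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit C-H vectors of a united-atom methylene (vectorised, (..., 3)).

    Both hydrogens lie perpendicular to the C(i-1)->C(i+1) axis, in-plane
    component opposite the backbone bisector, out-of-plane components split
    by the tetrahedral half-angle. Collinear backbones (no defined bisector)
    fall back to an arbitrary perpendicular pair, which leaves S_CD exact for
    axially symmetric chains.
    """
    a = next_c - prev_c
    a /= np.linalg.norm(a, axis=-1, keepdims=True)
    b = prev_c + next_c - 2.0 * this_c
    b -= np.sum(b * a, axis=-1, keepdims=True) * a
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    # arbitrary perpendicular where the three carbons are collinear
    ref = np.zeros_like(a)
    ref[..., 0] = 1.0
    alt = np.zeros_like(a)
    alt[..., 1] = 1.0
    use_alt = np.abs(np.sum(a * ref, axis=-1, keepdims=True)) > 0.9
    ref = np.where(use_alt, alt, ref)
    fallback = ref - np.sum(ref * a, axis=-1, keepdims=True) * a
    fallback /= np.linalg.norm(fallback, axis=-1, keepdims=True)
    bhat = np.where(nb > 1e-10, b / np.where(nb > 1e-10, nb, 1.0), fallback)
    normal = np.cross(a, bhat)
    half = np.deg2rad(109.47 / 2.0)
    h1 = -np.cos(half) * bhat + np.sin(half) * normal
    h2 = -np.cos(half) * bhat - np.sin(half) * normal
    return h1, h2


def order_parameters(
    traj: Trajectory,
    chain: str = "sn1",
    normal: np.ndarray = (0.0, 0.0, 1.0),
    frame_range: tuple[int, int] | None = None,
) -> OrderParameterProfile:
    """-S_CD per interior acyl carbon, averaged over lipids, hydrogens, frames."""
    topo = traj.topology
    names = topo.acyl_chain_definitions.get(chain)
    if not names or len(names) < 3:
        raise ValueError(f"acyl chain {chain!r} undefined or shorter than 3 carbons")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)

    lipid_resids = np.unique(topo.resids[topo.kinds == "lipid"])
    index_of: dict[tuple[int, str], int] = {}
    for i, a in enumerate(topo.atoms):
        if a.molecule_kind == "lipid" and a.name in names:
            index_of[(a.residue_index, a.name)] = i
    try:
        idx = np.array(
            [[index_of[(r, nm)] for nm in names] for r in lipid_resids], dtype=int
        )
    except KeyError as exc:
        raise ValueError(f"broken acyl chain definition: missing atom {exc}") from exc

    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    n_interior = len(names) - 2
    acc = np.zeros(n_interior)
    count = np.zeros(n_interior, dtype=int)
    for f in range(lo, hi):
        carbons = traj.coordinates[f][idx]          # (n_lipids, n_carbons, 3)
        prev_c, this_c, next_c = carbons[:, :-2], carbons[:, 1:-1], carbons[:, 2:]
        h1, h2 = _methylene_h_vectors(prev_c, this_c, next_c)
        for h in (h1, h2):
            cos_t = np.sum(h * normal, axis=-1)
            acc += np.sum(0.5 * (3.0 * cos_t**2 - 1.0), axis=0)
            count += carbons.shape[0]
    s_cd = acc / count
    return OrderParameterProfile(
        chain=chain,
        carbon_index=np.arange(2, len(names)),  # positions 2 .. n-1 along the chain
        minus_s_cd=-s_cd,
        n_samples=count,
    )
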