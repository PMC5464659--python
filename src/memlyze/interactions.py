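"""Geometric hydrogen-bond census, lateral RDF, and lipid residence times.

Hydrogen bonds between peptide backbones use the standard geometric criterion
(donor-acceptor distance <= 0.35 nm and H-donor-acceptor angle <= 30 deg,
minimum-image). Each bond is classified by the strand ranges of its two
residues into the intra-peptide (β1-β2, β3-β4, β4-β5 per chain) and
inter-peptide (same-numbered strands pooled, plus the β3-β5 cross pair)
categories; everything else is "other".

The radial distribution function is lateral (2D): the peptide spans the
bilayer, so shells are annuli around its xy centre and the density
normalisation uses targets per box xy area. The shell radius for residence
times is the distance below which 80% of the area under g(r) accumulates.

A lipid's dwell is a maximal run of frames with its head atom inside the
shell; runs separated by at most ``gap_tolerance`` absent frames merge, and
runs touching the trajectory ends are discarded as truncated. The residence
time is the mean dwell duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .core import Topology, Trajectory, min_image_distance, minimum_image
from .secondary import BackboneResidue, peptide_backbone, reconstruct_amide_hydrogens
from .strands import DEFAULT_STRAND_MAP, StrandMap

__all__ = [
    "HBondRecord",
    "HBondCensus",
    "RDFProfile",
    "ResidenceStats",
    "CATEGORIES",
    "detect_hbonds",
    "classify_hbond",
    "hbond_census",
    "peptide_lateral_center",
    "lateral_rdf",
    "cutoff_from_rdf",
    "residence_time",
]

D_CUT = 0.35       # nm, donor(N) - acceptor(O) distance
ANGLE_CUT = 30.0   # degrees, H-donor-acceptor angle

CATEGORIES = (
    "intra-A b1-b2", "intra-A b3-b4", "intra-A b4-b5",
    "intra-B b1-b2", "intra-B b3-b4", "intra-B b4-b5",
    "inter b1-b2", "inter b3", "inter b4", "inter b5", "inter b3-b5",
    "other",
)


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor_atom: int
    hydrogen: tuple[float, float, float]
    acceptor_atom: int
    donor_residue: tuple[str, int]
    acceptor_residue: tuple[str, int]
    category: str = "other"


@dataclass
class HBondCensus:
    mean: dict[str, float]
    sd: dict[str, float]
    n_frames: int


@dataclass
class RDFProfile:
    bin_centers: np.ndarray   # nm
    g: np.ndarray             # dimensionless
    cumulative: np.ndarray    # N(r): mean targets within r
    bin_width: float
    density: float            # targets per nm^2 (2D)
    n_frames: int


@dataclass
class ResidenceStats:
    dwell_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    tau: float = float("nan")
    n_events: int = 0
    cutoff: float = 0.0
    gap_tolerance: int = 0


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    box: np.ndarray | None = None,
    d_cut: float = D_CUT,
    angle_cut: float = ANGLE_CUT,
    frame_index: int = 0,
    residues: list[BackboneResidue] | None = None,
    strand_map: StrandMap | None = None,
) -> list[HBondRecord]:
    """Backbone amide-to-carbonyl hydrogen bonds in one frame.

    Donors are backbone N-H groups (amide H reconstructed when absent);
    acceptors are backbone carbonyl O. Pairs within the same residue or
    between direct chain neighbours are excluded. With ``box`` given,
    distances follow the minimum-image convention.
    """
    if residues is None:
        residues = peptide_backbone(topology)
    if not residues:
        return []
    h_xyz = reconstruct_amide_hydrogens(coords, residues)
    n_xyz = coords[[r.n for r in residues]]
    o_xyz = coords[[r.o for r in residues]]
    m = len(residues)

    d_no = n_xyz[:, None, :] - o_xyz[None, :, :]
    if box is not None:
        d_no = minimum_image(d_no, box)
    r_no = np.linalg.norm(d_no, axis=-1)
    # angle H-N-O at the donor nitrogen; N->O vector is -d_no
    nh = h_xyz - n_xyz  # (m, 3); NaN rows mark non-donors
    with np.errstate(invalid="ignore"):
        cos_a = np.sum(nh[:, None, :] * -d_no, axis=-1) / (
            np.linalg.norm(nh, axis=-1)[:, None] * np.maximum(r_no, 1e-12)
        )
    angle = np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0)))
    ok = (r_no <= d_cut) & (angle <= angle_cut)
    ok &= np.isfinite(cos_a)
    np.fill_diagonal(ok, False)
    for p, res in enumerate(residues):
        if res.prev is not None:
            ok[p, res.prev] = ok[res.prev, p] = False

    records = []
    smap = DEFAULT_STRAND_MAP if strand_map is None else strand_map
    for i, j in zip(*np.nonzero(ok)):
        rec = HBondRecord(
            frame=frame_index,
            donor_atom=residues[i].n,
            hydrogen=tuple(h_xyz[i]),
            acceptor_atom=residues[j].o,
            donor_residue=(residues[i].chain_id, residues[i].residue_index),
            acceptor_residue=(residues[j].chain_id, residues[j].residue_index),
        )
        records.append(
            HBondRecord(**{**rec.__dict__, "category": classify_hbond(rec, smap)})
        )
    return records


_INTRA_PAIRS = {
    frozenset(("b1", "b2")): "b1-b2",
    frozenset(("b3", "b4")): "b3-b4",
    frozenset(("b4", "b5")): "b4-b5",
}


def classify_hbond(record: HBondRecord, strand_map: StrandMap | None = None) -> str:
    """Strand-pair category of one hydrogen bond (see module docstring)."""
    smap = DEFAULT_STRAND_MAP if strand_map is None else strand_map
    (chain_d, resid_d) = record.donor_residue
    (chain_a, resid_a) = record.acceptor_residue
    for resid in (resid_d, resid_a):
        if not (1 <= resid <= smap.n_residues):
            raise ValueError(f"residue {resid} outside 1-{smap.n_residues}")
    sd = smap.strand_of(resid_d)
    sa = smap.strand_of(resid_a)
    if sd is None or sa is None:
        return "other"
    if chain_d == chain_a:
        pair = _INTRA_PAIRS.get(frozenset((sd, sa)))
        return f"intra-{chain_d} {pair}" if pair else "other"
    if sd == sa:
        # inter-peptide bonds between identically numbered strands;
        # the two N-terminal strands are pooled as in the census table
        return "inter b1-b2" if sd in ("b1", "b2") else f"inter {sd}"
    if frozenset((sd, sa)) == frozenset(("b1", "b2")):
        return "inter b1-b2"
    if frozenset((sd, sa)) == frozenset(("b3", "b5")):
        return "inter b3-b5"
    return "other"


def hbond_census(
    traj: Trajectory,
    strand_map: StrandMap | None = None,
    d_cut: float = D_CUT,
    angle_cut: float = ANGLE_CUT,
    frame_range: tuple[int, int] | None = None,
) -> HBondCensus:
    """Per-category mean +- SD of hydrogen-bond counts per frame."""
    smap = DEFAULT_STRAND_MAP if strand_map is None else strand_map
    residues = peptide_backbone(traj.topology)
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    counts = {c: np.zeros(hi - lo) for c in CATEGORIES}
    for k, f in enumerate(range(lo, hi)):
        recs = detect_hbonds(
            traj.coordinates[f], traj.topology, traj.boxes[f],
            d_cut, angle_cut, frame_index=f, residues=residues, strand_map=smap,
        )
        for rec in recs:
            counts[rec.category][k] += 1
    return HBondCensus(
        mean={c: float(v.mean()) for c, v in counts.items()},
        sd={c: float(v.std()) for c, v in counts.items()},
        n_frames=hi - lo,
    )


# ---------------------------------------------------------------------------
# lateral RDF and residence time
# ---------------------------------------------------------------------------

def peptide_lateral_center(coords: np.ndarray,
                           peptide_indices: np.ndarray) -> np.ndarray:
    """xy centroid of the peptide selection (assumed laterally unwrapped)."""
    return coords[np.asarray(peptide_indices, int), :2].mean(axis=0)


def lateral_rdf(
    traj: Trajectory,
    target_indices: np.ndarray,
    reference_indices: np.ndarray | None = None,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> RDFProfile:
    """2D radial distribution of target atoms around the peptide's xy centre.

    g(r) = <count in annulus> / (rho_2D * 2 pi r dr), rho_2D = targets per
    box xy area; N(r) is the cumulative mean count within r.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    target_indices = np.asarray(target_indices, dtype=int)
    if len(target_indices) < 2:
        raise ValueError("need at least 2 target atoms")
    box = traj.boxes[0]
    if r_max is None:
        r_max = 0.5 * min(box[0], box[1])
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        if reference_indices is None:
            raise ValueError("reference_indices is required")
        ref = peptide_lateral_center(coords, reference_indices)
        d = min_image_distance(
            coords[target_indices], np.append(ref, 0.0), traj.boxes[f], lateral=True
        )
        hist += np.histogram(d, bins=edges)[0]
    hist /= traj.n_frames
    area = float(box[0] * box[1])
    rho = len(target_indices) / area
    shell_areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = hist / (rho * shell_areas)
    return RDFProfile(
        bin_centers=centers,
        g=g,
        cumulative=np.cumsum(hist),
        bin_width=bin_width,
        density=rho,
        n_frames=traj.n_frames,
    )


def cutoff_from_rdf(profile: RDFProfile, fraction: float = 0.8,
                    r_max: float | None = None) -> float:
    """Smallest r where the running integral of g(r) dr reaches
    ``fraction`` of the integral up to ``r_max`` (linear interpolation)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    r = profile.bin_centers
    g = profile.g
    if r_max is not None:
        keep = r <= r_max
        r, g = r[keep], g[keep]
    if len(r) == 0 or np.all(g == 0):
        raise ValueError("RDF has no density below r_max")
    # integral over bins (each bin contributes g * dr)
    cum = np.cumsum(g) * profile.bin_width
    target = fraction * cum[-1]
    if fraction == 1.0:
        return float(r[-1] + 0.5 * profile.bin_width)
    k = int(np.searchsorted(cum, target))
    hi_edge = r[k] + 0.5 * profile.bin_width
    if k == 0:
        prev_cum, lo_edge = 0.0, r[0] - 0.5 * profile.bin_width
    else:
        prev_cum, lo_edge = cum[k - 1], r[k] - 0.5 * profile.bin_width
    frac_in_bin = (target - prev_cum) / (cum[k] - prev_cum)
    return float(lo_edge + frac_in_bin * (hi_edge - lo_edge))


def _runs(mask: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal True runs [start, stop) with gaps <= gap_tolerance merged."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > gap_tolerance:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def residence_time(
    traj: Trajectory,
    cutoff: float,
    peptide_indices: np.ndarray | None = None,
    head_indices: np.ndarray | None = None,
    gap_tolerance: int = 0,
    center_xy: np.ndarray | None = None,
) -> ResidenceStats:
    """Mean continuous dwell time of lipids within a lateral shell.

    Membership: head atom within ``cutoff`` (nm, lateral minimum-image) of the
    peptide's xy centre (or a fixed ``center_xy``). Runs touching either end
    of the trajectory are truncated observations and are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = traj.topology
    if head_indices is None:
        head_indices = topo.lipid_head_indices()
    head_indices = np.asarray(head_indices, dtype=int)
    n_frames = traj.n_frames
    member = np.zeros((n_frames, len(head_indices)), dtype=bool)
    for f in range(n_frames):
        coords = traj.coordinates[f]
        if center_xy is not None:
            ref = np.asarray(center_xy, dtype=float)
        else:
            if peptide_indices is None:
                raise ValueError("need peptide_indices or center_xy")
            ref = peptide_lateral_center(coords, peptide_indices)
        d = min_image_distance(
            coords[head_indices], np.append(ref, 0.0), traj.boxes[f], lateral=True
        )
        member[f] = d <= cutoff
    dwells = []
    dt = traj.frame_spacing
    for lipid in range(member.shape[1]):
        for start, stop in _runs(member[:, lipid], gap_tolerance):
            if start == 0 or stop == n_frames:
                continue  # truncated at a trajectory boundary
            dwells.append((stop - start) * dt)
    dwells = np.asarray(dwells, dtype=float)
    if len(dwells) == 0:
        warnings.warn("no complete membership events; residence time undefined")
        return ResidenceStats(cutoff=cutoff, gap_tolerance=gap_tolerance)
    return ResidenceStats(
        dwell_times=dwells,
        tau=float(dwells.mean()),
        n_events=len(dwells),
        cutoff=cutoff,
        gap_tolerance=gap_tolerance,
    )
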