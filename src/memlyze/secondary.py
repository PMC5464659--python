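"""Secondary-structure assignment collapsed to the {E, T, C} alphabet.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
energy

    E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN)   kcal/mol,

with a bond whenever E < -0.5 kcal/mol. Amide hydrogens absent from
united-atom models are reconstructed 0.1 nm from N along the previous
residue's O->C direction (the DSSP convention); proline and chain-initial
residues cannot donate.

Bonds feed the bridge/ladder and n-turn rules:

* parallel or antiparallel bridges (isolated ones included) -> E;
* 3-, 4- or 5-turns not already in a ladder -> T for the enclosed residues;
  runs of two consecutive same-n turn starts form helices, which collapse to
  C along with everything unassigned.

Turn bonds are only evaluated within a chain; bridges may cross chains
(inter-peptide sheets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory

__all__ = [
    "HBondGeometry",
    "SSMatrix",
    "PropensityTable",
    "ClashError",
    "BackboneResidue",
    "peptide_backbone",
    "reconstruct_amide_hydrogens",
    "kabsch_sander_energy",
    "kabsch_sander_bonds",
    "assign_ss",
    "ss_evolution",
    "ss_content",
    "ss_propensity",
    "strand_propensity_ratio",
    "INFINITE_RATIO",
]

KS_PREFACTOR = 0.084 * 332.0          # kcal/mol * Å
KS_CUTOFF = -0.5                      # kcal/mol
NH_BOND_LENGTH = 0.1                  # nm
CLASH_DISTANCE = 0.05                 # nm
_MIN_DISTANCE = 0.05                  # clamp in matrix evaluation (nm)

LABELS = ("E", "T", "C")


class ClashError(ValueError):
    """Donor and acceptor groups overlap (distance < 0.05 nm)."""


@dataclass(frozen=True)
class HBondGeometry:
    """Kabsch-Sander distances (nm) and energy (kcal/mol) for one N-H...O=C pair."""

    r_on: float
    r_ch: float
    r_oh: float
    r_cn: float
    energy: float

    @property
    def is_hbond(self) -> bool:
        return self.energy < KS_CUTOFF


@dataclass
class BackboneResidue:
    chain_id: str
    residue_index: int
    residue_name: str
    n: int       # atom indices into the topology
    ca: int
    c: int
    o: int
    prev: int | None = None   # position of the preceding residue in the same chain
    next: int | None = None


@dataclass
class SSMatrix:
    """Residues x frames labels over {E, T, C}."""

    labels: np.ndarray                 # (n_residues, n_frames), dtype '<U1'
    residues: list[tuple[str, int]]    # (chain_id, residue_index)
    times: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]

    def rows_for(self, chain_id: str, residue_range: tuple[int, int] | None = None
                 ) -> np.ndarray:
        rows = []
        for i, (ch, resid) in enumerate(self.residues):
            if ch != chain_id:
                continue
            if residue_range is not None and not (
                residue_range[0] <= resid <= residue_range[1]
            ):
                continue
            rows.append(i)
        return np.array(rows, dtype=int)


@dataclass
class PropensityTable:
    residues: list[tuple[str, int]]
    p_e: np.ndarray
    p_t: np.ndarray
    p_c: np.ndarray


INFINITE_RATIO = float("inf")


# ---------------------------------------------------------------------------
# backbone bookkeeping
# ---------------------------------------------------------------------------

def peptide_backbone(topology: Topology) -> list[BackboneResidue]:
    """Ordered peptide residues with their backbone atom indices.

    Residues missing any of N, CA, C, O are dropped (they are labelled C by
    the assigner, with a warning).
    """
    table: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(topology.atoms):
        if a.molecule_kind != "peptide":
            continue
        key = (a.chain_id, a.residue_index)
        if key not in table:
            table[key] = {}
            order.append(key)
        if a.name in ("N", "CA", "C", "O"):
            table[key][a.name] = i
    resnames = {}
    for i, a in enumerate(topology.atoms):
        if a.molecule_kind == "peptide":
            resnames[(a.chain_id, a.residue_index)] = a.residue_name
    residues: list[BackboneResidue] = []
    for key in order:
        atoms = table[key]
        if not all(n in atoms for n in ("N", "CA", "C", "O")):
            continue
        residues.append(
            BackboneResidue(
                chain_id=key[0], residue_index=key[1],
                residue_name=resnames[key],
                n=atoms["N"], ca=atoms["CA"], c=atoms["C"], o=atoms["O"],
            )
        )
    for p in range(len(residues)):
        if p > 0 and residues[p - 1].chain_id == residues[p].chain_id and (
            residues[p - 1].residue_index == residues[p].residue_index - 1
        ):
            residues[p].prev = p - 1
            residues[p - 1].next = p
    return residues


def reconstruct_amide_hydrogens(
    coords: np.ndarray, residues: list[BackboneResidue]
) -> np.ndarray:
    """Amide H positions, NaN where the residue cannot donate.

    H sits ``NH_BOND_LENGTH`` from N along the previous residue's O->C unit
    vector; chain-initial residues and prolines get NaN.
    """
    h = np.full((len(residues), 3), np.nan)
    for p, res in enumerate(residues):
        if res.prev is None or res.residue_name == "PRO":
            continue
        prev = residues[res.prev]
        co = coords[prev.c] - coords[prev.o]
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        h[p] = coords[res.n] + NH_BOND_LENGTH * co / norm
    return h


# ---------------------------------------------------------------------------
# Kabsch-Sander energy
# ---------------------------------------------------------------------------

def kabsch_sander_energy(
    n_pos: np.ndarray,
    h_pos: np.ndarray | None,
    c_pos: np.ndarray,
    o_pos: np.ndarray,
) -> HBondGeometry:
    """Electrostatic H-bond energy of one donor amide vs one acceptor carbonyl.

    ``h_pos=None`` marks a donor without an amide hydrogen (proline or chain
    start); the result then carries infinite energy and no bond.
    """
    n_pos = np.asarray(n_pos, float)
    c_pos = np.asarray(c_pos, float)
    o_pos = np.asarray(o_pos, float)
    r_on = float(np.linalg.norm(n_pos - o_pos))
    r_cn = float(np.linalg.norm(n_pos - c_pos))
    if h_pos is None or np.any(~np.isfinite(np.asarray(h_pos, float))):
        return HBondGeometry(r_on, r_cn, np.nan, r_cn, np.inf)
    h_pos = np.asarray(h_pos, float)
    r_oh = float(np.linalg.norm(h_pos - o_pos))
    r_ch = float(np.linalg.norm(h_pos - c_pos))
    if min(r_on, r_ch, r_oh, r_cn) < CLASH_DISTANCE:
        raise ClashError(
            f"donor/acceptor overlap: min distance "
            f"{min(r_on, r_ch, r_oh, r_cn):.4f} nm < {CLASH_DISTANCE} nm"
        )
    # formula uses Å
    energy = KS_PREFACTOR * (
        1.0 / (r_on * 10) + 1.0 / (r_ch * 10)
        - 1.0 / (r_oh * 10) - 1.0 / (r_cn * 10)
    )
    return HBondGeometry(r_on, r_ch, r_oh, r_cn, energy)


def kabsch_sander_bonds(
    coords: np.ndarray, residues: list[BackboneResidue]
) -> np.ndarray:
    """Boolean matrix bond[i, j]: the amide of residue i donates to the
    carbonyl of residue j. Vectorised over all pairs; inter-atomic distances
    are clamped at 0.05 nm so clashing (melted/disordered) geometry degrades
    to strong short-range repulsion-free scoring instead of raising.
    """
    m = len(residues)
    if m == 0:
        return np.zeros((0, 0), dtype=bool)
    n_xyz = coords[[r.n for r in residues]]
    c_xyz = coords[[r.c for r in residues]]
    o_xyz = coords[[r.o for r in residues]]
    h_xyz = reconstruct_amide_hydrogens(coords, residues)

    def dist(a, b):
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return np.maximum(d, _MIN_DISTANCE) * 10.0  # Å

    r_on = dist(n_xyz, o_xyz)
    r_cn = dist(n_xyz, c_xyz)
    r_oh = dist(h_xyz, o_xyz)
    r_ch = dist(h_xyz, c_xyz)
    with np.errstate(invalid="ignore"):
        energy = KS_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    bonds = np.where(np.isfinite(energy), energy < KS_CUTOFF, False)
    np.fill_diagonal(bonds, False)
    # a residue never bonds its direct chain neighbours
    for p, res in enumerate(residues):
        if res.prev is not None:
            bonds[p, res.prev] = bonds[res.prev, p] = False
    return bonds


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _bridge_matrix(bonds: np.ndarray, residues: list[BackboneResidue]) -> np.ndarray:
    """Residues taking part in a parallel or antiparallel bridge.

    Antiparallel bridge (i, j): bonds (i->j and j->i) or (i-1->j+1 and
    j-1->i+1); parallel bridge: (i-1->j and j->i+1) or (j-1->i and i->j+1).
    Neighbour offsets are chain-local; within a chain bridges need |i-j| >= 3.
    """
    m = len(residues)
    if m == 0:
        return np.zeros(0, dtype=bool)
    # pad with a sentinel row/column of False for missing neighbours
    bp = np.zeros((m + 1, m + 1), dtype=bool)
    bp[:m, :m] = bonds
    prv = np.array([m if r.prev is None else r.prev for r in residues])
    nxt = np.array([m if r.next is None else r.next for r in residues])
    idx = np.arange(m)

    anti = (bonds & bonds.T)
    t1 = bp[prv[:, None], nxt[None, :]]       # t1[i, j] = bond(i-1 -> j+1)
    anti |= t1 & t1.T
    # p1[i, j] = bond(i-1 -> j) & bond(j -> i+1)
    p1 = bp[prv[:, None], idx[None, :]] & bp[idx[None, :], nxt[:, None]]
    para = p1 | p1.T

    bridge = anti | para
    chains = np.array([r.chain_id for r in residues])
    same_chain = chains[:, None] == chains[None, :]
    close = np.abs(idx[:, None] - idx[None, :]) < 3
    bridge &= ~(same_chain & close)
    return bridge.any(axis=1)


def _turn_labels(bonds: np.ndarray, residues: list[BackboneResidue]) -> np.ndarray:
    """Residues enclosed by isolated hydrogen-bonded n-turns (n = 3, 4, 5).

    A turn starts at i when the amide of i+n donates to the carbonyl of i
    within one chain. Two consecutive same-n starts form a helix, which is
    collapsed to coil, so those residues are excluded here.
    """
    m = len(residues)
    in_turn = np.zeros(m, dtype=bool)
    pos_by_key = {(r.chain_id, r.residue_index): p for p, r in enumerate(residues)}
    for n in (3, 4, 5):
        starts = np.zeros(m, dtype=bool)
        for i, res in enumerate(residues):
            j = pos_by_key.get((res.chain_id, res.residue_index + n))
            if j is not None and bonds[j, i]:
                # require an unbroken chain between i and i+n
                contiguous = all(
                    pos_by_key.get((res.chain_id, res.residue_index + k)) is not None
                    for k in range(1, n)
                )
                if contiguous:
                    starts[i] = True
        helix_start = starts.copy()
        helix_start[1:] &= starts[:-1]          # start i with start at i-1
        helical = np.zeros(m, dtype=bool)
        for i in np.flatnonzero(helix_start):
            helical[i : i + n + 1] = True
        for i in np.flatnonzero(starts):
            if helical[i]:
                continue
            for k in range(1, n):
                p = pos_by_key[(residues[i].chain_id, residues[i].residue_index + k)]
                if not helical[p]:
                    in_turn[p] = True
    return in_turn


def assign_ss(
    coords: np.ndarray, topology: Topology,
    residues: list[BackboneResidue] | None = None,
) -> np.ndarray:
    """Per-residue labels over {E, T, C} for one frame.

    Residue order follows :func:`peptide_backbone`. Incomplete residues are
    not scored and land in C.
    """
    if residues is None:
        residues = peptide_backbone(topology)
    bonds = kabsch_sander_bonds(coords, residues)
    in_bridge = _bridge_matrix(bonds, residues)
    in_turn = _turn_labels(bonds, residues)
    labels = np.full(len(residues), "C", dtype="<U1")
    labels[in_turn] = "T"
    labels[in_bridge] = "E"
    return labels


def ss_evolution(traj: Trajectory) -> SSMatrix:
    """Assign every frame; residues x frames matrix (the evolution map)."""
    residues = peptide_backbone(traj.topology)
    if not residues:
        raise ValueError("trajectory contains no complete peptide residues")
    labels = np.empty((len(residues), traj.n_frames), dtype="<U1")
    for f in range(traj.n_frames):
        labels[:, f] = assign_ss(traj.coordinates[f], traj.topology, residues)
    keys = [(r.chain_id, r.residue_index) for r in residues]
    return SSMatrix(labels=labels, residues=keys, times=traj.times.copy())


def ss_content(matrix: SSMatrix) -> dict[str, float]:
    """Overall fractions of E, T and C (cell counts; they sum to 1)."""
    total = matrix.labels.size
    if total == 0:
        raise ValueError("empty secondary-structure matrix")
    return {lab: float(np.sum(matrix.labels == lab)) / total for lab in LABELS}


def ss_propensity(matrix: SSMatrix) -> PropensityTable:
    """Per-residue time fractions of each label (rows sum to 1)."""
    nf = matrix.n_frames
    return PropensityTable(
        residues=list(matrix.residues),
        p_e=np.sum(matrix.labels == "E", axis=1) / nf,
        p_t=np.sum(matrix.labels == "T", axis=1) / nf,
        p_c=np.sum(matrix.labels == "C", axis=1) / nf,
    )


def strand_propensity_ratio(
    table: PropensityTable,
    region: tuple[int, int],
    chain_a: str,
    chain_b: str,
) -> float:
    """Ratio (>= 1) of mean β-strand propensity over a residue region
    between the two peptides of a dimer.

    Returns ``inf`` (with a warning) when exactly one chain has zero mean;
    raises when both do.
    """
    import warnings

    lo, hi = region
    means = []
    for chain in (chain_a, chain_b):
        rows = [
            i for i, (ch, resid) in enumerate(table.residues)
            if ch == chain and lo <= resid <= hi
        ]
        if not rows:
            raise ValueError(f"region {region} is empty for chain {chain!r}")
        means.append(float(np.mean(table.p_e[rows])))
    a, b = means
    if a == 0.0 and b == 0.0:
        raise ValueError("both chains have zero strand propensity in the region")
    if min(a, b) == 0.0:
        warnings.warn("one chain has zero strand propensity; ratio is infinite")
        return INFINITE_RATIO
    return max(a, b) / min(a, b)
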