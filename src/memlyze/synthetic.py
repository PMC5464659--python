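"""Synthetic peptide-dimer and bilayer trajectories with known ground truth.

Every analysis stage in this package is validated against systems whose
answers are planted by construction:

* ``make_dimer`` builds two 42-residue backbone chains (N, CA, C, O per
  residue) with ideal extended-β geometry. Each chain carries the peptide's
  five-strand topology - an N-terminal hairpin (β1 2-5, β2 11-14) and a
  C-terminal three-strand sheet (β3 17-22, β4 31-36, β5 39-41) - laid out on
  a hydrogen-bond lattice whose Kabsch-Sander register is exact, so the
  secondary-structure assigner's labels are known a priori. The four dimer
  arrangements differ in which strands of the two chains are adjacent:
  2NCb pairs the N-terminal hairpins (inter-chain β1 contacts), CNNC pairs
  β3-β3, NCCN pairs β5-β5 and NCNC pairs β5(A)-β3(B), mirroring the observed
  inter-peptide hydrogen-bond patterns.

* ``make_bilayer`` builds two leaflets of pseudo-lipids (one P head atom plus
  two short all-trans acyl chains) on a jittered lattice with box xy area =
  n_lipids x apl0, optionally compressed around a central inclusion so the
  per-lipid Voronoi area inside the kernel is (1 - amplitude) x apl0.

* ``simulate`` evolves lipids by lateral Brownian motion with a two-state
  Markov exchange in/out of a shell around the inclusion (planted mean dwell
  time 1/k), renders positions through the compression map so the planted
  area signal persists dynamically, and melts selected strands to coil
  after scheduled frames.

Geometry caveats that are part of the planted truth: hydrogen-bonded
β-ladders couple strand pairs, so melting a strand also un-pairs its ladder
partner (melting β1 removes β2's bridges too); the strand-flanking "anchor"
residues 6/10 and 23/30 participate in the ladders and are labelled E; the
long β3-β4 loop (24-29) is irregular coil, while turns 7-9 and 37-38 are
hydrogen-bonded n-turns labelled T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ATOMIC_MASSES, Atom, Frame, Topology, Trajectory, minimum_image
from .strands import AB42_SEQUENCE, DEFAULT_STRAND_MAP, THREE_LETTER, StrandMap

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "ARRANGEMENTS",
    "make_dimer",
    "make_bilayer",
    "simulate",
    "compression_map",
]

ARRANGEMENTS = ("2NCb", "CNNC", "NCNC", "NCCN")

# backbone lattice constants (nm)
SLOT = 0.35        # x spacing between successive strand residues
ROW = 0.412        # y spacing between hydrogen-bonded strands
CN = 0.233         # C position along the chain direction from N
CA_OFF = 0.117     # CA position along the chain direction from N
O_OFF = 0.122      # carbonyl O offset perpendicular to the strand
PLEAT = 0.05       # CA out-of-plane pleat
XGAP = 0.7         # x offset of the C-terminal sheet
ZC = 1.2           # sheet-plane separation between the two sheets of a chain
MELT_SHIFT = 0.45  # out-of-plane displacement of melted strands
MELT_JITTER = 0.08 # per-frame Gaussian jitter of melted strands (per axis)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    Defaults are the desk-scale conditions every test runs under: 64 lipids
    per leaflet at the fluid-phase DPPC area 0.64 nm^2, lateral diffusion
    5e-5 nm^2/ps, shell exchange rate 0.01/ps (mean dwell 100 ps), 2000
    frames at 1 ps.
    """

    seed: int = 0
    n_lipids_per_leaflet: int = 64
    apl0: float = 0.64                      # nm^2
    compression_amplitude: float = 0.2      # fractional area reduction
    compression_radius: float = 1.5         # nm (virtual kernel radius)
    transition_radius: float | None = None  # default: 2 x compression_radius
    dimer_arrangement: str | None = None
    inclusion: str | None = None            # None | "rod" | "dimer"
    melt_schedule: tuple[tuple[str, str, int], ...] = ()  # (strand, chain, frame)
    diffusion: float = 5e-5                 # nm^2/ps
    exchange_rate: float = 0.01             # 1/ps (shell-exit rate)
    n_frames: int = 2000
    dt: float = 1.0                         # ps
    lattice_jitter: float = 0.05            # nm
    head_z: float = 1.9                     # leaflet half-separation, nm
    n_acyl_carbons: int = 4
    acyl_tilt: float = 0.0                  # degrees from the membrane normal
    n_waters: int = 0
    strand_map: StrandMap = field(default_factory=lambda: DEFAULT_STRAND_MAP)

    def __post_init__(self) -> None:
        if self.apl0 <= 0:
            raise ValueError("apl0 must be positive")
        if not (0.0 <= self.compression_amplitude < 1.0):
            raise ValueError("compression amplitude must lie in [0, 1)")
        if self.exchange_rate < 0:
            raise ValueError("exchange rate must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.dimer_arrangement is not None and (
            self.dimer_arrangement not in ARRANGEMENTS
        ):
            raise ValueError(
                f"unknown arrangement {self.dimer_arrangement!r}; "
                f"expected one of {ARRANGEMENTS}"
            )
        if self.n_acyl_carbons < 3:
            raise ValueError("acyl chains need >= 3 carbons")

    @property
    def effective_inclusion(self) -> str | None:
        if self.dimer_arrangement is not None:
            return "dimer"
        return self.inclusion

    @property
    def box_xy(self) -> float:
        return math.sqrt(self.n_lipids_per_leaflet * self.apl0)

    @property
    def shell_radius(self) -> float:
        """Rendered (measurable) radius of the exchange shell."""
        c = math.sqrt(1.0 - self.compression_amplitude)
        if self.effective_inclusion is None:
            return self.compression_radius
        return c * self.compression_radius


@dataclass
class GroundTruth:
    """Planted quantities of one synthetic trajectory."""

    apl0: float
    compressed_apl: float
    shell_radius: float
    mean_dwell: float                 # ps; 1/k
    leaflets: dict[int, str]          # lipid residue index -> top/bottom
    melt_schedule: tuple[tuple[str, str, int], ...]
    arrangement: str | None


# ---------------------------------------------------------------------------
# ideal-geometry dimer
# ---------------------------------------------------------------------------

def _orient(row: int, slot: int) -> float:
    """Sign of the carbonyl/amide y direction on the strand lattice."""
    return 1.0 if (row + slot) % 2 == 0 else -1.0


def _strand_residue(res: dict, slot: int, row: int, direction: int,
                    x_base: float, z: float) -> None:
    x_n = x_base + slot * SLOT + (CN if direction < 0 else 0.0)
    y = row * ROW
    o = _orient(row, slot)
    res["N"] = np.array([x_n, y, z])
    res["CA"] = np.array(
        [x_n + direction * CA_OFF, y, z + (PLEAT if slot % 2 == 0 else -PLEAT)]
    )
    res["C"] = np.array([x_n + direction * CN, y, z])
    res["O"] = res["C"] + np.array([0.0, o * O_OFF, 0.0])


def _free_residue(res: dict, n, ca, c, o_dir) -> None:
    res["N"] = np.asarray(n, float)
    res["CA"] = np.asarray(ca, float)
    res["C"] = np.asarray(c, float)
    res["O"] = res["C"] + O_OFF * np.asarray(o_dir, float) / np.linalg.norm(o_dir)


def _chain_template(z_n: float, z_c: float) -> dict[int, dict[str, np.ndarray]]:
    """Backbone coordinates of one chain in its local frame.

    The N-terminal hairpin occupies rows 0-1 at z = z_n, the C-terminal sheet
    rows 2-4 at z = z_c (x offset XGAP). Carbonyl orientations follow the
    lattice parity so the Kabsch-Sander hydrogen-bond register is exact.
    """
    res: dict[int, dict[str, np.ndarray]] = {i: {} for i in range(1, 43)}

    # row 0: residue 1 (coil), β1 = 2-5, anchor 6
    for resid, slot in [(1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 6)]:
        _strand_residue(res[resid], slot, row=0, direction=+1, x_base=0.0, z=z_n)
    # hairpin turn 7-9 (right side, lifted out of the sheet plane)
    _free_residue(res[7], (2.70, 0.05, z_n + 0.28), (2.80, 0.08, z_n + 0.36),
                  (2.90, 0.12, z_n + 0.30), (0, 0, 1))
    _free_residue(res[8], (2.95, 0.185, z_n + 0.30), (3.05, 0.21, z_n + 0.40),
                  (3.05, 0.25, z_n + 0.25), (0, 0, 1))
    # O(9) must point +y so the reconstructed H of residue 10 points -y
    _free_residue(res[9], (2.90, 0.30, z_n + 0.30), (2.80, 0.33, z_n + 0.38),
                  (2.70, 0.36, z_n + 0.28), (0, 1, 0))
    # row 1: anchor 10, β2 = 11-14
    for resid, slot in [(10, 6), (11, 5), (12, 4), (13, 3), (14, 2)]:
        _strand_residue(res[resid], slot, row=1, direction=-1, x_base=0.0, z=z_n)
    # linker 15-16 between the sheets; O(16) points -y so H(17) points +y
    zmid = 0.5 * (z_n + z_c)
    _free_residue(res[15], (0.75, 0.62, zmid - 0.35), (0.85, 0.66, zmid - 0.25),
                  (0.95, 0.70, zmid - 0.32), (0, 0, 1))
    _free_residue(res[16], (1.20, 0.74, zmid), (1.30, 0.78, zmid + 0.10),
                  (1.40, 0.82, zmid + 0.02), (0, -1, 0))
    # row 2: β3 = 17-22, anchor 23
    for resid, slot in [(17, 0), (18, 1), (19, 2), (20, 3), (21, 4), (22, 5), (23, 6)]:
        _strand_residue(res[resid], slot, row=2, direction=+1, x_base=XGAP, z=z_c)
    # irregular loop 24-29 (labelled coil); arcs to the right of the anchors
    xa = XGAP + 6 * SLOT
    for k, resid in enumerate(range(24, 30), start=1):
        t = k / 7.0
        n = np.array([xa + 0.95 * math.sin(math.pi * t), 2 * ROW + t * ROW,
                      z_c + 0.40 * math.sin(math.pi * t)])
        ca = n + np.array([0.08, 0.02, 0.10])
        c = n + np.array([0.16, 0.05, 0.02])
        # carbonyls point below the arc so reconstructed amides point away
        # from the sheet; O(29) must point +y to direct H(30) at O(23)
        o_dir = (0, 1, 0) if resid == 29 else (0, 0, -1)
        _free_residue(res[resid], n, ca, c, o_dir)
    # row 3: anchor 30, β4 = 31-36
    for resid, slot in [(30, 6), (31, 5), (32, 4), (33, 3), (34, 2), (35, 1), (36, 0)]:
        _strand_residue(res[resid], slot, row=3, direction=-1, x_base=XGAP, z=z_c)
    # tight turn 37-38 (left side); O(38) points +y so H(39) points -y
    _free_residue(res[37], (XGAP - 0.35, 1.28, z_c + 0.25),
                  (XGAP - 0.45, 1.32, z_c + 0.35),
                  (XGAP - 0.35, 1.40, z_c + 0.28), (0, 0, 1))
    _free_residue(res[38], (XGAP - 0.30, 1.50, z_c + 0.25),
                  (XGAP - 0.40, 1.54, z_c + 0.33),
                  (XGAP - 0.28, 1.58, z_c + 0.22), (0, 1, 0))
    # row 4: β5 = 39-41
    for resid, slot in [(39, 1), (40, 2), (41, 3)]:
        _strand_residue(res[resid], slot, row=4, direction=+1, x_base=XGAP, z=z_c)
    # C-terminal residue 42, off-lattice
    _free_residue(res[42], (XGAP + 1.40, 4 * ROW + 0.30, z_c + 0.30),
                  (XGAP + 1.50, 4 * ROW + 0.35, z_c + 0.40),
                  (XGAP + 1.60, 4 * ROW + 0.40, z_c + 0.30), (0, 0, 1))
    return res


_RZ = np.diag([-1.0, -1.0, 1.0])   # 180 deg about z
_RY = np.diag([-1.0, 1.0, -1.0])   # 180 deg about y


def _dimer_chains(arrangement: str) -> dict[str, dict[int, dict[str, np.ndarray]]]:
    a = _chain_template(z_n=0.0, z_c=ZC)

    def n_of(chain, resid):
        return chain[resid]["N"]

    if arrangement == "2NCb":
        b0 = _chain_template(z_n=0.0, z_c=-ZC)
        rot, anchor_res = _RZ, 5
        target = np.array([n_of(a, 3)[0] + CN, -ROW, 0.0])
    elif arrangement == "CNNC":
        b0 = _chain_template(z_n=-ZC, z_c=ZC)
        rot, anchor_res = _RZ, 20
        target = np.array([n_of(a, 18)[0] + CN, ROW, ZC])
    elif arrangement == "NCCN":
        b0 = _chain_template(z_n=-ZC, z_c=ZC)
        rot, anchor_res = _RZ, 40
        target = np.array([n_of(a, 40)[0] + CN, 5 * ROW, ZC])
    elif arrangement == "NCNC":
        b0 = _chain_template(z_n=ZC, z_c=-ZC)
        rot, anchor_res = _RY, 20
        target = np.array([n_of(a, 40)[0] + CN, 5 * ROW, ZC])
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    shift = target - rot @ b0[anchor_res]["N"]
    b = {
        resid: {name: rot @ xyz + shift for name, xyz in atoms.items()}
        for resid, atoms in b0.items()
    }
    return {"A": a, "B": b}


def make_dimer(
    spec: SyntheticSpec | str, margin: float = 2.0
) -> tuple[Topology, Frame]:
    """Two-chain ideal-geometry dimer in a padded orthorhombic box.

    Accepts a :class:`SyntheticSpec` or a bare arrangement name. Residue
    names follow the 42-residue amyloid-β sequence.
    """
    arrangement = spec if isinstance(spec, str) else spec.dimer_arrangement
    if arrangement is None:
        raise ValueError("spec.dimer_arrangement is not set")
    chains = _dimer_chains(arrangement)
    atoms: list[Atom] = []
    xyz: list[np.ndarray] = []
    for chain_id in ("A", "B"):
        for resid in range(1, 43):
            resname = THREE_LETTER[AB42_SEQUENCE[resid - 1]]
            for name in ("N", "CA", "C", "O"):
                element = "C" if name == "CA" else name[0]
                atoms.append(
                    Atom(name=name, element=element, residue_index=resid,
                         residue_name=resname, chain_id=chain_id,
                         molecule_kind="peptide", mass=ATOMIC_MASSES[element])
                )
                xyz.append(chains[chain_id][resid][name])
    coords = np.array(xyz)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    coords = coords - lo + margin
    box = hi - lo + 2 * margin
    topo = Topology(atoms=atoms, peptide_chains=["A", "B"])
    return topo, Frame(coords, box, 0.0)


def _melt_atom_mask(topology: Topology, strand: str, chain: str,
                    strand_map: StrandMap) -> np.ndarray:
    lo, hi = strand_map.strands[strand]
    return (
        (topology.kinds == "peptide")
        & (topology.chain_ids == chain)
        & (topology.resids >= lo)
        & (topology.resids <= hi)
    )


# ---------------------------------------------------------------------------
# bilayer
# ---------------------------------------------------------------------------

def compression_map(
    xy: np.ndarray,
    center: np.ndarray,
    box_xy: np.ndarray,
    amplitude: float,
    radius: float,
    transition_radius: float,
) -> np.ndarray:
    """Radial area-compression map around an inclusion.

    Points within ``radius`` of the centre contract by sqrt(1 - amplitude)
    (their local area scales by 1 - amplitude); the annulus out to
    ``transition_radius`` interpolates linearly back to the identity, and
    everything beyond is untouched. Monotone in r, evaluated on
    minimum-image displacements.
    """
    if amplitude == 0.0:
        return np.array(xy, dtype=float, copy=True)
    c = math.sqrt(1.0 - amplitude)
    v = minimum_image(np.asarray(xy, float) - center, box_xy)
    r = np.linalg.norm(v, axis=-1)
    rc = c * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        scale_mid = (rc + (r - radius) * (transition_radius - rc)
                     / (transition_radius - radius)) / r
    scale = np.where(r <= radius, c, np.where(r <= transition_radius, scale_mid, 1.0))
    scale = np.where(r < 1e-12, 1.0, scale)
    return np.mod(center + v * scale[..., None], box_xy)


def _transition_radius(spec: SyntheticSpec) -> float:
    if spec.transition_radius is not None:
        rt = spec.transition_radius
    else:
        rt = 2.0 * spec.compression_radius
    rt = min(rt, 0.49 * spec.box_xy)
    if rt <= spec.compression_radius:
        raise ValueError("transition radius must exceed the compression radius")
    return rt


def _lipid_atoms(spec: SyntheticSpec, start_resid: int) -> list[Atom]:
    atoms = []
    names = ["P"] + [f"C1{k}" for k in range(1, spec.n_acyl_carbons + 1)] + [
        f"C2{k}" for k in range(1, spec.n_acyl_carbons + 1)
    ]
    n_lipids = 2 * spec.n_lipids_per_leaflet
    for i in range(n_lipids):
        for name in names:
            element = name[0]
            atoms.append(
                Atom(name=name, element=element, residue_index=start_resid + i,
                     residue_name="DPPC", chain_id="", molecule_kind="lipid",
                     mass=ATOMIC_MASSES[element])
            )
    return atoms


def _acyl_offsets(spec: SyntheticSpec, leaflet_sign: float) -> np.ndarray:
    """Offsets of the 2 x n acyl carbons relative to the head atom.

    All-trans zig-zag pointing toward the membrane centre; the C(i-1)->C(i+1)
    axis is exactly the membrane normal (optionally tilted), so -S_CD of the
    untilted chain is 0.5 by construction.
    """
    n = spec.n_acyl_carbons
    k = np.arange(n)
    zig = np.where(k % 2 == 0, 0.042, -0.042)
    z = -(0.30 + 0.127 * k) * leaflet_sign
    sn1 = np.stack([zig, np.full(n, -0.08), z], axis=1)
    sn2 = np.stack([zig, np.full(n, +0.08), z], axis=1)
    offs = np.vstack([sn1, sn2])
    if spec.acyl_tilt:
        t = math.radians(spec.acyl_tilt)
        rot = np.array(
            [[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]]
        )
        offs = offs @ rot.T
    return offs


def _lattice(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    m = math.isqrt(spec.n_lipids_per_leaflet)
    if m * m != spec.n_lipids_per_leaflet:
        raise ValueError(
            f"n_lipids_per_leaflet must be a perfect square for the lattice, "
            f"got {spec.n_lipids_per_leaflet}"
        )
    spacing = spec.box_xy / m
    i, j = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    pts = (np.stack([i, j], axis=-1).reshape(-1, 2) + 0.5) * spacing
    if spec.lattice_jitter > 0:
        pts = pts + rng.normal(0.0, spec.lattice_jitter, pts.shape)
    return np.mod(pts, spec.box_xy)


def _rod_atoms_and_coords(spec: SyntheticSpec, lz: float) -> tuple[list[Atom], np.ndarray]:
    """A thin vertical inclusion spanning the box: a column of pseudo-atoms."""
    n = max(8, int(lz / 0.25))
    center = spec.box_xy / 2.0
    z = np.linspace(0.2, lz - 0.2, n)
    coords = np.stack([np.full(n, center), np.full(n, center), z], axis=1)
    atoms = [
        Atom(name="CA", element="C", residue_index=1, residue_name="ROD",
             chain_id="X", molecule_kind="peptide", mass=ATOMIC_MASSES["C"])
        for _ in range(n)
    ]
    return atoms, coords


def _dimer_membrane_coords(arrangement: str) -> tuple[list[Atom], np.ndarray]:
    """Dimer atoms mapped into the membrane frame.

    The strand axis (template x) becomes the membrane normal z, so the
    strands span the bilayer; the sheet-stacking and sheet-separation axes
    become lateral. Coordinates are centred at the origin.
    """
    topo, frame = make_dimer(arrangement, margin=0.0)
    xyz = frame.coordinates
    mapped = xyz[:, [1, 2, 0]]  # (x,y,z)_template -> (y,z,x)_membrane
    mapped = mapped - mapped.mean(axis=0)
    return topo.atoms, mapped


def make_bilayer(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[Topology, Frame]:
    """Two-leaflet pseudo-lipid bilayer, optionally with a central inclusion.

    Box xy area is exactly n_lipids_per_leaflet x apl0. With zero jitter and
    no inclusion every lipid's Voronoi area equals apl0; with an inclusion
    and a compression kernel, lipids inside the kernel are crowded to
    (1 - amplitude) x apl0.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    box_xy = spec.box_xy
    inclusion = spec.effective_inclusion

    pep_atoms: list[Atom] = []
    pep_coords = np.empty((0, 3))
    pep_extent = 0.0
    if inclusion == "dimer":
        pep_atoms, pep_coords = _dimer_membrane_coords(spec.dimer_arrangement)
        pep_extent = np.abs(pep_coords[:, 2]).max()
    lz = 2.0 * max(spec.head_z + 0.8, pep_extent + 0.8)
    center = np.array([box_xy / 2.0, box_xy / 2.0])
    if inclusion == "rod":
        pep_atoms, pep_coords = _rod_atoms_and_coords(spec, lz)
    elif inclusion == "dimer":
        pep_coords = pep_coords + np.array([center[0], center[1], lz / 2.0])

    top = _lattice(spec, rng)
    bottom = _lattice(spec, rng)
    if inclusion is not None and spec.compression_amplitude > 0:
        rt = _transition_radius(spec)
        box2 = np.array([box_xy, box_xy])
        top = compression_map(top, center, box2, spec.compression_amplitude,
                              spec.compression_radius, rt)
        bottom = compression_map(bottom, center, box2, spec.compression_amplitude,
                                 spec.compression_radius, rt)

    n_leaf = spec.n_lipids_per_leaflet
    lipid_atoms = _lipid_atoms(spec, start_resid=1)
    coords = [pep_coords] if len(pep_coords) else []
    for heads_xy, sign in ((top, +1.0), (bottom, -1.0)):
        offs = _acyl_offsets(spec, sign)
        z_head = lz / 2.0 + sign * spec.head_z
        heads = np.column_stack([heads_xy, np.full(len(heads_xy), z_head)])
        per_lipid = np.concatenate(
            [heads[:, None, :], heads[:, None, :] + offs[None, :, :]], axis=1
        )
        coords.append(per_lipid.reshape(-1, 3))

    water_atoms: list[Atom] = []
    if spec.n_waters > 0:
        zlo = lz / 2.0 + spec.head_z + 0.4
        n_each = spec.n_waters // 2
        w_top = np.column_stack([
            rng.uniform(0, box_xy, n_each), rng.uniform(0, box_xy, n_each),
            rng.uniform(zlo, lz - 0.2, n_each),
        ])
        w_bot = np.column_stack([
            rng.uniform(0, box_xy, spec.n_waters - n_each),
            rng.uniform(0, box_xy, spec.n_waters - n_each),
            rng.uniform(0.2, lz - zlo, spec.n_waters - n_each),
        ])
        coords.append(np.vstack([w_top, w_bot]))
        water_atoms = [
            Atom(name="OW", element="O", residue_index=i + 1, residue_name="SOL",
                 chain_id="", molecule_kind="water", mass=ATOMIC_MASSES["O"])
            for i in range(spec.n_waters)
        ]

    atoms = pep_atoms + lipid_atoms + water_atoms
    n_carbons = spec.n_acyl_carbons
    topo = Topology(
        atoms=atoms,
        peptide_chains=sorted({a.chain_id for a in pep_atoms if a.chain_id}),
        lipid_head_atom_name="P",
        acyl_chain_definitions={
            "sn1": [f"C1{k}" for k in range(1, n_carbons + 1)],
            "sn2": [f"C2{k}" for k in range(1, n_carbons + 1)],
        },
    )
    frame = Frame(np.vstack(coords), np.array([box_xy, box_xy, lz]), 0.0)
    frame.validate(topo)
    return topo, frame


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def simulate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Seed-deterministic synthetic trajectory with planted observables.

    Lipid virtual positions diffuse laterally; a two-state Markov process
    (exit rate k, entry rate balancing a uniform stationary density) flips
    shell membership, teleporting lipids across the shell boundary and
    reflecting diffusion at it, so membership dwell times are exponential
    with the planted mean 1/k. Rendered positions pass through the
    compression map, keeping the planted per-lipid area signal. Scheduled
    strand melts displace and jitter their residues out of the hydrogen-bond
    lattice from the melt frame on.
    """
    rng = np.random.default_rng(spec.seed)
    topo, frame0 = make_bilayer(spec, rng)
    box = frame0.box
    box2 = box[:2]
    center = box2 / 2.0
    inclusion = spec.effective_inclusion

    n_pep = int(np.sum(topo.kinds == "peptide"))
    n_lip = 2 * spec.n_lipids_per_leaflet
    atoms_per_lipid = 1 + 2 * spec.n_acyl_carbons
    lip_slice = slice(n_pep, n_pep + n_lip * atoms_per_lipid)
    head_offsets = n_pep + np.arange(n_lip) * atoms_per_lipid

    base = frame0.coordinates
    pep_base = base[:n_pep].copy()

    # recover virtual (uncompressed) head positions by regenerating the
    # lattices with a twin RNG stream
    rng_init = np.random.default_rng(spec.seed)
    virt = np.vstack([_lattice(spec, rng_init), _lattice(spec, rng_init)])
    head_z = base[head_offsets, 2]
    offs_top = np.vstack([[0.0, 0.0, 0.0], _acyl_offsets(spec, +1.0)])
    offs_bot = np.vstack([[0.0, 0.0, 0.0], _acyl_offsets(spec, -1.0)])
    leaflet_sign = np.where(np.arange(n_lip) < spec.n_lipids_per_leaflet, 1.0, -1.0)

    r_v = spec.compression_radius
    use_exchange = inclusion is not None and spec.exchange_rate > 0
    if use_exchange:
        area = box2[0] * box2[1]
        a_in = math.pi * r_v**2
        if a_in >= area:
            raise ValueError("shell does not fit in the box")
        k_out = spec.exchange_rate
        p_out = 1.0 - math.exp(-k_out * spec.dt)

    def radial(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = minimum_image(pts - center, box2)
        return np.linalg.norm(v, axis=1), v

    def sample_in(n: int) -> np.ndarray:
        r = r_v * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * math.pi, n)
        return np.mod(center + np.column_stack([r * np.cos(th), r * np.sin(th)]), box2)

    def sample_out(n: int) -> np.ndarray:
        out = np.empty((n, 2))
        need = np.arange(n)
        while len(need):
            cand = rng.uniform(0, box2, (len(need), 2))
            r, _ = radial(cand)
            good = r > r_v
            out[need[good]] = cand[good]
            need = need[~good]
        return out

    state_in = np.zeros(n_lip, dtype=bool)
    if use_exchange:
        r0, _ = radial(virt)
        state_in = r0 <= r_v

    rt = _transition_radius(spec) if spec.compression_amplitude > 0 else None

    melt_masks = []
    for strand, chain, melt_frame in spec.melt_schedule:
        mask = _melt_atom_mask(topo, strand, chain, spec.strand_map)
        if not mask.any():
            raise ValueError(f"melt target {strand}/{chain} matches no atoms")
        sign = 1.0 if chain == "A" else -1.0
        melt_masks.append((np.flatnonzero(mask), int(melt_frame), sign))

    sigma = math.sqrt(2.0 * spec.diffusion * spec.dt)
    n_frames = spec.n_frames
    all_coords = np.empty((n_frames, topo.n_atoms, 3))
    boxes = np.tile(box, (n_frames, 1))

    for f in range(n_frames):
        if f > 0:
            if sigma > 0:
                virt += rng.normal(0.0, sigma, virt.shape)
            virt = np.mod(virt, box2)
            if use_exchange:
                r, v = radial(virt)
                # reflect diffusion at the shell boundary, per state
                wrong_in = state_in & (r > r_v)
                wrong_out = (~state_in) & (r <= r_v)
                for wrong in (wrong_in, wrong_out):
                    if wrong.any():
                        rr = r[wrong]
                        refl = np.clip(2 * r_v - rr, 1e-6, None)
                        virt[wrong] = np.mod(
                            center + v[wrong] * (refl / np.maximum(rr, 1e-12))[:, None],
                            box2,
                        )
                # Markov exchange: each in-lipid exits with first-order rate
                # k; every exit is paired with the entry of a random outside
                # lipid, so the shell population (and the planted density)
                # stays exactly constant while in-dwells remain exponential
                u = rng.uniform(0, 1, n_lip)
                leave = state_in & (u < p_out)
                n_leave = int(leave.sum())
                if n_leave:
                    out_pool = np.flatnonzero(~state_in)
                    enter_idx = rng.choice(
                        out_pool, size=min(n_leave, len(out_pool)), replace=False
                    )
                    virt[leave] = sample_out(n_leave)
                    virt[enter_idx] = sample_in(len(enter_idx))
                    state_in[leave] = False
                    state_in[enter_idx] = True

        if spec.compression_amplitude > 0 and inclusion is not None:
            rendered = compression_map(
                virt, center, box2, spec.compression_amplitude, r_v, rt
            )
        else:
            rendered = virt
        heads = np.column_stack([rendered, head_z])
        lip = np.where(
            (leaflet_sign[:, None, None] > 0),
            heads[:, None, :] + offs_top[None, :, :],
            heads[:, None, :] + offs_bot[None, :, :],
        )
        coords = all_coords[f]
        coords[lip_slice] = lip.reshape(-1, 3)
        if n_pep:
            pep = pep_base.copy()
            for idx, melt_frame, sign in melt_masks:
                if f >= melt_frame:
                    pep[idx, 1] += sign * MELT_SHIFT
                    pep[idx] += rng.normal(0.0, MELT_JITTER, (len(idx), 3))
            coords[:n_pep] = pep
        elif len(melt_masks):
            raise ValueError("melt schedule given but no peptide present")
        if topo.n_atoms > lip_slice.stop:
            coords[lip_slice.stop:] = base[lip_slice.stop:]

    traj = Trajectory(
        topo, all_coords, boxes,
        times=np.arange(n_frames) * spec.dt, frame_spacing=spec.dt,
    )
    leaflets = {
        i + 1: ("top" if i < spec.n_lipids_per_leaflet else "bottom")
        for i in range(n_lip)
    }
    truth = GroundTruth(
        apl0=spec.apl0,
        compressed_apl=spec.apl0 * (1.0 - spec.compression_amplitude),
        shell_radius=spec.shell_radius,
        mean_dwell=(1.0 / spec.exchange_rate) if spec.exchange_rate > 0 else math.inf,
        leaflets=leaflets,
        melt_schedule=spec.melt_schedule,
        arrangement=spec.dimer_arrangement,
    )
    return traj, truth
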