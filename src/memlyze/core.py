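"""Core data model: topology, frames, trajectories, selections, periodic geometry.

Internal units are nm for lengths and ps for times throughout the package;
file readers convert at the boundary (GRO is nm-native, PDB is Å).
Atom indices are 0-based internally and 1-based in file formats and reports.
Only orthorhombic periodic boxes are supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "SelectionError",
    "select_atoms",
    "min_image_distance",
    "minimum_image",
    "DEFAULT_KIND_MAP",
    "ATOMIC_MASSES",
]

# Standard atomic masses (amu) for the elements occurring in peptide/lipid
# coarse backbones and common ions.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.453,
    "K": 39.098,
}

# Residue-name -> molecule-kind mapping. Shipped as data so that GRO dialects
# with different residue naming can override it (see read_structure's
# ``kind_map`` argument and the YAML config).
DEFAULT_KIND_MAP = {
    "DPPC": "lipid",
    "DMPC": "lipid",
    "POPC": "lipid",
    "SOL": "water",
    "HOH": "water",
    "WAT": "water",
    "NA": "ion",
    "NA+": "ion",
    "CL": "ion",
    "CL-": "ion",
    "K": "ion",
    "K+": "ion",
}

_VALID_KINDS = ("peptide", "lipid", "water", "ion")


class SelectionError(ValueError):
    """Raised for malformed selection queries or empty strict selections."""


def guess_element(atom_name: str, molecule_kind: str) -> str:
    """Infer the element from an atom name.

    Leading digits are stripped (e.g. ``1H``); for peptide and lipid atoms the
    first letter wins (so ``CA`` is carbon, not calcium), while for ions the
    full name is matched against the mass table.
    """
    name = atom_name.strip().upper()
    name = re.sub(r"^\d+", "", name)
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if molecule_kind == "ion" and name in ATOMIC_MASSES:
        return name
    return name[0]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int  # 1-based
    residue_name: str
    chain_id: str
    molecule_kind: str
    mass: float


@dataclass
class Topology:
    """Static description of the system: atoms, chains, lipid definitions."""

    atoms: list[Atom]
    peptide_chains: list[str] = field(default_factory=list)
    lipid_head_atom_name: str = "P"
    # per-lipid ordered carbon atom-name lists for the two acyl chains
    acyl_chain_definitions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.residue_index < 1:
                raise ValueError(f"residue index must be >= 1, got {a.residue_index}")
            if a.molecule_kind not in _VALID_KINDS:
                raise ValueError(f"unknown molecule kind {a.molecule_kind!r}")
            if a.molecule_kind == "peptide" and not a.chain_id:
                raise ValueError("peptide atoms must carry a chain id")
        for chain_name, carbons in self.acyl_chain_definitions.items():
            if len(carbons) < 3:
                raise ValueError(
                    f"acyl chain {chain_name!r} must list >= 3 carbons, got {len(carbons)}"
                )
        self._build_arrays()

    def _build_arrays(self) -> None:
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.resids = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.resnames = np.array([a.residue_name for a in self.atoms])
        self.chain_ids = np.array([a.chain_id for a in self.atoms])
        self.kinds = np.array([a.molecule_kind for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def lipid_head_indices(self) -> np.ndarray:
        """Indices of the one head reference atom per lipid, in lipid order."""
        mask = (self.kinds == "lipid") & (self.names == self.lipid_head_atom_name)
        idx = np.flatnonzero(mask)
        lipid_resids = np.unique(self.resids[self.kinds == "lipid"])
        if len(idx) != len(lipid_resids):
            raise ValueError(
                "every lipid must have exactly one head reference atom "
                f"({len(idx)} heads for {len(lipid_resids)} lipids)"
            )
        return idx

    def peptide_residues(self) -> list[tuple[str, int]]:
        """Ordered (chain_id, residue_index) pairs of peptide residues."""
        seen: list[tuple[str, int]] = []
        prev = None
        for a in self.atoms:
            if a.molecule_kind != "peptide":
                continue
            key = (a.chain_id, a.residue_index)
            if key != prev:
                seen.append(key)
                prev = key
        return seen


@dataclass
class Frame:
    """One set of coordinates (nm) with its orthorhombic box (nm) and time (ps)."""

    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (Lx, Ly, Lz)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise ValueError("box must be (Lx, Ly, Lz)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def validate(self, topology: Topology) -> None:
        if self.coordinates.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame has {self.coordinates.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )


class Trajectory:
    """Time-ordered frames sharing one topology.

    Coordinates are held as one (n_frames, n_atoms, 3) array; ``frames``
    yields lightweight :class:`Frame` views.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        boxes: np.ndarray,
        times: np.ndarray | None = None,
        frame_spacing: float | None = None,
    ) -> None:
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        self.boxes = np.asarray(boxes, dtype=float)
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if times is None:
            spacing = 1.0 if frame_spacing is None else float(frame_spacing)
            times = np.arange(self.n_frames, dtype=float) * spacing
        self.times = np.asarray(times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if frame_spacing is not None:
            self.frame_spacing = float(frame_spacing)
        elif self.n_frames > 1:
            self.frame_spacing = float(self.times[1] - self.times[0])
        else:
            self.frame_spacing = 1.0

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, topology: Topology, frames: list[Frame],
                    frame_spacing: float | None = None) -> "Trajectory":
        coords = np.stack([f.coordinates for f in frames])
        boxes = np.stack([f.box for f in frames])
        times = np.array([f.time for f in frames], dtype=float)
        if frame_spacing is None and len(frames) > 1 and np.all(np.diff(times) > 0):
            return cls(topology, coords, boxes, times=times)
        if len(frames) > 1 and not np.all(np.diff(times) > 0):
            spacing = 1.0 if frame_spacing is None else frame_spacing
            times = np.arange(len(frames), dtype=float) * spacing
        return cls(topology, coords, boxes, times=times, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Works on arrays of shape (..., k) with box of shape (k,); pass the first
    two box components for lateral (xy) displacements.
    """
    displacement = np.asarray(displacement, dtype=float)
    box = np.asarray(box, dtype=float)
    return displacement - box * np.round(displacement / box)


def min_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray, lateral: bool = False
) -> np.ndarray:
    """Euclidean distance between points under the minimum-image convention.

    ``a`` and ``b`` broadcast against each other; with ``lateral=True`` only
    the xy components enter (distances in the membrane plane).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = a - b
    if lateral:
        d = d[..., :2]
        box = box[:2]
    d = minimum_image(d, box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = ("N", "CA", "C")


def _parse_resid_ranges(tokens: list[str]) -> list[tuple[int, int]]:
    ranges = []
    for tok in tokens:
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", tok)
        if m is None:
            raise SelectionError(f"bad residue token {tok!r} (expected N or N-M)")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise SelectionError(f"descending residue range {tok!r}")
        ranges.append((lo, hi))
    return ranges


def select_atoms(
    topology: Topology, query: str, allow_empty: bool = False
) -> np.ndarray:
    """Evaluate a selection query and return sorted, unique 0-based indices.

    Grammar: clauses joined by ``and``; each clause is one of
    ``name <n> [<n> ...]``, ``resid <i>|<i>-<j> [...]``, ``chain <id> [...]``,
    ``kind <peptide|lipid|water|ion> [...]``, or a bare keyword ``backbone``,
    ``calpha``, ``heavy``, ``all``.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    clauses = [c.strip() for c in re.split(r"\band\b", query) if c.strip()]
    if not clauses:
        raise SelectionError("empty selection query")
    for clause in clauses:
        parts = clause.split()
        head, args = parts[0].lower(), parts[1:]
        if head == "name":
            if not args:
                raise SelectionError("'name' needs at least one atom name")
            mask &= np.isin(topology.names, args)
        elif head == "resid":
            if not args:
                raise SelectionError("'resid' needs at least one index or range")
            sub = np.zeros(topology.n_atoms, dtype=bool)
            for lo, hi in _parse_resid_ranges(args):
                sub |= (topology.resids >= lo) & (topology.resids <= hi)
            mask &= sub
        elif head == "chain":
            if not args:
                raise SelectionError("'chain' needs at least one chain id")
            mask &= np.isin(topology.chain_ids, args)
        elif head == "kind":
            if not args:
                raise SelectionError("'kind' needs at least one molecule kind")
            for k in args:
                if k not in _VALID_KINDS:
                    raise SelectionError(f"unknown molecule kind {k!r}")
            mask &= np.isin(topology.kinds, args)
        elif head == "backbone" and not args:
            mask &= np.isin(topology.names, _BACKBONE_NAMES) & (
                topology.kinds == "peptide"
            )
        elif head == "calpha" and not args:
            mask &= (topology.names == "CA") & (topology.kinds == "peptide")
        elif head == "heavy" and not args:
            mask &= topology.elements != "H"
        elif head == "all" and not args:
            pass
        else:
            raise SelectionError(f"unknown selection clause {clause!r}")
    idx = np.flatnonzero(mask)
    if len(idx) == 0 and not allow_empty:
        raise SelectionError(f"selection {query!r} matched no atoms")
    return idx
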