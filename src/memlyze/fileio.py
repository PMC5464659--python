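"""GRO and PDB readers/writers.

GRO files are fixed-width, nm-native, and may hold several concatenated
frames; velocities are ignored. PDB files use ATOM/HETATM records in Å
(converted to nm) with MODEL/ENDMDL framing and a CRYST1 box. Only
orthorhombic cells are supported; triclinic input raises
:class:`UnsupportedFormatError`.

GRO carries no chain identifiers, so peptide chains are inferred: a new chain
starts whenever the peptide residue numbering restarts (decreases) or peptide
atoms resume after a non-peptide block. Chains are lettered A, B, C, ...
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .core import (
    ATOMIC_MASSES,
    DEFAULT_KIND_MAP,
    Atom,
    Frame,
    Topology,
    Trajectory,
    guess_element,
)

__all__ = [
    "ParseError",
    "UnsupportedFormatError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
]

A_PER_NM = 10.0


class ParseError(ValueError):
    """Malformed record in a structure file; names the offending line."""


class UnsupportedFormatError(ValueError):
    """Valid file but unsupported dialect (e.g. triclinic box)."""


@dataclass
class _RawAtom:
    name: str
    residue_index: int
    residue_name: str
    chain_id: str  # "" when the format has none


def _build_topology(
    raw: list[_RawAtom],
    kind_map: dict[str, str] | None,
    lipid_head_atom_name: str,
    acyl_chain_definitions: dict[str, list[str]] | None,
) -> Topology:
    kind_map = DEFAULT_KIND_MAP if kind_map is None else kind_map
    kinds = [kind_map.get(r.residue_name, "peptide") for r in raw]

    # chain assignment for peptide atoms lacking chain ids
    chains: list[str] = []
    letters = string.ascii_uppercase
    chain_no = -1
    prev_resid = None
    prev_was_peptide = False
    for r, kind in zip(raw, kinds):
        if kind != "peptide":
            chains.append(r.chain_id)
            prev_was_peptide = False
            prev_resid = None
            continue
        if r.chain_id:
            chains.append(r.chain_id)
            prev_was_peptide = True
            continue
        if not prev_was_peptide or (prev_resid is not None and r.residue_index < prev_resid):
            chain_no += 1
        chains.append(letters[chain_no % 26])
        prev_resid = r.residue_index
        prev_was_peptide = True

    atoms = []
    for r, kind, chain in zip(raw, kinds, chains):
        element = guess_element(r.name, kind)
        mass = ATOMIC_MASSES.get(element)
        if mass is None:
            raise ParseError(f"no mass for element {element!r} (atom {r.name!r})")
        atoms.append(
            Atom(
                name=r.name,
                element=element,
                residue_index=r.residue_index,
                residue_name=r.residue_name,
                chain_id=chain,
                molecule_kind=kind,
                mass=mass,
            )
        )
    peptide_chains: list[str] = []
    for a in atoms:
        if a.molecule_kind == "peptide" and a.chain_id not in peptide_chains:
            peptide_chains.append(a.chain_id)
    if acyl_chain_definitions is None and any(k == "lipid" for k in kinds):
        acyl_chain_definitions = _infer_acyl_chains(atoms)
    return Topology(
        atoms=atoms,
        peptide_chains=peptide_chains,
        lipid_head_atom_name=lipid_head_atom_name,
        acyl_chain_definitions=acyl_chain_definitions or {},
    )


def _infer_acyl_chains(atoms: list[Atom]) -> dict[str, list[str]]:
    """Infer sn-1/sn-2 carbon name lists from the first lipid residue.

    Convention of the synthetic generator and of common united-atom DPPC
    topologies: sn-1 carbons named C1x, sn-2 carbons named C2x, in file order.
    """
    first_resid = None
    sn1: list[str] = []
    sn2: list[str] = []
    for a in atoms:
        if a.molecule_kind != "lipid":
            continue
        if first_resid is None:
            first_resid = a.residue_index
        if a.residue_index != first_resid:
            break
        if a.name.startswith("C1") and len(a.name) > 2:
            sn1.append(a.name)
        elif a.name.startswith("C2") and len(a.name) > 2:
            sn2.append(a.name)
    out = {}
    if len(sn1) >= 3:
        out["sn1"] = sn1
    if len(sn2) >= 3:
        out["sn2"] = sn2
    return out


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed box record: {line!r}") from exc
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise UnsupportedFormatError(
                f"line {lineno}: triclinic box is not supported"
            )
        box = np.array(vals[:3])
    else:
        raise ParseError(f"line {lineno}: box record needs 3 or 9 floats")
    if not np.all(box > 0):
        raise ParseError(f"line {lineno}: box lengths must be positive")
    return box


def _parse_gro_frame(lines: list[str], start: int):
    """Parse one GRO frame starting at ``lines[start]``; returns
    (raw_atoms, coords, box, time, next_index)."""
    if start >= len(lines):
        return None
    title = lines[start]
    if start + 1 >= len(lines):
        raise ParseError(f"line {start + 2}: missing atom-count record")
    try:
        n_atoms = int(lines[start + 1].strip())
    except ValueError as exc:
        raise ParseError(
            f"line {start + 2}: malformed atom count {lines[start + 1]!r}"
        ) from exc
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            time = 0.0
    atom_start = start + 2
    box_line = atom_start + n_atoms
    if box_line >= len(lines):
        raise ParseError("missing box record at end of GRO frame")
    raw: list[_RawAtom] = []
    coords = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        line = lines[atom_start + k]
        lineno = atom_start + k + 1
        if len(line) < 44:
            raise ParseError(f"line {lineno}: GRO atom record too short")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom record") from exc
        raw.append(_RawAtom(name=name, residue_index=resid, residue_name=resname,
                            chain_id=""))
        coords[k] = (x, y, z)
    box = _parse_gro_box(lines[box_line], box_line + 1)
    return raw, coords, box, time, box_line + 1


def _read_gro(path: str):
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    raw0 = None
    pos = 0
    frame_no = 0
    while pos < len(lines) and lines[pos:]:
        if all(not ln.strip() for ln in lines[pos:]):
            break
        parsed = _parse_gro_frame(lines, pos)
        if parsed is None:
            break
        raw, coords, box, time, pos = parsed
        if raw0 is None:
            raw0 = raw
        elif len(raw) != len(raw0):
            raise ParseError(
                f"frame {frame_no}: atom count {len(raw)} differs from frame 0 "
                f"({len(raw0)})"
            )
        frames.append((coords, box, time))
        frame_no += 1
    if raw0 is None:
        raise ParseError("empty GRO file")
    return raw0, frames


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _read_pdb(path: str):
    raw0: list[_RawAtom] | None = None
    frames = []
    box = None
    cur_raw: list[_RawAtom] = []
    cur_xyz: list[tuple[float, float, float]] = []
    frame_no = 0

    def close_frame():
        nonlocal raw0, frame_no, cur_raw, cur_xyz
        if not cur_xyz:
            return
        if raw0 is None:
            raw0 = list(cur_raw)
        elif len(cur_raw) != len(raw0):
            raise ParseError(
                f"frame {frame_no}: atom count {len(cur_raw)} differs from "
                f"frame 0 ({len(raw0)})"
            )
        frames.append(np.array(cur_xyz) / A_PER_NM)
        frame_no += 1
        cur_raw = []
        cur_xyz = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a = float(line[6:15])
                    b = float(line[15:24])
                    c = float(line[24:33])
                    alpha = float(line[33:40])
                    beta = float(line[40:47])
                    gamma = float(line[47:54])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed CRYST1") from exc
                if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
                    raise UnsupportedFormatError(
                        f"line {lineno}: triclinic cell is not supported"
                    )
                box = np.array([a, b, c]) / A_PER_NM
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed ATOM record") from exc
                cur_raw.append(
                    _RawAtom(name=name, residue_index=resid,
                             residue_name=resname, chain_id=chain)
                )
                cur_xyz.append((x, y, z))
            elif rec.startswith("ENDMDL"):
                close_frame()
            elif rec.startswith("END") and not rec.startswith("ENDMDL"):
                close_frame()
    close_frame()
    if raw0 is None:
        raise ParseError("no ATOM records found in PDB file")
    if box is None:
        raise ParseError("missing CRYST1 box record in PDB file")
    return raw0, [(xyz, box, float(i)) for i, xyz in enumerate(frames)]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _normalize_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = "GRO" if str(path).lower().endswith(".gro") else "PDB"
    fmt = fmt.upper()
    if fmt not in ("GRO", "PDB"):
        raise UnsupportedFormatError(f"unknown format {fmt!r}")
    return fmt


def read_structure(
    path: str,
    format: str | None = None,
    kind_map: dict[str, str] | None = None,
    lipid_head_atom_name: str = "P",
    acyl_chain_definitions: dict[str, list[str]] | None = None,
) -> tuple[Topology, Frame]:
    """Read the first frame of a GRO or PDB file.

    Returns the topology (molecule kinds inferred from residue names via
    ``kind_map``) and the first frame in nm.
    """
    fmt = _normalize_format(path, format)
    raw, frames = (_read_gro if fmt == "GRO" else _read_pdb)(path)
    topo = _build_topology(raw, kind_map, lipid_head_atom_name, acyl_chain_definitions)
    coords, box, time = frames[0]
    return topo, Frame(coords, box, time)


def read_trajectory(
    path: str,
    format: str | None = None,
    frame_spacing: float | None = None,
    kind_map: dict[str, str] | None = None,
    lipid_head_atom_name: str = "P",
    acyl_chain_definitions: dict[str, list[str]] | None = None,
) -> Trajectory:
    """Read a multi-frame GRO (concatenated frames) or multi-MODEL PDB file.

    Frame times come from the file when present (GRO ``t=`` titles); otherwise
    they are index x ``frame_spacing`` (default 1 ps).
    """
    fmt = _normalize_format(path, format)
    raw, frames = (_read_gro if fmt == "GRO" else _read_pdb)(path)
    topo = _build_topology(raw, kind_map, lipid_head_atom_name, acyl_chain_definitions)
    coords = np.stack([f[0] for f in frames])
    boxes = np.stack([f[1] for f in frames])
    times = np.array([f[2] for f in frames])
    have_times = fmt == "GRO" and len(frames) > 1 and np.all(np.diff(times) > 0)
    if have_times:
        return Trajectory(topo, coords, boxes, times=times)
    spacing = 1.0 if frame_spacing is None else frame_spacing
    return Trajectory(
        topo, coords, boxes,
        times=np.arange(len(frames)) * spacing, frame_spacing=spacing,
    )


def _gro_atom_lines(topology: Topology, coords: np.ndarray) -> list[str]:
    lines = []
    for i, a in enumerate(topology.atoms):
        lines.append(
            f"{a.residue_index % 100000:5d}{a.residue_name:<5.5s}{a.name:>5.5s}"
            f"{(i + 1) % 100000:5d}"
            f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
        )
    return lines


def _write_gro(fh, topology: Topology, frame: Frame, title: str) -> None:
    fh.write(f"{title} t= {frame.time:.3f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    fh.write("\n".join(_gro_atom_lines(topology, frame.coordinates)))
    fh.write(f"\n{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def _write_pdb_frame(fh, topology: Topology, frame: Frame, model: int | None) -> None:
    if model is not None:
        fh.write(f"MODEL     {model:4d}\n")
    xyz = frame.coordinates * A_PER_NM
    for i, a in enumerate(topology.atoms):
        name = a.name if len(a.name) == 4 else f" {a.name:<3.3s}"
        fh.write(
            f"ATOM  {(i + 1) % 100000:5d} {name:<4.4s} {a.residue_name:<4.4s}"
            f"{(a.chain_id or ' ')[:1]}{a.residue_index % 10000:4d}    "
            f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}"
            f"  1.00  0.00          {a.element:>2.2s}\n"
        )
    if model is not None:
        fh.write("ENDMDL\n")


def write_structure(path: str, topology: Topology, frame: Frame,
                    format: str | None = None, title: str = "memlyze") -> None:
    fmt = _normalize_format(path, format)
    frame.validate(topology)
    with open(path, "w") as fh:
        if fmt == "GRO":
            _write_gro(fh, topology, frame, title)
        else:
            b = frame.box * A_PER_NM
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            _write_pdb_frame(fh, topology, frame, model=None)
            fh.write("END\n")


def write_trajectory(path: str, trajectory: Trajectory,
                     format: str | None = None, title: str = "memlyze") -> None:
    fmt = _normalize_format(path, format)
    with open(path, "w") as fh:
        if fmt == "GRO":
            for fr in trajectory:
                _write_gro(fh, trajectory.topology, fr, title)
        else:
            b = trajectory.boxes[0] * A_PER_NM
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for m, fr in enumerate(trajectory, start=1):
                _write_pdb_frame(fh, trajectory.topology, fr, model=m)
            fh.write("END\n")
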