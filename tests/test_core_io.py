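"""Structure/trajectory I/O, selections, and periodic geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memlyze import (
    Frame,
    SyntheticSpec,
    Trajectory,
    make_bilayer,
    min_image_distance,
    read_structure,
    read_trajectory,
    select_atoms,
    write_structure,
    write_trajectory,
)
from memlyze.core import SelectionError
from memlyze.fileio import ParseError, UnsupportedFormatError

from .oracles import all_image_distances, brute_min_image_distance

def _gro_line(resid, resname, name, num, x, y, z):
    return f"{resid:5d}{resname:<5}{name:>5}{num:5d}{x:8.3f}{y:8.3f}{z:8.3f}"


GRO_TWO_ATOMS = "\n".join([
    "two atoms",
    "    2",
    _gro_line(1, "DPPC", "P", 1, 1.0, 2.0, 3.0),
    _gro_line(2, "DPPC", "P", 2, 4.0, 4.5, 1.25),
    "   5.00000   5.00000   5.00000",
]) + "\n"

PDB_ONE_ATOM = """CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A   1      10.000   0.000   0.000  1.00  0.00           C
END
"""


def test_gro_fields_read_directly(tmp_path):
    path = tmp_path / "two.gro"
    path.write_text(GRO_TWO_ATOMS)
    topo, frame = read_structure(str(path))
    assert topo.n_atoms == 2
    assert np.allclose(frame.box, [5.0, 5.0, 5.0])
    assert topo.kinds.tolist() == ["lipid", "lipid"]
    assert np.allclose(frame.coordinates[0], [1.0, 2.0, 3.0])


def test_pdb_angstrom_converted_to_nm(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(PDB_ONE_ATOM)
    topo, frame = read_structure(str(path))
    assert np.allclose(frame.coordinates[0], [1.0, 0.0, 0.0])
    assert np.allclose(frame.box, [5.0, 5.0, 5.0])
    assert topo.atoms[0].molecule_kind == "peptide"
    assert topo.atoms[0].chain_id == "A"


@pytest.mark.parametrize("fmt", ["GRO", "PDB"])
def test_roundtrip_preserves_coordinates_to_format_precision(tmp_path, rng, fmt):
    topo, frame = make_bilayer(
        SyntheticSpec(seed=2, n_lipids_per_leaflet=4, compression_amplitude=0.0)
    )
    coords = frame.coordinates + rng.uniform(-0.2, 0.2, frame.coordinates.shape)
    frame2 = Frame(np.round(np.abs(coords), 4), frame.box)
    path = tmp_path / f"rt.{fmt.lower()}"
    write_structure(str(path), topo, frame2, format=fmt)
    topo2, back = read_structure(str(path), format=fmt)
    assert topo2.n_atoms == topo.n_atoms
    assert np.allclose(back.coordinates, frame2.coordinates, atol=1e-3)
    assert topo2.resnames.tolist() == topo.resnames.tolist()
    assert topo2.kinds.tolist() == topo.kinds.tolist()


def test_multiframe_gro_roundtrip_and_times(tmp_path, small_bilayer):
    spec, (topo, frame) = small_bilayer
    frames = [Frame(frame.coordinates + 0.01 * i, frame.box, 500.0 * i)
              for i in range(3)]
    traj = Trajectory.from_frames(topo, frames)
    path = tmp_path / "traj.gro"
    write_trajectory(str(path), traj)
    back = read_trajectory(str(path))
    assert back.n_frames == 3
    assert back.frame_spacing == pytest.approx(500.0)
    assert np.allclose(back.times, [0.0, 500.0, 1000.0])


def test_atom_count_mismatch_names_frame(tmp_path):
    one = GRO_TWO_ATOMS
    short = "\n".join([
        "broken",
        "    1",
        _gro_line(1, "DPPC", "P", 1, 1.0, 2.0, 3.0),
        "   5.00000   5.00000   5.00000",
    ]) + "\n"
    path = tmp_path / "bad.gro"
    path.write_text(one + one + short)
    with pytest.raises(ParseError, match="frame 2"):
        read_trajectory(str(path))


def test_triclinic_box_rejected(tmp_path):
    path = tmp_path / "tri.gro"
    path.write_text(
        "tri\n    1\n" + _gro_line(1, "DPPC", "P", 1, 1.0, 2.0, 3.0)
        + "\n   5.0   5.0   5.0   0.0   0.0   1.2   0.0   0.0   0.0\n"
    )
    with pytest.raises(UnsupportedFormatError):
        read_structure(str(path))


def test_malformed_record_names_line(tmp_path):
    path = tmp_path / "bad.gro"
    bad_line = _gro_line(1, "DPPC", "P", 1, 1.0, 2.0, 3.0).replace("1.000", "x.xxx")
    path.write_text(f"bad\n    1\n{bad_line}\n 5 5 5\n")
    with pytest.raises(ParseError, match="line 3"):
        read_structure(str(path))


def test_gro_reader_agrees_with_mdanalysis(tmp_path, small_bilayer):
    MDAnalysis = pytest.importorskip("MDAnalysis")
    spec, (topo, frame) = small_bilayer
    path = tmp_path / "xcheck.gro"
    write_structure(str(path), topo, frame)
    u = MDAnalysis.Universe(str(path))
    assert len(u.atoms) == topo.n_atoms
    # MDAnalysis positions are in Angstrom
    topo2, fr2 = read_structure(str(path))
    assert np.allclose(u.atoms.positions / 10.0, fr2.coordinates, atol=1e-3)
    assert np.allclose(u.dimensions[:3] / 10.0, fr2.box)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def test_head_selection_counts_all_lipids(small_bilayer):
    spec, (topo, frame) = small_bilayer
    assert len(select_atoms(topo, "name P")) == 2 * spec.n_lipids_per_leaflet


def test_chain_and_residue_range_selection(dimer_2ncb):
    topo, _ = dimer_2ncb
    idx = select_atoms(topo, "chain A and resid 1-16")
    assert len(idx) == 16 * 4
    assert set(topo.resids[idx]) == set(range(1, 17))
    assert set(topo.chain_ids[idx]) == {"A"}


def test_empty_selection_raises_in_strict_mode(small_bilayer):
    _, (topo, _) = small_bilayer
    with pytest.raises(SelectionError):
        select_atoms(topo, "kind water and name P")
    assert len(select_atoms(topo, "kind water and name P", allow_empty=True)) == 0


def test_selection_idempotent_sorted_and_partitions(dimer_2ncb):
    topo, _ = dimer_2ncb
    a = select_atoms(topo, "chain A")
    assert np.array_equal(a, np.unique(a))
    assert np.array_equal(a, select_atoms(topo, "chain A"))
    b = select_atoms(topo, "chain B")
    union = np.union1d(a, b)
    assert np.array_equal(union, np.arange(topo.n_atoms))
    assert len(np.intersect1d(a, b)) == 0


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def test_min_image_wraparound():
    box = np.array([5.0, 5.0, 5.0])
    d = min_image_distance(np.array([0.1, 0, 0]), np.array([4.9, 0, 0]), box)
    assert d == pytest.approx(0.2, abs=1e-12)
    assert min_image_distance(np.ones(3), np.ones(3), box) == 0.0


def test_min_image_matches_brute_force_images(rng):
    box = np.array([3.0, 4.0, 5.0])
    for _ in range(1000):
        a = rng.uniform(0, box)
        b = rng.uniform(0, box)
        d = min_image_distance(a, b, box)
        assert d == pytest.approx(brute_min_image_distance(a, b, box), abs=1e-9)
        assert all(d <= img + 1e-9 for img in all_image_distances(a, b, box))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=6, max_size=6))
def test_min_image_never_exceeds_any_image(vals):
    box = np.array([2.0, 3.0, 4.0])
    a = np.array(vals[:3]) * box
    b = np.array(vals[3:]) * box
    d = min_image_distance(a, b, box)
    assert d <= min(all_image_distances(a, b, box)) + 1e-9


def test_lateral_distance_ignores_z():
    box = np.array([5.0, 5.0, 5.0])
    a = np.array([1.0, 1.0, 0.0])
    b = np.array([1.0, 1.0, 2.5])
    assert min_image_distance(a, b, box, lateral=True) == 0.0
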