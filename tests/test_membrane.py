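"""Leaflet assignment, grid APL vs Voronoi oracle, order parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memlyze import Frame, SyntheticSpec, Trajectory, make_bilayer, simulate
from memlyze.core import Atom, Topology, select_atoms
from memlyze.membrane import (
    DegenerateMembraneError,
    assign_leaflets,
    grid_apl,
    order_parameters,
    periodic_voronoi_areas,
    region_of_distance,
    s_cd_from_vectors,
    stratify_apl,
)


def _head_topology(n):
    atoms = [Atom("P", "P", i + 1, "DPPC", "", "lipid", 30.974) for i in range(n)]
    return Topology(atoms=atoms)


def test_leaflet_split_by_midplane():
    topo = _head_topology(2)
    frame = Frame(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 5.0]]), np.full(3, 6.0))
    leaf = assign_leaflets(frame, topo)
    assert leaf["bottom"].tolist() == [0]
    assert leaf["top"].tolist() == [1]


def test_symmetric_bilayer_splits_evenly(small_bilayer):
    spec, (topo, frame) = small_bilayer
    leaf = assign_leaflets(frame, topo)
    assert len(leaf["top"]) == len(leaf["bottom"]) == spec.n_lipids_per_leaflet


def test_leaflets_match_generator_labels():
    spec = SyntheticSpec(seed=9, n_lipids_per_leaflet=16, n_frames=2,
                         compression_amplitude=0.0, exchange_rate=0.0)
    traj, truth = simulate(spec)
    topo = traj.topology
    leaf = assign_leaflets(traj.frame(0), topo)
    for side in ("top", "bottom"):
        resids = topo.resids[leaf[side]]
        assert all(truth.leaflets[int(r)] == side for r in resids)


def test_coplanar_heads_rejected():
    topo = _head_topology(4)
    frame = Frame(np.column_stack([np.arange(4.0), np.arange(4.0),
                                   np.full(4, 2.0)]), np.full(3, 6.0))
    with pytest.raises(DegenerateMembraneError):
        assign_leaflets(frame, topo)


def test_square_lattice_grid_areas_exact():
    spec = SyntheticSpec(seed=0, n_lipids_per_leaflet=4, apl0=1.0,
                         lattice_jitter=0.0, compression_amplitude=0.0)
    topo, frame = make_bilayer(spec)
    leaf = assign_leaflets(frame, topo)
    areas, protein_area = grid_apl(frame, leaf["top"], grid=100)
    assert np.allclose(areas, 1.0, atol=1e-12)
    assert protein_area == 0.0


def test_grid_areas_tile_the_box_exactly(rng):
    spec = SyntheticSpec(seed=3, inclusion="rod", n_lipids_per_leaflet=16,
                         compression_amplitude=0.2, lattice_jitter=0.05)
    topo, frame = make_bilayer(spec)
    leaf = assign_leaflets(frame, topo)
    pep = select_atoms(topo, "kind peptide")
    areas, protein_area = grid_apl(frame, leaf["top"], grid=120,
                                   protein_indices=pep)
    assert areas.sum() + protein_area == pytest.approx(
        frame.box[0] * frame.box[1], rel=1e-12
    )


def test_grid_apl_close_to_periodic_voronoi(rng):
    box = np.array([6.4, 6.4])
    for _ in range(3):
        heads_xy = rng.uniform(0, box, size=(20, 2))
        coords = np.column_stack([heads_xy, np.full(20, 3.0)])
        frame = Frame(coords, np.array([box[0], box[1], 6.0]))
        areas, _ = grid_apl(frame, np.arange(20), grid=200)
        ref = periodic_voronoi_areas(heads_xy, box)
        assert np.max(np.abs(areas - ref) / ref) <= 0.02


def test_grid_apl_converges_to_voronoi(rng):
    box = np.array([6.4, 6.4])
    heads_xy = rng.uniform(0, box, size=(30, 2))
    coords = np.column_stack([heads_xy, np.full(30, 3.0)])
    frame = Frame(coords, np.array([box[0], box[1], 6.0]))
    ref = periodic_voronoi_areas(heads_xy, box)
    devs = []
    for grid in (100, 200, 400):
        areas, _ = grid_apl(frame, np.arange(30), grid=grid)
        devs.append(np.max(np.abs(areas - ref) / ref))
    assert devs[0] > devs[1] > devs[2]


def test_region_thresholds_and_closed_upper_bound():
    d = np.array([0.3, 0.5, 0.7, 1.0, 1.5])
    regions = region_of_distance(d, (0.5, 1.0))
    assert regions.tolist() == ["core", "core", "intermediate",
                                "intermediate", "remote"]


def test_stratified_areas_label_by_peptide_distance():
    atoms = [Atom("CA", "C", 1, "ROD", "X", "peptide", 12.0)]
    atoms += [Atom("P", "P", i + 2, "DPPC", "", "lipid", 30.974) for i in range(3)]
    topo = Topology(atoms=atoms, peptide_chains=["X"])
    coords = np.array([
        [2.0, 2.0, 2.0],
        [2.3, 2.0, 2.0],
        [2.0, 2.7, 2.0],
        [3.5, 2.0, 2.0],
    ])
    frame = Frame(coords, np.full(3, 8.0))
    table = stratify_apl(np.ones(3), frame, np.array([1, 2, 3]), np.array([0]))
    assert table["region"].tolist() == ["core", "intermediate", "remote"]


def test_planted_compression_recovered_within_tolerance():
    spec = SyntheticSpec(seed=3, inclusion="rod", n_lipids_per_leaflet=256,
                         compression_amplitude=0.2, compression_radius=2.5,
                         lattice_jitter=0.03)
    topo, frame = make_bilayer(spec)
    pep = select_atoms(topo, "kind peptide")
    leaf = assign_leaflets(frame, topo)
    planted = spec.apl0 * (1 - spec.compression_amplitude)
    for side in ("top", "bottom"):
        areas, _ = grid_apl(frame, leaf[side], grid=200)
        table = stratify_apl(areas, frame, leaf[side], pep, bounds=(1.0, 2.0))
        by_region = table.groupby("region")["area"].mean()
        assert by_region["core"] == pytest.approx(planted, rel=0.05)
        assert by_region["core"] < by_region["remote"]
        assert by_region["remote"] == pytest.approx(spec.apl0, rel=0.05)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def test_all_trans_chain_reports_half(small_bilayer):
    spec, (topo, frame) = small_bilayer
    traj = Trajectory.from_frames(topo, [frame], frame_spacing=1.0)
    for chain in ("sn1", "sn2"):
        prof = order_parameters(traj, chain)
        assert np.allclose(prof.minus_s_cd, 0.5, atol=1e-12)
        assert len(prof.carbon_index) == spec.n_acyl_carbons - 2


def test_ch_parallel_to_normal_gives_one():
    assert s_cd_from_vectors(np.array([[0.0, 0.0, 1.0]])) == pytest.approx(1.0)
    assert s_cd_from_vectors(np.array([[0.0, 0.0, -1.0]])) == pytest.approx(1.0)
    assert s_cd_from_vectors(np.array([[1.0, 0.0, 0.0]])) == pytest.approx(-0.5)


def test_isotropic_vectors_average_to_zero(rng):
    v = rng.normal(size=(100_000, 3))
    assert abs(s_cd_from_vectors(v)) <= 0.01


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_s_cd_bounds_on_arbitrary_vectors(seed):
    v = np.random.default_rng(seed).normal(size=(50, 3))
    assert -0.5 - 1e-12 <= s_cd_from_vectors(v) <= 1.0 + 1e-12


def test_broken_chain_definition_raises(small_bilayer):
    _, (topo, frame) = small_bilayer
    traj = Trajectory.from_frames(topo, [frame], frame_spacing=1.0)
    with pytest.raises(ValueError):
        order_parameters(traj, "sn9")
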