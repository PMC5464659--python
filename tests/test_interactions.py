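"""Hydrogen-bond detection/classification, lateral RDF, residence times."""

import numpy as np
import pytest

from memlyze import Frame, SyntheticSpec, Trajectory, make_dimer, simulate
from memlyze.core import Atom, Topology, select_atoms
from memlyze.interactions import (
    HBondRecord,
    RDFProfile,
    classify_hbond,
    cutoff_from_rdf,
    detect_hbonds,
    hbond_census,
    lateral_rdf,
    residence_time,
)
from memlyze.secondary import peptide_backbone, reconstruct_amide_hydrogens

D_CUT, ANGLE_CUT = 0.35, 30.0


def _two_residue_pair(donor_n, acceptor_o, acceptor_c, prev_co_dir):
    """Chain A residues 1-2 (residue 2 donates) and chain B residue 1
    (carbonyl acceptor); ``prev_co_dir`` orients the reconstructed amide H."""
    atoms, coords = [], []

    def add(name, resid, chain, pos):
        element = "C" if name == "CA" else name[0]
        atoms.append(Atom(name, element, resid, "GLY", chain, "peptide", 12.0))
        coords.append(pos)

    prev_c = donor_n - np.array([0.15, 0.1, 0.0])
    prev_o = prev_c - 0.122 * np.asarray(prev_co_dir) / np.linalg.norm(prev_co_dir)
    add("N", 1, "A", prev_c - np.array([0.2, 0.0, 0.0]))
    add("CA", 1, "A", prev_c - np.array([0.1, 0.05, 0.0]))
    add("C", 1, "A", prev_c)
    add("O", 1, "A", prev_o)
    add("N", 2, "A", donor_n)
    add("CA", 2, "A", donor_n + np.array([0.12, -0.05, 0.0]))
    add("C", 2, "A", donor_n + np.array([0.23, 0.0, 0.0]))
    add("O", 2, "A", donor_n + np.array([0.23, -0.12, 0.0]))
    add("N", 1, "B", acceptor_c + np.array([0.0, 0.25, 0.0]))
    add("CA", 1, "B", acceptor_c + np.array([0.1, 0.3, 0.0]))
    add("C", 1, "B", acceptor_c)
    add("O", 1, "B", acceptor_o)
    topo = Topology(atoms=atoms, peptide_chains=["A", "B"])
    return topo, np.array(coords)


def test_close_aligned_pair_detected():
    n = np.array([1.0, 1.0, 1.0])
    o = n + np.array([0.0, 0.28, 0.0])
    c = o + np.array([0.0, 0.123, 0.0])
    topo, coords = _two_residue_pair(n, o, c, prev_co_dir=(0, 1, 0))
    recs = detect_hbonds(coords, topo)
    pairs = {(r.donor_residue, r.acceptor_residue) for r in recs}
    assert (("A", 2), ("B", 1)) in pairs


def test_distant_pair_not_detected():
    n = np.array([1.0, 1.0, 1.0])
    o = n + np.array([0.0, 0.40, 0.0])
    c = o + np.array([0.0, 0.123, 0.0])
    topo, coords = _two_residue_pair(n, o, c, prev_co_dir=(0, 1, 0))
    recs = detect_hbonds(coords, topo)
    assert (("A", 2), ("B", 1)) not in {
        (r.donor_residue, r.acceptor_residue) for r in recs
    }


def test_detection_matches_inequality_oracle(rng):
    hits = 0
    for _ in range(1000):
        n = np.array([1.0, 1.0, 1.0])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        o = n + direction * rng.uniform(0.15, 0.55)
        c = o + rng.normal(size=3) * 0.1 + np.array([0.0, 0.12, 0.0])
        h_dir = rng.normal(size=3)
        topo, coords = _two_residue_pair(n, o, c, prev_co_dir=-h_dir)
        residues = peptide_backbone(topo)
        h = reconstruct_amide_hydrogens(coords, residues)
        donor = next(i for i, r in enumerate(residues)
                     if (r.chain_id, r.residue_index) == ("A", 2))
        # independent statement of the criterion
        r_no = np.linalg.norm(n - o)
        nh = h[donor] - n
        cos_a = np.dot(nh, o - n) / (np.linalg.norm(nh) * r_no)
        expected = r_no <= D_CUT and np.degrees(np.arccos(np.clip(cos_a, -1, 1))) <= ANGLE_CUT
        recs = detect_hbonds(coords, topo)
        got = (("A", 2), ("B", 1)) in {
            (r.donor_residue, r.acceptor_residue) for r in recs
        }
        assert got == expected
        hits += got
    assert 0 < hits < 1000  # both outcomes exercised


def _record(chain_d, resid_d, chain_a, resid_a):
    return HBondRecord(frame=0, donor_atom=0, hydrogen=(0, 0, 0),
                       acceptor_atom=1, donor_residue=(chain_d, resid_d),
                       acceptor_residue=(chain_a, resid_a))


@pytest.mark.parametrize(
    "record,expected",
    [
        (_record("A", 3, "A", 12), "intra-A b1-b2"),
        (_record("B", 33, "B", 41), "intra-B b4-b5"),
        (_record("A", 20, "B", 19), "inter b3"),
        (_record("A", 3, "B", 12), "inter b1-b2"),
        (_record("A", 40, "B", 20), "inter b3-b5"),
        (_record("A", 26, "B", 40), "other"),
        (_record("A", 3, "A", 20), "other"),
    ],
)
def test_hbond_categories(record, expected):
    assert classify_hbond(record) == expected


def test_residue_outside_range_rejected():
    with pytest.raises(ValueError):
        classify_hbond(_record("A", 43, "B", 3))


@pytest.mark.parametrize(
    "arrangement,nonzero,zero",
    [
        ("2NCb", "inter b1-b2", ("inter b3", "inter b4", "inter b5", "inter b3-b5")),
        ("CNNC", "inter b3", ("inter b1-b2", "inter b4", "inter b5", "inter b3-b5")),
        ("NCCN", "inter b5", ("inter b1-b2", "inter b3", "inter b4", "inter b3-b5")),
        ("NCNC", "inter b3-b5", ("inter b1-b2", "inter b3", "inter b4", "inter b5")),
    ],
)
def test_census_mirrors_contact_pattern(arrangement, nonzero, zero):
    topo, frame = make_dimer(arrangement)
    traj = Trajectory.from_frames(topo, [frame], frame_spacing=1.0)
    census = hbond_census(traj)
    assert census.mean[nonzero] > 0
    for cat in zero:
        assert census.mean[cat] == 0.0
    for chain in ("A", "B"):
        for pair in ("b1-b2", "b3-b4", "b4-b5"):
            assert census.mean[f"intra-{chain} {pair}"] > 0
    assert census.sd[nonzero] == 0.0  # static single frame


# ---------------------------------------------------------------------------
# RDF / residence
# ---------------------------------------------------------------------------

def _xy_trajectory(positions, box_xy=8.0, center=(4.0, 4.0), extra_ref=True):
    """Frames of lipid heads at given xy positions plus a fixed reference rod."""
    n_frames, n_heads, _ = positions.shape
    atoms = [Atom("CA", "C", 1, "ROD", "X", "peptide", 12.0)]
    atoms += [Atom("P", "P", i + 2, "DPPC", "", "lipid", 30.974)
              for i in range(n_heads)]
    topo = Topology(atoms=atoms, peptide_chains=["X"])
    frames = []
    for f in range(n_frames):
        coords = np.vstack([
            np.array([[center[0], center[1], 3.0]]),
            np.column_stack([positions[f], np.full(n_heads, 5.0)]),
        ])
        frames.append(Frame(coords, np.array([box_xy, box_xy, 6.0]), float(f)))
    return Trajectory.from_frames(topo, frames, frame_spacing=1.0)


def test_rdf_ring_occupies_single_bin():
    angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ring = 4.0 + 1.53 * np.column_stack([np.cos(angles), np.sin(angles)])
    traj = _xy_trajectory(ring[None, :, :])
    prof = lateral_rdf(traj, np.arange(1, 25), np.array([0]), bin_width=0.1)
    occupied = np.flatnonzero(prof.g > 0)
    assert len(occupied) == 1
    assert prof.bin_centers[occupied[0]] == pytest.approx(1.55, abs=1e-9)


def test_rdf_cumulative_counts_exact(rng):
    pos = rng.uniform(0, 8.0, size=(50, 40, 2))
    traj = _xy_trajectory(pos)
    prof = lateral_rdf(traj, np.arange(1, 41), np.array([0]), bin_width=0.05)
    d = np.linalg.norm(
        (pos - 4.0 + 4.0) % 8.0 - 4.0, axis=2
    )
    expected = np.mean(np.sum(d <= prof.bin_centers[-1] + 0.025, axis=1))
    assert prof.cumulative[-1] == pytest.approx(expected, rel=1e-9)


def test_rdf_uniform_gas_is_flat(rng):
    pos = rng.uniform(0, 8.0, size=(2000, 64, 2))
    traj = _xy_trajectory(pos)
    prof = lateral_rdf(traj, np.arange(1, 65), np.array([0]), bin_width=0.1)
    inner = prof.g[2:]  # skip the two smallest-area bins
    assert np.all(np.abs(inner - 1.0) < 0.15)
    assert abs(np.mean(inner) - 1.0) < 0.01


def _flat_profile(r_max=2.0, bin_width=0.05):
    centers = np.arange(bin_width / 2, r_max, bin_width)
    g = np.ones_like(centers)
    return RDFProfile(bin_centers=centers, g=g, cumulative=np.cumsum(g),
                      bin_width=bin_width, density=1.0, n_frames=1)


def test_cutoff_from_uniform_disc_is_fraction_of_rmax():
    prof = _flat_profile(r_max=2.0, bin_width=0.05)
    cut = cutoff_from_rdf(prof, fraction=0.8)
    assert cut == pytest.approx(0.8 * 2.0, abs=0.05)
    assert cutoff_from_rdf(prof, fraction=1.0) == pytest.approx(2.0, abs=1e-9)


def test_cutoff_all_mass_in_first_bin():
    prof = _flat_profile()
    prof.g = np.zeros_like(prof.g)
    prof.g[0] = 5.0
    assert cutoff_from_rdf(prof, 0.8) <= prof.bin_width
    with pytest.raises(ValueError):
        cutoff_from_rdf(prof, 1.5)


def test_residence_hand_counted_runs():
    n_frames = 40
    pos = np.full((n_frames, 1, 2), 7.5)           # far from the centre
    inside = list(range(5, 15)) + list(range(25, 30))
    for f in inside:
        pos[f, 0] = (4.0, 4.0)
    traj = _xy_trajectory(pos)
    stats = residence_time(traj, cutoff=1.0, peptide_indices=np.array([0]))
    assert sorted(stats.dwell_times.tolist()) == [5.0, 10.0]
    assert stats.tau == pytest.approx(7.5)


def test_boundary_runs_excluded_and_gap_merged():
    n_frames = 30
    pos = np.full((n_frames, 1, 2), 7.5)
    for f in list(range(0, 5)) + [10, 12] + list(range(27, 30)):
        pos[f, 0] = (4.0, 4.0)
    traj = _xy_trajectory(pos)
    strict = residence_time(traj, 1.0, peptide_indices=np.array([0]))
    assert sorted(strict.dwell_times.tolist()) == [1.0, 1.0]
    merged = residence_time(traj, 1.0, peptide_indices=np.array([0]),
                            gap_tolerance=1)
    assert merged.dwell_times.tolist() == [3.0]  # frames 10-12 as one run


def test_no_events_warns_with_empty_stats():
    pos = np.full((10, 1, 2), 7.5)
    traj = _xy_trajectory(pos)
    with pytest.warns(UserWarning):
        stats = residence_time(traj, 1.0, peptide_indices=np.array([0]))
    assert stats.n_events == 0
    assert np.isnan(stats.tau)


def test_planted_exchange_rate_recovered():
    spec = SyntheticSpec(seed=11, inclusion="rod", n_lipids_per_leaflet=16,
                         n_frames=6000, exchange_rate=0.01,
                         compression_amplitude=0.2)
    traj, truth = simulate(spec)
    pep = select_atoms(traj.topology, "kind peptide")
    stats = residence_time(traj, cutoff=truth.shell_radius, peptide_indices=pep)
    assert stats.tau == pytest.approx(truth.mean_dwell, rel=0.1)
    assert stats.n_events > 100
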