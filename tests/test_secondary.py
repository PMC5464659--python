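"""Kabsch-Sander energies and {E, T, C} assignment."""

import numpy as np
import pytest

from memlyze import make_dimer
from memlyze.secondary import (
    ClashError,
    PropensityTable,
    SSMatrix,
    assign_ss,
    kabsch_sander_energy,
    peptide_backbone,
    reconstruct_amide_hydrogens,
    ss_content,
    ss_evolution,
    ss_propensity,
    strand_propensity_ratio,
)
from memlyze.core import Atom, Topology

from .conftest import DIMER_LABELS


def test_energy_matches_hand_evaluated_formula():
    # distances (rON, rCH, rOH, rCN) = (2.9, 3.9, 1.9, 3.9) Angstrom
    n = np.array([0.0, 0.0, 0.29])
    h = np.array([0.0, 0.0, 0.19])
    o = np.zeros(3)
    c = np.array([0.3868229, 0.0, 0.24])
    geo = kabsch_sander_energy(n, h, c, o)
    assert geo.r_on == pytest.approx(0.29, abs=1e-6)
    assert geo.r_oh == pytest.approx(0.19, abs=1e-6)
    assert geo.r_cn == pytest.approx(0.39, abs=1e-4)
    assert geo.r_ch == pytest.approx(0.39, abs=1e-4)
    assert geo.energy == pytest.approx(-5.06, abs=0.01)
    assert geo.is_hbond


def test_equal_distances_cancel_to_zero_energy():
    # with H placed on N, rON == rOH and rCN == rCH
    n = np.array([0.0, 0.0, 0.3])
    c = np.array([0.25, 0.0, 0.1])
    geo = kabsch_sander_energy(n, n, c, np.zeros(3))
    assert geo.energy == pytest.approx(0.0, abs=1e-12)
    assert not geo.is_hbond


def test_distant_groups_never_bond():
    n = np.array([0.0, 0.0, 2.0])
    h = np.array([0.0, 0.0, 1.9])
    geo = kabsch_sander_energy(n, h, np.array([0.12, 0.0, -0.05]), np.zeros(3))
    # 1/r terms are bounded: |E| <= 0.084*332*4/19 ~ 1.5 but signs cancel
    assert geo.energy > -0.5


def test_missing_hydrogen_means_no_bond():
    geo = kabsch_sander_energy(np.array([0, 0, 0.29]), None,
                               np.array([0.39, 0, 0]), np.zeros(3))
    assert not geo.is_hbond
    assert np.isinf(geo.energy)


def test_overlapping_atoms_raise_clash():
    with pytest.raises(ClashError):
        kabsch_sander_energy(np.array([0, 0, 0.01]), np.array([0, 0, 0.02]),
                             np.array([0.3, 0, 0]), np.zeros(3))


def test_amide_h_reconstruction_conventions(dimer_2ncb):
    topo, frame = dimer_2ncb
    residues = peptide_backbone(topo)
    h = reconstruct_amide_hydrogens(frame.coordinates, residues)
    first_a = next(i for i, r in enumerate(residues)
                   if r.chain_id == "A" and r.residue_index == 1)
    assert np.all(np.isnan(h[first_a]))  # chain start cannot donate
    donor = next(i for i, r in enumerate(residues)
                 if r.chain_id == "A" and r.residue_index == 3)
    dist = np.linalg.norm(h[donor] - frame.coordinates[residues[donor].n])
    assert dist == pytest.approx(0.1, abs=1e-9)


@pytest.mark.parametrize("arrangement", ["2NCb", "CNNC", "NCNC", "NCCN"])
def test_ideal_dimer_assignment_matches_construction(arrangement):
    topo, frame = make_dimer(arrangement)
    residues = peptide_backbone(topo)
    labels = assign_ss(frame.coordinates, topo, residues)
    for lab, res in zip(labels, residues):
        assert lab == DIMER_LABELS[res.residue_index], (
            f"{res.chain_id}{res.residue_index}: {lab}"
        )


def test_isolated_extended_chain_is_all_coil():
    # single straight strand with alternating carbonyls and no partner
    atoms = []
    coords = []
    for i in range(8):
        x = 0.35 * i
        o_sign = 1.0 if i % 2 == 0 else -1.0
        for name, pos in [
            ("N", (x, 0.0, 0.0)),
            ("CA", (x + 0.117, 0.0, 0.05)),
            ("C", (x + 0.233, 0.0, 0.0)),
            ("O", (x + 0.233, 0.122 * o_sign, 0.0)),
        ]:
            element = "C" if name == "CA" else name[0]
            atoms.append(Atom(name=name, element=element, residue_index=i + 1,
                              residue_name="GLY", chain_id="A",
                              molecule_kind="peptide",
                              mass=12.0))
            coords.append(pos)
    topo = Topology(atoms=atoms, peptide_chains=["A"])
    labels = assign_ss(np.array(coords), topo)
    assert set(labels) == {"C"}


def test_assignment_is_rigid_motion_invariant(dimer_2ncb):
    from scipy.spatial.transform import Rotation

    topo, frame = dimer_2ncb
    ref = assign_ss(frame.coordinates, topo)
    R = Rotation.from_euler("xyz", [20, -35, 64], degrees=True).as_matrix()
    moved = frame.coordinates @ R.T + np.array([3.0, -1.0, 2.0])
    assert np.array_equal(assign_ss(moved, topo), ref)


def test_evolution_constant_then_melts(melt_trajectory):
    spec, traj, truth = melt_trajectory
    mat = ss_evolution(traj)
    assert mat.labels.shape == (84, spec.n_frames)
    # before the melt frame every residue keeps one label
    pre = mat.labels[:, :100]
    assert np.all(pre == pre[:, :1])
    rows = mat.rows_for("A", (2, 5))
    assert np.all(mat.labels[rows, :100] == "E")
    assert np.all(mat.labels[rows, 100:] == "C")


def test_content_and_propensity_normalisation(melt_trajectory):
    _, traj, _ = melt_trajectory
    mat = ss_evolution(traj)
    content = ss_content(mat)
    assert sum(content.values()) == pytest.approx(1.0, abs=1e-12)
    prop = ss_propensity(mat)
    assert np.allclose(prop.p_e + prop.p_t + prop.p_c, 1.0, atol=1e-12)


def test_content_counts_cells():
    labels = np.array([["E", "E", "C"], ["T", "C", "C"]])
    mat = SSMatrix(labels=labels, residues=[("A", 1), ("A", 2)],
                   times=np.arange(3.0))
    content = ss_content(mat)
    assert content == {"E": pytest.approx(2 / 6), "T": pytest.approx(1 / 6),
                       "C": pytest.approx(3 / 6)}
    prop = ss_propensity(mat)
    assert prop.p_e[0] == pytest.approx(2 / 3)
    assert prop.p_c[1] == pytest.approx(2 / 3)


def _prop_table(mean_a, mean_b):
    residues = [("A", r) for r in range(2, 6)] + [("B", r) for r in range(2, 6)]
    p_e = np.array([mean_a] * 4 + [mean_b] * 4)
    return PropensityTable(residues=residues, p_e=p_e,
                           p_t=np.zeros(8), p_c=1 - p_e)


def test_strand_ratio_conventions():
    assert strand_propensity_ratio(_prop_table(0.4, 0.4), (2, 5), "A", "B") == 1.0
    assert strand_propensity_ratio(_prop_table(0.6, 0.3), (2, 5), "A", "B") == 2.0
    assert strand_propensity_ratio(_prop_table(0.3, 0.6), (2, 5), "A", "B") == 2.0
    with pytest.warns(UserWarning):
        assert np.isinf(
            strand_propensity_ratio(_prop_table(0.5, 0.0), (2, 5), "A", "B")
        )
    with pytest.raises(ValueError):
        strand_propensity_ratio(_prop_table(0.0, 0.0), (2, 5), "A", "B")
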