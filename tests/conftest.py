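import numpy as np
import pytest

from memlyze import SyntheticSpec, make_bilayer, make_dimer, simulate

# intended per-residue labels of the ideal (unmelted) dimer geometry
DIMER_LABELS = {r: "C" for r in range(1, 43)}
for lo, hi in [(2, 6), (10, 14), (17, 23), (30, 36), (39, 41)]:
    for r in range(lo, hi + 1):
        DIMER_LABELS[r] = "E"
for r in (7, 8, 9, 37, 38):
    DIMER_LABELS[r] = "T"

@pytest.fixture(scope="session")
def dimer_2ncb():
    return make_dimer("2NCb")


@pytest.fixture(scope="session")
def small_bilayer():
    spec = SyntheticSpec(seed=5, n_lipids_per_leaflet=16,
                         compression_amplitude=0.0, lattice_jitter=0.04)
    return spec, make_bilayer(spec)


@pytest.fixture(scope="session")
def melt_trajectory():
    """2NCb dimer over a tiny membrane, β1 of both chains melting halfway."""
    spec = SyntheticSpec(
        seed=7, dimer_arrangement="2NCb", n_lipids_per_leaflet=16,
        n_frames=200, melt_schedule=(("b1", "A", 100), ("b1", "B", 100)),
        exchange_rate=0.0, compression_amplitude=0.0,
    )
    traj, truth = simulate(spec)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
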