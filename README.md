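# memlyze

Analysis of peptide-in-bilayer molecular-dynamics trajectories, built around
the question of how an inserted amyloid-β (Aβ42) dimer perturbs a DPPC
membrane. The package implements the full trajectory-analysis pipeline such a
study needs — and a synthetic trajectory generator with planted ground truth
so every stage can be validated end to end without running any MD.

## What it computes

For a trajectory (multi-frame GRO or multi-MODEL PDB, orthorhombic box):

* **Mass density profiles** along the membrane normal, windowed (e.g. first
  vs last quarter of the run), with a profile-overlap coefficient
  Σ min(p̂₁, p̂₂).
* **RMSD / RMSF** after mass-weighted Kabsch superposition (backbone N, CA, C
  by default).
* **Secondary structure** per residue and frame over the three-letter
  alphabet {E = β-strand, T = turn, C = coil}, assigned from Kabsch–Sander
  hydrogen bonds, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
  bond iff E < −0.5; bridges/ladders → E, isolated 3-, 4-, 5-turns → T,
  helices and the rest collapse to C. Derived: evolution maps, contents,
  per-residue propensities, and the inter-peptide β-strand propensity ratio
  max(P̄_A, P̄_B)/min(P̄_A, P̄_B) over a strand region.
* **GROMOS (Daura) conformational clustering** of extracted structures at a
  Cα-RMSD cutoff (default 0.25 nm), with the size/percentage table and
  central structures.
* **Area per lipid** by grid tessellation (each cell of an n×n grid goes to
  the laterally nearest projected head or peptide atom under periodic
  boundaries), stratified into core (≤ 0.5 nm from the peptide),
  intermediate (0.5–1.0 nm] and remote (> 1.0 nm) regions per leaflet.
* **Deuterium order parameters** S_CD = ⟨(3cos²θ − 1)/2⟩ per acyl carbon,
  with methylene hydrogens reconstructed for united-atom chains; reported as
  −S_CD.
* **Hydrogen-bond census** (0.35 nm / 30° geometric criterion) classified by
  strand pairs: intra-peptide β1–β2, β3–β4, β4–β5 per chain and
  inter-peptide same-strand contacts (β1/β2 pooled, β3, β4, β5, β3–β5).
* **Lateral RDF** of lipid heads around the peptide, the distance enclosing
  80% of the area under g(r), and the **lipid residence time** — the mean
  maximal continuous dwell of a head inside that shell.

## Worked example

The packaged config simulates a 2NCb dimer (the arrangement whose N-terminal
hairpins pair) inserted in a 288-lipid synthetic bilayer with a planted 20%
area compression around the inclusion and a planted β1 melt of chain B
halfway through, plus a pure-membrane reference:

```bash
memlyze run --config configs/synthetic_dimer.yaml
```

Key numbers from `memlyze_out/` (seed 0):

```
leaflet       region     mean   pure_mean     delta
 bottom         core    0.522       0.64     -0.118
 bottom intermediate    0.659       0.64      0.019
 bottom       remote    0.642       0.64      0.002
    top         core    0.427       0.64     -0.213
    top       remote    0.665       0.64      0.025
```

The core-region area per lipid is depressed well below the pure-membrane
0.64 nm² (the planted compression plus the area occupied by the peptide
itself), while the remote region stays within a few percent of the
reference — the planted perturbation is local. The secondary-structure
content comes out as E/T/C = 0.592/0.119/0.289, and the β-strand propensity
ratio between the two chains over β1 (residues 2–5) is **1.98**: chain B's
hairpin was melted for exactly half the frames, so its strand propensity is
half of chain A's.

The same stages are available individually (`memlyze density|rmsd|rmsf|ss|
cluster|apl|scd|hbonds|rdf|residence`) and as library functions, e.g.

```python
from memlyze import SyntheticSpec, simulate, select_atoms
from memlyze.interactions import residence_time

traj, truth = simulate(SyntheticSpec(seed=11, inclusion="rod",
                                     n_frames=20_000, exchange_rate=0.01))
stats = residence_time(traj, cutoff=truth.shell_radius,
                       peptide_indices=select_atoms(traj.topology, "kind peptide"))
print(stats.tau)   # ~99 ps for the planted 100 ps mean dwell
```

`memlyze compare outdir1 outdir2 ...` tabulates per-leaflet APL, structure
contents, residence times and first-cluster percentages side by side.

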