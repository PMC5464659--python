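# End-to-end demonstration config: a 2NCb dimer inserted in a synthetic DPPC
# bilayer, compared against a pure synthetic membrane reference.
#
# The synthetic blocks are SyntheticSpec fields; everything else mirrors the
# analysis defaults (cluster cutoff 0.25 nm, regions 0.5/1.0 nm, RDF area
# fraction 0.8). Run with:  memlyze run --config configs/synthetic_dimer.yaml
synthetic:
  dimer_arrangement: 2NCb
  n_lipids_per_leaflet: 144
  apl0: 0.64
  compression_amplitude: 0.2
  compression_radius: 2.2
  transition_radius: 3.5
  exchange_rate: 0.01
  diffusion: 5.0e-05
  lattice_jitter: 0.03
  n_frames: 150
  dt: 1.0
  melt_schedule:
    - [b1, B, 75]
reference_synthetic:
  dimer_arrangement: null
  inclusion: null
  n_lipids_per_leaflet: 144
  apl0: 0.64
  compression_amplitude: 0.0
  exchange_rate: 0.0
  diffusion: 5.0e-05
  lattice_jitter: 0.03
  n_frames: 150
  dt: 1.0
region_distance_mode: lateral
cluster_stride: 5
apl_stride: 5
seed: 0
out_dir: memlyze_out
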