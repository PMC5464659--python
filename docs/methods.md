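# Methods

This note documents the models and procedures memlyze implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where a choice was genuinely open.

## Units, conventions, formats

Lengths are nm and times ps everywhere inside the package; GRO files are read
natively, PDB coordinates are converted from Å at the boundary. Atom indices
are 0-based in memory and 1-based in files and reports. Only orthorhombic
boxes are supported, which keeps the minimum-image convention exact
(`d − L·round(d/L)` per axis); triclinic input raises an explicit
unsupported-format error. GRO carries no chain identifiers, so peptide chains
are inferred from residue-number restarts and lettered A, B, …; the
residue-name → molecule-kind mapping (DPPC → lipid, SOL/HOH → water, NA/CL →
ion, otherwise peptide) is configuration data, not hard-coded, because GRO
dialects vary.

## Superposition, RMSD, RMSF

Rigid superposition is the weighted Kabsch algorithm (SVD of the weighted
covariance with the determinant correction, so reflections are excluded);
weights default to atomic masses. RMSD series are computed per frame against
a reference after superposition on the analysis selection (backbone N, CA, C
by default; Cα only for clustering, matching the split usage customary for
these two analyses). RMSF is the per-atom RMS deviation from the time-mean
structure after each frame is fitted to the mean and the mean recomputed once
— one fixed-point iteration, which suffices to remove global rigid-body
motion (asserted by an invariance test). Degenerate (collinear) point sets
raise rather than returning an arbitrary rotation.

## Density profiles

Mass-weighted histograms along z, averaged over a frame window and divided by
the window-averaged bin volume (the box may fluctuate in an NPT run).
Windows are expressed as frame-range fractions so "first/last quarter"
scales to any trajectory length. The overlap of two profiles is
Σ min(p̂₁, p̂₂) over bins of the normalised profiles: 1 for identical shapes,
0 for disjoint support.

## Secondary structure (three-letter)

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
energy; a bond requires E < −0.5 kcal/mol. Amide hydrogens, absent in
united-atom models, are reconstructed 0.1 nm from N along the previous
residue's O→C direction; chain-initial residues and prolines cannot donate.
Bonds with both distances below 0.05 nm are clamped (single-pair evaluation
raises a clash error; the vectorised matrix path clamps so that disordered
geometry degrades gracefully).

Bridges follow the standard patterns — antiparallel (i→j and j→i) or
(i−1→j+1 and j−1→i+1); parallel (i−1→j and j→i+1) or (j−1→i and i→j+1) —
with |i−j| ≥ 3 within a chain; bridges may cross chains (inter-peptide
sheets) but n-turns are evaluated within a chain only. Every bridge
participant is labelled E (isolated bridges included: the three-letter
alphabet has no separate B class and folding bridges into E is conservative
toward "β-strand"). Residues enclosed by an isolated 3-, 4- or 5-turn are T.
Two consecutive same-n turn starts form a helix, and helices collapse to C
along with everything unassigned — the target alphabet tracks only
β-strand/turn/coil and the systems of interest are β-dominated, so helical
content is deliberately not surfaced as turn.

The inter-peptide strand-propensity ratio for a residue region is
max(P̄_E^A, P̄_E^B)/min(…), i.e. always ≥ 1; when exactly one chain has zero
mean propensity an infinite-ratio sentinel is returned with a warning.

## GROMOS clustering

The greedy neighbour algorithm: the structure with the most neighbours
within the RMSD cutoff (0.25 nm Cα by default) becomes a center, it and its
neighbours are removed, repeat. The neighbour-count tie-break — unspecified
in the algorithm's usual statements — is fixed to the lowest structure
index, making results deterministic and testable. Percentages are reported
to one decimal with round-half-even. The pairwise matrix is held dense; a
guard refuses more than 20,000 structures (a 40,000² float64 matrix is
~12 GB) unless explicitly overridden.

## Area per lipid and its stratification

Grid tessellation: the leaflet's head atoms, plus peptide atoms within a
±0.5 nm z-slab of the leaflet's mean head height (so mid-membrane peptide
atoms cannot steal head-plane area), are projected onto xy; each cell of an
n×n grid (default 200, giving ≤ ~1% RMS deviation from the exact periodic
Voronoi tessellation on test frames) is assigned to the laterally nearest
projected atom via a periodic KD-tree. A lipid's area is its cell count
times the cell area, so lipid areas plus peptide-occupied area tile the box
exactly by construction. The independent reference implementation —
scipy Voronoi on 3×3 tiled images with shoelace polygon areas — ships as
`periodic_voronoi_areas` and is used only for validation.

Region assignment uses the minimum over peptide atoms of the minimum-image
distance from the lipid head: core ≤ 0.5 nm, intermediate (0.5, 1.0] nm,
remote > 1.0 nm, with bounds closed on the upper edge (deterministic
boundary behaviour). 3D distance is the default — the conservative reading
for an inserted peptide — with a lateral (xy) variant behind a flag; the
packaged demonstration config uses the lateral variant because its peptide
spans the bilayer, making the lateral footprint the natural perturbed zone.

## Order parameters

S_CD per acyl carbon uses reconstructed methylene hydrogens: for carbon i the
two C–H unit vectors are perpendicular to the C(i−1)→C(i+1) axis, opposite
the in-plane bisector, split by the tetrahedral half-angle; chains report
interior carbons only. When the three carbons are collinear the bisector is
undefined and an arbitrary perpendicular pair is used — for an axially
symmetric (all-trans, chain along the normal) geometry every perpendicular
choice gives the same S_CD = −0.5 exactly. Values are reported as −S_CD,
positive for ordered chains, following the experimental plotting convention.

## Hydrogen-bond census

Geometric criterion: donor–acceptor (N···O) distance ≤ 0.35 nm and
H–N···O angle ≤ 30°, the de-facto standard defaults. Same-residue and
chain-adjacent pairs are excluded. Categories: same-chain bonds between β1
and β2 residues → intra-X β1–β2 (likewise β3–β4, β4–β5); cross-chain bonds
between identically numbered strands → inter βk, with the two N-terminal
strands pooled as "inter b1-b2" (a cross-chain β1↔β2 bond lands in the same
pooled category); cross-chain β3↔β5 → "inter b3-b5"; anything else →
"other". Means ± SD are per frame.

## Lateral RDF and residence time

The peptide spans the bilayer, so the RDF is two-dimensional around the
peptide's xy centroid: g(r) = ⟨count in annulus⟩ / (ρ₂D · 2πr·Δr) with ρ₂D
the target count per box xy area, plus the cumulative coordination count
N(r). The shell cutoff is the smallest r at which the running integral
∫g dr reaches 80% of the integral to r_max (linear interpolation inside a
bin) — for a uniform disc this is 0.8·r_max by construction.

Residence time: a lipid's membership series is "head within the cutoff of
the peptide's lateral centre"; maximal runs (gaps up to a configurable
tolerance merged, default 0) give dwell durations = run length × frame
spacing; runs touching either trajectory end are truncated observations and
are excluded; τ is the mean dwell. This estimator is deterministic and
recovers the generator's planted kinetics; discrete sampling biases it by
about +dt/2, negligible at the default 1 ps spacing against a 100 ps dwell.

## The synthetic generator

The generator exists to give every stage a recoverable planted answer; it is
not a physical simulation (no force field, no energetics, no membrane
undulations, no water dynamics).

**Peptide.** Each 42-residue chain is backbone-only (N, CA, C, O — enough
for Kabsch–Sander bonds and Cα clustering) and laid out on an ideal β-sheet
lattice: strand residues at 0.35 nm spacing, hydrogen-bonded rows 0.412 nm
apart, carbonyls alternating across each strand so the donor/acceptor
register is exact. The N-terminal hairpin (β1 2–5, β2 11–14) and the
C-terminal sheet (β3 17–22, β4 31–36, β5 39–41) occupy two sheet planes
1.2 nm apart. The residues flanking the strands (6/10 around the hairpin
turn and 23/30 around the long loop) anchor the ladders and are therefore
labelled E; turns 7–9 and 37–38 are hydrogen-bonded n-turns (labelled T);
the long loop 24–29 is irregular coil. The second chain is a rigid transform
of the first, placed so that exactly the arrangement-specific strands pair:
2NCb pairs β1–β1, CNNC β3–β3, NCCN β5–β5, NCNC β5(A)–β3(B), reproducing the
expected inter-peptide hydrogen-bond zero-patterns.

**Melting.** A melt-schedule entry (strand, chain, frame) displaces that
strand's residues 0.45 nm out of their sheet plane and adds fresh per-frame
Gaussian jitter (σ = 0.08 nm) from the melt frame on, which removes all its
Kabsch–Sander bonds. Because a β-ladder is a property of a strand *pair*,
melting a strand also removes its partner's bridges — melting β1 converts
β2 to coil as well; this coupling is part of the planted truth and any
hydrogen-bond-consistent generator must share it. Planted occupancy checks
therefore target the melted strand's own residues.

**Bilayer.** Two leaflets of pseudo-lipids (P head + two 4-carbon all-trans
acyl chains pointing inboard, so −S_CD = 0.5 exactly) on a jittered square
lattice; the box xy area is exactly n·apl0 (default 64 lipids/leaflet at the
fluid-phase DPPC area 0.64 nm²). A compression kernel around the inclusion
maps radii r ≤ R to r·√(1−a) (local area scaled by 1−a, default a = 0.2,
R = 1.5 nm) with a linear transition annulus back to the identity; lipids
well inside the kernel therefore have Voronoi area (1−a)·apl0 exactly, while
the transition annulus is mildly stretched. The packaged pipeline config
uses 144 lipids/leaflet so this stretch is diluted enough for the remote
region to sit within a few percent of the pure reference; 64/leaflet remains
the default scale for unit tests.

**Dynamics.** Lipids diffuse laterally in *virtual* (uncompressed)
coordinates (variance 2·D·dt per axis, D = 5·10⁻⁵ nm²/ps ≈ fluid-phase
DPPC) and are rendered through the compression map each frame, so the
planted area signal persists dynamically. Shell membership is an explicit
two-state process overlaid on positions: each in-shell lipid exits with
first-order rate k (default 0.01/ps, mean dwell 1/k = 100 ps); diffusion is
reflected at the shell boundary so membership equals the Markov state
exactly; and every exit is paired with the entry of a randomly chosen
outside lipid, which keeps the shell population — and hence the rendered
density — constant instead of letting it wander on the slow 1/k timescale.
In-shell dwells remain exponential with mean 1/k; no quantity is planted on
the out-of-shell dwells. The measurable shell radius (√(1−a)·R) and all
other planted values are returned in a `GroundTruth` record and written as a
TSV sidecar by `memlyze simulate`.

**What passing tests do and do not show.** The generator validates the
*analysis machinery*: unit conversions, periodic geometry, assignment rules,
tessellation accuracy, estimator bias. It does not emulate protein–lipid
energetics, membrane undulations, headgroup tilt, collective lipid flows or
conformational kinetics, so recovering planted values here says nothing
about force-field accuracy or sampling adequacy in real MD data — only that
the bookkeeping between coordinates and reported numbers is correct.

## Pipeline and determinism

`run_pipeline` executes all stages on one system plus an optional
pure-membrane reference, writing TSVs whose header comments carry a SHA-256
hash of the analysis parameters (output directory excluded) and a JSON
manifest with per-stage status. All randomness flows from the config seed
through `numpy.random.default_rng`, and output formatting is fixed, so a
repeated run is byte-identical. Desk-scale problem sizes throughout (10²
lipids, 10²–10⁴ frames, ≤ a few hundred clustered structures) keep the whole
validation suite in the tens of seconds on one CPU; the dense-matrix guard
documents rather than hides the cost of the 40,000-structure study scale.

## Known limitations

* GRO/PDB only; no binary trajectory formats (XTC/TRR/DCD) and no topology
  (.itp/.top) parsing.
* Orthorhombic cells only.
* The three-letter alphabet intentionally hides helix and bend classes.
* The residence-time estimator drops boundary-truncated dwells, which biases
  τ slightly downward when dwells are comparable to the trajectory length;
  choose trajectories ≳ 100× the expected dwell.
* The grid APL's single-lipid worst-case error at the default 200×200 grid
  is ~3% (a 0.64 nm² lipid spans ~625 cells); averages are accurate to ~1%.
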