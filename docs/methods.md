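# Methods

This note documents the models, conventions and design choices behind
`allocross`. It states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Scope and data model

The package analyses ensembles of a two-domain protein — an anchor domain
of two lobes (NBD-like), a short flexible linker, and an appended mobile
domain (SBD-like) — labelled by *ligand state*: a map from binding site to
occupant, e.g. `{NBD: ATP, SBD: NR}`. Internal units are **nm** for length
and **ps** for time; PDB Å are converted on read. Residue numbering is
1-based and taken from PDB residue sequence numbers, so literature residue
intervals (anchor 1–380, mobile 393–603, linker 383–396 in DnaK numbering)
can be used verbatim. Frames are assumed whole (not wrapped over periodic
boundaries); no minimum-image correction is applied anywhere.

File formats (PDB, multi-model PDB, XTC, DCD) are handled by mdtraj behind
the `io` module. Insertion codes are rejected by default. A truncated DCD
is detected by comparing the header frame count against frames actually
read, because the underlying plugin would otherwise silently short-read.
DCD carries no time metadata, and trajectory output frequency is generally
not recoverable from files, so the run-set manifest must declare `dt_ps`
explicitly.

### Meta-trajectory and tail windows

Analyses run on the equilibrated *tail* of each run. A run of `n` frames
with spacing `dt` is assigned duration `n·dt` (each frame owns one `dt`),
so a tail of `k·dt` ns keeps exactly the last `k` frames and a tail equal
to the full duration keeps every frame. `build_meta` concatenates these
windows across runs, preserving one provenance label per frame; segments
must share an atom count (a deliberate simplification — run sets for one
protein always do).

## gromos clustering

`gromos_cluster` implements greedy neighbour counting on a precomputed
frame×frame RMSD matrix: among unassigned frames, count unassigned
neighbours within the cutoff (self included); the frame with the most
neighbours — ties broken by lowest frame index — becomes a centre and is
removed together with its neighbours; repeat. Clusters are renumbered by
decreasing size (ties: earlier formation first), populations sum to 1 over
a true partition.

The RMSD matrix is computed over a Cα selection after least-squares
fitting *on that same selection* (the convention of the reference
clustering tools; `fit=False` is available for raw coordinate RMSD).
The fitted kernel is an in-package batched Kabsch: frames are centred and,
per reference frame, all 3×3 cross-covariance SVDs are solved at once with
the proper-rotation sign correction. It is float64-exact (a rigidly
rotated copy of a frame scores 0 to ~1e-12 nm) and builds a 1000-frame
matrix in a few seconds on one CPU.

Two notions of "cluster centre" exist: the gromos *seeding centre*
(max-neighbour frame, stored in `ClusterResult.centers`) and the *medoid*
(member minimising summed RMSD to all members). They coincide on
well-separated clusters but can differ on adversarial matrices;
`representative(..., matrix=...)` returns the medoid when the matrix is
available, otherwise the seeding centre.

Named residue-subset presets mirror the standard DnaK analysis intervals:
373–393 and 393–433 at 0.35 nm, 393–503 at 0.15 nm, whole chain at
0.35 nm, plus the shorter 393–413 alternative. Presets are data, not
policy — any interval/cutoff pair can be configured.

### Decomposition by ligand state

`decompose_by_label` splits each of the top-k clusters' membership by the
per-frame ligand-state key and normalises per label (each row sums to 1
over `cluster_1..k` plus a remainder bucket). Under the null (labels
carry no information) every row equals the overall populations; the test
suite asserts this with a chi-square check after label shuffling.

## Distance-fluctuation maps

For residues *i, j* with Cα–Cα distance `d_ij(t)`, the map entry is

    A_ij = ⟨d_ij²⟩ − ⟨d_ij⟩²,

the temporal variance of the inter-residue distance (a standard-deviation
variant is available via `statistic="std"`; variance is the default).
Lower values mean higher internal coordination (rigidity), so the signed
difference map `A − B` reads as: negative entries = rigidified in A.
Accumulation is streaming — per-pair sums of `d` and `d²`, shifted by the
first frame's distances so the rigid-body null is limited by ~1e-30 nm²
rather than by catastrophic cancellation — giving O(selection²) memory
independent of trajectory length. Because the statistic is built from
internal distances it is *exactly* invariant under global rigid motion,
which the suite asserts at 1e-12 nm².

`coordination_score` averages `A_ij` over an inter-block rectangle (e.g.
lobe I × lobe II); overlapping blocks exclude the shared zero diagonal.

## Centre-of-mass clouds

Every retained frame is Kabsch-fitted on the anchor selection (default:
anchor-domain Cα) to the starting structure; the centre of mass of the
mobile selection (default: all atoms of the mobile domain, mass-weighted —
the atom scope is configurable since "centre of mass" fixes the weighting
but not the scope) is then recorded. Two distributions summarise the
cloud, both in Å because that is how interdomain distances are quoted:

* **distance from start** — ‖point − reference‖ histogram and mean;
* **pair distances** — all unordered point pairs (seeded uniform
  subsample above 5·10⁴ points, since pairs grow quadratically).

Histograms default to 1 Å bins with edges aligned so bin *centres* sit on
integer multiples of the width (first bin centred on 0); the peak is the
modal bin centre, ties resolving toward the smaller distance. This makes
integer-Å peak values well defined without an arbitrary origin offset.
Replicas of one system are merged before histogramming.

## Superposition, dihedrals, RMSD series

`kabsch_fit` is the SVD Kabsch algorithm with the determinant correction
(always a proper rotation); degenerate point sets (< 3 points, collinear
or coincident) are rejected rather than silently fitted. Dihedrals follow
the IUPAC sign convention (computed with the standard two-perpendicular
formula; the suite cross-checks against an independent plane-normal
implementation and against mdtraj's sign). Circular means use the mean
resultant vector, mapping to (−180°, 180°] with the convention that the
antipode is +180°, so {+170°, −170°} averages to 180°. The ψ≈103°-type
hinge averages are reported as raw circular means; no cis/trans
classification is attempted since the underlying convention is ambiguous
at such values.

## Contacts, H-bonds, interfaces, strand content

* **Contact**: minimum heavy-atom distance between two residues
  ≤ 0.45 nm. The value is a standard residue-contact convention (the
  analysis lineage does not fix one) and is a configurable parameter.
* **H-bond**: donor–acceptor (N···O) distance ≤ 0.35 nm and H–donor–
  acceptor angle ≤ 30° — the defaults of the canonical MD H-bond tools.
  When the model has no hydrogens (Cα/backbone-only synthetic chains),
  detection falls back to the distance criterion alone and warns once.
* **Persistence**: an interaction is retained at occupancy ≥ 30% of
  analysed frames by default; occupancy is reported exactly, and at
  threshold 0 a pair must still occur in ≥ 1 frame.
* **Interface**: per-residue-pair *time-averaged* minimum distance,
  thresholded at 6 Å — averaged-matrix semantics, not any-frame
  membership (a per-frame-fraction mode exists for sensitivity checks).
  Both directions (A residues near B, B residues near A) derive from the
  same matrix, so the listing is symmetric in role.
* **Strand content**: a residue is β-strand in a frame if it forms an
  inter-strand bridge — reciprocal backbone N···O bonds in antiparallel
  register, or the offset pair in parallel register, with sequence
  separation ≥ 3 — and an adjacent residue continues the ladder. This is
  a deliberately minimal DSSP-like criterion: only strand *content* is
  needed, not 8-state assignment, and the criterion is documented and
  swappable.

## Synthetic data: what it emulates, and what it does not

The generator builds a Cα (optionally N/CA/C/O backbone) chain of four
contiguous blocks — lobe A, lobe B, linker, appended domain — with ideal
0.38 nm Cα spacing. Domains are compact globules laid out on a
deterministic boustrophedon lattice path (reproducibility without an MD
engine); the linker is extended. Defaults (40+40 lobe residues, 14
linker, 60 appended; domain σ = 0.02 nm, linker σ = 0.08 nm; two-state
offsets of 2 nm ≈ the tens-of-Å interdomain displacements seen in
chaperone ensembles; i.i.d. state draws) are chosen once to caricature the
real system's scales. Every generator is a pure function of (parameters,
seed) and emits its ground truth — the per-frame state sequence, the
planted frame subsets — which is what tests compare against.

Emulated features: multimodal interdomain placements with programmable
weights (i.i.d. or two-state Markov, since the analyses are time averages
and insensitive to ordering), differential internal rigidity via
per-region Gaussian σ, planted H-bonds with *exact* frame occupancy
(bonded geometry at 0.28 nm; broken frames violate the criterion by
≥ 0.1 nm), planted antiparallel strand ladders with exact frame fractions
(non-strand frames adopt an ideal helix, which the ladder criterion
correctly scores as 0).

Not emulated: force-field physics, solvent, realistic side chains,
correlated domain breathing, or thermodynamic state populations. Passing
tests therefore demonstrate that the *estimators* are correct and
well-calibrated on data with known structure — not that any biological
conclusion about a real chaperone would be recovered at a given
trajectory length.

## Pipeline determinism and numerical notes

Reports are nested dicts serialised as canonical JSON (sorted keys, no
timestamps); provenance carries the package version, a config hash and
the seed. Identical manifest + config + seed reproduce byte-identical
report bodies, and every report number equals the corresponding
standalone module call (asserted in the suite).

Numerical conventions worth knowing: RMSD matrices are symmetrised with a
zero diagonal and negative variances from rounding are clipped at 0;
empty selections are allowed but warn; collinear dihedral quadruples give
per-frame NaN with a warning and are dropped from circular means;
degenerate Kabsch inputs raise. Test problem sizes (chains of 78–214
residues, 100–1000 frames) were chosen as the smallest scales at which
the statistical assertions (binomial 3σ bands, variance-of-variance
bounds) are meaningful.

## Known limitations

* H-bond detection without hydrogens cannot apply the angular term; on
  hydrogen-free models it is a distance criterion only (flagged).
* The interface map is O(|A|·|B|) residue pairs with per-pair heavy-atom
  scans; for full-size proteins with long trajectories it is the slowest
  stage.
* Cluster-count monotonicity in the cutoff is asserted empirically on
  random matrices; it is a strong regularity of the greedy algorithm, not
  a theorem.
* Whether literature distance averages use Cα or closest-heavy atoms is
  often unstated; both rules are provided
  (`residue_pair_distance_series(atom_rule=...)`).
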