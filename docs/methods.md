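# Methods

## Model and assumptions

A target shape is a closed, genus-0 polyhedral surface: vertices with 3D
coordinates, oriented polygonal faces, and edges that each border exactly
two faces (V − E + F = 2 is checked on input). Every edge is rendered as a
DX bundle: two parallel duplexes joined by crossovers, lying side by side
in the face plane. The scaffold is a single strand (RNA by default; DNA is
accepted and transcribed) that traverses each edge twice, once per duplex,
antiparallel; staples are DNA.

Helical geometry is parameterized by `HelixParameters`:

| form  | bp/turn | rise (nm/bp) | diameter (nm) | asymmetry |
|-------|---------|--------------|----------------|-----------|
| A     | 11      | 0.267        | 2.3            | staple crossovers staggered 4 nt |
| AltA  | 11      | 0.267        | 2.3            | scaffold crossover staggered 5 nt |
| SymA  | 11      | 0.267        | 2.3            | none |
| B     | 10.5    | 0.34         | 2.0            | none (10/11 grid) |

The default A-form rise is the theoretical 0.267 nm/bp; the canonical
0.260 nm/bp can be selected by constructing `HelixParameters` explicitly.
Edges must be at least 4 helical turns (44 bp A-form), the smallest
fabricated edge length.

## Scaffold routing

Routing reduces to graph theory. Orienting all faces outward and walking
their boundaries covers every directed edge exactly once, i.e. every edge
twice in antiparallel directions — but as F disjoint loops, one per face.
A spanning tree T of the polyhedron graph is chosen (Prim's algorithm,
unit weights, lowest-index tie-break permuted deterministically by the
seed); each non-tree edge receives a scaffold double crossover at which
the two adjacent face loops exchange strands. The edges outside a spanning
tree of a polyhedral graph form a spanning tree of its dual (the face
adjacency graph), so the E − V + 1 exchanges merge all F loops into
exactly one scaffold cycle. Any spanning tree yields a valid routing; the
choice changes strand identities but not the design statistics (verified
exhaustively over all 16 tetrahedron trees). The scaffold nick is placed
at axial offset 0 of the first traversed tree edge, which coincides with a
vertex pass; if the scaffold is longer than the routing, the excess
remains one contiguous unpaired 3' overhang at the nick, and a scaffold
shorter than the routing is an error (no partial designs).

Scaffold-exchange offsets: A-form, Sym A-form and B-form split the edge
symmetrically at the midpoint (odd lengths round the 5' half down, e.g.
27/28 on a 55-bp edge). Alt A-form centers the exchange on the odd
half-turn position nearest (above) the midpoint with a 5-nt stagger
between duplexes: 25/30 on a 44-bp edge.

## Staple layout

The anchored numbers of the A-form convention are: first staple crossover
9 nt (5' side) and 13 nt (3' side) from each vertex (a 4-nt stagger about
the one-turn position) on edges without a scaffold crossover; on
scaffold-crossover edges, staple crossovers an odd number of half-turns
(5.5-nt units) from the exchange, staggered 5 nt so the station center
falls on the half-turn exactly; and a staple nick 6-7 bp 5' of each
scaffold exchange (7 nt on the entering duplex, 6 nt on the returning one,
so both spacings occur and the shortest possible segment is 6 bp).

Between those anchors the layout is genuinely under-specified in the
published convention, and we fixed it as follows: staple-crossover
stations sit at **every** helical turn from turn 1 to T − 1 (not every
second turn), giving the 10-14-nt staple-domain granularity
characteristic of DX vertex staples; on scaffold-crossover edges only the
two parity-legal stations at ±1.5 turns from the exchange are kept, and
any station whose junction would leave a domain shorter than 5 bp is
dropped. One-turn spacing was adopted after checking reconstruction
candidates against the duplex-segment counts of the five reference designs
(see "Fidelity" below); two-turn spacing produces far too few segments.

Staples are chained deterministically and purely locally, which makes the
staple count, the crossover-class counts and the segment count independent
of the spanning tree:

* every vertex pass carries one **vertex staple** spanning the terminal
  domain of the outgoing duplex (3' at the vertex) and the terminal domain
  of the incoming duplex (5' at the vertex), 21-38 nt;
* the k-th inter-station domain pair of an edge joins across the station
  on its 5' (duplex-0) side when k is odd, across its 3'-side station when
  k is even. Odd interior stations therefore become reciprocal double
  crossovers (DX2), the first/last stations single crossovers (DX1, with
  the abutting terminus labeled a staple single terminus), even interior
  stations plain nicks. This pattern provably never closes a cyclic
  staple: a staple ring around a vertex would need terminal-domain
  exchanges on every incident edge, and every vertex touches at least one
  tree edge, which has none.

All staples fall in 20-60 nt for the A-form reference designs (global
bound: ≥ 19 nt across all supported forms and edge lengths).

## Structural features and duplex segments

Every junction along the scaffold cycle where the pairing context changes
is labeled with one of seven feature classes: `scaffold_dx2` (2 per
non-tree edge), `scaffold_nick` (1), `staple_dx2`, `staple_dx1`,
`staple_single_term`, `staple_nick`, and `vertex` (one per vertex pass,
2E in total). Features live on junctions between adjacent bases; the
per-base table labels the base immediately 3' of the junction, vertices
label both flanking bases, and ties are resolved by class priority.
Scaffold nicks are annotated but conventionally excluded from the
feature-window analysis (coverage at the scaffold ends is unreliable in
real data). Duplex segments are the maximal feature-bordered paired runs;
they tile the paired scaffold exactly, and each records its 5'/3' end
features for downstream grouping.

### Fidelity of the reconstruction

For the five reference designs (tetrahedra at 5/6/7 turns, octahedron and
pentagonal bipyramid at 6 turns) the pipeline yields 60/66/72/130/162
segments — 490 pooled, minimum length 6 bp, both exactly as published.
The three published per-design counts (64/134/166) differ by 2-4. This is
not a tuning failure but a structural impossibility: writing the segment
count as (vertex passes) + (nick) + per-edge junction counts, no uniform
per-edge staple layout reproduces all three published counts
simultaneously — any two of them force tree/crossover-edge junction
counts that contradict the third (and degree-dependent vertex terms admit
no non-negative integer solution either). The published tallies therefore
reflect residual conventions we cannot recover from the printed record
(plausibly segments dropped for lacking probed bases with the real
scaffold sequences, which require the deposited data). We chose the layout
that matches the pooled count and minimum exactly while keeping staples
physical.

## Coordinate model

One pseudo-atom per base: duplex axes run parallel to the mesh edge at
±diameter/2 in the face plane; vertex coordinates are rescaled so the mean
edge length equals (bp) × (rise) — coordinates never influence routing.
Bases advance by the rise and rotate by 360/bp-per-turn degrees; scaffold
and staple backbones sit diametrically opposite at 0.8 nm radius, with the
twist phase referenced so scaffold backbones face each other at scaffold
exchanges and staple backbones at stations. Each base carries an
orthonormal frame (backbone radial, normal, strand direction). No
mechanical relaxation is applied: experimentally observed edge bowing,
duplex twist and vertex splay are not modeled. Output: CSV (positions +
frames) and coarse PDB (P pseudo-atoms).

## DMS-reactivity statistics

The analysis layer consumes per-position mutation-rate tables (position,
base, reactivity, coverage); G/U positions are masked since DMS reports
only A and C. Choices that matter:

* **Normalization**: median reactivity of the top 50% (count rounded up,
  e.g. 46 of 91) of A/C bases in the spiked-in control, sample divided by
  its ratio to the reference sample. Scale-equivariant by construction.
* **Melting temperatures**: Biopython's nearest-neighbor engine with the
  Sugimoto RNA/DNA-hybrid parameter set and the entropy-based
  monovalent-salt correction (`saltcorr=5`), 0.3 M Na+, 25 nM strands.
  The parameter-set/salt-correction pairing is pinned here because the
  two interact; tests verify the result against an independent hand
  summation of the published table to 0.1 °C.
* **Segment statistics**: interior means over A/C bases excluding the
  single terminal base at each end; terminal/interior ratios defined only
  for A/C terminals with positive interior mean; Spearman correlations of
  interior mean vs Tm, length, GC over segments with ≥1 interior A/C.
* **Tests**: non-parametric only — one-sided Mann-Whitney U for window
  positions vs all farther positions on the same side (α = 0.01),
  Wilcoxon signed-rank (zero differences dropped) for paired comparisons
  (α = 0.05 for ratio analyses). scipy's exact small-sample methods agree
  with brute-force permutation enumeration (verified for n ≤ 10). No
  multiple-testing correction is applied; raw p-values are reported.
* **Window analysis** pools feature instances across designs
  (`pooled_feature_windows`), mirroring joint analysis of independently
  probed objects; offsets −k/+k are the k-th bases 5'/3' of the feature
  junction.

## Synthetic reactivity generator

`simulate_reactivities` emulates the assumed statistical structure of
DMS-MaPseq output, not the read-level process: log-normal reactivities
(median 3% at unpaired A/C, σ = 0.45 in log space), staple-paired
positions suppressed by a protection factor (default 5), cytosines at 0.8×
the adenine rate, optional per-feature multipliers applied to the two
bases flanking each feature junction, Poisson coverage, and an appended
140-nt control region with exactly 91 probed A/C bases folded identically
in every sample. The bare-scaffold sample pairs a configurable fraction of
positions natively (default 0.58, matching the observed fraction for a
natural long RNA). It does **not** model sequence-context biases,
coverage-dependent noise, reverse-transcription artifacts or alternative
secondary-structure ensembles, so passing recovery tests demonstrates the
statistics layer is correct, not that real libraries behave this simply.
Recovery estimators in the tests compare geometric-mean terminal/interior
ratios at multiplied features against unmultiplied ends, which cancels the
small upward bias of the arithmetic interior mean.

## Numerical / degenerate-input conventions

Axial coordinates are 0-based internally and 1-based in all emitted
tables. Odd-length symmetric exchanges round the 5' half down. Stations
landing within 5 bp of a nick, exchange or vertex are dropped. Meshes with
holes, genus > 0, or edges bordering ≠2 faces are rejected with named
errors; binary PLY is rejected (ASCII only, for diff-able fixtures).
Mixed face winding is normalized outward via Newell normals against the
centroid (convex targets). 4-turn scaffold-crossover edges have no
parity-legal stations and are held by their vertex staples and nick-flanked
staples only.

## Known limitations

* Single-scaffold, dual-duplex-edge designs only; no single-duplex
  wireframe, multi-scaffold or bricklike routing.
* The staple layout between anchored offsets is a reconstruction; see
  "Fidelity" above.
* The coordinate model is coarse-grained (no energy minimization, no
  vertex relaxation) and intended for visualization and sanity checks.
* Thermodynamic staple optimization and reactivity-guided structure
  prediction are out of scope.
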