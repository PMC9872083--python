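# rnaori

Top-down sequence design of **RNA-scaffolded 3D wireframe origami** with
dual-duplex (DX) edges, plus the statistics layer for analyzing their
base-pairing by DMS chemical probing.

A long single-stranded RNA scaffold can be folded into a target polyhedron
by short complementary DNA staples. Because RNA:DNA hybrids adopt the
A-form helix (11 bp per turn, ~0.26 nm rise per bp, 2.3 nm diameter) rather
than B-form DNA (10.5 bp per turn), the crossover rules of classic DX
wireframe design must change. `rnaori` implements that A-form design
algorithm and the downstream analysis, for nucleic-acid nanotechnologists
who want to design such structures or interrogate their per-base stability.

## What it does

Given a closed polyhedral mesh (ASCII PLY or a built-in) and a scaffold
sequence (FASTA or a generated De Bruijn-style sequence), the pipeline:

1. **Discretizes** every edge to a multiple of 11 bp (A-form) or a rounded
   multiple of 10.5 bp (B-form).
2. **Routes the scaffold**: a seeded Prim spanning tree is computed; walking
   the oriented face boundaries covers every edge twice (two antiparallel
   duplexes per DX edge) as one loop per face, and a scaffold double
   crossover on every *non*-tree edge merges the face loops into a single
   closed cycle of length 2·Σ(edge bp).
3. **Places crossovers** by helix form. A-form puts the helical asymmetry
   into the staple crossovers (junctions 9 nt and 13 nt from each vertex, a
   4-nt stagger between the two duplexes); Alt A-form instead staggers the
   scaffold crossover by 5 nt (offsets 25/30 on a 44-bp edge); Sym A-form
   and B-form cross over symmetrically. On scaffold-crossover edges, staple
   crossovers sit an odd number of half-turns (5.5 nt units) from the
   scaffold exchange, and a staple nick lies 6-7 bp 5' of each exchange.
4. **Generates staples**: 20-60-nt DNA oligos chained through vertex spans
   and staple crossovers, each domain the reverse complement of its
   scaffold stretch.
5. **Annotates** every scaffold base with one of seven structural features
   (scaffold/staple double crossovers, single crossovers, staple nicks and
   single termini, vertices, scaffold nick) and tiles the paired scaffold
   into **duplex segments** — maximal feature-bordered paired runs.
6. **Analyzes DMS reactivities**: spike-in normalization across samples,
   scaffold-vs-origami protection (paired Wilcoxon), per-segment
   terminal/interior ratios, RNA/DNA-hybrid melting temperatures
   (nearest-neighbor model with salt correction at 0.3 M Na+), and
   feature-window Mann-Whitney tests. A synthetic reactivity generator
   emulates the assumed data structure so the whole layer is testable
   without sequencing data.

## Worked example

```python
from rnaori import router, scaffold_gen
from rnaori.fixtures import builtin_polyhedron
from rnaori.mesh_io import A_FORM, discretize_edges

mesh = discretize_edges(builtin_polyhedron("tetrahedron"), 6, A_FORM)
scaffold = scaffold_gen.generate_de_bruijn_scaffold(792, order=8, seed=1)
design = router.design(mesh, scaffold, "A", seed=0)
print(design.routing.length, len(design.staples))
print(design.plan.first_staple_crossover())
```

prints `792 30` and `(9, 13)`: the six 66-bp DX edges consume
2 × 6 × 66 = 792 scaffold nucleotides, folded by 30 staples of 22-34 nt,
with the first staple crossover 9 nt (5' side) and 13 nt (3' side) from
each vertex. Running `python examples/annotate_segments.py` then reports
the duplex segments of the five standard probing targets (60 + 66 + 72 +
130 + 162 = 490 segments, shortest 6 bp). See `examples/` for scaffold
generation, DMS analysis on synthetic data, and coarse 3D models, or use
the CLI:

```bash
rnaori scaffold --length 792 --order 8 --seed 1 --out scaffold.fasta
rnaori design tetra.ply scaffold.fasta --form aform --turns 6 --out design/
rnaori analyze design/segments.csv scaffold.fasta reactivities.csv --out stats/
```

## Layout caveat

The per-edge staple layout between the anchored crossover offsets is the
least-specified part of the published design convention. The
reconstruction here (staple-crossover stations every helical turn, giving
10-14-nt domains) reproduces the pooled duplex-segment count of the five
reference designs and the 6-bp minimum segment exactly, but individual
per-design segment counts can differ from the published tallies by 2-4
(~3%); see `docs/methods.md` for the analysis.
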