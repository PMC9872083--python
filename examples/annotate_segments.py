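"""Structural features and duplex segments for five probing targets.

Builds the tetrahedra with 5/6/7 turns per edge plus the octahedron and
pentagonal bipyramid at 6 turns, labels every scaffold base with its
structural feature (crossovers, nicks, termini, vertices) and tiles the
paired scaffold into feature-bordered duplex segments.
"""

from collections import Counter

from rnaori import annotator, router, scaffold_gen
from rnaori.fixtures import builtin_polyhedron
from rnaori.mesh_io import A_FORM, discretize_edges

sc1218 = scaffold_gen.generate_de_bruijn_scaffold(1218, 8, seed=1)
sc792 = scaffold_gen.generate_de_bruijn_scaffold(792, 8, seed=2)
sc1980 = scaffold_gen.generate_de_bruijn_scaffold(1980, 8, seed=3)

targets = {
    "rT55": ("tetrahedron", 5, scaffold_gen.ScaffoldSequence("s", sc1218.residues[:660])),
    "rT66": ("tetrahedron", 6, sc792),
    "rT77": ("tetrahedron", 7, scaffold_gen.ScaffoldSequence("s", sc1218.residues[:924])),
    "rO66": ("octahedron", 6, sc1980),
    "rPB66": ("pentagonal_bipyramid", 6, sc1980),
}

total = 0
for name, (poly, turns, scaffold) in targets.items():
    mesh = discretize_edges(builtin_polyhedron(poly), turns, A_FORM)
    design = router.design(mesh, scaffold, "A", seed=0)
    ann = annotator.annotate_features(design)
    segments = annotator.identify_segments(ann)
    total += len(segments)
    feats = Counter(f.kind for f in ann.features)
    print(f"{name}: {len(segments)} segments, "
          f"shortest {min(s.length for s in segments)} bp, features: {dict(feats)}")
print(f"total duplex segments across the five designs: {total}")
# Each segment is a maximal scaffold:staple paired run bordered by
# structural features; the 6-7 bp segments sit between a staple nick and a
# scaffold double crossover.
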