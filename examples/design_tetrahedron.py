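"""Design an RNA-scaffolded DX wireframe tetrahedron end to end.

Builds the regular tetrahedron with six helical turns (66 bp) per A-form
edge, generates a 792-nt low-self-complementarity RNA scaffold, routes it
through the polyhedron and prints the staple set.
"""

from rnaori import router, scaffold_gen
from rnaori.fixtures import builtin_polyhedron
from rnaori.mesh_io import A_FORM, discretize_edges

mesh = discretize_edges(builtin_polyhedron("tetrahedron"), 6, A_FORM)
scaffold = scaffold_gen.generate_de_bruijn_scaffold(792, order=8, seed=1)
design = router.design(mesh, scaffold, "A", seed=0)

print(f"edges: {mesh.n_edges} x {mesh.edge_length_bp[mesh.edges[0]]} bp (A-form)")
print(f"scaffold routed: {design.routing.length} nt "
      f"({design.paired_nt} paired, {design.overhang_nt} nt overhang)")
print(f"spanning tree edges: {sorted(design.tree.edges)}")
print(f"scaffold crossovers on {len(design.routing.scaffold_xovers)} non-tree edges")
j5, j3 = design.plan.first_staple_crossover()
print(f"first staple crossover: {j5} nt (5' side) / {j3} nt (3' side) from vertex")
print(f"staples: {len(design.staples)} "
      f"({min(s.length for s in design.staples)}-"
      f"{max(s.length for s in design.staples)} nt)")
for s in design.staples[:5]:
    print(f"  {s.id} {s.length:>3d} nt  5'-{s.sequence}-3'")
print("  ...")
# The routed length equals twice the total edge length (each edge is a
# two-duplex DX bundle), and every staple is the DNA reverse complement of
# the scaffold stretches it pins together.
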