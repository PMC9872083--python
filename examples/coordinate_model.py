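"""Predict a coarse 3D model (one pseudo-atom per base) for a design."""

import numpy as np

from rnaori import atomic_model, router, scaffold_gen
from rnaori.fixtures import builtin_polyhedron
from rnaori.mesh_io import A_FORM, discretize_edges

mesh = discretize_edges(builtin_polyhedron("pentagonal_bipyramid"), 6, A_FORM)
scaffold = scaffold_gen.generate_de_bruijn_scaffold(1980, 8, seed=1)
design = router.design(mesh, scaffold, "A", seed=0)

model = atomic_model.build_model(design)
coords = model.coordinates()
print(f"model: {len(model)} bases "
      f"({design.routing.length} scaffold + staples), rise {model.rise_nm} nm/bp")
print(f"twist per bp: {360 / model.bp_per_turn:.2f} degrees")
print(f"bounding box: {np.ptp(coords, axis=0).round(1)} nm")
print(f"expected edge length: 66 bp x {model.rise_nm} nm = {66*model.rise_nm:.1f} nm")

atomic_model.write_model(model, "pb66_model.csv", "csv")
atomic_model.write_model(model, "pb66_model.pdb", "pdb")
print("wrote pb66_model.csv and pb66_model.pdb (P pseudo-atoms, viewable in any molecular viewer)")
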