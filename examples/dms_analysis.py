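"""Chemical-probing analysis on synthetic DMS reactivities.

Simulates per-base DMS mutation rates for a folded tetrahedron and for its
bare scaffold (staples protect paired bases ~5-fold; a structured spike-in
control is appended for cross-sample normalization), then runs the full
statistics layer: normalization, scaffold-vs-origami protection, per-segment
summaries with RNA/DNA-hybrid melting temperatures, and reactivity windows
around structural features.
"""

from rnaori import annotator, dms_stats, router, scaffold_gen
from rnaori.fixtures import (
    SyntheticDMSParams,
    builtin_polyhedron,
    simulate_reactivities,
)
from rnaori.mesh_io import A_FORM, discretize_edges

mesh = discretize_edges(builtin_polyhedron("tetrahedron"), 6, A_FORM)
scaffold = scaffold_gen.generate_de_bruijn_scaffold(792, 8, seed=1)
design = router.design(mesh, scaffold, "A", seed=0)
ann = annotator.annotate_features(design)
segments = annotator.identify_segments(ann)

params = SyntheticDMSParams(
    protection_factor=5.0,
    scaffold_paired_fraction=0.0,  # fully denatured reference scaffold
    feature_multipliers={"staple_nick": 5.0, "vertex": 3.0},
)
scaf_only, origami, truth = simulate_reactivities(design, params, seed=42)
origami_n = dms_stats.normalize_profile(origami, scaf_only)

res = dms_stats.compare_scaffold_vs_origami(scaf_only, origami_n, segments)
print(f"median segment reactivity: scaffold {100*res['median_scaffold']:.2f}% "
      f"vs origami {100*res['median_origami']:.2f}%")
print(f"protection: {res['percent_reduction']:.0f}% lower in the origami "
      f"(Wilcoxon p = {res['wilcoxon_p']:.2e}, n = {res['n_segments']} segments)")
# With a 5x protection factor the expected reduction is 1 - 1/5 = 80%.

table = dms_stats.segment_stats(origami_n, segments, design.scaffold.residues)
corr = table.attrs["correlations"]
print(f"predicted segment Tm range: {table.tm_celsius.min():.1f}"
      f"-{table.tm_celsius.max():.1f} C at 0.3 M Na+")
print(f"Spearman rho, interior reactivity vs Tm: {corr['tm_celsius']['rho']:+.2f} "
      "(no coupling injected -> near zero)")

win = dms_stats.feature_window_distributions(origami_n, ann)
sig = win[win.significant]
print("significant window positions (alpha = 0.01):")
for _, row in sig.iterrows():
    print(f"  {row.feature} offset {row.offset:+d}: "
          f"median {100*row['median']:.2f}%, p = {row.p_greater_than_further:.1e}")
# Only the bases immediately flanking the multiplied features (staple nicks,
# vertices) should exceed the farther positions on the same side.
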