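from collections import Counter

import pytest

from rnaori import fixtures, router
from rnaori.mesh_io import A_FORM, B_FORM, discretize_edges
from rnaori.router import (
    build_spanning_tree,
    enumerate_spanning_trees,
    place_crossovers,
    route_scaffold,
    scaffold_crossover_split,
    write_staples_csv,
)
from rnaori.scaffold_gen import reverse_complement
from tests.conftest import periodic_scaffold


def _mesh(name, turns=6, helix=A_FORM):
    return discretize_edges(fixtures.builtin_polyhedron(name), turns, helix)


# ---------------------------------------------------------------------------
# spanning tree
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,tree_edges", [("tetrahedron", 3), ("octahedron", 5)])
def test_tree_size(name, tree_edges):
    g = _mesh(name)
    t = build_spanning_tree(g, seed=0)
    assert len(t.edges) == tree_edges


def test_k4_has_sixteen_spanning_trees():
    assert len(enumerate_spanning_trees(_mesh("tetrahedron"))) == 16


def test_tree_deterministic_per_seed():
    g = _mesh("octahedron")
    assert build_spanning_tree(g, 3).edges == build_spanning_tree(g, 3).edges
    trees = {build_spanning_tree(g, s).edges for s in range(8)}
    assert len(trees) > 1  # seeds explore different trees


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,turns,expected",
    [("tetrahedron", 6, 792), ("octahedron", 4, 1056), ("pentagonal_bipyramid", 6, 1980)],
)
def test_routing_consumes_expected_scaffold(name, turns, expected):
    g = _mesh(name, turns)
    r = route_scaffold(g, build_spanning_tree(g), "A")
    assert r.length == expected


def test_double_cover_and_single_cycle(five_designs):
    for des in five_designs.values():
        r = des.routing
        r.audit()  # every (edge, duplex, axial) slot exactly once
        seen = set(r.slots)
        assert len(seen) == 2 * r.graph.total_length_bp


def test_duplexes_traversed_antiparallel(octa66_1980):
    # the scaffold moves in one consistent direction per duplex (possibly in
    # two pieces around a scaffold crossover) and opposite directions on the
    # two duplexes of every edge
    r = octa66_1980.routing
    signs: dict[tuple[int, int], set[int]] = {}
    for a, b in zip(r.slots, r.slots[1:]):
        if a[0] == b[0] and a[1] == b[1]:
            signs.setdefault((a[0], a[1]), set()).add(b[2] - a[2])
    for s in signs.values():
        assert s == {1} or s == {-1}
    for e in range(len(r.edge_list)):
        assert signs[(e, 0)] != signs[(e, 1)]


def test_scaffold_crossovers_only_on_nontree_edges(octa66_1980):
    r = octa66_1980.routing
    assert len(r.scaffold_xovers) == 12 - 6 + 1
    for ei in r.scaffold_xovers:
        assert r.edge_list[ei] not in r.tree.edges


# ---------------------------------------------------------------------------
# crossover geometry
# ---------------------------------------------------------------------------

def test_first_staple_crossover_offsets_a_form(tetra66):
    assert tetra66.plan.first_staple_crossover() == (9, 13)


def test_staple_crossover_asymmetry_is_4nt(tetra66):
    for lay in tetra66.plan.layouts.values():
        if lay.scaffold_j is None:
            for st in lay.stations:
                assert abs(st.j1 - st.j0) == 4


@pytest.mark.parametrize(
    "n,form,expected",
    [(44, "AltA", (25, 30)), (44, "SymA", (22, 22)), (66, "A", (33, 33)),
     (55, "A", (27, 28))],
)
def test_scaffold_crossover_split(n, form, expected):
    assert scaffold_crossover_split(n, form) == expected


def test_alt_a_form_5nt_scaffold_asymmetry():
    for n in (44, 55, 66, 77):
        a0, a1 = scaffold_crossover_split(n, "AltA")
        assert a1 - a0 == 5


def test_crossover_parity_odd_half_turns(tetra66):
    """On scaffold-crossover edges, adjacent scaffold and staple crossovers
    sit an odd number of half-turns (5.5 nt) apart."""
    for ei, lay in tetra66.plan.layouts.items():
        if lay.scaffold_j is None:
            continue
        center = sum(lay.scaffold_j) / 2
        for st in lay.stations:
            spacing = abs(st.center - center) / 5.5
            assert spacing == pytest.approx(round(spacing))
            assert round(spacing) % 2 == 1


def test_alt_a_exchange_centers_on_odd_half_turn():
    for n in (44, 55, 66, 77):
        a0, a1 = scaffold_crossover_split(n, "AltA")
        half_turns = (a0 + a1) / 2 / 5.5
        assert half_turns == pytest.approx(round(half_turns))
        assert round(half_turns) % 2 == 1


# ---------------------------------------------------------------------------
# staples
# ---------------------------------------------------------------------------

def test_staple_domains_reverse_complement_scaffold(five_designs):
    for des in five_designs.values():
        res = des.scaffold.residues
        for s in des.staples:
            for a, b in s.scaffold_ranges:
                assert reverse_complement(res[a - 1 : b]).replace("U", "T") in s.sequence


def test_simple_reverse_complement_example():
    # scaffold 5'-AUGC-3' is bound by staple 5'-GCAT-3'
    assert reverse_complement("AUGC").replace("U", "T") == "GCAT"


def test_staple_coverage_conservation(five_designs):
    for des in five_designs.values():
        total = sum(s.length for s in des.staples)
        assert total == des.paired_nt
        cover = Counter()
        for s in des.staples:
            for e, d, lo, hi in s.domains:
                for ax in range(lo, hi + 1):
                    cover[(e, d, ax)] += 1
        assert set(cover.values()) == {1}
        assert len(cover) == des.routing.length


def test_staple_lengths_within_bounds(five_designs):
    for des in five_designs.values():
        for s in des.staples:
            assert 20 <= s.length <= des.rules.max_staple_nt


def test_overhang_bookkeeping(octa66_1980):
    assert octa66_1980.routing.length == 1584
    assert octa66_1980.paired_nt == 1584
    assert octa66_1980.overhang_nt == 396


def test_scaffold_too_short_is_an_error():
    g = _mesh("tetrahedron")
    with pytest.raises(ValueError, match="shorter than"):
        router.design(g, periodic_scaffold(791), "A")


def test_design_is_deterministic(tmp_path):
    g = _mesh("tetrahedron")
    outs = []
    for _ in range(2):
        des = router.design(g, periodic_scaffold(792), "A", seed=0)
        p = tmp_path / f"s{len(outs)}.csv"
        write_staples_csv(des, p)
        outs.append(p.read_bytes())
    assert outs[0] == outs[1]


def test_tree_independence_of_design_statistics():
    """Staple count, crossover counts by class and duplex-segment count are
    identical across all 16 spanning trees of the tetrahedron."""
    from rnaori import annotator

    g = _mesh("tetrahedron")
    sc = periodic_scaffold(792)
    stats = set()
    for t in enumerate_spanning_trees(g):
        r = route_scaffold(g, t, "A")
        plan = place_crossovers(r, A_FORM)
        staples, labels = router.generate_staples(r, plan, sc)
        des = router.OrigamiDesign(g, A_FORM, plan.rules, t, r, plan, staples, sc, labels, 0)
        segs = annotator.identify_segments(annotator.annotate_features(des))
        kinds = Counter(plan.station_kind.values())
        stats.add(
            (len(staples), len(segs), kinds["dx2"], kinds["dx1"], kinds["nick"])
        )
    assert len(stats) == 1


def test_b_form_edge_length_mismatch():
    g = _mesh("tetrahedron", 6, helix=B_FORM)
    assert g.total_length_bp == 6 * 63
    with pytest.raises(ValueError, match="shorter"):
        router.design(g, periodic_scaffold(756 - 1), "B")
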