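import pytest

from rnaori import fixtures, router, scaffold_gen
from rnaori.mesh_io import A_FORM, discretize_edges


def periodic_scaffold(n: int) -> scaffold_gen.ScaffoldSequence:
    """Deterministic RNA filler sequence for routing-level tests."""
    return scaffold_gen.ScaffoldSequence(f"per{n}", "".join("ACGU"[i % 4] for i in range(n)))


@pytest.fixture(scope="session")
def debruijn_1218():
    return scaffold_gen.generate_de_bruijn_scaffold(1218, 8, seed=1)


@pytest.fixture(scope="session")
def tetra66():
    g = discretize_edges(fixtures.builtin_polyhedron("tetrahedron"), 6, A_FORM)
    return router.design(g, periodic_scaffold(792), "A", seed=0)


@pytest.fixture(scope="session")
def octa66_1980():
    g = discretize_edges(fixtures.builtin_polyhedron("octahedron"), 6, A_FORM)
    return router.design(g, periodic_scaffold(1980), "A", seed=0)


@pytest.fixture(scope="session")
def five_designs(debruijn_1218):
    """The five A-form designs characterized by chemical probing."""
    d = {}
    specs = {
        "rT55": ("tetrahedron", 5, scaffold_gen.ScaffoldSequence("rT55", debruijn_1218.residues[:660])),
        "rT66": ("tetrahedron", 6, periodic_scaffold(792)),
        "rT77": ("tetrahedron", 7, scaffold_gen.ScaffoldSequence("rT77", debruijn_1218.residues[:924])),
        "rO66": ("octahedron", 6, periodic_scaffold(1980)),
        "rPB66": ("pentagonal_bipyramid", 6, periodic_scaffold(1980)),
    }
    for name, (poly, turns, sc) in specs.items():
        g = discretize_edges(fixtures.builtin_polyhedron(poly), turns, A_FORM)
        d[name] = router.design(g, sc, "A", seed=0)
    return d
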