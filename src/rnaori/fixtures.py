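"""Built-in target geometries and synthetic DMS-reactivity generation.

The built-in polyhedra are the wireframe targets characterized in the
supported workflow: the regular tetrahedron (four 3-way vertices), the
regular octahedron (4-way vertices) and the pentagonal bipyramid (the
most complex target, mixing 4-way and 5-way vertices).

:func:`simulate_reactivities` emulates the statistical structure of a
DMS-MaPseq per-base mutation-rate table for a folded origami and for the
bare scaffold, so the whole analysis pipeline is testable without
sequencing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rnaori.mesh_io import PolyhedronGraph, orient_faces_outward

_SQRT2 = math.sqrt(2.0)


def _tetrahedron() -> tuple[dict, list]:
    verts = {
        0: np.array([1.0, 1.0, 1.0]),
        1: np.array([1.0, -1.0, -1.0]),
        2: np.array([-1.0, 1.0, -1.0]),
        3: np.array([-1.0, -1.0, 1.0]),
    }
    faces = [(0, 1, 2), (0, 3, 1), (0, 2, 3), (1, 3, 2)]
    return verts, faces


def _octahedron() -> tuple[dict, list]:
    verts = {
        0: np.array([1.0, 0.0, 0.0]),
        1: np.array([-1.0, 0.0, 0.0]),
        2: np.array([0.0, 1.0, 0.0]),
        3: np.array([0.0, -1.0, 0.0]),
        4: np.array([0.0, 0.0, 1.0]),
        5: np.array([0.0, 0.0, -1.0]),
    }
    faces = [
        (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
        (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5),
    ]
    return verts, faces


def _pentagonal_bipyramid() -> tuple[dict, list]:
    # equilateral Johnson solid J13: unit edges, ring radius 1/(2 sin 36deg)
    r = 1.0 / (2.0 * math.sin(math.pi / 5.0))
    h = math.sqrt(1.0 - r * r)
    verts = {0: np.array([0.0, 0.0, h]), 1: np.array([0.0, 0.0, -h])}
    for k in range(5):
        ang = 2.0 * math.pi * k / 5.0
        verts[2 + k] = np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    faces = []
    for k in range(5):
        a, b = 2 + k, 2 + (k + 1) % 5
        faces.append((0, a, b))
        faces.append((1, b, a))
    return verts, faces


_BUILTINS = {
    "tetrahedron": _tetrahedron,
    "octahedron": _octahedron,
    "pentagonal_bipyramid": _pentagonal_bipyramid,
}


def builtin_polyhedron(name: str) -> PolyhedronGraph:
    """Return a validated built-in mesh by name.

    Known names: ``tetrahedron``, ``octahedron``, ``pentagonal_bipyramid``.
    """
    try:
        verts, faces = _BUILTINS[name]()
    except KeyError:
        raise ValueError(
            f"unknown polyhedron {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    faces = orient_faces_outward(verts, faces)
    return PolyhedronGraph(vertices=verts, faces=faces, name=name)


# ---------------------------------------------------------------------------
# synthetic DMS reactivities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDMSParams:
    """Parameters of the synthetic DMS-MaPseq reactivity model.

    Reactivities are log-normal: unpaired A/C positions draw from
    ``exp(N(log_mu_unpaired, sigma))``, staple-paired positions are
    suppressed by ``protection_factor``.  Bases adjacent (+/-1) to a
    structural feature are multiplied by the feature's entry in
    ``feature_multipliers``.  Cytosines react at ``c_to_a_ratio`` times
    the adenine rate.  G/U positions are masked (DMS probes A/C only).
    """

    log_mu_unpaired: float = math.log(0.03)   # median unpaired rate 3%
    sigma: float = 0.45
    protection_factor: float = 5.0
    feature_multipliers: dict = field(default_factory=dict)
    c_to_a_ratio: float = 0.8
    scaffold_paired_fraction: float = 0.58    # native structure of bare scaffold
    coverage_mean: int = 20000
    max_rate: float = 0.25


# control region emulating a structured spike-in: fixed base pattern with
# 91 A/C positions among 140 nt, half paired
CONTROL_LENGTH = 140


def _control_template(rng: np.random.Generator) -> tuple[str, np.ndarray]:
    bases = rng.choice(list("ACGU"), size=CONTROL_LENGTH, p=[0.35, 0.30, 0.17, 0.18])
    ac = np.isin(bases, ["A", "C"])
    # ensure exactly 91 A/C positions for a stable normalization set
    idx = np.flatnonzero(ac)
    excess = len(idx) - 91
    if excess > 0:
        flip = idx[:excess]
        bases[flip] = "G"
    elif excess < 0:
        gu = np.flatnonzero(~ac)[: -excess]
        bases[gu] = "A"
    paired = rng.random(CONTROL_LENGTH) < 0.5
    return "".join(bases), paired


def simulate_reactivities(design, params: SyntheticDMSParams | None = None,
                          seed: int = 0):
    """Paired synthetic profiles for a design: (scaffold-only, origami, truth).

    Returns two :class:`rnaori.dms_stats.DMSProfile` objects sharing the
    scaffold coordinate system plus a spiked-in control region, and a
    ground-truth record of which positions were paired/elevated in each.
    """
    from rnaori.annotator import annotate_features
    from rnaori.dms_stats import DMSProfile

    params = params or SyntheticDMSParams()
    rng = np.random.default_rng(seed)
    ann = annotate_features(design)
    L = design.scaffold.length_nt
    residues = design.scaffold.residues

    ctrl_seq, ctrl_paired = _control_template(rng)
    full_bases = residues + ctrl_seq
    n_total = L + CONTROL_LENGTH
    control_positions = list(range(L + 1, n_total + 1))

    paired_origami = np.zeros(n_total, bool)
    paired_origami[: design.paired_nt] = True
    # bare scaffold: native structure pairs a random fraction
    paired_scaffold = np.zeros(n_total, bool)
    paired_scaffold[:L] = rng.random(L) < params.scaffold_paired_fraction
    # the control is folded identically in every sample
    paired_origami[L:] = ctrl_paired
    paired_scaffold[L:] = ctrl_paired

    # feature-adjacent multipliers apply in the origami sample only
    mult = np.ones(n_total)
    for feat in ann.features:
        m = params.feature_multipliers.get(feat.kind, 1.0)
        if m != 1.0:
            for pos in (feat.after_position, feat.after_position % design.paired_nt + 1):
                mult[pos - 1] *= m

    def draw(paired: np.ndarray, multipliers: np.ndarray | None) -> np.ndarray:
        base_rate = np.exp(rng.normal(params.log_mu_unpaired, params.sigma, n_total))
        is_c = np.frombuffer("".join(full_bases).encode(), dtype="S1") == b"C"
        base_rate[is_c] *= params.c_to_a_ratio
        rate = np.where(paired, base_rate / params.protection_factor, base_rate)
        if multipliers is not None:
            rate = rate * multipliers
        return np.clip(rate, 0.0, params.max_rate)

    rate_scaffold = draw(paired_scaffold, None)
    rate_origami = draw(paired_origami, mult)

    is_ac = np.isin(list(full_bases), ["A", "C"])
    rate_scaffold[~is_ac] = np.nan
    rate_origami[~is_ac] = np.nan
    coverage = rng.poisson(params.coverage_mean, n_total)

    def profile(rate, label):
        return DMSProfile(
            positions=np.arange(1, n_total + 1),
            bases=np.array(list(full_bases)),
            reactivity=rate,
            coverage=coverage.copy(),
            control_positions=control_positions,
            sample=label,
        )

    truth = {
        "paired_origami": paired_origami,
        "paired_scaffold": paired_scaffold,
        "multipliers": mult,
        "params": params,
    }
    return profile(rate_scaffold, "scaffold_only"), profile(rate_origami, "origami"), truth
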