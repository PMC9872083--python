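"""Per-nucleotide structural features and duplex segments of a design.

Every junction along the scaffold where the pairing context changes is a
structural feature, one of seven classes: scaffold double crossover
(``scaffold_dx2``), scaffold terminus (``scaffold_nick``), staple double
crossover (``staple_dx2``), staple single crossover / mesojunction
(``staple_dx1``), abutting staple termini on one duplex (``staple_nick``),
a staple terminus abutting another staple's single crossover
(``staple_single_term``), and polyhedron vertices (``vertex``).

A *duplex segment* is a maximal run of contiguous scaffold:staple base
pairs bordered by a feature at each end with none in the middle; segments
tile the staple-paired scaffold exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

FEATURE_KINDS = (
    "scaffold_dx2",
    "scaffold_nick",
    "staple_dx2",
    "staple_dx1",
    "staple_nick",
    "staple_single_term",
    "vertex",
)

# when one base flanks two features, the more specific label wins
_PRIORITY = {k: i for i, k in enumerate(FEATURE_KINDS)}


@dataclass(frozen=True)
class FeatureInstance:
    """A structural feature at the junction after scaffold position
    ``after_position`` (1-based; the junction lies between it and the
    next position 3' of it)."""

    kind: str
    after_position: int
    edge: int | None = None


@dataclass(frozen=True)
class NucleotideAnnotation:
    position: int          # 1-based scaffold index, 5'->3'
    base: str
    edge: int | None       # edge index; None for unpaired overhang
    duplex: int | None
    axial: int | None      # 1-based offset from the edge's lower vertex
    staple_id: str | None
    feature: str           # one of FEATURE_KINDS or "none"
    paired: bool


@dataclass(frozen=True)
class DuplexSegment:
    """Maximal contiguous scaffold:staple duplex run, feature-bordered."""

    start: int             # 1-based scaffold positions, inclusive
    end: int
    feature5: str          # feature at the 5' end
    feature3: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interior(self) -> range:
        """Scaffold positions excluding the single terminal base each end."""
        return range(self.start + 1, self.end)


@dataclass
class DesignAnnotation:
    nucleotides: list[NucleotideAnnotation]
    features: list[FeatureInstance]
    segments: list[DuplexSegment] = field(default_factory=list)


def annotate_features(design) -> DesignAnnotation:
    """Walk the scaffold cycle and mark every structural feature.

    Feature positions are junctions between adjacent scaffold bases; the
    per-base table labels the base immediately 3' of each junction
    (vertices label both flanking bases, matching the convention that a
    vertex sits between two edge termini).
    """
    routing = design.routing
    slots = routing.slots
    P = routing.length
    L = design.scaffold.length_nt
    residues = design.scaffold.residues
    graph = routing.graph
    edge_list = routing.edge_list

    features: list[FeatureInstance] = []
    for i in range(P):
        s_a, s_b = slots[i], slots[(i + 1) % P]
        pos = i + 1  # junction after this scaffold position
        if i == P - 1:
            features.append(FeatureInstance("scaffold_nick", pos))
            continue
        if s_a[0] != s_b[0]:
            features.append(FeatureInstance("vertex", pos, s_a[0]))
        elif s_a[1] != s_b[1]:
            features.append(FeatureInstance("scaffold_dx2", pos, s_a[0]))
        else:
            e, d = s_a[0], s_a[1]
            j = min(s_a[2], s_b[2])
            label = design.junction_labels.get((e, d, j))
            if label is not None:
                features.append(FeatureInstance(label, pos, e))

    # per-base labels
    base_label: dict[int, str] = {}

    def put(pos: int, kind: str) -> None:
        old = base_label.get(pos)
        if old is None or _PRIORITY[kind] < _PRIORITY[old]:
            base_label[pos] = kind

    for f in features:
        after = f.after_position
        nxt = after % P + 1
        put(nxt, f.kind)
        if f.kind == "vertex":
            put(after, f.kind)

    staple_of: dict[int, str] = {}
    pos_of = routing.slot_index()
    for st in design.staples:
        for e, d, lo, hi in st.domains:
            for ax in range(lo, hi + 1):
                staple_of[pos_of[(e, d, ax)] + 1] = st.id

    nucleotides = []
    for p in range(1, L + 1):
        if p <= P:
            e, d, ax = slots[p - 1]
            nucleotides.append(
                NucleotideAnnotation(
                    p, residues[p - 1], e, d, ax,
                    staple_of.get(p), base_label.get(p, "none"), True,
                )
            )
        else:
            nucleotides.append(
                NucleotideAnnotation(
                    p, residues[p - 1], None, None, None, None, "none", False
                )
            )
    return DesignAnnotation(nucleotides, features)


def identify_segments(annotation: DesignAnnotation) -> list[DuplexSegment]:
    """Split the paired scaffold at every feature junction.

    The scaffold nick closes the walk, so segments tile positions
    1..paired_length; each records the bordering feature at both ends.
    """
    feats = sorted(annotation.features, key=lambda f: f.after_position)
    if not feats:
        raise ValueError("no features; is the design annotated?")
    segments: list[DuplexSegment] = []
    prev_pos = 0
    prev_kind = feats[-1].kind  # feature preceding position 1, cyclically
    for f in feats:
        if f.after_position > prev_pos:
            segments.append(
                DuplexSegment(prev_pos + 1, f.after_position, prev_kind, f.kind)
            )
        prev_pos, prev_kind = f.after_position, f.kind
    annotation.segments = segments
    return segments


def write_feature_table(annotation: DesignAnnotation, features_csv, segments_csv) -> None:
    with open(features_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["position", "base", "edge", "duplex", "axial",
             "staple_id", "feature", "paired"]
        )
        for n in annotation.nucleotides:
            w.writerow(
                [n.position, n.base,
                 "" if n.edge is None else n.edge,
                 "" if n.duplex is None else n.duplex,
                 "" if n.axial is None else n.axial,
                 n.staple_id or "", n.feature, int(n.paired)]
            )
    with open(segments_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start", "end", "length_bp", "feature5", "feature3"])
        for s in annotation.segments:
            w.writerow([s.start, s.end, s.length, s.feature5, s.feature3])


def read_segments_csv(path) -> list[DuplexSegment]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                DuplexSegment(
                    int(row["start"]), int(row["end"]),
                    row["feature5"], row["feature3"],
                )
            )
    return out
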