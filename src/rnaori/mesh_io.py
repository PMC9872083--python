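"""Polyhedral target geometries: ASCII PLY I/O, validation, discretization.

A target shape is a closed, genus-0 polyhedral surface.  Vertices carry 3D
coordinates (arbitrary length units; only used for the coordinate model),
faces are oriented vertex cycles, and each edge is eventually assigned a
length in base pairs that is commensurate with the chosen duplex geometry:
multiples of 11 bp for A-form edges, rounded multiples of 10.5 bp for
B-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

MIN_TURNS_PER_EDGE = 4  # smallest fabricated edge: 4 helical turns (44 bp A-form)


class PlyParseError(ValueError):
    """Malformed PLY input; message names the offending line."""


class MeshValidationError(ValueError):
    """Geometry violates the closed-surface requirements."""


@dataclass(frozen=True)
class HelixParameters:
    """Duplex geometry for one helical form.

    ``bp_per_turn`` is 11 for the A-form variants and 10.5 for B-form.
    ``rise_nm_per_bp`` defaults to the theoretical A-form rise of
    0.267 nm/bp (canonical 0.260 also common); B-form uses 0.34 nm/bp.
    ``diameter_nm`` is the helix diameter (2.3 nm A-form, 2.0 nm B-form).
    """

    form: str  # one of {"A", "AltA", "SymA", "B"}
    bp_per_turn: float
    rise_nm_per_bp: float
    diameter_nm: float

    def __post_init__(self) -> None:
        if self.form not in {"A", "AltA", "SymA", "B"}:
            raise ValueError(f"unknown helix form {self.form!r}")
        if self.bp_per_turn not in (11, 10.5):
            raise ValueError("bp_per_turn must be 11 (A) or 10.5 (B)")
        if not 0.25 <= self.rise_nm_per_bp <= 0.35:
            raise ValueError("rise_nm_per_bp outside plausible range [0.25, 0.35]")

    @property
    def is_a_form(self) -> bool:
        return self.bp_per_turn == 11

    @property
    def twist_deg_per_bp(self) -> float:
        return 360.0 / self.bp_per_turn


#: Standard parameter sets.  A-form: 11 bp/turn, 0.267 nm/bp theoretical rise,
#: 2.3 nm diameter.  B-form: 10.5 bp/turn, 0.34 nm/bp, 2.0 nm.
A_FORM = HelixParameters("A", 11, 0.267, 2.3)
ALT_A_FORM = HelixParameters("AltA", 11, 0.267, 2.3)
SYM_A_FORM = HelixParameters("SymA", 11, 0.267, 2.3)
B_FORM = HelixParameters("B", 10.5, 0.34, 2.0)

HELIX_FORMS = {"A": A_FORM, "AltA": ALT_A_FORM, "SymA": SYM_A_FORM, "B": B_FORM}


@dataclass
class PolyhedronGraph:
    """Closed polyhedral mesh with optional per-edge lengths in bp.

    ``vertices`` maps vertex id -> xyz position; ``faces`` are vertex-id
    cycles oriented so the face normal points away from the centroid;
    ``edges`` is a sorted list of unordered vertex pairs; ``edge_length_bp``
    maps each edge pair to its discretized length (empty until
    :func:`discretize_edges` runs).
    """

    vertices: dict[int, np.ndarray]
    faces: list[tuple[int, ...]]
    edges: list[tuple[int, int]] = field(default_factory=list)
    edge_length_bp: dict[tuple[int, int], int] = field(default_factory=dict)
    name: str = "mesh"

    def __post_init__(self) -> None:
        if not self.edges:
            self.edges = _edges_from_faces(self.faces)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertex_degree(self) -> dict[int, int]:
        deg: dict[int, int] = {v: 0 for v in self.vertices}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def length_bp(self, u: int, v: int) -> int:
        return self.edge_length_bp[_norm_edge(u, v)]

    @property
    def total_length_bp(self) -> int:
        return sum(self.edge_length_bp[e] for e in self.edges)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        ids = set(self.vertices)
        for f in self.faces:
            if len(f) < 3:
                raise MeshValidationError(f"face {f} has fewer than 3 vertices")
            if not set(f) <= ids:
                raise MeshValidationError(f"face {f} references unknown vertices")

        # every undirected edge must border exactly two faces, once per direction
        directed: dict[tuple[int, int], int] = {}
        for f in self.faces:
            for a, b in zip(f, f[1:] + f[:1]):
                directed[(a, b)] = directed.get((a, b), 0) + 1
        for u, v in self.edges:
            n_uv = directed.get((u, v), 0)
            n_vu = directed.get((v, u), 0)
            if n_uv + n_vu != 2:
                raise MeshValidationError(
                    f"edge ({u},{v}) borders {n_uv + n_vu} faces; "
                    "a closed surface requires exactly 2"
                )
            if n_uv != 1 or n_vu != 1:
                raise MeshValidationError(
                    f"edge ({u},{v}) traversed twice in the same direction; "
                    "face winding is inconsistent"
                )

        euler = self.n_vertices - self.n_edges + self.n_faces
        if euler != 2:
            raise MeshValidationError(
                f"V-E+F = {euler}, expected 2 for a closed genus-0 surface"
            )
        if not _connected(self.vertices.keys(), self.edges):
            raise MeshValidationError("mesh graph is not connected")

        if self.edge_length_bp:
            missing = set(self.edges) - set(self.edge_length_bp)
            if missing:
                raise MeshValidationError(f"edges missing length_bp: {sorted(missing)}")
            for e, n in self.edge_length_bp.items():
                if n <= 0:
                    raise MeshValidationError(f"edge {e} has non-positive length {n}")


def _norm_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def _edges_from_faces(faces: list[tuple[int, ...]]) -> list[tuple[int, int]]:
    out = {
        _norm_edge(a, b) for f in faces for a, b in zip(f, f[1:] + f[:1])
    }
    return sorted(out)


def _connected(vertex_ids, edges) -> bool:
    ids = list(vertex_ids)
    if not ids:
        return False
    adj: dict[int, list[int]] = {v: [] for v in ids}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {ids[0]}
    stack = [ids[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(ids)


# ---------------------------------------------------------------------------
# face orientation
# ---------------------------------------------------------------------------

def orient_faces_outward(
    vertices: dict[int, np.ndarray], faces: list[tuple[int, ...]]
) -> list[tuple[int, ...]]:
    """Return faces rewound so each normal points away from the centroid.

    Input winding may be mixed; each polygon is flipped independently based
    on the sign of (face centroid - mesh centroid) . (face normal).  For
    convex polyhedra (the supported targets) this yields a consistent
    outward orientation.
    """
    centroid = np.mean(list(vertices.values()), axis=0)
    oriented = []
    for f in faces:
        pts = np.array([vertices[i] for i in f], dtype=float)
        fc = pts.mean(axis=0)
        # Newell's method: robust polygon normal
        normal = np.zeros(3)
        for i in range(len(pts)):
            a, b = pts[i], pts[(i + 1) % len(pts)]
            normal += np.cross(a, b)
        if np.dot(normal, fc - centroid) < 0:
            f = tuple(reversed(f))
        oriented.append(tuple(f))
    return oriented


# ---------------------------------------------------------------------------
# ASCII PLY I/O
# ---------------------------------------------------------------------------

def read_ply(path) -> PolyhedronGraph:
    """Parse an ASCII PLY file into a validated :class:`PolyhedronGraph`.

    Only the ASCII dialect is accepted (binary PLY raises
    :class:`PlyParseError`); vertex elements must provide x/y/z properties
    and face elements a vertex-index list.  Edge lengths are left
    unassigned; call :func:`discretize_edges` next.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    def err(i: int, msg: str) -> PlyParseError:
        return PlyParseError(f"{path}, line {i + 1}: {msg}")

    if not lines or lines[0].strip() != "ply":
        raise err(0, "missing 'ply' magic")

    counts: dict[str, int] = {}
    order: list[str] = []
    vertex_props: list[str] = []
    current = None
    i = 1
    fmt_seen = False
    while i < len(lines):
        tok = lines[i].split()
        if not tok or tok[0] == "comment":
            i += 1
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise err(i, f"unsupported PLY format {tok[1]!r}; only ascii")
            fmt_seen = True
        elif tok[0] == "element":
            if len(tok) != 3:
                raise err(i, "malformed element declaration")
            current = tok[1]
            try:
                counts[current] = int(tok[2])
            except ValueError:
                raise err(i, f"bad element count {tok[2]!r}") from None
            order.append(current)
        elif tok[0] == "property":
            if current == "vertex" and tok[1] != "list":
                vertex_props.append(tok[-1])
        elif tok[0] == "end_header":
            i += 1
            break
        else:
            raise err(i, f"unknown header keyword {tok[0]!r}")
        i += 1
    else:
        raise err(len(lines) - 1, "missing end_header")

    if not fmt_seen:
        raise err(1, "missing format declaration")
    if "vertex" not in counts or "face" not in counts:
        raise err(i - 1, "PLY must declare 'vertex' and 'face' elements")
    for ax in "xyz":
        if ax not in vertex_props:
            raise err(i - 1, f"vertex element lacks property {ax!r}")

    vertices: dict[int, np.ndarray] = {}
    faces: list[tuple[int, ...]] = []
    for elem in order:
        n = counts[elem]
        for k in range(n):
            if i >= len(lines):
                raise err(len(lines) - 1, f"unexpected EOF in element {elem!r}")
            tok = lines[i].split()
            if elem == "vertex":
                if len(tok) < len(vertex_props):
                    raise err(i, "too few vertex values")
                vals = dict(zip(vertex_props, tok))
                try:
                    vertices[k] = np.array(
                        [float(vals["x"]), float(vals["y"]), float(vals["z"])]
                    )
                except ValueError:
                    raise err(i, "non-numeric vertex coordinate") from None
            elif elem == "face":
                try:
                    cnt = int(tok[0])
                    idx = tuple(int(t) for t in tok[1 : 1 + cnt])
                except (ValueError, IndexError):
                    raise err(i, "malformed face row") from None
                if len(idx) != cnt:
                    raise err(i, f"face declares {cnt} indices, found {len(idx)}")
                faces.append(idx)
            i += 1

    faces = orient_faces_outward(vertices, faces)
    try:
        return PolyhedronGraph(vertices=vertices, faces=faces, name=str(path))
    except MeshValidationError:
        raise


def write_ply(graph: PolyhedronGraph, path) -> None:
    """Emit the mesh as ASCII PLY (round-trips through :func:`read_ply`)."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {graph.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {graph.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for vid in sorted(graph.vertices):
            x, y, z = graph.vertices[vid]
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        for f in graph.faces:
            fh.write(" ".join([str(len(f))] + [str(v) for v in f]) + "\n")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_edges(
    graph: PolyhedronGraph,
    turns_per_edge: int | float,
    helix_params: HelixParameters,
) -> PolyhedronGraph:
    """Assign every edge a base-pair length for ``turns_per_edge`` turns.

    A-form variants use exact multiples of 11 bp per turn; B-form rounds
    10.5 bp per turn to the nearest integer (6 turns -> 63 bp).  All edges
    of the supported equilateral targets receive the same length; the
    minimum fabricated edge is 4 turns (44 bp A-form).
    """
    if turns_per_edge < MIN_TURNS_PER_EDGE:
        raise ValueError(
            f"turns_per_edge={turns_per_edge} below the minimum of "
            f"{MIN_TURNS_PER_EDGE} turns (44 bp A-form edge)"
        )
    if helix_params.is_a_form:
        if turns_per_edge != int(turns_per_edge):
            raise ValueError("A-form edges require an integer number of turns")
        length = 11 * int(turns_per_edge)
    else:
        length = int(round(10.5 * turns_per_edge))
    lengths = {e: length for e in graph.edges}
    out = replace(graph, edge_length_bp=lengths)
    out.validate()
    return out


def scale_to_physical(graph: PolyhedronGraph, helix: HelixParameters) -> PolyhedronGraph:
    """Rescale vertex coordinates so mean edge length = mean(length_bp) x rise.

    Vertex coordinates never influence routing; they only set the scale of
    the predicted coordinate model.
    """
    if not graph.edge_length_bp:
        raise ValueError("discretize edges before scaling")
    geo = [
        float(np.linalg.norm(graph.vertices[u] - graph.vertices[v]))
        for u, v in graph.edges
    ]
    target = [graph.edge_length_bp[e] * helix.rise_nm_per_bp for e in graph.edges]
    factor = math.fsum(target) / math.fsum(geo)
    centroid = np.mean(list(graph.vertices.values()), axis=0)
    verts = {
        k: (v - centroid) * factor for k, v in graph.vertices.items()
    }
    return replace(graph, vertices=verts)
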