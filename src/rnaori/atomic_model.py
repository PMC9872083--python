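"""Coarse 3D coordinate model of a design: one pseudo-atom per base.

Each DX edge is modeled as two parallel duplex axes along the mesh edge,
separated by the helix diameter.  Bases advance along the axis by the
helical rise and around it by the helical twist (360/bp_per_turn deg per
bp); scaffold and staple backbones sit diametrically opposite on a fixed
backbone radius.  Per base the model stores a position (nm) and an
orthonormal base reference frame.  No mechanical relaxation is applied:
vertex splay, edge bowing and duplex twist observed experimentally are
not modeled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from rnaori.mesh_io import scale_to_physical

BACKBONE_RADIUS_NM = 0.8


@dataclass(frozen=True)
class ModelRow:
    strand: str            # "scaffold" or staple id
    index: int             # 1-based along the strand 5'->3'
    base: str
    position: np.ndarray   # nm
    frame: np.ndarray      # 3x3 orthonormal, rows = (e1, e2, e3)


@dataclass
class AtomicModel:
    rows: list[ModelRow]
    rise_nm: float
    bp_per_turn: float
    diameter_nm: float

    def __len__(self) -> int:
        return len(self.rows)

    def coordinates(self) -> np.ndarray:
        return np.array([r.position for r in self.rows])


def _edge_frames(graph, helix):
    """Per edge: unit axis, outward radial, side unit vector."""
    centroid = np.mean(list(graph.vertices.values()), axis=0)
    frames = {}
    for ei, (u, v) in enumerate(graph.edges):
        a, b = graph.vertices[u], graph.vertices[v]
        axis = b - a
        n = np.linalg.norm(axis)
        axis = axis / n
        mid = (a + b) / 2.0
        radial = mid - centroid
        radial -= axis * np.dot(radial, axis)
        nr = np.linalg.norm(radial)
        if nr < 1e-9:  # edge through the centroid; pick any perpendicular
            radial = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(radial) < 1e-9:
                radial = np.cross(axis, [0.0, 1.0, 0.0])
            nr = np.linalg.norm(radial)
        radial = radial / nr
        side = np.cross(axis, radial)
        frames[ei] = (a, b, axis, radial, side)
    return frames


def build_model(design) -> "AtomicModel":
    """Predict coordinates and frames for every scaffold and staple base."""
    graph = design.graph
    if not graph.vertices:
        raise ValueError("mesh geometry required to build a model")
    helix = design.helix
    graph = scale_to_physical(graph, helix)
    routing = design.routing
    frames = _edge_frames(graph, helix)
    rise = helix.rise_nm_per_bp
    omega = 2.0 * np.pi / helix.bp_per_turn
    half_sep = helix.diameter_nm / 2.0

    # twist phase reference per edge: scaffold backbones face each other at
    # the scaffold-exchange center; on tree edges staple backbones face at
    # the staple-crossover stations (half a turn offset from the scaffold)
    phase_ref = {}
    for ei in range(len(routing.edge_list)):
        lay = design.plan.layouts[ei]
        if lay.scaffold_j is not None:
            phase_ref[ei] = sum(lay.scaffold_j) / 2.0
        elif lay.stations:
            phase_ref[ei] = min(s.center for s in lay.stations) - helix.bp_per_turn / 4.0
        else:
            phase_ref[ei] = 0.0

    def base_geometry(slot, strand: str):
        ei, d, ax = slot
        a, b, axis, radial, side = frames[ei]
        n = design.routing.graph.edge_length_bp[routing.edge_list[ei]]
        axial_pt = a + axis * ((ax - 0.5) / n) * np.linalg.norm(b - a)
        sgn = -1.0 if d == 0 else 1.0
        duplex_center = axial_pt + sgn * half_sep * side
        toward = -sgn * side  # unit vector toward the partner duplex
        theta = omega * (ax - phase_ref[ei])
        e1 = toward * np.cos(theta) + radial * np.sin(theta)
        if strand != "scaffold":
            e1 = -e1  # staple backbone diametrically opposite
        pos = duplex_center + BACKBONE_RADIUS_NM * e1
        # strand direction: scaffold runs u->v on duplex 0
        e3 = axis if (d == 0) == (strand == "scaffold") else -axis
        e2 = np.cross(e3, e1)
        return pos, np.vstack([e1, e2, e3])

    rows: list[ModelRow] = []
    residues = design.scaffold.residues
    for i, slot in enumerate(routing.slots):
        pos, fr = base_geometry(slot, "scaffold")
        rows.append(ModelRow("scaffold", i + 1, residues[i], pos, fr))
    pos_of = routing.slot_index()
    for st in design.staples:
        k = 0
        for e, d, lo, hi in st.domains:
            rng = range(hi, lo - 1, -1) if d == 0 else range(lo, hi + 1)
            for ax in rng:
                k += 1
                slot = (e, d, ax)
                pos, fr = base_geometry(slot, "staple")
                rows.append(ModelRow(st.id, k, st.sequence[k - 1], pos, fr))
    return AtomicModel(rows, rise, helix.bp_per_turn, helix.diameter_nm)


def write_model(model: AtomicModel, path, format: str = "csv") -> None:
    """Write the model as CSV (full frames) or coarse PDB (P pseudo-atoms)."""
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["strand", "index", "base", "x", "y", "z"]
                + [f"{v}{i}" for v in ("e1", "e2", "e3") for i in "xyz"]
            )
            for r in model.rows:
                w.writerow(
                    [r.strand, r.index, r.base]
                    + [f"{c:.4f}" for c in r.position]
                    + [f"{c:.4f}" for c in r.frame.ravel()]
                )
    elif format == "pdb":
        import string

        chain_ids = string.ascii_uppercase + string.ascii_lowercase + string.digits
        with open(path, "w") as fh:
            serial = 0
            chains: dict[str, tuple[str, int]] = {}  # strand -> (chain, resseq base)
            for r in model.rows:
                serial += 1
                if serial > 99999:
                    break
                if r.strand not in chains:
                    k = len(chains)
                    # strands beyond the chain alphabet share a chain but get
                    # disjoint residue-number ranges
                    chains[r.strand] = (chain_ids[k % len(chain_ids)],
                                        (k // len(chain_ids)) * 200)
                ch, base_seq = chains[r.strand]
                x, y, z = r.position * 10.0  # nm -> Angstrom
                fh.write(
                    f"ATOM  {serial:5d}  P     {r.base} {ch}"
                    f"{(base_seq + r.index) % 10000:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P\n"
                )
            fh.write("END\n")
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model_csv(path) -> AtomicModel:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            pos = np.array([float(rec["x"]), float(rec["y"]), float(rec["z"])])
            fr = np.array(
                [
                    [float(rec[f"{v}{i}"]) for i in "xyz"]
                    for v in ("e1", "e2", "e3")
                ]
            )
            rows.append(ModelRow(rec["strand"], int(rec["index"]), rec["base"], pos, fr))
    return AtomicModel(rows, np.nan, np.nan, np.nan)
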