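"""Planar tessellation data model for apical epithelial surfaces.

A :class:`Tessellation` is an in-memory twin of a segmented apical surface:
polygonal cells, the junctional vertices where three or more cells (or the
tissue boundary) meet, and the bonds (cell-cell or cell-background walls)
connecting those vertices.  All coordinates are micrometres in a mathematical
y-up frame whose +x axis is the proximodistal (base-to-apex) tissue axis and
whose +y axis is the mediolateral (medial-to-lateral) axis, i.e. "top is
lateral, right is apex".

The module also owns the JSON mesh dialect (see ``docs/mesh_schema.md``),
construction of a tessellation from a collection of cell polygons, vertex
merging, and structural validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

#: label used for the exterior region in bond flanks and raster images
BACKGROUND = 0

CELL_TYPES = frozenset(
    {
        "IHC",
        "OHC1",
        "OHC2",
        "OHC3",
        "IPhC",
        "pillar",
        "Deiters",
        "border",
        "mKO",
        "lKO",
        "Hensen",
        "Claudius",
        "other",
    }
)

DOMAINS = frozenset(
    {
        "KO_medial",
        "KO_lateral",
        "sensory_medial",
        "sensory_lateral",
        "nonsensory_lateral",
    }
)

#: hair-cell types (inner plus the three outer rows)
HC_TYPES = frozenset({"IHC", "OHC1", "OHC2", "OHC3"})


class MeshSchemaError(ValueError):
    """Raised when a mesh file violates the JSON dialect."""


class TessellationError(ValueError):
    """Raised for structural errors while building or editing a tessellation."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class AxisFrame:
    """Tissue axis frame: orthonormal PD/ML axes and the pixel size in um/px."""

    pd_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    ml_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pd_axis = np.asarray(self.pd_axis, dtype=float)
        self.ml_axis = np.asarray(self.ml_axis, dtype=float)


@dataclass
class CellRecord:
    cell_id: int
    polygon: np.ndarray  # (n, 2) float, CCW, um
    centroid: np.ndarray  # (2,) float, um
    cell_type: str = "other"
    domain: str | None = None
    kinocilium: np.ndarray | None = None
    channel_intensity: dict[str, float] = field(default_factory=dict)
    touches_boundary: bool = False

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.polygon))

    @property
    def perimeter(self) -> float:
        p = np.vstack([self.polygon, self.polygon[:1]])
        return float(np.sum(np.hypot(*(np.diff(p, axis=0).T))))


@dataclass
class VertexRecord:
    vertex_id: int
    position: np.ndarray  # (2,) um
    incident_cells: set[int]  # cell ids, background excluded
    interior: bool  # True when no background incidence

    @property
    def order(self) -> int:
        """Number of incident regions; the background counts as one region."""
        return len(self.incident_cells) + (0 if self.interior else 1)


@dataclass
class BondRecord:
    bond_id: int
    endpoints: tuple[int, int]  # vertex ids
    flanking_cells: tuple[int, int]  # cell ids; BACKGROUND for the exterior
    polyline: np.ndarray  # (n, 2) um, from endpoints[0] to endpoints[1]
    intensity: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*(np.diff(self.polyline, axis=0).T))))

    @property
    def is_interior(self) -> bool:
        return BACKGROUND not in self.flanking_cells


@dataclass
class Tessellation:
    cells: dict[int, CellRecord] = field(default_factory=dict)
    vertices: dict[int, VertexRecord] = field(default_factory=dict)
    bonds: dict[int, BondRecord] = field(default_factory=dict)
    frame: AxisFrame = field(default_factory=AxisFrame)
    provenance: str = ""

    # -- convenience ------------------------------------------------------
    def cells_of_type(self, cell_types: str | Iterable[str]) -> list[CellRecord]:
        if isinstance(cell_types, str):
            cell_types = {cell_types}
        else:
            cell_types = set(cell_types)
        return [c for c in self.cells.values() if c.cell_type in cell_types]

    def cells_of_domain(self, domains: str | Iterable[str]) -> list[CellRecord]:
        if isinstance(domains, str):
            domains = {domains}
        else:
            domains = set(domains)
        return [c for c in self.cells.values() if c.domain in domains]

    def interior_cells(self) -> list[CellRecord]:
        return [c for c in self.cells.values() if not c.touches_boundary]

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.vstack([c.polygon for c in self.cells.values()])
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )


def shoelace_area(polygon: np.ndarray) -> float:
    """Signed polygon area (positive for counter-clockwise orientation)."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def adjacency_graph(tess: Tessellation) -> nx.Graph:
    """Cell adjacency graph: cells are nodes, an edge per shared bond."""
    g = nx.Graph()
    g.add_nodes_from(tess.cells)
    for b in tess.bonds.values():
        a, c = b.flanking_cells
        if a != BACKGROUND and c != BACKGROUND and a != c:
            g.add_edge(a, c)
    return g


# ---------------------------------------------------------------------------
# construction from polygons
# ---------------------------------------------------------------------------

_SNAP_DECIMALS = 6


def _snap(pt: Sequence[float]) -> tuple[float, float]:
    return (round(float(pt[0]), _SNAP_DECIMALS), round(float(pt[1]), _SNAP_DECIMALS))


def _explode_segments(geom) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    lines = []
    if geom.geom_type == "LineString":
        lines = [geom]
    elif geom.geom_type == "MultiLineString":
        lines = list(geom.geoms)
    elif geom.geom_type == "GeometryCollection":
        lines = [g for g in geom.geoms if g.geom_type == "LineString"]
    segs = []
    for ln in lines:
        coords = [_snap(c) for c in ln.coords]
        for a, b in zip(coords[:-1], coords[1:]):
            if a != b:
                segs.append((a, b))
    return segs


def tessellation_from_polygons(
    polygons: Mapping[int, np.ndarray],
    frame: AxisFrame | None = None,
    merge_tol: float = 0.0,
    provenance: str = "",
) -> Tessellation:
    """Build a full tessellation (vertices, bonds, cells) from cell outlines.

    The polygon boundaries are noded against each other, every elementary
    wall segment is attributed to its two flanking regions by probing points
    just off its midpoint, and maximal constant-flank chains between junction
    points become bonds.  Cell polygons are then re-derived from the bond
    network so that cells, bonds and vertices stay mutually consistent.

    Parameters
    ----------
    polygons
        Map of positive cell id to an (n, 2) array of outline points (um).
    merge_tol
        Vertices closer than this are merged after construction (um).
    """
    if frame is None:
        frame = AxisFrame()
    shp: dict[int, Polygon] = {}
    for cid, poly in polygons.items():
        if cid <= 0:
            raise TessellationError(f"cell id must be positive, got {cid}")
        p = Polygon(np.round(np.asarray(poly, dtype=float), _SNAP_DECIMALS))
        if not p.is_valid or p.area <= 0:
            p = p.buffer(0)
        shp[int(cid)] = p

    linework = unary_union([p.exterior for p in shp.values()])
    segments = _explode_segments(linework)

    ids = list(shp.keys())
    tree = shapely.STRtree([shp[i] for i in ids])

    def locate(x: float, y: float) -> int:
        pt = Point(x, y)
        for idx in tree.query(pt):
            if shp[ids[idx]].covers(pt):
                return ids[idx]
        return BACKGROUND

    # flank attribution per elementary segment
    seg_flanks: list[tuple[int, int]] = []
    kept_segments = []
    for a, b in segments:
        mx, my = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
        dx, dy = b[0] - a[0], b[1] - a[1]
        norm = math.hypot(dx, dy)
        eps = min(1e-3, 0.25 * norm)
        nxv, nyv = -dy / norm * eps, dx / norm * eps
        left = locate(mx + nxv, my + nyv)
        right = locate(mx - nxv, my - nyv)
        if left == right:
            continue  # spurious interior linework
        kept_segments.append((a, b))
        seg_flanks.append((left, right))

    return _assemble(kept_segments, seg_flanks, frame, merge_tol, provenance)


def _assemble(
    segments: list[tuple[tuple[float, float], tuple[float, float]]],
    seg_flanks: list[tuple[int, int]],
    frame: AxisFrame,
    merge_tol: float,
    provenance: str,
) -> Tessellation:
    """Chain attributed wall segments into vertices/bonds and derive cells."""
    node_edges: dict[tuple[float, float], list[int]] = {}
    for i, (a, b) in enumerate(segments):
        node_edges.setdefault(a, []).append(i)
        node_edges.setdefault(b, []).append(i)

    def pairset(i: int) -> frozenset:
        return frozenset(seg_flanks[i])

    junction: set[tuple[float, float]] = set()
    for node, incid in node_edges.items():
        if len(incid) != 2 or pairset(incid[0]) != pairset(incid[1]):
            junction.add(node)

    used = [False] * len(segments)

    def other_end(i: int, node):
        a, b = segments[i]
        return b if a == node else a

    def walk(start_seg: int, start_node):
        """Follow pass-through nodes from start_node until a junction."""
        pts = [start_node]
        seg = start_seg
        node = start_node
        while True:
            used[seg] = True
            node = other_end(seg, node)
            pts.append(node)
            if node in junction:
                return pts, seg
            nxt = [j for j in node_edges[node] if not used[j]]
            if not nxt:
                return pts, seg  # closed back to start
            seg = nxt[0]

    bond_chains: list[tuple[list, tuple[int, int]]] = []
    for node in sorted(junction):
        for i in sorted(node_edges[node]):
            if used[i]:
                continue
            pts, _ = walk(i, node)
            bond_chains.append((pts, seg_flanks[i]))
    # closed loops with no junction on them (e.g. an isolated enclosed cell)
    for i in range(len(segments)):
        if not used[i]:
            pts, _ = walk(i, segments[i][0])
            bond_chains.append((pts, seg_flanks[i]))

    # vertices at chain endpoints
    vert_id_of: dict[tuple[float, float], int] = {}
    vertices: dict[int, VertexRecord] = {}

    def get_vertex(node) -> int:
        if node not in vert_id_of:
            vid = len(vert_id_of) + 1
            vert_id_of[node] = vid
            vertices[vid] = VertexRecord(
                vertex_id=vid,
                position=np.array(node, dtype=float),
                incident_cells=set(),
                interior=True,
            )
        return vert_id_of[node]

    bonds: dict[int, BondRecord] = {}
    for bid, (pts, flanks) in enumerate(bond_chains, start=1):
        v0 = get_vertex(pts[0])
        v1 = get_vertex(pts[-1])
        bonds[bid] = BondRecord(
            bond_id=bid,
            endpoints=(v0, v1),
            flanking_cells=(int(flanks[0]), int(flanks[1])),
            polyline=np.array(pts, dtype=float),
        )
        for v in (v0, v1):
            for f in flanks:
                if f == BACKGROUND:
                    vertices[v].interior = False
                else:
                    vertices[v].incident_cells.add(int(f))

    tess = Tessellation(
        cells={}, vertices=vertices, bonds=bonds, frame=frame, provenance=provenance
    )
    if merge_tol > 0:
        merge_close_vertices(tess, merge_tol)
    rebuild_cell_polygons(tess)
    return tess


def merge_close_vertices(tess: Tessellation, tol: float) -> Tessellation:
    """Merge vertices closer than ``tol`` (single-linkage), in place.

    Bonds collapsing onto a single merged vertex are removed; incident-cell
    sets are unioned.  Cell polygons are *not* rebuilt here — callers that
    already have cells must call :func:`rebuild_cell_polygons` afterwards.
    """
    if not tess.vertices or tol <= 0:
        return tess
    vids = sorted(tess.vertices)
    pos = np.array([tess.vertices[v].position for v in vids])
    pairs = cKDTree(pos).query_pairs(tol)
    if not pairs:
        return tess
    parent = {v: v for v in vids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, j in pairs:
        a, b = find(vids[i]), find(vids[j])
        if a != b:
            parent[max(a, b)] = min(a, b)

    clusters: dict[int, list[int]] = {}
    for v in vids:
        clusters.setdefault(find(v), []).append(v)

    for root, members in clusters.items():
        if len(members) == 1:
            continue
        keep = tess.vertices[root]
        keep.position = np.mean(
            [tess.vertices[m].position for m in members], axis=0
        )
        for m in members:
            if m == root:
                continue
            keep.incident_cells |= tess.vertices[m].incident_cells
            if not tess.vertices[m].interior:
                keep.interior = False
            del tess.vertices[m]

    remap = {v: find(v) for v in vids}
    drop = []
    for bid, bond in tess.bonds.items():
        e0, e1 = remap[bond.endpoints[0]], remap[bond.endpoints[1]]
        if e0 == e1 and bond.endpoints[0] != bond.endpoints[1]:
            drop.append(bid)  # bond collapsed by the merge
            continue
        poly = bond.polyline.copy()
        poly[0] = tess.vertices[e0].position
        poly[-1] = tess.vertices[e1].position
        bond.endpoints = (e0, e1)
        bond.polyline = poly
    for bid in drop:
        del tess.bonds[bid]
    return tess


def rebuild_cell_polygons(tess: Tessellation) -> Tessellation:
    """Re-derive every cell polygon/centroid from the bond network, in place.

    Any cell labels/annotations already present are preserved.
    """
    cell_bonds: dict[int, list[int]] = {}
    for bid, bond in tess.bonds.items():
        for f in bond.flanking_cells:
            if f != BACKGROUND:
                cell_bonds.setdefault(f, []).append(bid)

    new_cells: dict[int, CellRecord] = {}
    for cid, bids in sorted(cell_bonds.items()):
        ring = _chain_cell_boundary(tess, cid, bids)
        if shoelace_area(ring) < 0:
            ring = ring[::-1]
        poly = Polygon(ring)
        centroid = np.array(poly.centroid.coords[0])
        touches = any(
            BACKGROUND in tess.bonds[b].flanking_cells for b in bids
        )
        old = tess.cells.get(cid)
        rec = CellRecord(
            cell_id=cid,
            polygon=ring,
            centroid=centroid,
            touches_boundary=touches,
        )
        if old is not None:
            rec.cell_type = old.cell_type
            rec.domain = old.domain
            rec.kinocilium = old.kinocilium
            rec.channel_intensity = old.channel_intensity
        new_cells[cid] = rec
    tess.cells = new_cells
    return tess


def _chain_cell_boundary(tess: Tessellation, cid: int, bids: list[int]) -> np.ndarray:
    """Order a cell's bonds into a closed outline (open ring, no repeat)."""
    if len(bids) == 1:
        poly = tess.bonds[bids[0]].polyline
        return _dedup_ring(poly[:-1])
    at_vertex: dict[int, list[int]] = {}
    for b in bids:
        for v in tess.bonds[b].endpoints:
            at_vertex.setdefault(v, []).append(b)
    start_bond = min(bids)
    start_v = tess.bonds[start_bond].endpoints[0]
    chain_pts: list[np.ndarray] = []
    bond = start_bond
    cur = start_v
    used = {start_bond}
    while True:
        rec = tess.bonds[bond]
        poly = rec.polyline
        if rec.endpoints[0] == cur:
            nxt = rec.endpoints[1]
        else:
            poly = poly[::-1]
            nxt = rec.endpoints[0]
        chain_pts.append(poly[:-1])
        cur = nxt
        if cur == start_v:
            break
        candidates = [b for b in at_vertex.get(cur, []) if b not in used]
        if not candidates:
            raise TessellationError(
                f"cell {cid}: boundary bonds do not close into a ring"
            )
        bond = candidates[0]
        used.add(bond)
    if len(used) != len(bids):
        raise TessellationError(f"cell {cid}: disconnected boundary bonds")
    return _dedup_ring(np.vstack(chain_pts))


def _dedup_ring(pts: np.ndarray) -> np.ndarray:
    keep = [0]
    for i in range(1, len(pts)):
        if not np.allclose(pts[i], pts[keep[-1]], atol=1e-9):
            keep.append(i)
    out = pts[keep]
    if len(out) > 1 and np.allclose(out[0], out[-1], atol=1e-9):
        out = out[:-1]
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    entity: str
    invariant: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.entity}: {self.invariant} — {self.message}"


def validate(tess: Tessellation) -> list[Violation]:
    """Check every structural invariant; return one report per violation."""
    out: list[Violation] = []
    f = tess.frame
    if abs(np.dot(f.pd_axis, f.ml_axis)) > 1e-9:
        out.append(Violation("frame", "axes orthogonal", "pd_axis not ⊥ ml_axis"))
    for name, ax in (("pd_axis", f.pd_axis), ("ml_axis", f.ml_axis)):
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            out.append(Violation("frame", "unit axes", f"{name} not unit norm"))
    if f.pixel_size <= 0:
        out.append(Violation("frame", "pixel_size > 0", f"got {f.pixel_size}"))

    adjacency = {
        frozenset(b.flanking_cells)
        for b in tess.bonds.values()
        if b.is_interior
    }
    for cid, cell in tess.cells.items():
        ent = f"cell {cid}"
        if cid <= 0:
            out.append(Violation(ent, "positive id", f"id {cid}"))
        poly = Polygon(cell.polygon)
        if not poly.is_simple or not poly.is_valid:
            out.append(Violation(ent, "simple polygon", "self-intersecting outline"))
            continue
        if shoelace_area(cell.polygon) <= 0:
            out.append(
                Violation(ent, "signed area > 0", "polygon is clockwise or degenerate")
            )
        hull = poly.convex_hull
        if not hull.buffer(1e-6).covers(Point(cell.centroid)):
            out.append(Violation(ent, "centroid inside hull", "centroid outside"))
        if cell.kinocilium is not None:
            r_eq = math.sqrt(max(poly.area, 0.0) / math.pi)
            minx, miny, maxx, maxy = poly.bounds
            kx, ky = cell.kinocilium
            if not (
                minx - r_eq <= kx <= maxx + r_eq and miny - r_eq <= ky <= maxy + r_eq
            ):
                out.append(
                    Violation(
                        ent,
                        "kinocilium near cell",
                        "kinocilium outside inflated bounding box",
                    )
                )
        for ch, v in cell.channel_intensity.items():
            if v < 0:
                out.append(Violation(ent, "intensity >= 0", f"channel {ch} = {v}"))

    for vid, vert in tess.vertices.items():
        ent = f"vertex {vid}"
        if vert.order < 2:
            out.append(Violation(ent, "order >= 2", f"order {vert.order}"))
        if vert.interior and vert.order < 3:
            out.append(
                Violation(ent, "interior order >= 3", f"interior with order {vert.order}")
            )
        for cid in vert.incident_cells:
            if cid not in tess.cells:
                out.append(Violation(ent, "references resolve", f"unknown cell {cid}"))

    for bid, bond in tess.bonds.items():
        ent = f"bond {bid}"
        for v in bond.endpoints:
            if v not in tess.vertices:
                out.append(Violation(ent, "references resolve", f"unknown vertex {v}"))
        for c in bond.flanking_cells:
            if c != BACKGROUND and c not in tess.cells:
                out.append(Violation(ent, "references resolve", f"unknown cell {c}"))
        if len(bond.polyline) < 2:
            out.append(Violation(ent, "polyline length", "fewer than 2 points"))
        if bond.is_interior and frozenset(bond.flanking_cells) not in adjacency:
            # cannot happen by construction; kept for hand-built meshes
            out.append(Violation(ent, "flanks adjacent", "flanking cells not adjacent"))

    if tess.cells:
        total = sum(c.area for c in tess.cells.values())
        x0, y0, x1, y1 = tess.bounds()
        if total > (x1 - x0) * (y1 - y0) * (1 + 1e-9):
            out.append(
                Violation(
                    "tessellation",
                    "area <= bounding box",
                    f"cell area {total:.3f} exceeds bbox",
                )
            )
    return out


# ---------------------------------------------------------------------------
# JSON mesh dialect
# ---------------------------------------------------------------------------

_TOP_KEYS = ("frame", "cells", "vertices", "bonds", "provenance")


def save_mesh(tess: Tessellation, path) -> None:
    """Write a tessellation to the JSON mesh dialect (coordinates in um)."""
    doc = {
        "frame": {
            "pd_axis": tess.frame.pd_axis.tolist(),
            "ml_axis": tess.frame.ml_axis.tolist(),
            "pixel_size": tess.frame.pixel_size,
        },
        "cells": [
            {
                "cell_id": c.cell_id,
                "polygon": np.asarray(c.polygon, dtype=float).tolist(),
                "centroid": np.asarray(c.centroid, dtype=float).tolist(),
                "cell_type": c.cell_type,
                "domain": c.domain,
                "kinocilium": None
                if c.kinocilium is None
                else np.asarray(c.kinocilium, dtype=float).tolist(),
                "channel_intensity": {k: float(v) for k, v in c.channel_intensity.items()},
                "touches_boundary": bool(c.touches_boundary),
            }
            for _, c in sorted(tess.cells.items())
        ],
        "vertices": [
            {
                "vertex_id": v.vertex_id,
                "position": np.asarray(v.position, dtype=float).tolist(),
                "incident_cells": sorted(int(i) for i in v.incident_cells),
                "interior": bool(v.interior),
            }
            for _, v in sorted(tess.vertices.items())
        ],
        "bonds": [
            {
                "bond_id": b.bond_id,
                "endpoints": [int(b.endpoints[0]), int(b.endpoints[1])],
                "flanking_cells": [int(b.flanking_cells[0]), int(b.flanking_cells[1])],
                "polyline": np.asarray(b.polyline, dtype=float).tolist(),
                "intensity": {k: float(v) for k, v in b.intensity.items()},
            }
            for _, b in sorted(tess.bonds.items())
        ],
        "provenance": tess.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_mesh(path) -> Tessellation:
    """Read the JSON mesh dialect; raises :class:`MeshSchemaError` on defects."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in _TOP_KEYS:
        if key not in doc:
            raise MeshSchemaError(f"missing top-level field {key!r}")
    fr = doc["frame"]
    for key in ("pd_axis", "ml_axis", "pixel_size"):
        if key not in fr:
            raise MeshSchemaError(f"missing frame field {key!r}")
    frame = AxisFrame(
        pd_axis=np.array(fr["pd_axis"], dtype=float),
        ml_axis=np.array(fr["ml_axis"], dtype=float),
        pixel_size=float(fr["pixel_size"]),
    )
    cells: dict[int, CellRecord] = {}
    for c in doc["cells"]:
        for key in ("cell_id", "polygon", "centroid"):
            if key not in c:
                raise MeshSchemaError(f"missing cell field {key!r}")
        cells[int(c["cell_id"])] = CellRecord(
            cell_id=int(c["cell_id"]),
            polygon=np.array(c["polygon"], dtype=float),
            centroid=np.array(c["centroid"], dtype=float),
            cell_type=c.get("cell_type", "other"),
            domain=c.get("domain"),
            kinocilium=None
            if c.get("kinocilium") is None
            else np.array(c["kinocilium"], dtype=float),
            channel_intensity=dict(c.get("channel_intensity", {})),
            touches_boundary=bool(c.get("touches_boundary", False)),
        )
    vertices: dict[int, VertexRecord] = {}
    for v in doc["vertices"]:
        for key in ("vertex_id", "position", "incident_cells", "interior"):
            if key not in v:
                raise MeshSchemaError(f"missing vertex field {key!r}")
        vertices[int(v["vertex_id"])] = VertexRecord(
            vertex_id=int(v["vertex_id"]),
            position=np.array(v["position"], dtype=float),
            incident_cells=set(int(i) for i in v["incident_cells"]),
            interior=bool(v["interior"]),
        )
    bonds: dict[int, BondRecord] = {}
    for b in doc["bonds"]:
        for key in ("bond_id", "endpoints", "flanking_cells", "polyline"):
            if key not in b:
                raise MeshSchemaError(f"missing bond field {key!r}")
        bonds[int(b["bond_id"])] = BondRecord(
            bond_id=int(b["bond_id"]),
            endpoints=(int(b["endpoints"][0]), int(b["endpoints"][1])),
            flanking_cells=(int(b["flanking_cells"][0]), int(b["flanking_cells"][1])),
            polyline=np.array(b["polyline"], dtype=float),
            intensity=dict(b.get("intensity", {})),
        )
    tess = Tessellation(
        cells=cells,
        vertices=vertices,
        bonds=bonds,
        frame=frame,
        provenance=doc["provenance"],
    )
    # dangling references are schema errors, not validation reports
    for vid, v in vertices.items():
        for cid in v.incident_cells:
            if cid not in cells:
                raise MeshSchemaError(f"vertex {vid} references absent cell {cid}")
    for bid, b in bonds.items():
        for v in b.endpoints:
            if v not in vertices:
                raise MeshSchemaError(f"bond {bid} references absent vertex {v}")
        for c in b.flanking_cells:
            if c != BACKGROUND and c not in cells:
                raise MeshSchemaError(f"bond {bid} references absent cell {c}")
    return tess


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------


def apply_annotations(tess: Tessellation, table) -> Tessellation:
    """Attach cell types/domains from a table with cell_id, cell_type, domain."""
    import pandas as pd

    df = pd.DataFrame(table)
    for _, row in df.iterrows():
        cid = int(row["cell_id"])
        if cid not in tess.cells:
            raise TessellationError(f"annotation references absent cell {cid}")
        ct = str(row["cell_type"])
        if ct not in CELL_TYPES:
            raise TessellationError(f"unknown cell type {ct!r} for cell {cid}")
        dom = row.get("domain")
        if dom is not None and not (isinstance(dom, float) and math.isnan(dom)):
            dom = str(dom)
            if dom not in DOMAINS:
                raise TessellationError(f"unknown domain {dom!r} for cell {cid}")
            tess.cells[cid].domain = dom
        tess.cells[cid].cell_type = ct
    return tess


def apply_kinocilia(tess: Tessellation, table) -> Tessellation:
    """Attach kinocilium coordinates from a table with cell_id, x_um, y_um."""
    import pandas as pd

    df = pd.DataFrame(table)
    for _, row in df.iterrows():
        cid = int(row["cell_id"])
        if cid not in tess.cells:
            raise TessellationError(f"kinocilium references absent cell {cid}")
        tess.cells[cid].kinocilium = np.array(
            [float(row["x_um"]), float(row["y_um"])]
        )
    return tess
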