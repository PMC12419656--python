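"""Label-image ingestion and rasterization.

Conventions: pixels are indexed 0-based, a pixel's coordinate is its centre,
and cell outlines are traced along pixel *corners* (the half-integer lattice),
so a raster-derived polygon's shoelace area equals pixel_count x pixel_size^2
exactly.  Image rasters are y-down; they are flipped on ingest so that the
in-memory frame is y-up with +y pointing lateral ("top is lateral").
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .tessellation import (
    BACKGROUND,
    AxisFrame,
    BondRecord,
    Tessellation,
    TessellationError,
    VertexRecord,
    merge_close_vertices,
    rebuild_cell_polygons,
)


def polygonize_labels(
    label_image: np.ndarray,
    pixel_size: float,
    merge_tol: float | None = None,
) -> Tessellation:
    """Convert an integer label image into a :class:`Tessellation`.

    Junction points where three or more regions (background included) meet on
    the pixel-corner lattice become vertices; vertices closer than
    ``merge_tol`` (default 2.5 x pixel_size) are merged, which re-unifies
    vertices of order four and above that the pixel grid splits into nearby
    three-fold junctions (observed splits extend to two pixels diagonal).
    ``merge_tol`` is the single most result-sensitive ingest parameter and is
    recorded in the tessellation provenance.

    Raises
    ------
    TessellationError
        For non-integer rasters or labels split into several 4-connected
        components (the offending label id is named).
    """
    labels = np.asarray(label_image)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TessellationError(
            f"label image must be an integer raster, got dtype {labels.dtype}"
        )
    if labels.ndim != 2:
        raise TessellationError("label image must be a single 2-D plane")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if merge_tol is None:
        merge_tol = 2.5 * pixel_size
    if merge_tol < 0:
        raise ValueError("merge_tol must be >= 0")
    labels = labels.astype(np.int64)
    if labels.min() < 0:
        raise TessellationError("labels must be non-negative integers")

    _check_connected(labels)

    H, W = labels.shape
    A = np.pad(labels, 1)  # (H+2, W+2)

    # corner (r, c), r in 0..H, c in 0..W, touches padded pixels
    # A[r, c], A[r, c+1], A[r+1, c], A[r+1, c+1]
    v00 = A[0 : H + 1, 0 : W + 1]
    v01 = A[0 : H + 1, 1 : W + 2]
    v10 = A[1 : H + 2, 0 : W + 1]
    v11 = A[1 : H + 2, 1 : W + 2]

    n_distinct = (
        1
        + (v01 != v00).astype(np.int8)
        + ((v10 != v00) & (v10 != v01)).astype(np.int8)
        + ((v11 != v00) & (v11 != v01) & (v11 != v10)).astype(np.int8)
    )
    diagonal_pinch = (v00 == v11) & (v01 == v10) & (v00 != v01)
    junction_mask = (n_distinct >= 3) | diagonal_pinch

    # boundary edges on the corner lattice
    # horizontal edge (r, c)-(r, c+1): above = A[r, c+1], below = A[r+1, c+1]
    ha = A[0 : H + 1, 1 : W + 1]
    hb = A[1 : H + 2, 1 : W + 1]
    hmask = ha != hb  # shape (H+1, W)
    # vertical edge (r, c)-(r+1, c): left = A[r+1, c], right = A[r+1, c+1]
    va = A[1 : H + 1, 0 : W + 1]
    vb = A[1 : H + 1, 1 : W + 2]
    vmask = va != vb  # shape (H, W+1)

    segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    seg_flanks: list[tuple[int, int]] = []
    hr, hc = np.nonzero(hmask)
    for r, c in zip(hr.tolist(), hc.tolist()):
        segments.append(((r, c), (r, c + 1)))
        seg_flanks.append((int(ha[r, c]), int(hb[r, c])))
    vr, vc = np.nonzero(vmask)
    for r, c in zip(vr.tolist(), vc.tolist()):
        segments.append(((r, c), (r + 1, c)))
        seg_flanks.append((int(va[r, c]), int(vb[r, c])))

    jr, jc = np.nonzero(junction_mask)
    junctions = set(zip(jr.tolist(), jc.tolist()))

    tess = _assemble_grid(
        segments, seg_flanks, junctions, H, pixel_size, merge_tol
    )
    tess.provenance = (
        f"polygonize_labels(pixel_size={pixel_size}, merge_tol={merge_tol})"
    )
    return tess


def _check_connected(labels: np.ndarray) -> None:
    from skimage.measure import label as cc_label

    comp = cc_label(labels, connectivity=1, background=0)
    fg = labels > 0
    if not fg.any():
        return
    pairs = np.unique(np.stack([labels[fg], comp[fg]]), axis=1)
    lab_ids, counts = np.unique(pairs[0], return_counts=True)
    bad = lab_ids[counts > 1]
    if bad.size:
        raise TessellationError(
            f"label {int(bad[0])} forms multiple connected components"
        )


def _assemble_grid(segments, seg_flanks, junctions, H, pixel_size, merge_tol):
    """Chain grid wall segments between junction corners into bonds."""
    node_edges: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(segments):
        node_edges.setdefault(a, []).append(i)
        node_edges.setdefault(b, []).append(i)

    used = [False] * len(segments)

    def to_um(node) -> tuple[float, float]:
        r, c = node
        return (c * pixel_size, (H - r) * pixel_size)

    def walk(start_seg, start_node):
        pts = [start_node]
        seg, node = start_seg, start_node
        while True:
            used[seg] = True
            a, b = segments[seg]
            node = b if a == node else a
            pts.append(node)
            if node in junctions:
                return pts
            nxt = [j for j in node_edges[node] if not used[j]]
            if not nxt:
                return pts
            seg = nxt[0]

    chains: list[tuple[list, tuple[int, int]]] = []
    for node in sorted(junctions):
        for i in sorted(node_edges.get(node, [])):
            if not used[i]:
                chains.append((walk(i, node), seg_flanks[i]))
    for i in range(len(segments)):  # junction-free loops (isolated cells)
        if not used[i]:
            chains.append((walk(i, segments[i][0]), seg_flanks[i]))

    vert_of: dict[tuple[int, int], int] = {}
    vertices: dict[int, VertexRecord] = {}

    def vertex_at(node) -> int:
        if node not in vert_of:
            vid = len(vert_of) + 1
            vert_of[node] = vid
            vertices[vid] = VertexRecord(
                vertex_id=vid,
                position=np.array(to_um(node)),
                incident_cells=set(),
                interior=True,
            )
        return vert_of[node]

    bonds: dict[int, BondRecord] = {}
    for bid, (pts, flanks) in enumerate(chains, start=1):
        v0, v1 = vertex_at(pts[0]), vertex_at(pts[-1])
        bonds[bid] = BondRecord(
            bond_id=bid,
            endpoints=(v0, v1),
            flanking_cells=(int(flanks[0]), int(flanks[1])),
            polyline=np.array([to_um(p) for p in pts]),
        )
        for v in (v0, v1):
            for f in flanks:
                if f == BACKGROUND:
                    vertices[v].interior = False
                else:
                    vertices[v].incident_cells.add(int(f))

    tess = Tessellation(
        cells={},
        vertices=vertices,
        bonds=bonds,
        frame=AxisFrame(pixel_size=pixel_size),
    )
    if merge_tol > 0:
        merge_close_vertices(tess, merge_tol)
    rebuild_cell_polygons(tess)
    return tess


def rasterize(tess: Tessellation, pixel_size: float) -> np.ndarray:
    """Paint each pixel with the id of the cell containing its centre.

    The raster covers the tessellation's bounding box; row 0 is the lateral
    (top) edge, matching image convention.  Pixels whose centre falls exactly
    on a wall are assigned to the lowest-id covering cell.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if not tess.cells:
        return np.zeros((0, 0), dtype=np.uint32)
    x0, y0, x1, y1 = tess.bounds()
    W = max(1, int(np.ceil((x1 - x0) / pixel_size - 1e-9)))
    H = max(1, int(np.ceil((y1 - y0) / pixel_size - 1e-9)))
    out = np.zeros((H, W), dtype=np.uint32)

    polys = {cid: Polygon(c.polygon) for cid, c in tess.cells.items()}
    for cid in sorted(polys):
        poly = polys[cid]
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor((minx - x0) / pixel_size - 0.5)))
        c1 = min(W - 1, int(np.ceil((maxx - x0) / pixel_size - 0.5)))
        r1 = min(H - 1, int(np.ceil((y1 - miny) / pixel_size - 0.5)))
        r0 = max(0, int(np.floor((y1 - maxy) / pixel_size - 0.5)))
        if c1 < c0 or r1 < r0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        xs = x0 + (cols + 0.5) * pixel_size
        ys = y1 - (rows + 0.5) * pixel_size
        gx, gy = np.meshgrid(xs, ys)
        mask = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        window = out[r0 : r1 + 1, c0 : c1 + 1]
        window[mask & (window == 0)] = cid

    _fill_boundary_pixels(out, polys, x0, y1, pixel_size)
    _repair_connectivity(out, tess)
    return out


def _repair_connectivity(out: np.ndarray, tess: Tessellation) -> None:
    """Reassign sub-pixel orphan fragments (thin wedges at rosettes whose
    neck is narrower than a pixel) to a neighbouring cell, choosing the
    neighbour that creates no pixel contact absent from the mesh adjacency."""
    from skimage.measure import label as cc_label

    from .tessellation import adjacency_graph

    mesh_adj = {frozenset(e) for e in adjacency_graph(tess).edges}
    H, W = out.shape
    for _ in range(4):
        comp = cc_label(out, connectivity=1, background=0)
        fg = out > 0
        pairs = np.stack([out[fg], comp[fg]])
        uniq, counts = np.unique(pairs, axis=1, return_counts=True)
        changed = False
        for lab in np.unique(uniq[0]):
            sel = uniq[0] == lab
            if sel.sum() <= 1:
                continue
            comps = uniq[1][sel]
            sizes = counts[sel]
            main = comps[np.argmax(sizes)]
            for orphan in comps[comps != main]:
                rr, cc = np.nonzero(comp == orphan)
                for r, c in zip(rr.tolist(), cc.tolist()):
                    nbs = {
                        int(out[rq, cq])
                        for rq, cq in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                        if 0 <= rq < H and 0 <= cq < W and out[rq, cq] > 0
                    }
                    nbs.discard(int(lab))
                    if not nbs:
                        out[r, c] = 0
                        changed = True
                        continue
                    best, best_cost = None, None
                    for cand in sorted(nbs):
                        cost = sum(
                            1
                            for other in nbs
                            if other != cand
                            and frozenset((cand, other)) not in mesh_adj
                        )
                        if best_cost is None or cost < best_cost:
                            best, best_cost = cand, cost
                    out[r, c] = best
                    changed = True
        if not changed:
            break


def _fill_boundary_pixels(out, polys, x0, y1, pixel_size):
    """Assign pixels whose centre sits exactly on a wall (rare ties)."""
    H, W = out.shape
    empty = out == 0
    if not empty.any():
        return
    # only consider empty pixels with a labeled 4-neighbour
    nb = np.zeros_like(empty)
    nb[1:, :] |= out[:-1, :] > 0
    nb[:-1, :] |= out[1:, :] > 0
    nb[:, 1:] |= out[:, :-1] > 0
    nb[:, :-1] |= out[:, 1:] > 0
    cand = empty & nb
    rr, cc = np.nonzero(cand)
    if rr.size == 0:
        return
    ids = sorted(polys)
    tree = shapely.STRtree([polys[i] for i in ids])
    for r, c in zip(rr.tolist(), cc.tolist()):
        pt = Point(x0 + (c + 0.5) * pixel_size, y1 - (r + 0.5) * pixel_size)
        hits = [ids[i] for i in tree.query(pt) if polys[ids[i]].covers(pt)]
        if not hits:
            continue
        # keep the filled pixel 4-connected to an existing region of its label
        neighbors = {
            int(out[rq, cq])
            for rq, cq in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= rq < H and 0 <= cq < W and out[rq, cq] > 0
        }
        adjacent_hits = [h for h in hits if h in neighbors]
        out[r, c] = min(adjacent_hits) if adjacent_hits else min(hits)


def read_label_tiff(path) -> np.ndarray:
    """Read a single-plane unsigned-integer label TIFF."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise TessellationError("label TIFF must be a single plane")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TessellationError("label TIFF must be integer typed")
    return arr


def write_label_tiff(path, labels: np.ndarray) -> None:
    import tifffile

    arr = np.asarray(labels)
    if arr.max(initial=0) < 2**16:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.uint32)
    tifffile.imwrite(path, arr)
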