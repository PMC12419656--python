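"""Synthetic organ-of-Corti tessellation strips with known ground truth.

Generates planar strips of polygonal cells ordered medial-to-lateral into the
compartments of the embryonic cochlear duct (Kölliker's organ, the medial and
lateral sensory domains, and the lateral non-sensory domain), with
controllable per-domain apical area, anisotropy, preferred elongation axis,
higher-order-vertex fraction, kinocilium offset statistics, inner-hair-cell
row waviness, and step-like adhesion-molecule intensity channels.

Mechanism: per-domain anisotropically stretched seed lattices, a
guard-point-bounded Voronoi partition relaxed by two Lloyd steps in the
contracted metric, inverse stretch back to tissue coordinates, then targeted
collapse of the shortest interior bonds to create vertices where four or more
cells meet (rosettes).  Every statistic the measurement modules report is a
generator parameter, so the whole pipeline is testable without image data.

One root seed feeds fixed per-stage substreams, so adding a downstream stage
never perturbs an earlier one.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .tessellation import (
    BACKGROUND,
    HC_TYPES,
    AxisFrame,
    BondRecord,
    Tessellation,
    TessellationError,
    rebuild_cell_polygons,
    tessellation_from_polygons,
)
from .topology import _vertex_in_region

# fixed substream labels (stage -> integer), so streams are independent
_STREAMS = {"seeds": 1, "inject": 2, "kinocilia": 3, "channels": 4}

#: fraction of the seed-lattice spacing used as 1-sigma positional jitter,
#: per unit of area_cv; calibrated once against the E15.5 aspect-ratio target
_JITTER_PER_CV = 0.8

#: shortest bond the generator will leave in a finished mesh (um); walls
#: shorter than ~5 px at the working raster resolutions are unresolvable
_MIN_BOND_UM = 0.8


@dataclass
class DomainSpec:
    """One mediolateral compartment of the strip."""

    domain: str
    n_rows: int
    target_area: float  # um^2, mean apical area
    area_cv: float = 0.2  # drives seed jitter, hence area spread
    anisotropy: float = 1.0  # major/minor stretch of the generating metric
    elongation_axis: float = 0.0  # degrees vs +x (PD), in [0, 180)
    high_order_fraction: float = 0.0  # target fraction of vertices, order >= 4
    cell_type_pattern: tuple[tuple[str, ...], ...] = ()  # row motifs

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.target_area <= 0:
            raise ValueError("target_area must be > 0")
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")
        if not 0 <= self.elongation_axis < 180:
            raise ValueError("elongation_axis must be in [0, 180)")
        if not 0 <= self.high_order_fraction < 0.8:
            raise ValueError("high_order_fraction must be in [0, 0.8)")


@dataclass
class PolaritySpec:
    mean_angle: float = 90.0  # degrees CCW from +PD; 90 = lateral
    kappa: float = 2.0  # von Mises concentration, >= 0
    offset_fraction: float = 0.4  # kinocilium radius / cell radius, in [0, 1]

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 <= self.offset_fraction <= 1:
            raise ValueError("offset_fraction must be in [0, 1]")


@dataclass
class ChannelSpec:
    """A step-like mediolateral intensity channel (adhesion-molecule proxy)."""

    name: str
    medial_level: float
    lateral_level: float
    step_position: float  # fraction of the mediolateral span, in [0, 1]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.step_position <= 1:
            raise ValueError("step_position must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class StripConfig:
    length_um: float
    domain_specs: tuple[DomainSpec, ...]  # ordered medial -> lateral
    polarity: PolaritySpec = field(default_factory=PolaritySpec)
    ihc_row_wave: tuple[float, float] = (0.0, 40.0)  # (amplitude um, wavelength um)
    channels: tuple[ChannelSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.domain_specs:
            raise ValueError("domain_specs must be non-empty")
        amp, wl = self.ihc_row_wave
        if amp > 0 and wl <= 0:
            raise ValueError("wave wavelength must be > 0 when amplitude > 0")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_SENSORY_MEDIAL_PATTERN = (("IHC", "IPhC"), ("pillar",))
_SENSORY_LATERAL_PATTERN = (
    ("OHC1", "Deiters"),
    ("OHC2", "Deiters"),
    ("OHC3", "Deiters"),
)


def preset(name: str) -> StripConfig:
    """Named strip configurations calibrated to the study's printed values.

    ``E15.5-base``: symmetric Kölliker's-organ cells (mean aspect ratio
    ~0.87), high-order vertex fractions 0.33 (sensory), 0.40 (mKO), 0.21
    (lKO).  ``E18.5-base``: sensory fraction 0.20, mKO 0.40, lKO 0.13, with
    mKO cells smaller and elongated along the tissue (PD) axis and lKO cells
    elongated orthogonally (mediolateral, 90 degrees).  ``looptail-like``:
    the E18.5 stage with the mKO/lKO area and axis contrasts collapsed.
    """
    if name == "E15.5-base":
        return StripConfig(
            length_um=320.0,
            domain_specs=(
                DomainSpec("KO_medial", 6, 40.0, 0.25, 1.0, 0.0, 0.40, (("mKO",),)),
                DomainSpec("KO_lateral", 6, 45.0, 0.25, 1.0, 0.0, 0.21, (("lKO",),)),
                DomainSpec(
                    "sensory_medial", 2, 30.0, 0.12, 1.0, 0.0, 0.33,
                    _SENSORY_MEDIAL_PATTERN,
                ),
                DomainSpec(
                    "sensory_lateral", 3, 28.0, 0.12, 1.0, 0.0, 0.33,
                    _SENSORY_LATERAL_PATTERN,
                ),
                DomainSpec(
                    "nonsensory_lateral", 4, 35.0, 0.25, 1.0, 0.0, 0.05,
                    (("Hensen",), ("Hensen",), ("Claudius",), ("Claudius",)),
                ),
            ),
            polarity=PolaritySpec(mean_angle=90.0, kappa=2.0, offset_fraction=0.4),
            ihc_row_wave=(1.0, 40.0),
            channels=(
                ChannelSpec("Cdh1", 1.0, 0.25, 0.62, 0.05),
                ChannelSpec("Cdh2", 0.2, 1.0, 0.62, 0.05),
                ChannelSpec("Cdh4", 0.15, 1.0, 0.80, 0.05),
            ),
            seed=0,
        )
    if name == "E18.5-base":
        return StripConfig(
            length_um=320.0,
            domain_specs=(
                DomainSpec("KO_medial", 7, 28.0, 0.20, 1.5, 0.0, 0.40, (("mKO",),)),
                DomainSpec("KO_lateral", 4, 55.0, 0.20, 1.8, 90.0, 0.13, (("lKO",),)),
                DomainSpec(
                    "sensory_medial", 2, 30.0, 0.12, 1.0, 0.0, 0.20,
                    _SENSORY_MEDIAL_PATTERN,
                ),
                DomainSpec(
                    "sensory_lateral", 3, 28.0, 0.12, 1.0, 0.0, 0.20,
                    _SENSORY_LATERAL_PATTERN,
                ),
                DomainSpec(
                    "nonsensory_lateral", 4, 50.0, 0.25, 1.0, 0.0, 0.05,
                    (("Hensen",), ("Hensen",), ("Claudius",), ("Claudius",)),
                ),
            ),
            polarity=PolaritySpec(mean_angle=90.0, kappa=8.0, offset_fraction=0.5),
            ihc_row_wave=(0.5, 40.0),
            channels=(
                ChannelSpec("Cdh1", 1.0, 0.25, 0.62, 0.05),
                ChannelSpec("Cdh2", 0.2, 1.0, 0.62, 0.05),
                ChannelSpec("Cdh4", 0.15, 1.0, 0.80, 0.05),
            ),
            seed=0,
        )
    if name == "looptail-like":
        base = preset("E18.5-base")
        specs = list(base.domain_specs)
        specs[0] = replace(
            specs[0], target_area=40.0, anisotropy=1.0, elongation_axis=0.0, n_rows=5
        )
        specs[1] = replace(
            specs[1], target_area=40.0, anisotropy=1.0, elongation_axis=0.0, n_rows=5
        )
        return replace(base, domain_specs=tuple(specs))
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = ("E15.5-base", "E18.5-base", "looptail-like")


# ---------------------------------------------------------------------------
# bounded anisotropic Voronoi with Lloyd relaxation
# ---------------------------------------------------------------------------


def _metric_matrix(anisotropy: float, axis_deg: float) -> np.ndarray:
    """real = M @ relaxed: unit isotropic cells map to cells stretched by
    sqrt(a) along the elongation axis and contracted by sqrt(a) across it."""
    s = math.sqrt(anisotropy)
    psi = math.radians(axis_deg)
    rot = np.array(
        [[math.cos(psi), -math.sin(psi)], [math.sin(psi), math.cos(psi)]]
    )
    return rot @ np.diag([s, 1.0 / s]) @ rot.T


def _order_ring(pts: np.ndarray) -> np.ndarray:
    ctr = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - ctr[1], pts[:, 0] - ctr[0])
    return pts[np.argsort(ang)]


def _bounded_voronoi_cells(
    points: np.ndarray, boundary: Polygon
) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to a convex boundary polygon.

    Boundedness is enforced by mirroring all points across every boundary
    edge, which also makes the clipped cells meet the boundary cleanly.
    """
    coords = np.asarray(boundary.exterior.coords)
    guards = []
    for i in range(len(coords) - 1):
        p0, p1 = coords[i], coords[i + 1]
        d = p1 - p0
        d = d / np.linalg.norm(d)
        n = np.array([-d[1], d[0]])
        offs = (points - p0) @ n
        guards.append(points - 2.0 * offs[:, None] * n[None, :])
    allpts = np.vstack([points] + guards)
    vor = Voronoi(allpts)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            raise TessellationError("unbounded Voronoi region despite guards")
        poly = Polygon(_order_ring(vor.vertices[region]))
        if not poly.within(boundary.buffer(1e-9)):
            poly = poly.intersection(boundary)
        cells.append(poly)
    return cells


def _lloyd(points: np.ndarray, boundary: Polygon, n_iter: int = 2) -> np.ndarray:
    pts = points.copy()
    for _ in range(n_iter):
        cells = _bounded_voronoi_cells(pts, boundary)
        pts = np.array([c.centroid.coords[0] for c in cells])
    return pts


# ---------------------------------------------------------------------------
# strip generation
# ---------------------------------------------------------------------------


def _row_type(spec: DomainSpec, row: int, col: int) -> str:
    if not spec.cell_type_pattern:
        return "other"
    motif = spec.cell_type_pattern[row % len(spec.cell_type_pattern)]
    return motif[col % len(motif)]


def generate_strip(config: StripConfig) -> Tessellation:
    """Generate a labelled tessellation strip; deterministic for fixed seed."""
    rng = np.random.default_rng([config.seed, _STREAMS["seeds"]])
    L = config.length_um

    polygons: dict[int, np.ndarray] = {}
    labels: dict[int, tuple[str, str]] = {}  # cell_id -> (type, domain)
    next_id = 1
    y_cursor = 0.0
    for spec in config.domain_specs:
        M = _metric_matrix(spec.anisotropy, spec.elongation_axis)
        s = math.sqrt(spec.target_area)
        # hexagonal packing ratios: row pitch sqrt(3)/2 x column pitch,
        # so relaxed cells approach regular hexagons
        hex_w = s * math.sqrt(2.0 / math.sqrt(3.0))
        hex_h = s * math.sqrt(math.sqrt(3.0) / 2.0)
        w = hex_w * float(np.linalg.norm(M @ np.array([1.0, 0.0])))
        h = hex_h * float(np.linalg.norm(M @ np.array([0.0, 1.0])))
        n_cols = int(round(L / w))
        if n_cols < 2 or spec.n_rows * h > 10 * L:
            raise TessellationError(
                f"infeasible geometry for domain {spec.domain}: "
                f"target areas exceed the strip footprint"
            )
        dx = L / n_cols
        band_h = spec.n_rows * h
        y0, y1 = y_cursor, y_cursor + band_h
        y_cursor = y1

        jitter = _JITTER_PER_CV * spec.area_cv
        seeds = []
        meta = []
        for row in range(spec.n_rows):
            stagger = 0.5 * dx if row % 2 else 0.0
            for col in range(n_cols):
                x = (col + 0.5) * dx + stagger
                y = y0 + (row + 0.5) * h
                x += rng.normal(0.0, jitter * dx)
                y += rng.normal(0.0, jitter * h)
                x = min(max(x, 0.05 * dx), L - 0.05 * dx)
                y = min(max(y, y0 + 0.05 * h), y1 - 0.05 * h)
                seeds.append((x, y))
                meta.append((row, col))
        seeds = np.array(seeds)

        # relax in the contracted metric, then stretch back
        band = Polygon([(0, y0), (L, y0), (L, y1), (0, y1)])
        Minv = np.linalg.inv(M)
        origin = np.array([0.0, y0])
        band_relax = Polygon((np.asarray(band.exterior.coords) - origin) @ Minv.T)
        seeds_relax = (seeds - origin) @ Minv.T
        seeds_relax = _lloyd(seeds_relax, band_relax, n_iter=2)
        cells_relax = _bounded_voronoi_cells(seeds_relax, band_relax)
        for (row, col), cell in zip(meta, cells_relax):
            ring = np.asarray(cell.exterior.coords)[:-1] @ M.T + origin
            polygons[next_id] = ring
            labels[next_id] = (_row_type(spec, row, col), spec.domain)
            next_id += 1

    tess = tessellation_from_polygons(
        polygons,
        frame=AxisFrame(pixel_size=1.0),
        merge_tol=0.25,
        provenance=f"generate_strip(seed={config.seed})",
    )
    for cid, (ctype, domain) in labels.items():
        if cid in tess.cells:
            tess.cells[cid].cell_type = ctype
            tess.cells[cid].domain = domain

    amp, wl = config.ihc_row_wave
    if amp > 0:
        _apply_wave(tess, amp, wl)

    # sliver bonds (mostly at band joins) are below raster resolution and
    # would break rasterize/polygonize adjacency round trips; collapse them
    # into rosette vertices up front (they count toward injection targets)
    _collapse_short_bonds(tess, min_len=1.25 * _MIN_BOND_UM)

    # contiguous domains sharing a target fraction are injected jointly, so
    # the measured fraction of their union matches the target
    groups: list[tuple[float, list[str]]] = []
    for spec in config.domain_specs:
        if groups and groups[-1][0] == spec.high_order_fraction:
            groups[-1][1].append(spec.domain)
        else:
            groups.append((spec.high_order_fraction, [spec.domain]))
    # rosette formation is interleaved with rounding relaxation: real tissue
    # relaxes junctional geometry around rosettes, and without it the
    # collapsed cells accumulate unrealistic elongation
    n_chunks = 4
    for chunk in range(1, n_chunks + 1):
        for p_high, domains in groups:
            if p_high > 0:
                inject_high_order_vertices(
                    tess,
                    p_high * chunk / n_chunks,
                    seed=config.seed,
                    region=domains,
                )
        _relax_rounding(tess, n_iter=2)
    _relax_rounding(tess, n_iter=4)
    # rosette formation can shorten bonds at merged vertices; sweep residual
    # slivers so every wall stays resolvable on rasters
    _collapse_short_bonds(tess, min_len=_MIN_BOND_UM)
    rebuild_cell_polygons(tess)

    place_kinocilia(tess, config.polarity, HC_TYPES, seed=config.seed)
    assign_channels(tess, config.channels, seed=config.seed)
    tess.provenance = (
        f"generate_strip(seed={config.seed}, length={L}, "
        f"domains={[d.domain for d in config.domain_specs]})"
    )
    return tess


def _apply_wave(tess: Tessellation, amplitude: float, wavelength: float) -> None:
    """Smooth area-preserving shear y -> y + A sin(2 pi x / lambda).

    Applied to the whole strip so walls, centroids and domain boundaries all
    follow the wave coherently, as the curved cochlear duct does.
    """

    def f(pts: np.ndarray) -> np.ndarray:
        out = np.array(pts, dtype=float)
        out[:, 1] += amplitude * np.sin(2 * np.pi * out[:, 0] / wavelength)
        return out

    for v in tess.vertices.values():
        v.position = f(v.position[None, :])[0]
    for b in tess.bonds.values():
        b.polyline = f(b.polyline)
    rebuild_cell_polygons(tess)


# ---------------------------------------------------------------------------
# high-order vertex injection
# ---------------------------------------------------------------------------


def inject_high_order_vertices(
    tess: Tessellation,
    p: float,
    seed: int = 0,
    region: str | Iterable[str] | None = None,
    tol: float = 0.01,
) -> Tessellation:
    """Collapse shortest interior bonds until the fraction of interior
    vertices with order >= 4 reaches ``p`` (within ``tol``), in place.

    ``region`` restricts both the collapsed bonds and the fraction accounting
    to the named domain(s), using the same majority-incidence vertex
    assignment as :func:`cortimorph.topology.vertex_fraction`, so a measured
    round trip recovers ``p``.  Bond selection is shortest-first but avoids
    reducing any cell below four sides (the length key carries a penalty for
    few-sided flanking cells).  Raises when ``p`` cannot be reached without
    degenerating cells, reporting the achieved fraction.
    """
    if not 0 <= p < 0.8:
        raise ValueError("p must be in [0, 0.8)")
    if p == 0:
        return tess
    domains = None
    if region is not None:
        domains = {region} if isinstance(region, str) else set(region)

    def assigned(v) -> bool:
        if not v.interior:
            return False
        if domains is None:
            return True
        return _vertex_in_region(v, tess, domains)

    def strict(v) -> bool:
        if not v.interior:
            return False
        if domains is None:
            return True
        return all(tess.cells[c].domain in domains for c in v.incident_cells)

    def fraction() -> tuple[float, int, int]:
        sel = [v for v in tess.vertices.values() if assigned(v)]
        high = sum(1 for v in sel if v.order >= 4)
        return (high / len(sel) if sel else 0.0), high, len(sel)

    cell_sides: dict[int, int] = {}
    vbonds: dict[int, set[int]] = {vid: set() for vid in tess.vertices}
    for bid, b in tess.bonds.items():
        for c in b.flanking_cells:
            if c != BACKGROUND:
                cell_sides[c] = cell_sides.get(c, 0) + 1
        for v in b.endpoints:
            vbonds[v].add(bid)

    mean_len = float(
        np.mean([b.length for b in tess.bonds.values() if b.is_interior])
    )

    def key(b: BondRecord) -> float:
        # penalise collapsing bonds whose flanking cells are already few-sided
        sa, sb = (cell_sides[c] for c in b.flanking_cells)
        return b.length + 0.8 * mean_len * max(0, 12 - (sa + sb))

    heap: list[tuple[float, int]] = [
        (key(b), bid) for bid, b in tess.bonds.items() if b.is_interior
    ]
    heapq.heapify(heap)

    frac, high, total = fraction()
    while frac < p - 0.5 * tol:
        bid = None
        while heap:
            k, cand = heapq.heappop(heap)
            b = tess.bonds.get(cand)
            if b is None or not b.is_interior:
                continue
            k_now = key(b)
            if k_now > k + 1e-9:  # stale key: re-queue lazily
                heapq.heappush(heap, (k_now, cand))
                continue
            if b.endpoints[0] == b.endpoints[1]:
                continue
            v0, v1 = (tess.vertices[e] for e in b.endpoints)
            if not (strict(v0) and strict(v1)):
                continue
            if any(cell_sides[c] <= 4 for c in b.flanking_cells):
                continue
            # a parallel bond between the same vertices would become a loop
            if any(
                oid != cand
                and set(tess.bonds[oid].endpoints) == set(b.endpoints)
                for oid in vbonds[b.endpoints[0]]
            ):
                continue
            bid = cand
            break
        if bid is None:
            raise TessellationError(
                f"high-order fraction {p:.3f} unreachable without degenerate "
                f"cells; achieved {frac:.3f} ({high}/{total})"
            )
        _collapse_bond(tess, bid, cell_sides, vbonds)
        frac, high, total = fraction()

    rebuild_cell_polygons(tess)
    return tess


def _collapse_bond(tess, bid, cell_sides, vbonds) -> None:
    """Merge a bond's endpoints at its midpoint, removing the bond."""
    bond = tess.bonds[bid]
    keep_id, drop_id = sorted(bond.endpoints)
    keep, dropv = tess.vertices[keep_id], tess.vertices[drop_id]
    mid = 0.5 * (keep.position + dropv.position)
    keep.position = mid
    keep.incident_cells |= dropv.incident_cells
    keep.interior = keep.interior and dropv.interior
    del tess.vertices[drop_id]
    for c in bond.flanking_cells:
        if c != BACKGROUND:
            cell_sides[c] -= 1
    del tess.bonds[bid]
    vbonds[keep_id].discard(bid)
    vbonds[drop_id].discard(bid)
    affected = vbonds.pop(drop_id)
    for obid in list(affected) + list(vbonds[keep_id]):
        other = tess.bonds.get(obid)
        if other is None:
            continue
        e0, e1 = other.endpoints
        if e0 == drop_id:
            e0 = keep_id
        if e1 == drop_id:
            e1 = keep_id
        if e0 == e1:  # parallel bond collapsed into a self-loop: remove
            for c in other.flanking_cells:
                if c != BACKGROUND:
                    cell_sides[c] -= 1
            del tess.bonds[obid]
            vbonds[keep_id].discard(obid)
            continue
        other.endpoints = (e0, e1)
        poly = other.polyline.copy()
        poly[0] = tess.vertices[e0].position
        poly[-1] = tess.vertices[e1].position
        other.polyline = poly
        vbonds[keep_id].add(obid)


def _collapse_short_bonds(tess: Tessellation, min_len: float) -> None:
    """Collapse every interior bond shorter than ``min_len`` (um), in place."""
    cell_sides: dict[int, int] = {}
    vbonds: dict[int, set[int]] = {vid: set() for vid in tess.vertices}
    for bid, b in tess.bonds.items():
        for c in b.flanking_cells:
            if c != BACKGROUND:
                cell_sides[c] = cell_sides.get(c, 0) + 1
        for v in b.endpoints:
            vbonds[v].add(bid)
    changed = True
    while changed:
        changed = False
        for bid in sorted(tess.bonds):
            b = tess.bonds[bid]
            if not b.is_interior or b.length >= min_len:
                continue
            if b.endpoints[0] == b.endpoints[1]:
                continue
            if any(cell_sides[c] <= 4 for c in b.flanking_cells):
                continue
            if any(
                oid != bid and set(tess.bonds[oid].endpoints) == set(b.endpoints)
                for oid in vbonds[b.endpoints[0]]
            ):
                continue
            _collapse_bond(tess, bid, cell_sides, vbonds)
            changed = True
    rebuild_cell_polygons(tess)


def _relax_rounding(tess: Tessellation, n_iter: int, eta: float = 0.4) -> None:
    """Push interior vertices toward the equal-area regular-polygon radius of
    each incident cell, rounding cells without changing topology.

    Steps are clamped to a fraction of the shortest incident bond so walls
    can never be pushed across each other, and a move is rejected when it
    would shrink an incident bond below ``_MIN_BOND_UM`` (bonds that short
    are unresolvable on rasters at the pipeline's working pixel sizes).
    """
    for _ in range(n_iter):
        cen: dict[int, np.ndarray] = {}
        tgt: dict[int, float] = {}
        for cid, c in tess.cells.items():
            k = max(len(c.polygon), 3)
            cen[cid] = c.centroid
            tgt[cid] = math.sqrt(2.0 * c.area / (k * math.sin(2 * math.pi / k)))
        min_len: dict[int, float] = {}
        incident: dict[int, list[int]] = {vid: [] for vid in tess.vertices}
        for bid, b in tess.bonds.items():
            L = b.length
            for v in b.endpoints:
                min_len[v] = min(min_len.get(v, math.inf), L)
                incident[v].append(bid)
        new_pos: dict[int, np.ndarray] = {}
        for vid, v in tess.vertices.items():
            if not v.interior or not v.incident_cells:
                continue
            force = np.zeros(2)
            for cid in v.incident_cells:
                d = v.position - cen[cid]
                dist = math.hypot(*d)
                if dist < 1e-9:
                    continue
                force += (tgt[cid] - dist) * d / dist
            step = eta * force / len(v.incident_cells)
            cap = 0.3 * min_len.get(vid, 1.0)
            norm = math.hypot(*step)
            if norm > cap:
                step *= cap / norm
            # reject moves that would squeeze an incident bond under the floor
            cand = v.position + step
            for _try in range(3):
                ok = True
                for bid in incident[vid]:
                    e0, e1 = tess.bonds[bid].endpoints
                    other = tess.vertices[e1 if e0 == vid else e0].position
                    new = math.hypot(*(cand - other))
                    if new < _MIN_BOND_UM and new < math.hypot(
                        *(v.position - other)
                    ):
                        ok = False
                        break
                if ok:
                    break
                step = 0.5 * step
                cand = v.position + step
            else:
                continue
            new_pos[vid] = cand
        for vid, pos in new_pos.items():
            tess.vertices[vid].position = pos
        for b in tess.bonds.values():
            poly = b.polyline.copy()
            poly[0] = tess.vertices[b.endpoints[0]].position
            poly[-1] = tess.vertices[b.endpoints[1]].position
            b.polyline = poly
        rebuild_cell_polygons(tess)


# ---------------------------------------------------------------------------
# kinocilia and channels
# ---------------------------------------------------------------------------


def place_kinocilia(
    tess: Tessellation,
    spec: PolaritySpec,
    cell_types: Iterable[str] = HC_TYPES,
    seed: int = 0,
) -> Tessellation:
    """Place a kinocilium in every cell of the named types, at radius
    offset_fraction x sqrt(A/pi) and a von Mises angle about mean_angle."""
    rng = np.random.default_rng([seed, _STREAMS["kinocilia"]])
    types = set(cell_types)
    mu = math.radians(spec.mean_angle)
    frame = tess.frame
    for cid in sorted(tess.cells):
        cell = tess.cells[cid]
        if cell.cell_type not in types:
            continue
        if spec.kappa >= 1e6:
            theta = mu
        else:
            theta = float(rng.vonmises(mu, spec.kappa))
        radius = math.sqrt(cell.area / math.pi)
        offset = spec.offset_fraction * radius * (
            math.cos(theta) * frame.pd_axis + math.sin(theta) * frame.ml_axis
        )
        cell.kinocilium = cell.centroid + offset
    return tess


def assign_channels(
    tess: Tessellation,
    channels: Sequence[ChannelSpec],
    seed: int = 0,
) -> Tessellation:
    """Assign step-profile intensities (plus Gaussian noise, clipped at 0)
    to every cell, by which side of the mediolateral step its centroid is."""
    if not channels:
        return tess
    rng = np.random.default_rng([seed, _STREAMS["channels"]])
    _, y0, _, y1 = tess.bounds()
    span = y1 - y0
    for ch in channels:
        y_step = y0 + ch.step_position * span
        for cid in sorted(tess.cells):
            cell = tess.cells[cid]
            base = ch.medial_level if cell.centroid[1] < y_step else ch.lateral_level
            val = base + (rng.normal(0.0, ch.noise_sd) if ch.noise_sd > 0 else 0.0)
            cell.channel_intensity[ch.name] = max(0.0, float(val))
    return tess
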