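"""Domain-scale measures: compartment widths, row tortuosity, mediolateral
intensity profiles, and junction intensities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from .tessellation import BACKGROUND, Tessellation


@dataclass
class TortuosityResult:
    window_start_index: int
    path_length: float  # L, um, polyline through consecutive centroids
    straight_length: float  # l, um, first-to-last centroid distance

    @property
    def tortuosity(self) -> float:
        return self.path_length / self.straight_length


def polyline_tortuosity(points: np.ndarray) -> tuple[float, float]:
    """(L, l): arc length of the centroid polyline and end-to-end distance."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    seg = np.diff(pts, axis=0)
    L = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    l = float(np.hypot(*(pts[-1] - pts[0])))
    if l <= 0:
        raise ValueError("coincident endpoints: tortuosity undefined")
    return L, l


def row_tortuosity(
    tess: Tessellation, cell_type: str = "IHC", window: int = 10
) -> list[TortuosityResult]:
    """Tortuosity T = L/l of a cell row in non-overlapping windows.

    Cells of the given type are ordered by their proximodistal (x) centroid
    coordinate; each window of ``window`` consecutive centroids yields one T.
    Cells truncated by the field-of-view boundary are excluded (their
    centroids are clipping artifacts).
    """
    cells = sorted(
        (c for c in tess.cells_of_type(cell_type) if not c.touches_boundary),
        key=lambda c: float(c.centroid[0]),
    )
    if len(cells) < window:
        raise ValueError(
            f"need at least {window} cells of type {cell_type}, have {len(cells)}"
        )
    centroids = np.array([c.centroid for c in cells])
    out = []
    for start in range(0, len(cells) - window + 1, window):
        L, l = polyline_tortuosity(centroids[start : start + window])
        out.append(
            TortuosityResult(
                window_start_index=start, path_length=L, straight_length=l
            )
        )
    return out


@dataclass
class WidthProfile:
    positions: np.ndarray  # fractional PD positions in (0, 1)
    widths: np.ndarray  # um
    boundary_pair: tuple[str, str]


def _group_union(tess: Tessellation, group: str | Iterable[str]):
    names = {group} if isinstance(group, str) else set(group)
    polys = [
        Polygon(c.polygon)
        for c in tess.cells.values()
        if c.cell_type in names or c.domain in names
    ]
    if not polys:
        raise ValueError(f"no cells match group {sorted(names)}")
    return unary_union(polys)


def domain_width(
    tess: Tessellation,
    medial_edge: str | Iterable[str],
    lateral_edge: str | Iterable[str],
    n_positions: int = 9,
) -> WidthProfile:
    """Compartment width at equidistant proximodistal positions.

    At each sampled PD position a mediolateral section line is cast; the
    width is the distance from the medial edge of the ``medial_edge`` cell
    group to the lateral edge of the ``lateral_edge`` group.  Positions where
    either boundary does not span the section are skipped with a warning.
    """
    med = _group_union(tess, medial_edge)
    lat = _group_union(tess, lateral_edge)
    x0, y0, x1, y1 = tess.bounds()
    fracs = (np.arange(n_positions) + 1.0) / (n_positions + 1.0)
    positions, widths = [], []
    for f in fracs:
        x = x0 + f * (x1 - x0)
        section = LineString([(x, y0 - 1.0), (x, y1 + 1.0)])
        mi = section.intersection(med)
        li = section.intersection(lat)
        if mi.is_empty or li.is_empty:
            warnings.warn(
                f"boundary does not span PD position {f:.3f}; skipped",
                stacklevel=2,
            )
            continue
        y_med = mi.bounds[1]  # medial-most (lowest y) of the medial group
        y_lat = li.bounds[3]  # lateral-most (highest y) of the lateral group
        if y_lat <= y_med:
            warnings.warn(
                f"degenerate width at PD position {f:.3f}; skipped", stacklevel=2
            )
            continue
        positions.append(f)
        widths.append(y_lat - y_med)
    label = lambda g: g if isinstance(g, str) else "+".join(sorted(g))
    return WidthProfile(
        positions=np.array(positions),
        widths=np.array(widths),
        boundary_pair=(label(medial_edge), label(lateral_edge)),
    )


@dataclass
class IntensityProfile:
    channel: str
    ml_coordinate: np.ndarray  # bin centres, normalized [0, 1] medial->lateral
    relative_intensity: np.ndarray  # bin means / max bin mean

    def step_position(self) -> float:
        """Change-point estimate: the split minimising within-half variance
        over all bin boundaries (exhaustive search; NaN bins ignored)."""
        y = self.relative_intensity
        ok = ~np.isnan(y)
        best, best_sse = 0.5, np.inf
        edges = np.linspace(0.0, 1.0, len(y) + 1)
        for i in range(1, len(y)):
            lo, hi = y[:i][ok[:i]], y[i:][ok[i:]]
            if lo.size == 0 or hi.size == 0:
                continue
            sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if sse < best_sse - 1e-12:
                best_sse, best = sse, edges[i]
        return float(best)


def ml_intensity_profile(
    tess: Tessellation, channel: str, n_bins: int = 50
) -> IntensityProfile:
    """Mean channel intensity in mediolateral bins, normalised to the maximum
    bin (the 'relative fluorescence intensity' convention)."""
    cells = [c for c in tess.cells.values() if channel in c.channel_intensity]
    if not cells:
        raise ValueError(f"channel {channel!r} missing from all cells")
    _, y0, _, y1 = tess.bounds()
    span = y1 - y0
    coord = np.array([(c.centroid[1] - y0) / span for c in cells])
    vals = np.array([c.channel_intensity[channel] for c in cells])
    idx = np.clip((coord * n_bins).astype(int), 0, n_bins - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    peak = np.nanmax(means)
    rel = means / peak if peak > 0 else means
    centres = (np.arange(n_bins) + 0.5) / n_bins
    return IntensityProfile(
        channel=channel, ml_coordinate=centres, relative_intensity=rel
    )


def sample_bond_intensities(
    tess: Tessellation,
    image: np.ndarray,
    pixel_size: float,
    channel: str,
) -> Tessellation:
    """Mean raster intensity along each bond polyline (1-px dilated), stored
    in ``bond.intensity[channel]``.  The image is y-down; the tessellation's
    bounding box is assumed to map onto the full image."""
    from skimage.draw import line as draw_line

    H, W = image.shape
    x0, y0, x1, y1 = tess.bounds()
    for bond in tess.bonds.values():
        pix: set[tuple[int, int]] = set()
        pts = bond.polyline
        for a, b in zip(pts[:-1], pts[1:]):
            r0 = int(np.clip((y1 - a[1]) / pixel_size, 0, H - 1))
            c0 = int(np.clip((a[0] - x0) / pixel_size, 0, W - 1))
            r1 = int(np.clip((y1 - b[1]) / pixel_size, 0, H - 1))
            c1 = int(np.clip((b[0] - x0) / pixel_size, 0, W - 1))
            rr, cc = draw_line(r0, c0, r1, c1)
            for r, c in zip(rr, cc):
                for dr, dc in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
                    rq, cq = r + dr, c + dc
                    if 0 <= rq < H and 0 <= cq < W:
                        pix.add((rq, cq))
        if pix:
            arr = np.array(list(pix))
            bond.intensity[channel] = float(image[arr[:, 0], arr[:, 1]].mean())
    return tess


def junction_mean_intensity(
    tess: Tessellation,
    channel: str,
    cell_types: Sequence[str] | None = None,
):
    """Mean bond intensity per cell type, over bonds whose *both* flanking
    cells are of that type.  Raises for a requested type with no such bonds."""
    import pandas as pd

    groups: dict[str, list[float]] = {}
    for bond in tess.bonds.values():
        if channel not in bond.intensity:
            continue
        a, b = bond.flanking_cells
        if a == BACKGROUND or b == BACKGROUND:
            continue
        ta, tb = tess.cells[a].cell_type, tess.cells[b].cell_type
        if ta == tb:
            groups.setdefault(ta, []).append(bond.intensity[channel])
    if cell_types is not None:
        for t in cell_types:
            if t not in groups:
                raise ValueError(f"no {channel!r}-sampled junctions for group {t!r}")
        groups = {t: groups[t] for t in cell_types}
    if not groups:
        raise ValueError(f"no bonds carry channel {channel!r}")
    return pd.Series(
        {t: float(np.mean(v)) for t, v in sorted(groups.items())},
        name=f"junction_mean_{channel}",
    )
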