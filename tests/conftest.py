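"""Shared fixtures: cached synthetic meshes and small geometric helpers."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import cortimorph as cm


@functools.lru_cache(maxsize=None)
def _preset_mesh_cached(name: str, seed: int) -> cm.Tessellation:
    cfg = cm.preset(name)
    cfg.seed = seed
    return cm.generate_strip(cfg)


@pytest.fixture(scope="session")
def preset_mesh():
    """Factory returning (cached) generated preset strips by (name, seed)."""
    return _preset_mesh_cached


def mini_config(**overrides) -> cm.StripConfig:
    """A small single-KO-domain strip for fast unit tests (~170 cells)."""
    kwargs = dict(
        length_um=120.0,
        domain_specs=(
            cm.DomainSpec(
                "KO_medial", 6, 36.0, 0.2, 1.0, 0.0, 0.0, (("mKO",),)
            ),
        ),
        polarity=cm.PolaritySpec(mean_angle=90.0, kappa=2.0, offset_fraction=0.4),
        ihc_row_wave=(0.0, 40.0),
        channels=(),
        seed=7,
    )
    kwargs.update(overrides)
    return cm.StripConfig(**kwargs)


@functools.lru_cache(maxsize=None)
def _mini_mesh_cached(seed: int = 7) -> cm.Tessellation:
    return cm.generate_strip(mini_config(seed=seed))


@pytest.fixture(scope="session")
def mini_mesh() -> cm.Tessellation:
    """Cached single-domain strip, no rosettes, no wave."""
    return _mini_mesh_cached(7)


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def make_cell(polygon: np.ndarray, cell_id: int = 1, **kwargs) -> cm.CellRecord:
    from shapely.geometry import Polygon

    poly = Polygon(polygon)
    return cm.CellRecord(
        cell_id=cell_id,
        polygon=np.asarray(polygon, dtype=float),
        centroid=np.array(poly.centroid.coords[0]),
        **kwargs,
    )


def voronoi_label_image(n_cells: int, size: int, seed: int) -> np.ndarray:
    """Discrete Voronoi raster: each pixel takes the label of the nearest of
    ``n_cells`` random seed points (labels 1..n)."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, size, size=(n_cells, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    centers = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    vor = (d2.argmin(axis=1) + 1).reshape(size, size).astype(np.int32)
    # thin cells can split on the grid; relabel by 4-connected component so
    # every label is a single region
    from skimage.measure import label as cc_label

    return cc_label(vor, connectivity=1, background=0).astype(np.int32)


def hexagon_label_image(rings: int = 1, scale: int = 24) -> np.ndarray:
    """Rasterized hexagonal lattice patch (1 + 3*rings*(rings+1) hexagons)."""
    centers = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                x = scale * 1.5 * q
                y = scale * np.sqrt(3) * (r + q / 2.0)
                centers.append((x, y))
    centers = np.array(centers)
    pad = scale * 2.2
    x0, y0 = centers[:, 0].min() - pad, centers[:, 1].min() - pad
    x1, y1 = centers[:, 0].max() + pad, centers[:, 1].max() + pad
    W, H = int(np.ceil(x1 - x0)), int(np.ceil(y1 - y0))
    yy, xx = np.mgrid[0:H, 0:W]
    px = np.stack([xx.ravel() + 0.5 + x0, yy.ravel() + 0.5 + y0], axis=1)
    d2 = ((px[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2.argmin(axis=1) + 1).reshape(H, W).astype(np.int32)
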