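"""Shape metrics: closed forms, the direction-scan Feret oracle, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cortimorph as cm
from cortimorph.morphometry import axial_mean_angle, ellipse_axes, feret_diameters

from conftest import make_cell, regular_polygon

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


def scan_feret(points: np.ndarray, step_deg: float = 0.1):
    """Exhaustive direction-scan oracle for caliper widths.

    Projects the points onto every direction on a fine angular grid; the
    caliper width at angle a is the projection span onto direction a.
    """
    ang = np.radians(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = dirs @ np.asarray(points, dtype=float).T
    widths = proj.max(axis=1) - proj.min(axis=1)
    i_max = int(np.argmax(widths))
    return (
        float(widths.max()),
        float(widths.min()),
        float(np.degrees(ang[i_max])),
    )


def axial_distance(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


class TestClosedForms:
    def test_unit_square(self):
        s = cm.cell_shape(make_cell(UNIT_SQUARE), method="feret")
        assert s.area == pytest.approx(1.0)
        assert s.perimeter == pytest.approx(4.0)
        assert s.circularity == pytest.approx(np.pi / 4, abs=1e-9)
        assert s.shape_index == pytest.approx(4.0)
        assert s.aspect_ratio == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert s.feret_angle == pytest.approx(45.0, abs=1e-6)

    def test_square_ellipse_aspect_ratio_is_one(self):
        s = cm.cell_shape(make_cell(UNIT_SQUARE), method="ellipse")
        assert s.aspect_ratio == pytest.approx(1.0, abs=1e-9)

    def test_near_circle_isoperimetric_limit(self):
        cell = make_cell(regular_polygon(256))
        s = cm.cell_shape(cell, method="feret")
        assert 0.999 <= s.circularity <= 1.0
        assert s.shape_index == pytest.approx(2 * np.sqrt(np.pi), abs=1e-3)
        assert 0.999 <= s.aspect_ratio <= 1.0

    def test_rectangle_against_scan_oracle(self):
        rect = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        fmax, fmin, phi = feret_diameters(rect)
        omax, omin, ophi = scan_feret(rect)
        assert fmax == pytest.approx(omax, rel=1e-6)
        assert fmin == pytest.approx(omin, rel=1e-4)
        assert axial_distance(phi, ophi) < 0.2
        major, minor, _ = ellipse_axes(rect)
        assert minor / major == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_polygon_rejected(self):
        sliver = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        cell = cm.CellRecord(cell_id=1, polygon=sliver, centroid=np.zeros(2))
        with pytest.raises(ValueError):
            cm.cell_shape(cell)


def test_random_convex_polygons_match_scan_oracle():
    rng = np.random.default_rng(42)
    from scipy.spatial import ConvexHull

    for _ in range(100):
        pts = rng.normal(size=(12, 2)) * rng.uniform(0.5, 3.0, size=2)
        hull = pts[ConvexHull(pts).vertices]
        fmax, fmin, phi = feret_diameters(hull)
        omax, omin, ophi = scan_feret(hull)
        assert fmax == pytest.approx(omax, rel=0.005)
        assert fmin == pytest.approx(omin, rel=0.005)
        assert axial_distance(phi, ophi) < 0.5


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    scale=st.floats(0.01, 100.0),
    angle=st.floats(0.0, 180.0),
    n=st.integers(5, 12),
    seed=st.integers(0, 10_000),
)
def test_scale_invariance_and_rotation_covariance(scale, angle, n, seed):
    rng = np.random.default_rng(seed)
    radii = rng.uniform(0.5, 1.5, size=n)
    base = regular_polygon(n) * radii[:, None]
    s0 = cm.cell_shape(make_cell(base), method="feret")

    s_scaled = cm.cell_shape(make_cell(base * scale), method="feret")
    assert s_scaled.circularity == pytest.approx(s0.circularity, abs=1e-9)
    assert s_scaled.shape_index == pytest.approx(s0.shape_index, abs=1e-7)
    assert s_scaled.aspect_ratio == pytest.approx(s0.aspect_ratio, abs=1e-9)
    assert axial_distance(s_scaled.feret_angle, s0.feret_angle) < 1e-6

    a = np.radians(angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    s_rot = cm.cell_shape(make_cell(base @ rot.T), method="feret")
    assert s_rot.circularity == pytest.approx(s0.circularity, abs=1e-9)
    assert s_rot.aspect_ratio == pytest.approx(s0.aspect_ratio, abs=1e-7)
    assert axial_distance(s_rot.feret_angle, (s0.feret_angle + angle) % 180) < 0.2


class TestSelectElongated:
    def test_circles_all_excluded(self):
        shapes = [cm.cell_shape(make_cell(regular_polygon(128, center=(i * 3, 0)), cell_id=i + 1)) for i in range(5)]
        assert cm.select_elongated(shapes, 0.8) == []

    def test_threshold_one_passes_squares(self):
        shapes = [cm.cell_shape(make_cell(UNIT_SQUARE))] * 3
        assert len(cm.select_elongated(shapes, 1.0)) == 3

    def test_order_preserved(self):
        sq = cm.cell_shape(make_cell(UNIT_SQUARE, cell_id=1))
        rect = cm.cell_shape(
            make_cell(np.array([[0, 0], [4, 0], [4, 1], [0, 1]], float), cell_id=2)
        )
        out = cm.select_elongated([rect, sq], 1.0)
        assert [s.cell_id for s in out] == [2, 1]


class TestRoseHistogram:
    def test_single_bin(self):
        rose = cm.rose_histogram([90.0] * 7, 10.0)
        assert rose.n == 7
        assert rose.bin_counts[9] == 7
        assert rose.bin_counts.sum() == 7

    def test_uniform_angles(self):
        rose = cm.rose_histogram(np.arange(180.0), 10.0)
        assert (rose.bin_counts == 10).all()

    def test_empty_input(self):
        rose = cm.rose_histogram([], 10.0)
        assert rose.n == 0 and rose.bin_counts.sum() == 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            cm.rose_histogram([1.0], 7.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-720, 720), max_size=50), st.sampled_from([5.0, 10.0, 15.0, 30.0]))
    def test_counts_conserved(self, angles, width):
        rose = cm.rose_histogram(angles, width)
        assert rose.bin_counts.sum() == rose.n == len(angles)


def test_preset_rose_modes_orthogonal(preset_mesh):
    """At the later stage, medial KO cells elongate along the tissue axis and
    lateral KO cells orthogonal to it: modal rose bins sit 90 deg apart."""
    tess = preset_mesh("E18.5-base", 1)
    modes = {}
    for dom in ("KO_medial", "KO_lateral"):
        shapes = cm.measure_cells(
            [c for c in tess.cells.values() if c.domain == dom]
        )
        elong = cm.select_elongated(shapes, 0.8)
        assert len(elong) >= 20
        rose = cm.rose_histogram([s.feret_angle for s in elong], 10.0)
        modes[dom] = rose.modal_angle()
    assert axial_distance(modes["KO_medial"], modes["KO_lateral"]) == pytest.approx(
        90.0, abs=20.0
    )


def test_axial_mean_angle_wraps():
    assert axial_mean_angle([170.0, 10.0]) == pytest.approx(0.0, abs=1e-6) or \
        axial_mean_angle([170.0, 10.0]) == pytest.approx(180.0, abs=1e-6)
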