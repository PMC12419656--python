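"""Tissue-scale metrics: tortuosity, widths, profiles, junction intensities."""

import copy
import math

import numpy as np
import pytest

import cortimorph as cm
from cortimorph.tissue import polyline_tortuosity

from conftest import mini_config


class TestTortuosity:
    def test_collinear_points(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        L, l = polyline_tortuosity(pts)
        assert L / l == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_closed_form(self):
        """Ten points equally spaced on a semicircle: the chord path over the
        diameter has the analytic value (9 chords of angle pi/9 each)."""
        ang = np.linspace(0.0, np.pi, 10)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        L, l = polyline_tortuosity(pts)
        expected = 9 * 2 * math.sin(math.pi / 18) / 2.0
        assert L / l == pytest.approx(expected, rel=1e-12)
        assert L / l < math.pi / 2  # discrete chords undershoot the arc limit

    def test_rigid_motion_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(12, 2)), axis=0)
        L0, l0 = polyline_tortuosity(pts)
        a = 0.7
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved = 3.0 * (pts @ rot.T) + np.array([5.0, -2.0])
        L1, l1 = polyline_tortuosity(moved)
        assert L1 / l1 == pytest.approx(L0 / l0, abs=1e-9)

    def test_straight_ihc_row_unity(self):
        """Zero jitter, zero wave: IHC centroids are exactly collinear."""
        cfg = mini_config(
            domain_specs=(
                cm.DomainSpec("KO_medial", 1, 30.0, 0.0, 1.0, 0.0, 0.0, (("mKO",),)),
                cm.DomainSpec(
                    "sensory_medial", 2, 30.0, 0.0, 1.0, 0.0, 0.0,
                    (("IHC",), ("pillar",)),
                ),
                cm.DomainSpec(
                    "nonsensory_lateral", 1, 30.0, 0.0, 1.0, 0.0, 0.0, (("Hensen",),)
                ),
            ),
            length_um=160.0,
            seed=2,
        )
        tess = cm.generate_strip(cfg)
        results = cm.row_tortuosity(tess, "IHC", window=10)
        assert len(results) >= 2
        # relaxation end effects perturb the outermost cells only slightly...
        for r in results:
            assert r.tortuosity == pytest.approx(1.0, abs=1e-4)
        # ...and the fully interior window is straight to machine precision
        assert results[1].tortuosity == pytest.approx(1.0, abs=1e-6)

    def test_wavy_row_exceeds_unity(self, preset_mesh):
        tess = preset_mesh("E15.5-base", 1)
        results = cm.row_tortuosity(tess, "IHC", window=10)
        assert results and all(r.tortuosity > 1.0 for r in results)
        # windows are non-overlapping with stride = window
        starts = [r.window_start_index for r in results]
        assert starts == list(range(0, len(starts) * 10, 10))

    def test_too_few_cells_rejected(self, mini_mesh):
        with pytest.raises(ValueError):
            cm.row_tortuosity(mini_mesh, "IHC", window=10)


class TestDomainWidth:
    def test_rectangular_strip_constant_width(self, mini_mesh):
        wp = cm.domain_width(mini_mesh, "KO_medial", "KO_medial", n_positions=9)
        assert len(wp.widths) == 9
        x0, y0, x1, y1 = mini_mesh.bounds()
        assert np.allclose(wp.widths, y1 - y0, atol=0.15)

    def test_tapering_width_slope_recovered(self):
        """Single row of quads whose height tapers linearly: the fitted slope
        of the width profile matches the built taper within 5%."""
        n, h0, slope = 40, 20.0, -0.2
        polys = {}
        for i in range(n):
            x0, x1 = float(i), float(i + 1)
            polys[i + 1] = np.array(
                [
                    [x0, 0.0],
                    [x1, 0.0],
                    [x1, h0 + slope * x1],
                    [x0, h0 + slope * x0],
                ]
            )
        tess = cm.tessellation_from_polygons(polys)
        for c in tess.cells.values():
            c.domain = "KO_medial"
        wp = cm.domain_width(tess, "KO_medial", "KO_medial", n_positions=9)
        xs = wp.positions * n  # fractional -> um (strip length n um)
        fit = np.polyfit(xs, wp.widths, 1)
        assert fit[0] == pytest.approx(slope, rel=0.05)

    def test_missing_group_rejected(self, mini_mesh):
        with pytest.raises(ValueError):
            cm.domain_width(mini_mesh, "Hensen", "Claudius")


class TestIntensityProfile:
    def test_uniform_channel_flat(self, mini_mesh):
        tess = copy.deepcopy(mini_mesh)
        cm.assign_channels(tess, [cm.ChannelSpec("flat", 2.0, 2.0, 0.5, 0.0)], seed=1)
        prof = cm.ml_intensity_profile(tess, "flat", n_bins=10)
        vals = prof.relative_intensity[~np.isnan(prof.relative_intensity)]
        assert np.allclose(vals, 1.0)

    def test_noiseless_step_position(self, mini_mesh):
        tess = copy.deepcopy(mini_mesh)
        cm.assign_channels(tess, [cm.ChannelSpec("step", 1.0, 0.1, 0.5, 0.0)], seed=1)
        prof = cm.ml_intensity_profile(tess, "step", n_bins=20)
        assert prof.step_position() == pytest.approx(0.5, abs=0.05)
        assert np.nanmax(prof.relative_intensity) == 1.0

    def test_noisy_step_recovered(self, mini_mesh):
        tess = copy.deepcopy(mini_mesh)
        cm.assign_channels(
            tess, [cm.ChannelSpec("noisy", 1.0, 0.2, 0.4, 0.08)], seed=5
        )
        prof = cm.ml_intensity_profile(tess, "noisy", n_bins=20)
        assert prof.step_position() == pytest.approx(0.4, abs=0.05)

    def test_missing_channel_rejected(self, mini_mesh):
        with pytest.raises(ValueError):
            cm.ml_intensity_profile(mini_mesh, "absent")

    def test_max_normalisation_exact(self, preset_mesh):
        tess = preset_mesh("E15.5-base", 1)
        for channel in ("Cdh1", "Cdh2", "Cdh4"):
            prof = cm.ml_intensity_profile(tess, channel)
            assert np.nanmax(prof.relative_intensity) == 1.0

    def test_preset_step_positions_recovered(self, preset_mesh):
        tess = preset_mesh("E15.5-base", 1)
        cfg = cm.preset("E15.5-base")
        for spec in cfg.channels:
            prof = cm.ml_intensity_profile(tess, spec.name)
            assert prof.step_position() == pytest.approx(
                spec.step_position, abs=0.05
            )


class TestJunctionIntensity:
    @pytest.fixture()
    def painted(self, preset_mesh):
        """Uniform image except pixels near Hensen-Hensen walls at 2x."""
        tess = copy.deepcopy(preset_mesh("E15.5-base", 1))
        px = 0.25
        img = cm.rasterize(tess, px).astype(float)
        img[:] = 1.0
        from skimage.draw import line as draw_line

        H, W = img.shape
        x0, y0, x1, y1 = tess.bounds()
        for b in tess.bonds.values():
            a, c = b.flanking_cells
            if a == 0 or c == 0:
                continue
            if not (
                tess.cells[a].cell_type == "Hensen"
                and tess.cells[c].cell_type == "Hensen"
            ):
                continue
            for p, q in zip(b.polyline[:-1], b.polyline[1:]):
                rr, cc = draw_line(
                    int(np.clip((y1 - p[1]) / px, 0, H - 1)),
                    int(np.clip((p[0] - x0) / px, 0, W - 1)),
                    int(np.clip((y1 - q[1]) / px, 0, H - 1)),
                    int(np.clip((q[0] - x0) / px, 0, W - 1)),
                )
                for r, c2 in zip(rr, cc):
                    img[
                        max(r - 2, 0) : r + 3, max(c2 - 2, 0) : c2 + 3
                    ] = 2.0
        return tess, img, px

    def test_constant_image_all_groups_equal(self, mini_mesh):
        tess = copy.deepcopy(mini_mesh)
        img = np.full((100, 100), 3.0)
        cm.sample_bond_intensities(tess, img, 1.2, "flat")
        means = cm.junction_mean_intensity(tess, "flat")
        assert np.allclose(means.values, 3.0)

    def test_painted_group_doubles(self, painted):
        tess, img, px = painted
        cm.sample_bond_intensities(tess, img, px, "paint")
        means = cm.junction_mean_intensity(tess, "paint")
        others = means.drop("Hensen").max()
        assert means["Hensen"] > 1.8
        assert others < 1.3

    def test_empty_group_named_in_error(self, mini_mesh):
        tess = copy.deepcopy(mini_mesh)
        img = np.ones((50, 50))
        cm.sample_bond_intensities(tess, img, 2.5, "flat")
        with pytest.raises(ValueError, match="Claudius"):
            cm.junction_mean_intensity(tess, "flat", cell_types=["Claudius"])
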