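"""End-to-end orchestration: generate/ingest -> validate -> measure -> write.

Every run emits one CSV per measurement family plus ``manifest.json``
recording all parameters, seeds and tolerances that affect a number in the
outputs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


from .morphometry import (
    axial_mean_angle,
    measure_cells,
    rose_histogram,
    select_elongated,
    shapes_to_frame,
)
from .polarity import circular_summary, polar_export, polarity_vectors
from .raster import polygonize_labels, read_label_tiff
from .stats import comparisons_to_frame, rank_sum_test
from .tessellation import (
    Tessellation,
    apply_annotations,
    apply_kinocilia,
    load_mesh,
    validate,
)
from .tissue import domain_width, ml_intensity_profile, row_tortuosity
from .topology import topology_to_frame, vertex_fraction


class PipelineStageError(RuntimeError):
    """An error wrapped with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Input source and measurement parameters for one pipeline run."""

    preset: str | None = None  # named synthetic preset, or
    mesh_path: str | None = None  # a JSON mesh, or
    labels_path: str | None = None  # a label TIFF plus annotation tables
    annotations_path: str | None = None
    kinocilia_path: str | None = None
    pixel_size: float = 0.25  # um/px for TIFF ingest
    merge_tol: float | None = None  # vertex merge tolerance, um
    seed: int = 1
    outdir: str = "cortimorph_out"
    c_max: float = 0.8  # circularity threshold for elongated cells
    rose_bin_width: float = 10.0
    tortuosity_window: int = 10
    n_width_positions: int = 9
    n_profile_bins: int = 50
    vertex_order_k: int = 4
    regions: tuple = (
        ("sensory", ("sensory_medial", "sensory_lateral")),
        ("mKO", ("KO_medial",)),
        ("lKO", ("KO_lateral",)),
    )
    extra: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


@_stage("tessellation_core")
def _acquire(config: PipelineConfig) -> Tessellation:
    from .synthetic import generate_strip, preset as load_preset

    if config.preset is not None:
        cfg = load_preset(config.preset)
        cfg.seed = config.seed
        return generate_strip(cfg)
    if config.mesh_path is not None:
        return load_mesh(config.mesh_path)
    if config.labels_path is not None:
        import pandas as pd

        labels = read_label_tiff(config.labels_path)
        tess = polygonize_labels(
            labels, config.pixel_size, merge_tol=config.merge_tol
        )
        if config.annotations_path:
            apply_annotations(tess, pd.read_csv(config.annotations_path))
        if config.kinocilia_path:
            apply_kinocilia(tess, pd.read_csv(config.kinocilia_path))
        return tess
    raise ValueError("config names no input (preset, mesh_path or labels_path)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full measurement pipeline and write the report bundle.

    Returns a dict of the in-memory results keyed like the output files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    tess = _acquire(config)
    violations = validate(tess)
    if violations:
        raise PipelineStageError(
            "tessellation_core",
            ValueError(f"{len(violations)} invariant violations: {violations[:3]}"),
        )
    results["tessellation"] = tess

    shapes = _measure_shapes(tess, config, outdir, results)
    _measure_topology(tess, config, outdir, results)
    _measure_polarity(tess, outdir, results)
    _measure_tissue(tess, config, outdir, results)

    manifest = {
        "software": "cortimorph 0.1.0",
        "seed": config.seed,
        "source": config.preset or config.mesh_path or config.labels_path,
        "n_cells": len(tess.cells),
        "n_vertices": len(tess.vertices),
        "n_bonds": len(tess.bonds),
        "parameters": {
            "pixel_size_um": config.pixel_size,
            "merge_tol_um": config.merge_tol
            if config.merge_tol is not None
            else 2.5 * config.pixel_size,
            "circularity_threshold": config.c_max,
            "rose_bin_width_deg": config.rose_bin_width,
            "tortuosity_window_cells": config.tortuosity_window,
            "n_width_positions": config.n_width_positions,
            "n_profile_bins": config.n_profile_bins,
            "vertex_order_threshold_k": config.vertex_order_k,
            "boundary_cells_excluded_from_shapes": True,
            "unit_of_analysis": "cells pooled within strip",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


@_stage("morphometry")
def _measure_shapes(tess, config, outdir, results):
    shapes = measure_cells(tess.cells.values())
    df = shapes_to_frame(shapes)
    df.to_csv(outdir / "shapes.csv", index=False)
    results["shapes"] = df
    elongated = select_elongated(shapes, config.c_max)
    rose = rose_histogram(
        [s.feret_angle for s in elongated], config.rose_bin_width
    )
    import pandas as pd

    rose_df = pd.DataFrame(
        {
            "bin_lo": rose.bin_edges[:-1],
            "bin_hi": rose.bin_edges[1:],
            "count": rose.bin_counts,
        }
    )
    rose_df.to_csv(outdir / "rose.csv", index=False)
    results["rose"] = rose_df
    if elongated:
        results["mean_elongation_axis"] = axial_mean_angle(
            [s.feret_angle for s in elongated]
        )
    return shapes


@_stage("topology")
def _measure_topology(tess, config, outdir, results):
    rows = []
    try:
        rows.append(vertex_fraction(tess, None, config.vertex_order_k))
    except ValueError:
        pass
    for name, domains in config.regions:
        try:
            r = vertex_fraction(tess, domains, config.vertex_order_k)
            r.region = name
            rows.append(r)
        except ValueError:
            continue
    df = topology_to_frame(rows)
    df.to_csv(outdir / "topology.csv", index=False)
    results["topology"] = df


@_stage("polarity")
def _measure_polarity(tess, outdir, results):
    import pandas as pd

    vectors = polarity_vectors(tess)
    df = polar_export(vectors)
    df.to_csv(outdir / "polarity.csv", index=False)
    results["polarity"] = df
    summaries = []
    for ctype in sorted({v.cell_type for v in vectors if v.defined}):
        summ = circular_summary(
            [v.theta for v in vectors if v.defined and v.cell_type == ctype]
        )
        summaries.append(
            {
                "cell_type": ctype,
                "mean_angle": summ.mean_angle,
                "resultant_length": summ.resultant_length,
                "circular_sd_deg": summ.circular_sd_deg,
                "n": summ.n,
            }
        )
    sdf = pd.DataFrame(summaries)
    sdf.to_csv(outdir / "polarity_summary.csv", index=False)
    results["polarity_summary"] = sdf


@_stage("tissue_metrics")
def _measure_tissue(tess, config, outdir, results):
    import pandas as pd

    try:
        tort = row_tortuosity(tess, "IHC", config.tortuosity_window)
        tdf = pd.DataFrame(
            {
                "window_start_index": [t.window_start_index for t in tort],
                "L_um": [t.path_length for t in tort],
                "l_um": [t.straight_length for t in tort],
                "tortuosity": [t.tortuosity for t in tort],
            }
        )
    except ValueError:
        tdf = pd.DataFrame(
            columns=["window_start_index", "L_um", "l_um", "tortuosity"]
        )
    tdf.to_csv(outdir / "tortuosity.csv", index=False)
    results["tortuosity"] = tdf

    try:
        wp = domain_width(tess, "IHC", "border", config.n_width_positions)
    except ValueError:
        try:
            wp = domain_width(
                tess, "sensory_medial", "sensory_lateral", config.n_width_positions
            )
        except ValueError:
            wp = None
    if wp is not None:
        wdf = pd.DataFrame(
            {
                "pd_position": wp.positions,
                "width_um": wp.widths,
                "medial_edge": wp.boundary_pair[0],
                "lateral_edge": wp.boundary_pair[1],
            }
        )
    else:
        wdf = pd.DataFrame(
            columns=["pd_position", "width_um", "medial_edge", "lateral_edge"]
        )
    wdf.to_csv(outdir / "widths.csv", index=False)
    results["widths"] = wdf

    channels = sorted(
        {ch for c in tess.cells.values() for ch in c.channel_intensity}
    )
    frames = []
    for ch in channels:
        prof = ml_intensity_profile(tess, ch, config.n_profile_bins)
        frames.append(
            pd.DataFrame(
                {
                    "channel": ch,
                    "ml_coordinate": prof.ml_coordinate,
                    "relative_intensity": prof.relative_intensity,
                }
            )
        )
    pdf = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["channel", "ml_coordinate", "relative_intensity"])
    )
    pdf.to_csv(outdir / "profiles.csv", index=False)
    results["profiles"] = pdf


@_stage("stats_report")
def compare_bundles(shapes_a, shapes_b, labels=("A", "B"), metrics=None, out=None):
    """Rank-sum comparison of every shared numeric shape metric."""
    import pandas as pd

    if metrics is None:
        metrics = [
            "area_um2",
            "perimeter_um",
            "circularity",
            "shape_index",
            "aspect_ratio",
        ]
    comps = []
    for metric in metrics:
        if metric not in shapes_a.columns or metric not in shapes_b.columns:
            continue
        comps.append(
            rank_sum_test(
                shapes_a[metric].dropna(),
                shapes_b[metric].dropna(),
                metric=metric,
                labels=labels,
            )
        )
    df = comparisons_to_frame(comps)
    df.attrs["n_metrics_tested"] = len(comps)  # no multiplicity correction applied
    if out is not None:
        df.to_csv(out, index=False)
    return df
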