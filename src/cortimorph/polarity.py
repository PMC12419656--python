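"""Kinocilium planar-polarity vectors and circular statistics.

Each hair cell's polarity is the vector from its centroid to its kinocilium,
with length normalised to the equivalent-circle radius sqrt(A/pi) and angle
theta measured counter-clockwise from the +PD (proximodistal) axis over the
full circle [0, 360).  Groups of angles are summarised by the circular mean,
the mean resultant length R and the circular standard deviation
s = sqrt(-2 ln R) (Mardia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tessellation import AxisFrame, CellRecord, Tessellation


@dataclass
class PolarityVector:
    cell_id: int
    r: float  # offset length / equivalent-circle radius
    theta: float  # degrees CCW from +PD axis, [0, 360)
    defined: bool  # False when kinocilium coincides with the centroid
    cell_type: str = "other"


@dataclass
class CircularSummary:
    mean_angle: float  # degrees in [0, 360)
    resultant_length: float  # R in [0, 1]
    circular_sd: float  # radians, sqrt(-2 ln R); inf when R ~ 0
    n: int
    degenerate: bool = False  # True when R < 1e-12 (sd is the inf sentinel)

    @property
    def circular_sd_deg(self) -> float:
        return math.degrees(self.circular_sd)


def polarity_vector(cell: CellRecord, frame: AxisFrame | None = None) -> PolarityVector:
    """Centroid-to-kinocilium vector in normalised polar form."""
    if cell.kinocilium is None:
        raise ValueError(f"cell {cell.cell_id} has no kinocilium")
    if frame is None:
        frame = AxisFrame()
    offset = np.asarray(cell.kinocilium, dtype=float) - np.asarray(
        cell.centroid, dtype=float
    )
    area = cell.area
    norm = float(np.hypot(*offset))
    if norm < 1e-9 * math.sqrt(max(area, 1e-300)):
        return PolarityVector(
            cell_id=cell.cell_id, r=0.0, theta=0.0, defined=False,
            cell_type=cell.cell_type,
        )
    radius = math.sqrt(area / math.pi)
    u = float(np.dot(offset, frame.pd_axis))
    v = float(np.dot(offset, frame.ml_axis))
    theta = math.degrees(math.atan2(v, u)) % 360.0
    return PolarityVector(
        cell_id=cell.cell_id,
        r=norm / radius,
        theta=theta,
        defined=True,
        cell_type=cell.cell_type,
    )


def polarity_vectors(
    tess: Tessellation, cell_types: Iterable[str] | None = None
) -> list[PolarityVector]:
    """Polarity vectors for every annotated cell carrying a kinocilium."""
    types = None if cell_types is None else set(cell_types)
    out = []
    for cid in sorted(tess.cells):
        cell = tess.cells[cid]
        if cell.kinocilium is None:
            continue
        if types is not None and cell.cell_type not in types:
            continue
        out.append(polarity_vector(cell, tess.frame))
    return out


def circular_summary(angles_deg: Sequence[float]) -> CircularSummary:
    """Circular mean, mean resultant length and circular SD of angles."""
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise ValueError("circular_summary requires at least one angle")
    s, c = np.sin(a).sum(), np.cos(a).sum()
    rbar = float(np.hypot(s, c) / a.size)
    rbar = min(rbar, 1.0)
    if rbar > 1.0 - 1e-12:  # fully concentrated sample: s is exactly 0
        rbar = 1.0
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if rbar < 1e-12:
        return CircularSummary(
            mean_angle=mu, resultant_length=0.0, circular_sd=math.inf,
            n=int(a.size), degenerate=True,
        )
    sd = math.sqrt(max(-2.0 * math.log(rbar), 0.0))
    return CircularSummary(
        mean_angle=mu, resultant_length=rbar, circular_sd=sd, n=int(a.size)
    )


def polar_export(vectors: Sequence[PolarityVector]):
    """Polar-coordinate table (cell_id, r, theta), one row per defined vector.

    The group summary arrow (mean angle, length proportional to R) travels in
    ``DataFrame.attrs["summary"]``.
    """
    import pandas as pd

    defined = [v for v in vectors if v.defined]
    df = pd.DataFrame(
        [
            {"cell_id": v.cell_id, "cell_type": v.cell_type, "r": v.r, "theta": v.theta}
            for v in defined
        ],
        columns=["cell_id", "cell_type", "r", "theta"],
    )
    if defined:
        summ = circular_summary([v.theta for v in defined])
        df.attrs["summary"] = {
            "mean_angle": summ.mean_angle,
            "resultant_length": summ.resultant_length,
            "circular_sd_rad": summ.circular_sd,
            "circular_sd_deg": summ.circular_sd_deg,
            "n": summ.n,
        }
    else:
        df.attrs["summary"] = {
            "mean_angle": float("nan"),
            "resultant_length": float("nan"),
            "circular_sd_rad": float("nan"),
            "circular_sd_deg": float("nan"),
            "n": 0,
        }
    return df
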