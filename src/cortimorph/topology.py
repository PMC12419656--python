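"""Vertex-order statistics and adjacency-derived contact/enclosure metrics.

In an epithelium, neighbour exchange (a T1 transition or rosette) passes
through a configuration where four or more cells meet at a junctional vertex,
so the fraction of vertices with order >= 4 is a static proxy for ongoing
cell intercalation.  Only interior vertices (no background incidence) are
counted; boundary vertices are excluded from totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .tessellation import BACKGROUND, HC_TYPES, Tessellation, VertexRecord


@dataclass
class VertexFractionResult:
    n_high: int  # interior vertices with order >= k
    n_total: int  # interior vertices counted
    k: int
    region: str = "all"

    @property
    def fraction(self) -> float:
        return self.n_high / self.n_total

    @property
    def percent_rounded(self) -> int:
        return int(round(100.0 * self.fraction))

    @classmethod
    def from_counts(cls, n_high: int, n_total: int, k: int = 4, region: str = "all"):
        """Build directly from tabulated (high, total) vertex counts."""
        if n_total <= 0 or n_high < 0 or n_high > n_total:
            raise ValueError("need 0 <= n_high <= n_total with n_total > 0")
        return cls(n_high=n_high, n_total=n_total, k=k, region=region)


def _vertex_in_region(vertex: VertexRecord, tess: Tessellation, region: set[str]) -> bool:
    """Majority-incidence region assignment; ties are included."""
    inside = sum(1 for c in vertex.incident_cells if tess.cells[c].domain in region)
    outside = len(vertex.incident_cells) - inside
    return inside > 0 and inside >= outside


def vertex_fraction(
    tess: Tessellation,
    region: str | Iterable[str] | None = None,
    k: int = 4,
) -> VertexFractionResult:
    """Fraction of interior vertices at which ``k`` or more cells meet.

    ``region`` restricts to vertices whose incident cells lie (by majority,
    ties included) in the named domain(s).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if region is None:
        selected = [v for v in tess.vertices.values() if v.interior]
        label = "all"
    else:
        domains = {region} if isinstance(region, str) else set(region)
        selected = [
            v
            for v in tess.vertices.values()
            if v.interior and _vertex_in_region(v, tess, domains)
        ]
        label = "+".join(sorted(domains))
    if not selected:
        raise ValueError(f"region {label!r} selects no interior vertices")
    n_high = sum(1 for v in selected if v.order >= k)
    return VertexFractionResult(
        n_high=n_high, n_total=len(selected), k=k, region=label
    )


def neighbor_map(tess: Tessellation) -> dict[int, set[int]]:
    """Bond-sharing neighbours per cell (background excluded)."""
    nbrs: dict[int, set[int]] = {cid: set() for cid in tess.cells}
    for b in tess.bonds.values():
        a, c = b.flanking_cells
        if a != BACKGROUND and c != BACKGROUND and a != c:
            nbrs[a].add(c)
            nbrs[c].add(a)
    return nbrs


@dataclass
class ContactFractionResult:
    n_hc: int
    n_hc_with_hc_neighbor: int
    n_hc_bonds: int  # bonds with at least one HC flank
    n_hc_hc_bonds: int  # bonds with both flanks HC

    @property
    def per_hc_fraction(self) -> float:
        """Fraction of hair cells sharing >= 1 bond with another hair cell."""
        return self.n_hc_with_hc_neighbor / self.n_hc

    @property
    def per_bond_fraction(self) -> float:
        """Alternative denominator: HC-HC bonds / HC-incident bonds."""
        return self.n_hc_hc_bonds / self.n_hc_bonds if self.n_hc_bonds else 0.0


def hc_hc_contact_fraction(tess: Tessellation) -> ContactFractionResult:
    """Hair-cell/hair-cell contact statistics (HC = IHC, OHC1-3)."""
    hc_ids = {c.cell_id for c in tess.cells.values() if c.cell_type in HC_TYPES}
    if not hc_ids:
        raise ValueError("no hair cells present")
    nbrs = neighbor_map(tess)
    with_contact = sum(1 for cid in hc_ids if nbrs[cid] & hc_ids)
    n_hc_bonds = n_hc_hc = 0
    for b in tess.bonds.values():
        a, c = b.flanking_cells
        a_hc, c_hc = a in hc_ids, c in hc_ids
        if a_hc or c_hc:
            n_hc_bonds += 1
        if a_hc and c_hc:
            n_hc_hc += 1
    return ContactFractionResult(
        n_hc=len(hc_ids),
        n_hc_with_hc_neighbor=with_contact,
        n_hc_bonds=n_hc_bonds,
        n_hc_hc_bonds=n_hc_hc,
    )


def enclosed_cell_count(
    tess: Tessellation, inner_type: str, surrounding_domain: str
) -> int:
    """Cells of ``inner_type`` whose every bond-neighbour lies in
    ``surrounding_domain`` (boundary-touching cells cannot be enclosed)."""
    nbrs = neighbor_map(tess)
    count = 0
    for cell in tess.cells.values():
        if cell.cell_type != inner_type or cell.touches_boundary:
            continue
        neigh = nbrs[cell.cell_id]
        if neigh and all(
            tess.cells[n].domain == surrounding_domain for n in neigh
        ):
            count += 1
    return count


def topology_to_frame(results: Iterable[VertexFractionResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region": r.region,
                "k": r.k,
                "n_high": r.n_high,
                "n_total": r.n_total,
                "fraction": r.fraction,
                "percent_rounded": r.percent_rounded,
            }
            for r in results
        ]
    )
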