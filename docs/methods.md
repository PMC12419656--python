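# Methods

## Scope and model of the data

`cortimorph` quantifies the planar organization of the embryonic organ of
Corti from segmented apical surfaces. The data model is a 2-D tessellation:
polygonal cells, junctional vertices where three or more regions meet, and
bonds (walls) connecting vertices, in a y-up micrometre frame with +x the
proximodistal (base→apex) axis and +y the mediolateral axis. Everything the
package measures — cell shape, vertex order, kinocilium polarity, row
tortuosity, compartment width, intensity profiles — is a function of this
tessellation, so the pipeline is agnostic to whether the tessellation came
from a segmented label image, a mesh file, or the synthetic generator.

Measurements are 2-D (apical-plane). The pipeline does not segment membranes
from fluorescence and does not handle z-stacks.

## Per-cell shape metrics

For a cell with area `A` and perimeter `P`:

- circularity `c = 4πA/P²` (1 for a disk),
- shape index `Q = P/√A` (minimum `2√π ≈ 3.545` for a disk),
- aspect ratio `AR`, default the minor/major ratio of the second-area-moment
  fitted ellipse — the quantity ImageJ's shape descriptors report as "AR".
  A caliper-based alternative, minFeret/maxFeret, is available with
  `method="feret"`. The two differ systematically on polygons: a square has
  ellipse AR 1.0 but Feret AR 0.707, and Feret AR of any hexagonal cell is
  capped at 0.866. Means near 0.9 for epithelial cells are therefore only
  attainable under the ellipse definition, which is why it is the default.
- Feret angle `φ`: orientation of the maximal caliper diameter against +x,
  folded to [0°, 180°), ties broken toward the smaller angle. Computed by
  rotating calipers on the convex hull (max Feret = largest pairwise hull
  distance; min Feret = smallest width over hull-edge normals) and verified
  in tests against an exhaustive 0.1° direction-scan oracle.

Cells truncated by the field-of-view boundary are flagged on ingest and
excluded from shape statistics by default.

The elongation-axis procedure selects cells with `c < 0.8` (threshold
configurable) and bins their Feret angles into axial rose histograms
(default 10° bins, half-open `[lo, hi)`, angles folded mod 180°).

## Vertex-order topology

Neighbour exchange in epithelia passes through configurations where four or
more cells meet at a vertex; the fraction of such vertices is the static
intercalation proxy. `vertex_fraction` counts interior vertices only (no
background incidence) with order ≥ k, default k = 4 ("4 or more cells",
which is the convention that reproduces the printed worked examples
205/615 → 33% and 122/625 → 20%). A region filter assigns each vertex by
majority incidence of its cells' domains, ties included.

On pixel grids, vertices of order ≥ 4 split into nearby 3-fold corner
junctions. `polygonize_labels` therefore merges vertices closer than
`merge_tol` (default 2.5 × pixel size; splits up to 2 px were observed on
rasterized rosettes). This is the single most result-sensitive ingest
parameter; it is recorded in the tessellation provenance and in every run
manifest.

## Kinocilium polarity

Each hair cell's polarity vector runs from its centroid to its kinocilium;
its length is normalised by the equivalent-circle radius `√(A/π)` ("cell
radius" is otherwise undefined for polygons) and its angle θ is measured
counter-clockwise from +PD over the full circle. Elongation axes, by
contrast, are axial (mod 180°). Group dispersion uses the circular mean,
mean resultant length `R̄`, and circular SD `s = √(−2 ln R̄)` (Mardia); for
`R̄ < 1e-12` the SD is reported as +∞ and flagged. Whether θ is signed CW or
CCW from the PD axis is a convention; all dispersion quantities are
sign-invariant.

## Tissue-scale metrics

- Tortuosity: inner-hair-cell centroids ordered by PD coordinate, windows of
  10 cells, non-overlapping (stride = window), `T = L/l` with `L` the
  polyline length and `l` the end-to-end distance. Boundary-truncated cells
  are excluded because their centroids are clipping artifacts.
- Compartment width: at `n` equidistant PD positions (default 9) a
  mediolateral section is cast; width runs from the medial edge of the
  medial cell group to the lateral edge of the lateral group. In straight
  synthetic strips this equals the ML distance; in curved tissue it
  approximates the width perpendicular to the local PD tangent.
- Mediolateral intensity profiles: per-cell channel intensities averaged in
  bins of the normalised ML coordinate (default 50) and divided by the
  maximum bin, matching "relative fluorescence intensity" axes. The
  normalisation and absence of background subtraction are declared
  conventions, not reproduction claims. The change-point estimate is an
  exhaustive one-split search minimising within-segment variance.
- Junction intensities: bond polylines are rasterised (1-px dilation), the
  image is averaged along each, and bonds whose two flanking cells share a
  type are grouped by that type.

## Rank-sum comparison

Group comparison uses a natively implemented two-sided Mann-Whitney test:
exact enumeration of rank assignments when `n₁+n₂ ≤ 12` with no ties,
otherwise the normal approximation with tie and continuity corrections. The
exact branch is verified against an independent enumeration oracle and
against `scipy.stats.mannwhitneyu(method="exact")`; the approximate branch is
calibrated by Monte Carlo (type-I error 0.05 ± 0.01 at n = 30/30, 10⁴
replicates). No multiple-testing correction is applied; reports carry raw
p-values and the number of metrics tested.

## Synthetic strips

Because the study's confocal images are not deposited, every measurement is
validated against a generator whose ground truth is exactly the quantities
the pipeline reports. A strip is a medial→lateral stack of domain bands
(mKO, lKO, medial sensory with interdigitated IHC/IPhC and a pillar row,
lateral sensory with three OHC/Deiters rows, Hensen/Claudius): stylized
layout, per S-figure schematics of the tissue.

Per band: seeds on a hexagonal lattice (column pitch `√(2/√3)·√A`, row pitch
`√(√3/2)·√A`) with Gaussian jitter proportional to `area_cv`; coordinates are
contracted by `√a` along the elongation axis, a guard-point-bounded Voronoi
partition is relaxed by two Lloyd steps in that metric, and cells are
stretched back — giving cells elongated by `a` along the chosen axis with
mean area `A`. A smooth area-preserving shear `y → y + A·sin(2πx/λ)` applied
to the whole strip produces the inner-hair-cell row waviness that tortuosity
measures.

Rosettes are created by collapsing the shortest interior bonds until the
measured fraction of order ≥ 4 vertices reaches the per-domain target within
±0.01, using the same majority-incidence region accounting as the measuring
code, so round trips recover the configured value by construction. Collapse
selection penalises bonds whose flanking cells are already few-sided (no
cell drops below four sides). Injection proceeds in four chunks interleaved
with a rounding relaxation — interior vertices are pushed toward each
incident cell's equal-area regular-polygon circumradius, with steps clamped
to 30% of the shortest incident bond — because without relaxation the
collapsed cells accumulate elongation no real, mechanically relaxed
epithelium shows. A minimum-bond floor of 0.8 µm is enforced (pre-injection
sweep of band-join slivers, relaxation guard, final sweep) so that every
wall is resolvable when the mesh is rasterised; this is what makes
`polygonize(rasterize(t))` adjacency-exact on all presets.

Kinocilia are placed at radius `offset_fraction · √(A/π)` with von Mises
angles; step-like "cadherin" channels assign medial/lateral levels by
centroid side of a configurable ML step plus clipped Gaussian noise. One
root seed feeds fixed per-stage substreams (seeds/inject/kinocilia/
channels), so adding a stage never perturbs an earlier one, and identical
(config, seed) gives byte-identical serialized meshes.

### Presets and calibration

`E15.5-base`: isotropic KO cells (40/45 µm², jitter calibrated once so the
measured mean ellipse AR of interior KO cells is ≈ 0.87), high-order
fractions 0.33 across the sensory domains (injected jointly so the union
measures 0.33), 0.40 in mKO, 0.21 in lKO; polarity κ = 2 at mean 90°
(lateral); row wave 1 µm over 40 µm.

`E18.5-base`: sensory fraction 0.20, mKO 0.40, lKO 0.13; mKO cells smaller
(28 µm²) and elongated along PD (a = 1.5, axis 0°), lKO larger (55 µm²) and
elongated mediolaterally (a = 1.8, axis 90°); polarity κ = 8 (tightened).
The stage's aspect-ratio distributions are shown in the source only as rose
plots, so the anisotropy values are qualitative axis contrasts, not
quantitative calibrations; mKO area is likewise a design choice (printed
data give only "smaller than lKO").

`looptail-like`: the E18.5 configuration with the mKO/lKO area and axis
contrasts collapsed (both 40 µm², isotropic), emulating the planar-polarity
mutant in which compartment shape contrasts fail to develop.

Strips are ~320 µm long with ≈ 1000 cells (≈ 600 KO cells), the scale of one
imaged field; this keeps a full generate-measure cycle around ten seconds.

### What the generator does and does not emulate

It reproduces target mean areas, anisotropies and axes, rosette fractions,
polarity concentration, row waviness, and step-like intensity fields — the
quantities the measurement modules report. It does not simulate
developmental dynamics (intercalation over time, signalling, growth),
curvature of the cochlear spiral, cell-type-specific junctional tensions, or
imaging noise in the segmentation itself. Passing tests therefore show that
the measurement code recovers known ground truth from realistic geometry,
not that the biological claims of any particular study are reproduced.

## Numerical choices

- Raster polygons are traced along pixel corners, so shoelace area equals
  pixel count × pixel size² exactly; raster ingest flips images to the y-up
  frame; a pixel's coordinate is its centre.
- `rasterize` assigns pixels by centre containment; centres exactly on walls
  go to the lowest-id covering cell, and sub-pixel orphan fragments (thin
  wedges at rosettes) are reassigned to a neighbour that introduces no
  adjacency absent from the mesh.
- Mesh construction from polygons nodes all boundaries (shapely
  `unary_union`), attributes each elementary wall segment by probing points
  1 nm–1 µm off its midpoint, and chains constant-flank segments into bonds;
  coordinates are snapped at 1e-6 µm.
- Vertex merging is single-linkage within the tolerance; bonds collapsing
  onto one vertex are dropped.
- Degenerate inputs: polygons with area < 1e-9 µm², empty samples, empty
  regions and missing channels raise `ValueError` with the offending entity
  named; `validate()` reports (rather than raises) structural violations.

## Known limitations

- Ellipse AR and Feret AR are not interchangeable; comparisons against
  caliper-based numbers must pass `method="feret"`.
- The generator's area CV is controlled only indirectly through seed jitter;
  its aspect-ratio spread (≈ 0.05) is narrower than real tissue (≈ 0.12).
- `domain_width` requires the edge groups to span the sampled PD positions;
  interdigitated rows (IHC alternating with IPhC) can leave gaps at single
  positions, which are skipped with a warning.
- Exact adjacency round trips are guaranteed only at raster resolutions
  where the minimum wall length (0.8 µm in generated meshes) exceeds about
  five pixels.
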