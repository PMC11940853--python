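# Methods

## The model

A region is represented as a *cell space*: a square grid (default cell side
L = 2,000 m) laid over a categorical land-use/cover raster (default 10 m
pixels, nine classes: small/large-scale agriculture, herbaceous/shrub
pasture, initial/advanced secondary vegetation, hydrography, forest,
non-forest). Each cell is treated as an independent small landscape. A
supervised classifier assigns each cell one of five production landscape
units (PLU): three peasant types (extractivist; agro-extractivist with
temporary agriculture; mosaic with açaí, agriculture and pasture) and two
capitalist types (irrigated açaí; cattle). The classifier never sees the
archetype definitions — only per-cell metrics — so recovery of the labels
is a genuine test of the metric-plus-classifier chain.

## Açaí-potential rules

Potential occurrence of native açaí is a deterministic pixel rule over
(land-cover class, hydro-topographic zone):

| | lowland | transition | slope | upland |
|---|---|---|---|---|
| forest | high | high | moderate | low |
| secondary vegetation (either stage) | high | high | **low*** | low |
| all other classes | absent | absent | absent | absent |

(*) Secondary vegetation on slope is not covered by the published wording
(which names "forest cover" on slopes and "secondary vegetation and/or
forest" on upland); we assign *low*, consistent with the gradient that
secondary vegetation carries lower potential than primary forest, and
expose the choice as `secondary_on_slope` ("low" | "moderate" | "absent").
Nodata in either input propagates as nodata. The *high* class replaces the
underlying vegetation class in the unified product; all other pixels pass
through unchanged, so pixel count is conserved.

## Landscape metrics

Class-level FRAGSTATS raster conventions:

* patches are 8-connected components (configurable to 4);
* edges are counted between 4-adjacent pixel pairs of different classes;
* the cell/window boundary **counts** as edge. This keeps LSI ≥ 1 for every
  nonempty class and makes LSI and AWMPFD exactly 1 for any square patch,
  including one touching the border; the alternative dialect (boundary not
  counted) is available via `count_boundary_edges=False`.
* a patch crossing a cell boundary is split and measured separately on each
  side: the cell is the landscape.

Formulas, with pⱼ the patch perimeter (m), aⱼ the patch area (m², > 1):
CA = Σaⱼ (ha); PD = patches per 100 ha of cell; MPS = CA/NP;
LSI = 0.25·Σpⱼ/√(Σaⱼ); AWMPFD = Σⱼ (2 ln(0.25 pⱼ)/ln aⱼ)(aⱼ/Σa);
TABO = max aⱼ; IJI = 100·[−Σₖ (eₖ/E) ln(eₖ/E)]/ln(m−1) where eₖ is edge
length shared between the focal class and class k, E = Σeₖ and m the
number of classes present in the cell (undefined when m < 3 or E = 0).

**Sentinels.** Undefined metrics (class absent; IJI with m < 3) are encoded
as −1.0, never 0: a zero would conflate "absent" with "maximally compact",
and the threshold trees can branch on the sentinel directly.

**Context.** HID_min is the Euclidean distance (m) from the cell centroid
to the nearest river polyline, 0 when a river intersects the cell;
P_HID ∈ {0,1}; road distance analogous; establishment count and mean/max
`area_ha` are taken over polygons intersecting the cell (full polygon
area, not the clipped part). Distances use the region-wide layers, not the
per-cell clips.

The feature inventory is the deterministic cross-product of 7 metrics × 10
unified classes plus 6 context columns (76 columns). The richer inventories
of production GIS toolboxes arise from larger metric × class products; the
inventory here is config-derived and versioned through the column list, not
hard-coded to any fixed count.

## Classifier

Trees: greedy top-down induction maximizing weighted information gain
(Shannon entropy); candidate thresholds are midpoints between consecutive
distinct sorted values; gain ties break to the lower column index, then the
lower threshold; stopping at purity, max depth (default 10) or min leaf
size (default 2); leaves take the weighted-majority class with ties to the
fixed class order PLU1…PLU5.

Boosting: weights start uniform; each iteration fits a full tree (not a
stump — each iteration is an independent classification), computes the
weighted error ε_t, and multiplies misclassified weights by
exp(α_t), α_t = ln((1−ε_t)/ε_t) + ln(K−1), K = 5, then renormalizes
(weights sum to 1 to 1e−9 after every step). Stopping: ε_t = 0
("stabilized"), ε_t ≥ 1 − 1/K ("error_too_high"), or the iteration cap
(default 99). The stopping reason and the full ε trajectory are recorded
rather than assuming any particular number of kept trees.

Prediction is an **unweighted majority vote** across trees — the documented
deviation from weighted SAMME voting, matching the most-frequent-class
description of the method being reproduced — with ties broken by higher
training prevalence, then fixed class order. The random seed affects only
the stratified 70/30 split (per class: floor(0.7·n) to training); induction
is deterministic.

## Synthetic generator

The generator realizes the five archetypes as parameterized recipes over
cells: base class, blob patches (random-walk growth to an exact pixel
count) for peasant/secondary-vegetation classes, rectangles for capitalist
classes, per-cell establishment rectangles in disjoint sub-slots, and river
or road anchoring. Cells are assigned to archetypes column-by-column from
the west, rivers run through the peasant columns and roads through the
capitalist ones, so riverine context is guaranteed by construction.
Hydro-topography is a monotone distance-to-river surrogate (lowland ≤ 400 m,
transition ≤ 900 m, slope ≤ 1,500 m, upland beyond) — not a hydrological
model. Key quantitative defaults, chosen to match the documented regimes:

* peasant plots 0.5–2 ha; capitalist blocks 2–200 ha (realized as 2 × 2
  slot blocks of ≈60–85 ha inside a 400 ha cell);
* peasant establishments ≤ 280 ha (6–10 per riverine cell, 3–5 in
  mosaics); capitalist establishments one per cell at ≈340–380 ha (> 280);
* default PLU mix proportional to the mapped study region's cell counts
  (335/496/202/44/8 over 1,085); the study runner instead mixes
  proportionally to the 48/48/48/20/48 sampling design so the 212 labeled
  cells always exist;
* one RNG stream per region (rivers → roads → cells row-major), so a
  (config, seed) pair is bit-identical across runs.

Per-archetype class fractions are judgment calls exposed in the recipes,
not claims about the real region, which publishes only qualitative
patterns. What the generator does **not** emulate: radiometric or seasonal
variation, classification noise in the input land-cover map, real
hydrology and topography, mixed or transitional cells, and spatial
autocorrelation between neighboring cells of different types. Passing
tests therefore show that the metric definitions, the rules and the
classifier chain are implemented correctly and can recover clean
archetypes; they do not show field-level accuracy on real imagery — the
synthetic classes are far more separable than real landscapes (held-out
accuracy here saturates at 1.0 and boosting stops at the first iteration,
where a real study stabilizes only after several cycles with interim
errors of a few percent).

## Cell-space details

Pixel-center membership with half-open cell intervals [x₀, x₀+L) ×
[y₀, y₀+L): every pixel contributes to exactly one cell and per-class
pixel counts sum to the whole-raster counts. Border cells may extend past
the raster and are masked at the edge. Cells with ≥ 90% hydrography +
nodata (configurable) are flagged *unmapped* and excluded from
classification and from share denominators — a declared surrogate for the
gap between cells generated and cells mapped in a real region with wide
open water, not a reconstruction of any particular exclusion rule.

## Problem sizes and numerical choices

The study runner uses a 30 × 30 km region (225 cells of 200 × 200 px),
the smallest grid hosting the 212-cell sampling design with margin;
generation plus feature extraction takes a few seconds. Equality tests
against the brute-force oracle run exact (no tolerance) on rasters up to
8 × 8; float comparisons elsewhere use pytest's default relative
tolerance. Degenerate inputs are errors, not warnings: empty training
sets, train fractions outside (0, 1), classes with fewer than two samples,
mismatched raster frames, unknown class codes (reported with the offending
pixel), zero mapped cells.

## Known limitations

* The acai rules are a regional indicator, not a species distribution
  model; the hydro-topographic surrogate ignores real terrain.
* Establishment geometry is rectangular and cell-aligned; real cadastral
  parcels straddle cells.
* IJI follows the class-level focal-class formulation; cells dominated by
  one or two classes yield sentinels by design.
* The confusion-percentage ambiguity (share of reference class vs share of
  all test cells) is resolved by emitting both rates.
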