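"""Synthetic region generator realizing the five PLU landscape archetypes.

The generator produces everything the pipeline consumes — a categorical
land-cover raster, a hydro-topographic raster, river and road polylines,
rural-establishment polygons and ground-truth PLU labels per grid cell — so
every downstream stage is testable without any external data.

Archetypes (one per PLU type) are parameterized recipes over a cell:

* **PLU1** (extractivist peasant): river-anchored; forest-dominated with a
  few isolated advanced-secondary-vegetation patches; no agriculture. The
  river band makes the hydro-topography lowland/transition, so most of the
  cell becomes high acai potential after unification.
* **PLU2** (agro-extractivist peasant with temporary agriculture): as PLU1
  plus small irregular plots of small-scale agriculture (0.5-2 ha) and
  small fragments of initial secondary vegetation.
* **PLU3** (peasant mosaic): upland; mosaic of small-scale agriculture,
  initial secondary vegetation and small irregular pastures over forest.
* **PLU4** (capitalist irrigated acai): upland, road-anchored; rectangular
  large-scale-agriculture blocks dominate; establishments exceed 280 ha.
* **PLU5** (capitalist cattle): upland; rectangular herbaceous/shrub
  pasture with isolated forest fragments; establishments exceed 280 ha.

Cells are assigned to archetypes column-by-column from the river side
(PLU1 nearest, PLU5 farthest), which guarantees the riverine context of the
peasant units and the road-side upland context of the capitalist ones. One
RNG stream per region, seeded explicitly, is consumed in a documented
order (rivers, roads, then cells row-major), so identical configs with the
same seed are bit-identical.

Peasant plots follow the regional plot-size regime (0.5-2 ha); capitalist
blocks run from 2 ha up to 200 ha or more; peasant establishments stay
below 280 ha while capitalist establishments exceed it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Polygon

from . import io as pio
from .cellspace import CellGrid, build_cell_grid
from .core import (
    LANDCOVER_CODES,
    NODATA,
    PLU_CLASSES,
    Raster,
    VectorLayer,
    ZONE_CODES,
    hydrotopo_legend,
    landcover_legend,
)

_AGPE = LANDCOVER_CODES["small_scale_ag"]
_AGLE = LANDCOVER_CODES["large_scale_ag"]
_PL = LANDCOVER_CODES["herb_pasture"]
_PS = LANDCOVER_CODES["shrub_pasture"]
_VSI = LANDCOVER_CODES["init_sec_veg"]
_VSA = LANDCOVER_CODES["adv_sec_veg"]
_HID = LANDCOVER_CODES["hydrography"]
_FLO = LANDCOVER_CODES["forest"]

#: cell shares per PLU reproducing the study region's mapped proportions
DEFAULT_PLU_MIX: dict[str, float] = {
    "PLU1": 335 / 1085,
    "PLU2": 496 / 1085,
    "PLU3": 202 / 1085,
    "PLU4": 44 / 1085,
    "PLU5": 8 / 1085,
}


@dataclass
class ArchetypeRecipe:
    """Per-cell composition rules for one PLU archetype."""

    base_class: int
    river: bool = False
    road: bool = False
    # (class, n_patches_range, patch_ha_range, rectangular)
    patches: list[tuple[int, tuple[int, int], tuple[float, float], bool]] = field(
        default_factory=list
    )
    # dominant rectangular blocks laid out on a 2x2 slot grid (capitalist
    # archetypes): class code and per-slot fill fraction range
    block_fill_class: int | None = None
    block_fill_frac: tuple[float, float] = (0.6, 0.85)
    n_establishments: tuple[int, int] = (0, 0)
    establishment_ha: tuple[float, float] = (0.0, 0.0)
    capitalist_establishment: bool = False


def default_recipes(
    peasant_plot_ha: tuple[float, float],
    capitalist_plot_ha: tuple[float, float],
) -> dict[str, ArchetypeRecipe]:
    lo, hi = peasant_plot_ha
    return {
        "PLU1": ArchetypeRecipe(
            base_class=_FLO,
            river=True,
            patches=[(_VSA, (2, 4), (lo, hi), False)],
            n_establishments=(6, 10),
            establishment_ha=(2.0, 12.0),
        ),
        "PLU2": ArchetypeRecipe(
            base_class=_FLO,
            river=True,
            patches=[
                (_AGPE, (4, 8), (lo, hi), False),
                (_VSA, (2, 3), (lo, hi), False),
                (_VSI, (2, 4), (0.3, 1.0), False),
            ],
            n_establishments=(6, 10),
            establishment_ha=(2.0, 12.0),
        ),
        "PLU3": ArchetypeRecipe(
            base_class=_FLO,
            patches=[
                (_AGPE, (15, 25), (lo, hi), False),
                (_VSI, (8, 14), (lo, hi), False),
                (_PL, (2, 4), (0.5, 3.0), False),
                (_PS, (1, 2), (0.5, 2.0), False),
            ],
            n_establishments=(3, 5),
            establishment_ha=(2.0, 12.0),
        ),
        "PLU4": ArchetypeRecipe(
            base_class=_VSI,
            road=True,
            block_fill_class=_AGLE,
            block_fill_frac=(0.6, 0.85),
            patches=[(_FLO, (1, 2), (1.0, 4.0), False)],
            n_establishments=(1, 1),
            capitalist_establishment=True,
        ),
        "PLU5": ArchetypeRecipe(
            base_class=_PL,
            road=True,
            patches=[
                (_PS, (2, 3), (10.0, 40.0), True),
                (_FLO, (1, 3), (1.0, 5.0), False),
            ],
            n_establishments=(1, 1),
            capitalist_establishment=True,
        ),
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic region."""

    extent_m: tuple[float, float] = (16_000.0, 16_000.0)
    resolution_m: float = 10.0
    cell_size_m: float = 2_000.0
    plu_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLU_MIX))
    peasant_plot_ha_range: tuple[float, float] = (0.5, 2.0)
    capitalist_plot_ha_range: tuple[float, float] = (2.0, 200.0)
    establishment_max_ha_peasant: float = 280.0
    river_density: float = 1.0  # polylines per riverine cell-column run
    hydrotopo_bands_m: tuple[float, float, float] = (400.0, 900.0, 1500.0)
    river_halfwidth_m: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.plu_mix.values()) - 1.0) > 1e-9:
            raise ValueError("plu_mix must sum to 1")
        if any(v < 0 for v in self.plu_mix.values()):
            raise ValueError("plu_mix shares must be non-negative")
        if self.resolution_m <= 0 or self.cell_size_m <= 0:
            raise ValueError("resolution and cell size must be positive")
        ratio = self.cell_size_m / self.resolution_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("resolution_m must divide cell_size_m")
        for rng_pair in (self.peasant_plot_ha_range, self.capitalist_plot_ha_range):
            if rng_pair[0] <= 0 or rng_pair[1] < rng_pair[0]:
                raise ValueError("plot-size ranges must be positive and ordered")
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")


@dataclass
class SyntheticRegion:
    landcover: Raster
    hydrotopo: Raster
    rivers: VectorLayer
    roads: VectorLayer
    establishments: VectorLayer
    truth_labels: dict[int, str]
    grid: CellGrid
    config: SimulationConfig


def apportion_cells(n_cells: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment; every positive share gets >= 1 cell."""
    positive = {k: v for k, v in mix.items() if v > 0}
    if n_cells < len(positive):
        raise ValueError(
            f"extent too small: {n_cells} cells cannot host {len(positive)} PLU types"
        )
    quotas = {k: n_cells * v for k, v in positive.items()}
    counts = {k: max(1, math.floor(q)) for k, q in quotas.items()}
    while sum(counts.values()) > n_cells:  # floor-1 rule may overshoot on tiny grids
        k = max(counts, key=lambda c: (counts[c] - quotas[c], c))
        counts[k] -= 1
    remainders = sorted(
        positive, key=lambda k: (quotas[k] - counts[k], k), reverse=True
    )
    i = 0
    while sum(counts.values()) < n_cells:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    return {k: counts.get(k, 0) for k in mix}


def _grow_blob(
    free: np.ndarray, occupied: np.ndarray, n_pixels: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Grow a random-walk blob of exactly n_pixels on free, non-adjacent pixels.

    Returns an (n, 2) array of (row, col) or None when no placement fits.
    ``occupied`` marks same-class pixels whose 8-neighborhood must be avoided
    so separately placed patches never merge.
    """
    h, w = free.shape
    blocked = ndimage.binary_dilation(occupied, structure=np.ones((3, 3), bool))
    allowed = free & ~blocked
    allowed[0, :] = allowed[-1, :] = allowed[:, 0] = allowed[:, -1] = False
    candidates = np.argwhere(allowed)
    if len(candidates) == 0:
        return None
    for _ in range(25):
        seed_r, seed_c = candidates[rng.integers(len(candidates))]
        taken = {(int(seed_r), int(seed_c))}
        frontier = []

        def push(r: int, c: int) -> None:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and allowed[rr, cc] and (rr, cc) not in taken:
                    frontier.append((rr, cc))

        push(int(seed_r), int(seed_c))
        while len(taken) < n_pixels and frontier:
            idx = rng.integers(len(frontier))
            r, c = frontier.pop(int(idx))
            if (r, c) in taken or not allowed[r, c]:
                continue
            taken.add((r, c))
            push(r, c)
        if len(taken) == n_pixels:
            return np.array(sorted(taken))
    return None


def _place_rectangle(
    free: np.ndarray, occupied: np.ndarray, n_pixels: int, rng: np.random.Generator
) -> tuple[slice, slice] | None:
    """Find a free axis-aligned rectangle of ~n_pixels (exact when possible)."""
    h, w = free.shape
    blocked = ndimage.binary_dilation(occupied, structure=np.ones((3, 3), bool))
    usable = free & ~blocked
    for _ in range(40):
        aspect = rng.uniform(0.6, 1.6)
        rh = max(2, int(round(math.sqrt(n_pixels * aspect))))
        rw = max(2, int(round(n_pixels / rh)))
        if rh >= h - 2 or rw >= w - 2:
            continue
        r0 = int(rng.integers(1, h - rh - 1))
        c0 = int(rng.integers(1, w - rw - 1))
        window = usable[r0 : r0 + rh, c0 : c0 + rw]
        if window.all():
            return slice(r0, r0 + rh), slice(c0, c0 + rw)
    return None


def _river_path(
    x_center: float, y_lo: float, y_hi: float, rng: np.random.Generator
) -> LineString:
    """Gently meandering north-south polyline."""
    amplitude = rng.uniform(40.0, 120.0)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    wavelength = rng.uniform(1_500.0, 3_000.0)
    ys = np.arange(y_lo, y_hi + 1.0, 100.0)
    xs = x_center + amplitude * np.sin(2.0 * math.pi * ys / wavelength + phase)
    return LineString(np.column_stack([xs, ys]))


def generate_region(config: SimulationConfig) -> SyntheticRegion:
    """Generate one labeled synthetic region from its configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    res = config.resolution_m
    width, height = config.extent_m
    grid = build_cell_grid((width, height), config.cell_size_m)
    n_cells = len(grid)

    counts = apportion_cells(n_cells, config.plu_mix)
    # assign archetypes column-major from the river (west) side
    ordered_cells = sorted(grid, key=lambda c: (c.col, c.row))
    labels: dict[int, str] = {}
    cursor = 0
    for plu in PLU_CLASSES:
        for _ in range(counts.get(plu, 0)):
            labels[ordered_cells[cursor].cell_id] = plu
            cursor += 1

    recipes = default_recipes(
        config.peasant_plot_ha_range, config.capitalist_plot_ha_range
    )
    riverine_cols = sorted(
        {c.col for c in grid if recipes[labels[c.cell_id]].river}
    )
    road_cols = sorted({c.col for c in grid if recipes[labels[c.cell_id]].road})

    # 1. rivers: one meandering polyline per contiguous riverine run per column
    rivers: list[LineString] = []
    for col in riverine_cols:
        rows = sorted(c.row for c in grid if c.col == col and recipes[labels[c.cell_id]].river)
        runs: list[list[int]] = [[rows[0]]]
        for r in rows[1:]:
            (runs[-1].append(r) if r == runs[-1][-1] + 1 else runs.append([r]))
        for run in runs:
            top_cell = next(c for c in grid if c.col == col and c.row == run[0])
            bot_cell = next(c for c in grid if c.col == col and c.row == run[-1])
            x_center = (top_cell.bounds[0] + top_cell.bounds[2]) / 2.0
            y_lo, y_hi = bot_cell.bounds[1], top_cell.bounds[3]
            rivers.append(_river_path(x_center, y_lo, y_hi, rng))

    # 2. roads: straight north-south polylines along capitalist columns
    roads: list[LineString] = []
    for col in road_cols:
        cells = [c for c in grid if c.col == col and recipes[labels[c.cell_id]].road]
        x = (cells[0].bounds[0] + cells[0].bounds[2]) / 2.0 + rng.uniform(-200.0, 200.0)
        y_lo = min(c.bounds[1] for c in cells)
        y_hi = max(c.bounds[3] for c in cells)
        roads.append(LineString([(x, y_lo), (x, y_hi)]))

    n_rows_px = int(round(height / res))
    n_cols_px = int(round(width / res))
    landcover = np.full((n_rows_px, n_cols_px), NODATA, dtype=np.uint8)
    px_per_ha = 10_000.0 / res**2
    span = int(round(config.cell_size_m / res))
    y_top = height

    establishments: list[Polygon] = []
    est_props: list[dict] = []

    # 3. cell content, row-major so the RNG order is reproducible
    for cell in grid:
        plu = labels[cell.cell_id]
        recipe = recipes[plu]
        r0 = int(round((y_top - cell.bounds[3]) / res))
        c0 = int(round(cell.bounds[0] / res))
        r1, c1 = min(r0 + span, n_rows_px), min(c0 + span, n_cols_px)
        window = np.full((r1 - r0, c1 - c0), recipe.base_class, dtype=np.uint8)

        # river pixels first so nothing overwrites the channel
        if recipe.river:
            for line in rivers:
                xs, ys = np.asarray(line.coords)[:, 0], np.asarray(line.coords)[:, 1]
                for rr in range(window.shape[0]):
                    y = y_top - (r0 + rr + 0.5) * res
                    if y < ys.min() or y > ys.max():
                        continue
                    x_river = float(np.interp(y, ys, xs))
                    lo_px = int(math.floor((x_river - config.river_halfwidth_m) / res)) - c0
                    hi_px = int(math.ceil((x_river + config.river_halfwidth_m) / res)) - c0
                    lo_px, hi_px = max(lo_px, 0), min(hi_px, window.shape[1])
                    if lo_px < hi_px:
                        window[rr, lo_px:hi_px] = _HID
        free = window == recipe.base_class

        if recipe.block_fill_class is not None:
            # dominant rectangular blocks, one per 2x2 slot, 1-px gaps so
            # the blocks stay separate patches
            n_side = 2
            sh, sw = window.shape[0] // n_side, window.shape[1] // n_side
            for qr in range(n_side):
                for qc in range(n_side):
                    frac = float(rng.uniform(*recipe.block_fill_frac))
                    aspect = float(rng.uniform(0.9, 1.1))
                    bh = min(sh - 2, max(2, int(round(sh * math.sqrt(frac) * aspect))))
                    bw = min(sw - 2, max(2, int(round(sw * math.sqrt(frac) / aspect))))
                    orr = qr * sh + int(rng.integers(1, sh - bh))
                    occ = qc * sw + int(rng.integers(1, sw - bw))
                    sl = (slice(orr, orr + bh), slice(occ, occ + bw))
                    window[sl] = recipe.block_fill_class
                    free[sl] = False

        for cls, n_range, ha_range, rectangular in recipe.patches:
            n_patches = int(rng.integers(n_range[0], n_range[1] + 1))
            occupied = window == cls
            for _ in range(n_patches):
                target_ha = float(rng.uniform(*ha_range))
                n_pixels = max(4, int(round(target_ha * px_per_ha)))
                if rectangular:
                    found = _place_rectangle(free, occupied, n_pixels, rng)
                    if found is None:
                        raise RuntimeError(
                            f"could not place a {cls} block of {target_ha:.1f} ha in cell "
                            f"{cell.cell_id} ({plu})"
                        )
                    window[found] = cls
                    free[found] = False
                    occupied[found] = True
                else:
                    blob = _grow_blob(free, occupied, n_pixels, rng)
                    if blob is None:
                        raise RuntimeError(
                            f"could not place a {cls} patch of {target_ha:.1f} ha in cell "
                            f"{cell.cell_id} ({plu})"
                        )
                    window[blob[:, 0], blob[:, 1]] = cls
                    free[blob[:, 0], blob[:, 1]] = False
                    occupied[blob[:, 0], blob[:, 1]] = True

        landcover[r0:r1, c0:c1] = window

        # establishments: disjoint sub-slots guarantee non-overlap
        xmin, ymin, xmax, ymax = cell.bounds
        if recipe.capitalist_establishment:
            inset = config.cell_size_m * rng.uniform(0.02, 0.05)
            poly = Polygon(
                [
                    (xmin + inset, ymin + inset),
                    (xmax - inset, ymin + inset),
                    (xmax - inset, ymax - inset),
                    (xmin + inset, ymax - inset),
                ]
            )
            establishments.append(poly)
            est_props.append({"area_ha": poly.area / 10_000.0, "cell_id": cell.cell_id})
        elif recipe.n_establishments[1] > 0:
            n_est = int(
                rng.integers(recipe.n_establishments[0], recipe.n_establishments[1] + 1)
            )
            n_slots = 5
            slot = config.cell_size_m / n_slots
            chosen = rng.choice(n_slots * n_slots, size=n_est, replace=False)
            for s in chosen:
                sr, sc = divmod(int(s), n_slots)
                ha = float(rng.uniform(*recipe.establishment_ha))
                if ha > config.establishment_max_ha_peasant:
                    ha = config.establishment_max_ha_peasant
                side = math.sqrt(ha * 10_000.0)
                side = min(side, slot * 0.9)
                ox = xmin + sc * slot + rng.uniform(0, slot - side)
                oy = ymin + sr * slot + rng.uniform(0, slot - side)
                poly = Polygon(
                    [(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)]
                )
                if poly.area <= 0:
                    raise ValueError("zero-area establishment generated")
                establishments.append(poly)
                est_props.append(
                    {"area_ha": poly.area / 10_000.0, "cell_id": cell.cell_id}
                )

    # 4. hydro-topography: distance-to-river bands (lowland nearest the river)
    river_mask = landcover == _HID
    if river_mask.any():
        dist_px = ndimage.distance_transform_edt(~river_mask)
        dist_m = dist_px * res
    else:
        dist_m = np.full(landcover.shape, np.inf)
    b1, b2, b3 = config.hydrotopo_bands_m
    hydro = np.full(landcover.shape, ZONE_CODES["upland"], dtype=np.uint8)
    hydro[dist_m <= b3] = ZONE_CODES["slope"]
    hydro[dist_m <= b2] = ZONE_CODES["transition"]
    hydro[dist_m <= b1] = ZONE_CODES["lowland"]

    landcover_raster = Raster(landcover, (0.0, 0.0), res, NODATA)
    hydro_raster = Raster(hydro, (0.0, 0.0), res, NODATA)
    return SyntheticRegion(
        landcover=landcover_raster,
        hydrotopo=hydro_raster,
        rivers=VectorLayer(rivers, [{"river_id": i} for i in range(len(rivers))]),
        roads=VectorLayer(roads, [{"road_id": i} for i in range(len(roads))]),
        establishments=VectorLayer(establishments, est_props),
        truth_labels=labels,
        grid=grid,
        config=config,
    )


def sample_training_cells(
    truth_labels: dict[int, str],
    per_class: dict[str, int],
    seed: int = 0,
) -> dict[int, str]:
    """Draw a labeled sample of cells matching per-class counts."""
    rng = np.random.default_rng(seed)
    sample: dict[int, str] = {}
    for plu in sorted(per_class):
        ids = sorted(cid for cid, lab in truth_labels.items() if lab == plu)
        if len(ids) < per_class[plu]:
            raise ValueError(
                f"region has only {len(ids)} {plu} cells, need {per_class[plu]}"
            )
        chosen = rng.choice(ids, size=per_class[plu], replace=False)
        for cid in chosen:
            sample[int(cid)] = plu
    return sample


def export_region(region: SyntheticRegion, directory: str | Path) -> dict[str, Path]:
    """Write the region as text artifacts that round-trip through the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for geom, props in region.establishments:
        if geom.area <= 0:
            raise ValueError("zero-area establishment in region")
    paths = {
        "landcover": pio.write_ascii_grid(region.landcover, directory / "landcover.asc"),
        "hydrotopo": pio.write_ascii_grid(region.hydrotopo, directory / "hydrotopo.asc"),
        "rivers": pio.write_geojson(region.rivers, directory / "rivers.geojson"),
        "roads": pio.write_geojson(region.roads, directory / "roads.geojson"),
        "establishments": pio.write_geojson(
            region.establishments, directory / "establishments.geojson"
        ),
        "truth_labels": pio.write_labels_csv(
            region.truth_labels, directory / "truth_labels.csv"
        ),
        "landcover_legend": pio.write_legend(
            landcover_legend(), directory / "landcover_legend.yaml"
        ),
        "hydrotopo_legend": pio.write_legend(
            hydrotopo_legend(), directory / "hydrotopo_legend.yaml"
        ),
    }
    cfg = {
        "extent_m": list(region.config.extent_m),
        "resolution_m": region.config.resolution_m,
        "cell_size_m": region.config.cell_size_m,
        "plu_mix": dict(region.config.plu_mix),
        "seed": region.config.seed,
    }
    paths["provenance"] = pio.write_provenance(
        directory / "provenance.json", config=cfg, seed=region.config.seed
    )
    return paths
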