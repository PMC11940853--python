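"""Square cell grid over a region and assignment of content to cells.

The grid is the unit of landscape representation: each cell (2 x 2 km by
default) is treated as a small landscape whose composition, structure and
context are later summarized into the classifier's feature vector. Cells
tile the extent with half-open intervals so every raster pixel contributes
to exactly one cell (pixel-center rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .core import LANDCOVER_CODES, Raster, VectorLayer


@dataclass(frozen=True)
class Cell:
    cell_id: int
    row: int
    col: int
    bounds: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)

    @property
    def centroid(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.bounds
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)

    @property
    def box(self):
        return box(*self.bounds)


@dataclass
class CellGrid:
    """Row-major grid of square cells; row 0 is the northernmost band."""

    cell_size_m: float
    origin: tuple[float, float]  # lower-left corner of the gridded extent
    extent_m: tuple[float, float]
    n_rows: int
    n_cols: int
    cells: list[Cell] = field(default_factory=list)

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: int) -> Cell:
        return self.cells[cell_id]


def build_cell_grid(
    extent_m: tuple[float, float],
    cell_size_m: float = 2000.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> CellGrid:
    """Tile an extent with ceil(width/L) x ceil(height/L) square cells.

    Border cells may extend past the extent; raster content there is simply
    masked at the raster edge. Cell ids are row-major from the north-west
    corner and are stable for a given extent and cell size.
    """
    width, height = extent_m
    if width <= 0 or height <= 0 or cell_size_m <= 0:
        raise ValueError("extent and cell size must be positive")
    n_cols = math.ceil(width / cell_size_m)
    n_rows = math.ceil(height / cell_size_m)
    x0, y0 = origin
    y_top = y0 + height
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cell_id = r * n_cols + c
            xmin = x0 + c * cell_size_m
            ymax = y_top - r * cell_size_m
            cells.append(
                Cell(cell_id, r, c, (xmin, ymax - cell_size_m, xmin + cell_size_m, ymax))
            )
    return CellGrid(cell_size_m, origin, (width, height), n_rows, n_cols, cells)


@dataclass
class CellContent:
    """Raster and vector content clipped to one cell."""

    cell_id: int
    window: np.ndarray  # categorical pixels of the cell (may be clipped at edges)
    census: dict[int, int]  # class code -> pixel count (nodata excluded)
    nodata_count: int
    rivers: VectorLayer
    roads: VectorLayer
    establishments: VectorLayer  # features intersecting the cell (unclipped)

    @property
    def n_pixels(self) -> int:
        return int(self.window.size)


def raster_window(grid: CellGrid, raster: Raster, cell: Cell) -> np.ndarray:
    """Pixels whose centers fall inside the cell's half-open bounds."""
    res = raster.resolution_m
    n_rows_px, n_cols_px = raster.shape
    xmin, _, _, ymax = cell.bounds
    x0 = raster.origin[0]
    y_top = raster.origin[1] + n_rows_px * res
    c0 = int(round((xmin - x0) / res))
    r0 = int(round((y_top - ymax) / res))
    span = int(round(grid.cell_size_m / res))
    r1 = min(r0 + span, n_rows_px)
    c1 = min(c0 + span, n_cols_px)
    r0 = max(r0, 0)
    c0 = max(c0, 0)
    return raster.data[r0:r1, c0:c1]


def assign_cell_content(
    grid: CellGrid,
    unified: Raster,
    rivers: VectorLayer | None = None,
    roads: VectorLayer | None = None,
    establishments: VectorLayer | None = None,
) -> dict[int, CellContent]:
    """Clip raster and vector content to every cell of the grid.

    Raster pixels follow the pixel-center rule (each pixel in exactly one
    cell); polylines are clipped to cell bounds; establishment polygons are
    attached to every cell they intersect, keeping their full ``area_ha``.
    """
    if grid.cell_size_m % unified.resolution_m != 0:
        raise ValueError("raster resolution must divide the cell size")
    rivers = rivers or VectorLayer()
    roads = roads or VectorLayer()
    establishments = establishments or VectorLayer()
    contents: dict[int, CellContent] = {}
    for cell in grid:
        window = raster_window(grid, unified, cell)
        codes, counts = np.unique(window, return_counts=True)
        census = {int(k): int(v) for k, v in zip(codes, counts) if k != unified.nodata}
        nodata_count = int(window.size - sum(census.values()))
        cbox = cell.box
        cell_rivers = VectorLayer(
            [g.intersection(cbox) for g, _ in rivers if g.intersects(cbox)]
        )
        cell_roads = VectorLayer(
            [g.intersection(cbox) for g, _ in roads if g.intersects(cbox)]
        )
        est_geoms, est_props = [], []
        for g, props in establishments:
            if g.intersects(cbox):
                est_geoms.append(g)
                est_props.append(props)
        contents[cell.cell_id] = CellContent(
            cell_id=cell.cell_id,
            window=window,
            census=census,
            nodata_count=nodata_count,
            rivers=cell_rivers,
            roads=cell_roads,
            establishments=VectorLayer(est_geoms, est_props),
        )
    return contents


def unmapped_cells(
    contents: dict[int, CellContent],
    *,
    threshold: float = 0.9,
) -> set[int]:
    """Cells dominated by hydrography + nodata, excluded from classification.

    A cell is flagged unmapped when at least ``threshold`` of its pixels are
    open water or unobserved — such cells carry no terrestrial production
    landscape to classify.
    """
    hid = LANDCOVER_CODES["hydrography"]
    flagged = set()
    for cid, content in contents.items():
        if content.n_pixels == 0:
            flagged.add(cid)
            continue
        wet = content.census.get(hid, 0) + content.nodata_count
        if wet / content.n_pixels >= threshold:
            flagged.add(cid)
    return flagged


def grid_to_vector(grid: CellGrid) -> VectorLayer:
    """Grid cells as GeoJSON-ready polygons carrying their cell_id."""
    return VectorLayer(
        geometries=[cell.box for cell in grid],
        properties=[{"cell_id": cell.cell_id, "row": cell.row, "col": cell.col} for cell in grid],
    )


def grid_summary_frame(grid: CellGrid) -> pd.DataFrame:
    rows = [
        {"cell_id": c.cell_id, "row": c.row, "col": c.col, **dict(zip(("xmin", "ymin", "xmax", "ymax"), c.bounds))}
        for c in grid
    ]
    return pd.DataFrame(rows)
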