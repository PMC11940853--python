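"""Per-cell landscape composition, structure and context metrics.

Each grid cell is treated as its own small landscape and summarized with
class-level metrics in the FRAGSTATS raster dialect:

* ``CA``     class area (ha),
* ``PD``     patch density (patches per 100 ha of cell),
* ``MPS``    mean patch size (ha),
* ``LSI``    landscape shape index, ``0.25 * E / sqrt(A)`` with ``E`` the
  total class edge length (m) and ``A`` the class area (m^2); exactly 1 for
  a single square patch,
* ``AWMPFD`` area-weighted mean patch fractal dimension,
  ``sum_j (2 ln(0.25 p_j) / ln a_j) * a_j / sum_k a_k``,
* ``IJI``    interspersion-juxtaposition index of the focal class's edges
  against the other classes present in the cell (percent, 100 = maximum
  entropy),
* ``TABO``   area of the largest object (patch) of the class (ha),

plus context metrics: minimum distance from the cell centroid to rivers
(``HID_min``), river presence (``P_HID``), road distance (``ROD_min``),
and the count / mean size / max size of rural establishments intersecting
the cell.

Conventions (configurable): patches are 8-connected; edges are counted
between 4-adjacent pixel pairs of different classes; the window boundary
counts as edge, which keeps ``LSI >= 1`` for every nonempty class.
Metrics that are undefined for a cell (class absent; fewer than three
classes present for IJI) are encoded as the sentinel ``-1.0``, never as a
silent zero — the classifier can branch on the sentinel, and "absent" is
not conflated with "compact".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point

from .cellspace import CellContent, CellGrid
from .core import CLASS_ABBREV, LANDCOVER_CODES, Legend, VectorLayer, unified_legend

SENTINEL: float = -1.0

#: structure-metric identifiers emitted per class, in column order
CLASS_METRICS: tuple[str, ...] = ("CA", "PD", "MPS", "LSI", "AWMPFD", "IJI", "TABO")
#: context-metric identifiers, in column order
CONTEXT_METRICS: tuple[str, ...] = (
    "HID_min",
    "P_HID",
    "ROD_min",
    "N_ESTAB",
    "ESTAB_mean_ha",
    "ESTAB_max_ha",
)

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class Patch:
    """Maximal connected component of same-class pixels within one cell."""

    cell_id: int
    class_code: int
    n_pixels: int
    area_ha: float
    perimeter_m: float


def _patch_perimeters(labels: np.ndarray, n_patches: int, count_boundary: bool) -> np.ndarray:
    """Exposed 4-edges per labeled patch, in pixel-edge units."""
    perim = np.zeros(n_patches + 1, dtype=np.int64)
    if count_boundary:
        padded = np.pad(labels, 1, constant_values=0)
    else:
        padded = labels
    for axis in (0, 1):
        a = np.moveaxis(padded, axis, 0)
        front, back = a[:-1], a[1:]
        diff = front != back
        perim += np.bincount(front[diff], minlength=n_patches + 1)
        perim += np.bincount(back[diff], minlength=n_patches + 1)
    return perim[1:]


def label_patches(
    window: np.ndarray,
    *,
    connectivity: int = 8,
    resolution_m: float = 10.0,
    nodata: int = 255,
    cell_id: int = 0,
    count_boundary_edges: bool = True,
) -> list[Patch]:
    """Connected-component patches of every class present in a cell window."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if window.size == 0:
        return []
    patches: list[Patch] = []
    px_area_ha = resolution_m**2 / 10_000.0
    for code in sorted(int(c) for c in np.unique(window) if c != nodata):
        mask = window == code
        labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
        sizes = np.bincount(labels.ravel())[1:]
        perims = _patch_perimeters(labels, n, count_boundary_edges)
        for j in range(n):
            patches.append(
                Patch(
                    cell_id=cell_id,
                    class_code=code,
                    n_pixels=int(sizes[j]),
                    area_ha=float(sizes[j]) * px_area_ha,
                    perimeter_m=float(perims[j]) * resolution_m,
                )
            )
    return patches


# ---------------------------------------------------------------------------
# class-level structure metrics
# ---------------------------------------------------------------------------

def class_area(patches: list[Patch], class_code: int) -> float:
    """CA: summed patch area of the class in hectares (0 when absent)."""
    return float(sum(p.area_ha for p in patches if p.class_code == class_code))


def patch_density(patches: list[Patch], class_code: int, cell_area_ha: float) -> float:
    """PD: patches of the class per 100 ha of cell."""
    if cell_area_ha <= 0:
        raise ValueError("cell area must be positive")
    n = sum(1 for p in patches if p.class_code == class_code)
    return n / cell_area_ha * 100.0


def mean_patch_size(patches: list[Patch], class_code: int) -> float:
    """MPS: CA / NP in hectares; sentinel when the class is absent."""
    own = [p for p in patches if p.class_code == class_code]
    if not own:
        return SENTINEL
    return sum(p.area_ha for p in own) / len(own)


def landscape_shape_index(patches: list[Patch], class_code: int) -> float:
    """LSI: 0.25 * total class edge (m) / sqrt(total class area, m^2)."""
    own = [p for p in patches if p.class_code == class_code]
    if not own:
        return SENTINEL
    edge_m = sum(p.perimeter_m for p in own)
    area_m2 = sum(p.area_ha for p in own) * 10_000.0
    return 0.25 * edge_m / math.sqrt(area_m2)


def awmpfd(patches: list[Patch], class_code: int) -> float:
    """AWMPFD: area-weighted mean patch fractal dimension (1 for squares)."""
    own = [p for p in patches if p.class_code == class_code]
    if not own:
        return SENTINEL
    total = sum(p.area_ha for p in own)
    value = 0.0
    for p in own:
        a_m2 = p.area_ha * 10_000.0
        value += (2.0 * math.log(0.25 * p.perimeter_m) / math.log(a_m2)) * (p.area_ha / total)
    return value


def largest_object_area(patches: list[Patch], class_code: int) -> float:
    """TABO: area of the largest patch of the class (ha); 0 when absent."""
    own = [p.area_ha for p in patches if p.class_code == class_code]
    return max(own) if own else 0.0


def adjacency_tallies(
    window: np.ndarray, *, nodata: int = 255
) -> dict[tuple[int, int], int]:
    """Counts of 4-adjacent pixel pairs between different classes.

    Keys are unordered class pairs stored as (small code, large code); the
    window boundary and nodata pixels contribute no adjacency.
    """
    tallies: dict[tuple[int, int], int] = {}
    for axis in (0, 1):
        a = np.moveaxis(window, axis, 0)
        front, back = a[:-1], a[1:]
        mask = (front != back) & (front != nodata) & (back != nodata)
        lo = np.minimum(front[mask], back[mask]).astype(np.int64)
        hi = np.maximum(front[mask], back[mask]).astype(np.int64)
        pairs, counts = np.unique(lo * 1000 + hi, return_counts=True)
        for key, n in zip(pairs, counts):
            pair = (int(key // 1000), int(key % 1000))
            tallies[pair] = tallies.get(pair, 0) + int(n)
    return tallies


def iji(
    tallies: dict[tuple[int, int], int],
    focal_class: int,
    classes_present: set[int] | frozenset[int],
    *,
    resolution_m: float = 10.0,
) -> float:
    """IJI: entropy of the focal class's edge distribution over neighbors.

    ``100 * [-sum_k (e_k/E) ln(e_k/E)] / ln(m - 1)`` where ``e_k`` is the
    edge length shared with class ``k``, ``E`` their sum and ``m`` the
    number of classes present in the cell. Sentinel when fewer than three
    classes are present or the focal class shares no edge.
    """
    m = len(classes_present)
    if m < 3 or focal_class not in classes_present:
        return SENTINEL
    edges = {}
    for (a, b), n in tallies.items():
        if a == focal_class:
            edges[b] = edges.get(b, 0) + n
        elif b == focal_class:
            edges[a] = edges.get(a, 0) + n
    total = sum(edges.values()) * resolution_m
    if total <= 0:
        return SENTINEL
    h = 0.0
    for n in edges.values():
        share = n * resolution_m / total
        h -= share * math.log(share)
    return 100.0 * h / math.log(m - 1)


# ---------------------------------------------------------------------------
# context metrics
# ---------------------------------------------------------------------------

def context_metrics(
    cell,
    rivers: VectorLayer,
    roads: VectorLayer,
    establishments: VectorLayer,
) -> dict[str, float]:
    """Distance-to-network and establishment context for one cell.

    ``HID_min`` is the minimum Euclidean distance (m) from the cell centroid
    to any river polyline, 0 when a river crosses the cell; ``P_HID`` flags
    river presence. Establishment statistics use the polygons' ``area_ha``
    property over the features intersecting the cell. Empty layers yield the
    sentinel for distances and sizes.
    """
    centroid = Point(*cell.centroid)
    cbox = cell.box

    def _dist(layer: VectorLayer) -> tuple[float, float]:
        if len(layer) == 0:
            return SENTINEL, 0.0
        inside = any(g.intersects(cbox) for g, _ in layer)
        if inside:
            return 0.0, 1.0
        return min(g.distance(centroid) for g, _ in layer), 0.0

    hid_min, p_hid = _dist(rivers)
    rod_min, _ = _dist(roads)
    areas = [
        float(props.get("area_ha", g.area / 10_000.0))
        for g, props in establishments
        if g.intersects(cbox)
    ]
    return {
        "HID_min": hid_min,
        "P_HID": p_hid,
        "ROD_min": rod_min,
        "N_ESTAB": float(len(areas)),
        "ESTAB_mean_ha": float(np.mean(areas)) if areas else SENTINEL,
        "ESTAB_max_ha": float(max(areas)) if areas else SENTINEL,
    }


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def feature_columns(legend: Legend | None = None) -> list[str]:
    """Deterministic column inventory: metric x class cross-product + context."""
    legend = legend or unified_legend()
    columns = []
    for code in sorted(legend.codes.values()):
        abbrev = CLASS_ABBREV.get(code, f"C{code}")
        for metric in CLASS_METRICS:
            columns.append(f"{metric}_{abbrev}")
    columns.extend(CONTEXT_METRICS)
    return columns


def cell_features(
    content: CellContent,
    cell,
    *,
    legend: Legend | None = None,
    resolution_m: float = 10.0,
    connectivity: int = 8,
    nodata: int = 255,
    rivers: VectorLayer | None = None,
    roads: VectorLayer | None = None,
    establishments: VectorLayer | None = None,
) -> dict[str, float]:
    """All structure and context metrics for one cell."""
    legend = legend or unified_legend()
    patches = label_patches(
        content.window,
        connectivity=connectivity,
        resolution_m=resolution_m,
        nodata=nodata,
        cell_id=content.cell_id,
    )
    cell_area_ha = content.window.size * resolution_m**2 / 10_000.0
    tallies = adjacency_tallies(content.window, nodata=nodata)
    present = set(content.census)
    row: dict[str, float] = {}
    for code in sorted(legend.codes.values()):
        abbrev = CLASS_ABBREV.get(code, f"C{code}")
        row[f"CA_{abbrev}"] = class_area(patches, code)
        row[f"PD_{abbrev}"] = patch_density(patches, code, cell_area_ha) if cell_area_ha else SENTINEL
        row[f"MPS_{abbrev}"] = mean_patch_size(patches, code)
        row[f"LSI_{abbrev}"] = landscape_shape_index(patches, code)
        row[f"AWMPFD_{abbrev}"] = awmpfd(patches, code)
        row[f"IJI_{abbrev}"] = iji(tallies, code, present, resolution_m=resolution_m)
        row[f"TABO_{abbrev}"] = largest_object_area(patches, code)
    row.update(
        context_metrics(
            cell,
            rivers if rivers is not None else content.rivers,
            roads if roads is not None else content.roads,
            establishments if establishments is not None else content.establishments,
        )
    )
    return row


def build_feature_table(
    grid: CellGrid,
    contents: dict[int, CellContent],
    *,
    legend: Legend | None = None,
    resolution_m: float = 10.0,
    connectivity: int = 8,
    nodata: int = 255,
    rivers: VectorLayer | None = None,
    roads: VectorLayer | None = None,
) -> pd.DataFrame:
    """Cell x metric feature table with a deterministic column inventory.

    Every cell of the grid gets a row; every metric/class combination gets a
    column (undefined values carry the sentinel). Uses each cell's already
    clipped content, so a patch crossing a cell boundary contributes to each
    side separately. ``rivers``/``roads`` are the region-wide layers used
    for centroid distances (a cell far from any river still gets a finite
    ``HID_min``); when omitted, distances fall back to the per-cell clips.
    """
    legend = legend or unified_legend()
    columns = feature_columns(legend)
    rows = []
    for cell in grid:
        if cell.cell_id not in contents:
            raise ValueError(f"no content for cell {cell.cell_id}")
        rows.append(
            cell_features(
                contents[cell.cell_id],
                cell,
                legend=legend,
                resolution_m=resolution_m,
                connectivity=connectivity,
                nodata=nodata,
                rivers=rivers,
                roads=roads,
            )
        )
    table = pd.DataFrame(rows, index=[c.cell_id for c in grid])
    table.index.name = "cell_id"
    return table[columns]


def feature_schema(legend: Legend | None = None) -> dict[str, str]:
    """Units per feature column, for the CSV sidecar."""
    units = {
        "CA": "ha",
        "PD": "patches per 100 ha",
        "MPS": "ha",
        "LSI": "dimensionless",
        "AWMPFD": "dimensionless",
        "IJI": "percent",
        "TABO": "ha",
    }
    schema = {}
    for col in feature_columns(legend):
        prefix = col.split("_")[0]
        if col in CONTEXT_METRICS:
            schema[col] = {
                "HID_min": "m",
                "P_HID": "boolean",
                "ROD_min": "m",
                "N_ESTAB": "count",
                "ESTAB_mean_ha": "ha",
                "ESTAB_max_ha": "ha",
            }[col]
        else:
            schema[col] = units[prefix]
    return schema
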