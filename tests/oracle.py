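"""Independent brute-force oracle for landscape metrics.

Pure-python flood fill and edge counting, deliberately sharing no code
with plumap.metrics: used to verify the vectorized implementation exactly
on small rasters.
"""

from __future__ import annotations

import math

NEIGH4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGH8 = NEIGH4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def flood_fill_patches(window, connectivity=8, nodata=255):
    """List of (class_code, frozenset of (r, c)) connected components."""
    h = len(window)
    w = len(window[0]) if h else 0
    seen = [[False] * w for _ in range(h)]
    neigh = NEIGH8 if connectivity == 8 else NEIGH4
    patches = []
    for r in range(h):
        for c in range(w):
            if seen[r][c] or window[r][c] == nodata:
                continue
            code = window[r][c]
            stack = [(r, c)]
            seen[r][c] = True
            pixels = set()
            while stack:
                rr, cc = stack.pop()
                pixels.add((rr, cc))
                for dr, dc in neigh:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and not seen[nr][nc] and window[nr][nc] == code:
                        seen[nr][nc] = True
                        stack.append((nr, nc))
            patches.append((int(code), frozenset(pixels)))
    return patches


def patch_perimeter_px(pixels, shape, count_boundary=True):
    """Exposed 4-edges of a pixel set, in pixel-edge units."""
    h, w = shape
    edges = 0
    for r, c in pixels:
        for dr, dc in NEIGH4:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w):
                edges += 1 if count_boundary else 0
            elif (nr, nc) not in pixels:
                edges += 1
    return edges


def adjacency_edges(window, nodata=255):
    """4-adjacent different-class pixel pairs, keyed (small, large)."""
    h = len(window)
    w = len(window[0]) if h else 0
    tallies = {}
    for r in range(h):
        for c in range(w):
            a = window[r][c]
            if a == nodata:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w:
                    b = window[nr][nc]
                    if b != nodata and b != a:
                        key = (min(a, b), max(a, b))
                        tallies[key] = tallies.get(key, 0) + 1
    return tallies


def oracle_class_metrics(window, class_code, resolution_m=10.0, connectivity=8, nodata=255):
    """All class-level metrics for one class, computed the slow way."""
    window = [list(map(int, row)) for row in window]
    h, w = len(window), len(window[0])
    px_ha = resolution_m**2 / 10_000.0
    patches = [p for code, p in flood_fill_patches(window, connectivity, nodata) if code == class_code]
    n_valid = sum(1 for row in window for v in row if v != nodata)
    cell_area_ha = h * w * px_ha
    out = {"CA": sum(len(p) for p in patches) * px_ha}
    out["PD"] = len(patches) / cell_area_ha * 100.0
    out["TABO"] = max((len(p) for p in patches), default=0) * px_ha
    if not patches:
        out["MPS"] = out["LSI"] = out["AWMPFD"] = -1.0
    else:
        out["MPS"] = out["CA"] / len(patches)
        perims_m = [patch_perimeter_px(p, (h, w)) * resolution_m for p in patches]
        total_edge = sum(perims_m)
        total_area_m2 = sum(len(p) for p in patches) * resolution_m**2
        out["LSI"] = 0.25 * total_edge / math.sqrt(total_area_m2)
        total_ha = out["CA"]
        out["AWMPFD"] = sum(
            (2.0 * math.log(0.25 * pm) / math.log(len(p) * resolution_m**2))
            * (len(p) * px_ha / total_ha)
            for p, pm in zip(patches, perims_m)
        )
    # IJI
    present = {v for row in window for v in row if v != nodata}
    tallies = adjacency_edges(window, nodata)
    edges = {}
    for (a, b), n in tallies.items():
        if a == class_code:
            edges[b] = edges.get(b, 0) + n
        elif b == class_code:
            edges[a] = edges.get(a, 0) + n
    total = sum(edges.values())
    if len(present) < 3 or total == 0 or class_code not in present:
        out["IJI"] = -1.0
    else:
        h_ent = -sum((n / total) * math.log(n / total) for n in edges.values())
        out["IJI"] = 100.0 * h_ent / math.log(len(present) - 1)
    out["n_valid"] = n_valid
    return out


def shoelace_area(coords):
    """Polygon area by the shoelace formula (exterior ring coordinates)."""
    area = 0.0
    n = len(coords)
    for i in range(n):
        x1, y1 = coords[i][:2]
        x2, y2 = coords[(i + 1) % n][:2]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0
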