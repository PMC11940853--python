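"""Readers and writers for the pipeline's on-disk formats.

Rasters travel as ESRI ASCII grids (plain-text ``.asc``) with integer class
codes; vector layers as GeoJSON FeatureCollections; labels and feature
tables as CSV; legends and configuration as YAML. Every writer can attach a
provenance sidecar (tool version, config hash, seed) so outputs are
traceable without touching the payload bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .core import Legend, Raster, VectorLayer

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a categorical raster as an ESRI ASCII grid."""
    path = Path(path)
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.3f}\n"
        f"yllcorner {raster.origin[1]:.3f}\n"
        f"cellsize {raster.resolution_m:.3f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data.astype(int), fmt="%d")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=int)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise ValueError(f"grid body shape {data.shape} does not match header {expected}")
    return Raster(
        data=data,
        origin=(header["xllcorner"], header["yllcorner"]),
        resolution_m=header["cellsize"],
        nodata=int(header["nodata_value"]),
    )


def read_raster(path: str | Path, legend: Legend | None = None) -> Raster:
    """Read a categorical raster, validating codes against a legend."""
    raster = read_ascii_grid(path)
    if legend is not None:
        raster.nodata = legend.nodata
        raster.validate_codes(legend.allowed_codes())
    return raster


# ---------------------------------------------------------------------------
# vectors (GeoJSON)
# ---------------------------------------------------------------------------

def write_geojson(layer: VectorLayer, path: str | Path) -> Path:
    path = Path(path)
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in layer
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    return path


def read_geojson(path: str | Path) -> VectorLayer:
    with open(path) as fh:
        collection = json.load(fh)
    geometries = [shape(f["geometry"]) for f in collection["features"]]
    properties = [f.get("properties") or {} for f in collection["features"]]
    return VectorLayer(geometries=geometries, properties=properties)


# ---------------------------------------------------------------------------
# tables, legends, configs
# ---------------------------------------------------------------------------

def write_labels_csv(labels: dict[int, str], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {"cell_id": sorted(labels), "plu_label": [labels[k] for k in sorted(labels)]}
    )
    frame.to_csv(path, index=False)
    return path


def read_labels_csv(path: str | Path) -> dict[int, str]:
    frame = pd.read_csv(path)
    return dict(zip(frame["cell_id"].astype(int), frame["plu_label"].astype(str)))


def write_legend(legend: Legend, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "name": legend.name,
        "version": legend.version,
        "nodata": legend.nodata,
        "codes": dict(legend.codes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_legend(path: str | Path) -> Legend:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return Legend(
        name=payload["name"],
        codes={str(k): int(v) for k, v in payload["codes"].items()},
        nodata=int(payload.get("nodata", 255)),
        version=str(payload.get("version", "1")),
    )


def config_hash(config: object) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, *, config: object, seed: int | None) -> Path:
    """Write a provenance sidecar next to an output file."""
    path = Path(path)
    payload = {
        "tool": "plumap",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path
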