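"""End-to-end PLU mapping pipeline.

Stages run in a fixed order — acai potential, land-cover unification, cell
grid, feature extraction, train/test split, boosted-tree training,
prediction, accuracy assessment, map summary — and every stage's output is
written to the output directory with a provenance sidecar (tool version,
config hash, seed). A stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import acai, cellspace, classifier, evaluation, io as pio, metrics
from .classifier import BoostConfig
from .core import Raster, VectorLayer, unified_legend

log = logging.getLogger("plumap")


@dataclass
class PipelineConfig:
    landcover_path: str
    hydrotopo_path: str
    rivers_path: str | None = None
    roads_path: str | None = None
    establishments_path: str | None = None
    training_labels_path: str | None = None
    model_path: str | None = None  # skip training, predict with this model
    out_dir: str = "plu_out"
    cell_size_m: float = 2000.0
    connectivity: int = 8
    secondary_on_slope: str = "low"
    unmapped_threshold: float = 0.9
    boost: BoostConfig = field(default_factory=BoostConfig)
    seed: int = 0

    def as_dict(self) -> dict:
        payload = {k: v for k, v in vars(self).items() if k != "boost"}
        payload["boost"] = vars(self.boost)
        return payload


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    features: pd.DataFrame
    predictions: pd.Series
    model: classifier.BoostedTreeModel
    confusion: evaluation.ConfusionMatrix | None
    summary: evaluation.PLUSummary
    unmapped: set[int]
    artifacts: dict[str, Path]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc

        return inner

    return wrap


def extract_features(
    landcover: Raster,
    hydrotopo: Raster,
    rivers: VectorLayer,
    roads: VectorLayer,
    establishments: VectorLayer,
    *,
    cell_size_m: float = 2000.0,
    connectivity: int = 8,
    secondary_on_slope: str = "low",
    unmapped_threshold: float = 0.9,
):
    """Library-level shortcut: acai -> unify -> grid -> features.

    Returns ``(features, grid, unmapped_cell_ids)``.
    """
    potential = acai.classify_acai_potential(
        landcover, hydrotopo, secondary_on_slope=secondary_on_slope
    )
    unified = acai.integrate_landcover(landcover, potential)
    grid = cellspace.build_cell_grid(
        (landcover.width_m, landcover.height_m), cell_size_m, landcover.origin
    )
    contents = cellspace.assign_cell_content(grid, unified, rivers, roads, establishments)
    unmapped = cellspace.unmapped_cells(contents, threshold=unmapped_threshold)
    table = metrics.build_feature_table(
        grid,
        contents,
        resolution_m=landcover.resolution_m,
        connectivity=connectivity,
        nodata=unified.nodata,
        rivers=rivers,
        roads=roads,
    )
    return table, grid, unmapped


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    cfg_dict = config.as_dict()

    read = _stage("read_inputs")(_read_inputs)
    landcover, hydrotopo, rivers, roads, establishments = read(config)

    features, grid, unmapped = _stage("features")(extract_features)(
        landcover,
        hydrotopo,
        rivers,
        roads,
        establishments,
        cell_size_m=config.cell_size_m,
        connectivity=config.connectivity,
        secondary_on_slope=config.secondary_on_slope,
        unmapped_threshold=config.unmapped_threshold,
    )
    artifacts["features"] = out / "features.csv"
    features.to_csv(artifacts["features"], float_format="%.6f")
    with open(out / "features_schema.json", "w") as fh:
        json.dump(metrics.feature_schema(unified_legend()), fh, indent=1)
    log.info("features: %d cells x %d columns, %d unmapped", *features.shape, len(unmapped))

    confusion = None
    if config.model_path:
        model = _stage("load_model")(classifier.load_model)(config.model_path)
    else:
        if not config.training_labels_path:
            raise StageError("train", ValueError("no training labels or model supplied"))
        labels = pd.Series(pio.read_labels_csv(config.training_labels_path))
        labels = labels[~labels.index.isin(unmapped)]
        train_ids, test_ids = _stage("split")(classifier.split_samples)(
            labels, config.boost.train_frac, config.seed
        )
        model = _stage("train")(classifier.train_boosted)(
            features.loc[train_ids], labels.loc[train_ids], config.boost
        )
        artifacts["model"] = classifier.save_model(model, out / "model.json")
        test_pred = _stage("predict_test")(classifier.predict)(
            model, features.loc[test_ids]
        )
        confusion = _stage("evaluate")(evaluation.confusion_matrix)(
            labels.loc[test_ids], test_pred
        )
        artifacts["confusion"] = out / "confusion.csv"
        confusion.to_frame().to_csv(artifacts["confusion"])
        with open(out / "confusion.json", "w") as fh:
            json.dump(
                {
                    "orientation": "rows=reference, cols=predicted",
                    "classes": list(confusion.classes),
                    "counts": confusion.counts.tolist(),
                    "overall_accuracy": confusion.overall_accuracy,
                    "kappa": confusion.kappa,
                    "confusion_pct_of_reference": confusion.pairwise_confusion_pct(
                        "reference"
                    ).round(6).to_dict(),
                    "confusion_pct_of_total": confusion.pairwise_confusion_pct(
                        "total"
                    ).round(6).to_dict(),
                },
                fh,
                indent=1,
            )
        trajectory = evaluation.error_trajectory_report(model)
        artifacts["error_trajectory"] = out / "error_trajectory.csv"
        trajectory.to_csv(artifacts["error_trajectory"], index=False, float_format="%.4f")

    mapped_ids = [cid for cid in features.index if cid not in unmapped]
    predictions = _stage("predict")(classifier.predict)(model, features.loc[mapped_ids])
    artifacts["plu_map"] = pio.write_labels_csv(dict(predictions), out / "plu_map.csv")

    summary = _stage("summarize")(evaluation.summarize_plu)(
        predictions, unmapped_count=len(unmapped)
    )
    artifacts["summary"] = out / "plu_summary.csv"
    summary.to_frame().to_csv(artifacts["summary"], index=False, float_format="%.6f")
    with open(out / "plu_summary.json", "w") as fh:
        json.dump(
            {
                "counts": summary.counts,
                "shares_pct": summary.shares_pct,
                "peasant_share_pct": summary.peasant_share_pct,
                "capitalist_share_pct": summary.capitalist_share_pct,
                "mapped_cells": summary.mapped_total,
                "unmapped_cells": len(unmapped),
            },
            fh,
            indent=1,
        )
    pio.write_provenance(out / "provenance.json", config=cfg_dict, seed=config.seed)
    return PipelineResult(
        features=features,
        predictions=predictions,
        model=model,
        confusion=confusion,
        summary=summary,
        unmapped=unmapped,
        artifacts=artifacts,
    )


def _read_inputs(config: PipelineConfig):
    from .core import hydrotopo_legend, landcover_legend

    landcover = pio.read_raster(config.landcover_path, landcover_legend())
    hydrotopo = pio.read_raster(config.hydrotopo_path, hydrotopo_legend())
    rivers = pio.read_geojson(config.rivers_path) if config.rivers_path else VectorLayer()
    roads = pio.read_geojson(config.roads_path) if config.roads_path else VectorLayer()
    establishments = (
        pio.read_geojson(config.establishments_path)
        if config.establishments_path
        else VectorLayer()
    )
    return landcover, hydrotopo, rivers, roads, establishments
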