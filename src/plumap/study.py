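"""The end-to-end synthetic study: design constants and one-call runner.

Reproduces the mapping study's design on generated data: a 2 x 2 km cell
grid, a labeled sample of 212 cells (48 per PLU except 20 for PLU4, whose
landscape pattern is rarer), a stratified 70/30 train/test split, boosted
decision trees capped at 99 iterations, and a confusion-matrix assessment
on the held-out 30%.

The default region is 30 x 30 km (225 cells) with the PLU mix proportional
to the sample design, the smallest grid that can host all 212 labeled
cells with a margin; generation plus feature extraction runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classifier, evaluation
from .classifier import BoostConfig
from .pipeline import extract_features
from .synthetic import SimulationConfig, generate_region, sample_training_cells

#: labeled cells collected per PLU type
SAMPLE_DESIGN: dict[str, int] = {
    "PLU1": 48,
    "PLU2": 48,
    "PLU3": 48,
    "PLU4": 20,
    "PLU5": 48,
}
TRAIN_FRAC: float = 0.7
MAX_ITERATIONS: int = 99

#: per-PLU cell counts of the mapped study region (Mocajuba + Cametá, 2021)
STUDY_REGION_COUNTS: dict[str, int] = {
    "PLU1": 335,
    "PLU2": 496,
    "PLU3": 202,
    "PLU4": 44,
    "PLU5": 8,
}
#: grid cells generated per municipality before exclusions
CELLS_GENERATED: dict[str, int] = {"Mocajuba": 290, "Cametá": 1001}


def study_region_config(seed: int) -> SimulationConfig:
    total = sum(SAMPLE_DESIGN.values())
    return SimulationConfig(
        extent_m=(30_000.0, 30_000.0),
        plu_mix={k: v / total for k, v in SAMPLE_DESIGN.items()},
        seed=seed,
    )


@dataclass
class StudyResult:
    model: classifier.BoostedTreeModel
    confusion: evaluation.ConfusionMatrix
    summary: evaluation.PLUSummary
    features: pd.DataFrame
    truth: pd.Series
    predictions: pd.Series
    n_train: int
    n_test: int


def run_study(seed: int = 1) -> StudyResult:
    """Generate a region, train under the study design, and assess."""
    region = generate_region(study_region_config(seed))
    features, _, unmapped = extract_features(
        region.landcover,
        region.hydrotopo,
        region.rivers,
        region.roads,
        region.establishments,
    )
    truth = pd.Series(region.truth_labels)
    sample = pd.Series(
        sample_training_cells(region.truth_labels, SAMPLE_DESIGN, seed=seed)
    )
    train_ids, test_ids = classifier.split_samples(sample, TRAIN_FRAC, seed=seed)
    model = classifier.train_boosted(
        features.loc[train_ids],
        sample.loc[train_ids],
        BoostConfig(max_iter=MAX_ITERATIONS, seed=seed),
    )
    test_pred = classifier.predict(model, features.loc[test_ids])
    confusion = evaluation.confusion_matrix(sample.loc[test_ids], test_pred)
    mapped = [cid for cid in features.index if cid not in unmapped]
    predictions = classifier.predict(model, features.loc[mapped])
    summary = evaluation.summarize_plu(predictions, unmapped_count=len(unmapped))
    return StudyResult(
        model=model,
        confusion=confusion,
        summary=summary,
        features=features,
        truth=truth,
        predictions=predictions,
        n_train=len(train_ids),
        n_test=len(test_ids),
    )
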