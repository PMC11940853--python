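"""Train the boosted-tree classifier under the study design and map the region.

Samples 212 labeled cells (48 per PLU, 20 for PLU4), splits them 70/30 with
stratification, trains boosted entropy trees (at most 99 iterations), maps
every cell by majority vote and assesses the held-out 30% with a confusion
matrix and kappa.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import plumap.io as pio
from plumap import classifier
from plumap.classifier import BoostConfig
from plumap.evaluation import confusion_matrix, error_trajectory_report, summarize_plu
from plumap.study import MAX_ITERATIONS, SAMPLE_DESIGN, TRAIN_FRAC
from plumap.synthetic import sample_training_cells

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    features_path = ROOT / "scratch" / "features.csv"
    if not features_path.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    features = pd.read_csv(features_path, index_col="cell_id")
    truth = pd.Series(pio.read_labels_csv(ROOT / "scratch" / "region" / "truth_labels.csv"))

    sample = pd.Series(sample_training_cells(dict(truth), SAMPLE_DESIGN, seed=SEED))
    train_ids, test_ids = classifier.split_samples(sample, TRAIN_FRAC, seed=SEED)
    print(f"{len(sample)} labeled cells -> {len(train_ids)} train / {len(test_ids)} test")

    model = classifier.train_boosted(
        features.loc[train_ids], sample.loc[train_ids],
        BoostConfig(max_iter=MAX_ITERATIONS, seed=SEED),
    )
    classifier.save_model(model, ROOT / "scratch" / "model.json")
    trajectory = error_trajectory_report(model)
    print(f"boosting: {len(model.trees)} trees, {model.stopping_reason} at "
          f"iteration {model.stopping_iteration}; training error "
          f"{trajectory['training_error_pct'].iloc[-1]:.1f}% at stop")

    test_pred = classifier.predict(model, features.loc[test_ids])
    cm = confusion_matrix(sample.loc[test_ids], test_pred)
    print(f"held-out: overall accuracy {cm.overall_accuracy:.3f}, kappa {cm.kappa:.3f}")
    print(cm.to_frame().to_string())

    predictions = classifier.predict(model, features)
    map_summary = summarize_plu(predictions)
    truth_acc = float((predictions == truth.loc[predictions.index]).mean())
    print(f"map agreement with generator truth: {truth_acc:.3f}")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    cm.to_frame().to_csv(out / "confusion.csv")
    trajectory.to_csv(out / "error_trajectory.csv", index=False, float_format="%.4f")
    with open(out / "map_assessment.json", "w") as fh:
        json.dump(
            {
                "seed": SEED,
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "overall_accuracy": cm.overall_accuracy,
                "kappa": cm.kappa,
                "stopping_iteration": model.stopping_iteration,
                "stopping_reason": model.stopping_reason,
                "map_counts": map_summary.counts,
                "map_agreement_with_truth": truth_acc,
            },
            fh,
            indent=1,
        )


if __name__ == "__main__":
    main()
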