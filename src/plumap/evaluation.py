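"""Accuracy assessment and PLU map summaries.

Confusion matrices follow the convention rows = reference, columns =
predicted (stated in every serialized header). Overall accuracy is
``trace / total``; the kappa coefficient is the chance-corrected agreement
``(p_o - p_e) / (1 - p_e)`` with ``p_e = sum_k row_k * col_k / total^2``.
Pairwise confusion between classes is reported both as a share of the
reference class's samples and as a share of all test samples, since either
base can be meant when a single percentage is quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PLU_CLASSES


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = reference, cols = predicted
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def kappa(self) -> float:
        total = self.total
        p_o = np.trace(self.counts) / total
        p_e = float((self.counts.sum(axis=1) * self.counts.sum(axis=0)).sum()) / total**2
        if p_e == 1.0:
            return 1.0 if p_o == 1.0 else 0.0
        return float((p_o - p_e) / (1.0 - p_e))

    def producer_accuracy(self) -> pd.Series:
        """Per-class recall: diagonal over reference (row) totals."""
        rows = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(rows > 0, np.diag(self.counts) / rows, np.nan)
        return pd.Series(vals, index=list(self.classes), name="producer_accuracy")

    def user_accuracy(self) -> pd.Series:
        """Per-class precision: diagonal over predicted (column) totals."""
        cols = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cols > 0, np.diag(self.counts) / cols, np.nan)
        return pd.Series(vals, index=list(self.classes), name="user_accuracy")

    def pairwise_confusion_pct(self, base: str = "reference") -> pd.DataFrame:
        """Percent of class i samples predicted as class j.

        ``base="reference"`` divides by the row totals (share of the
        reference class); ``base="total"`` divides by all samples.
        """
        if base == "reference":
            denom = self.counts.sum(axis=1, keepdims=True).astype(float)
            denom[denom == 0] = np.nan
            vals = self.counts / denom * 100.0
        elif base == "total":
            vals = self.counts / self.total * 100.0
        else:
            raise ValueError("base must be 'reference' or 'total'")
        return pd.DataFrame(vals, index=list(self.classes), columns=list(self.classes))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))
        frame.index.name = "reference"
        frame.columns.name = "predicted"
        return frame


def confusion_matrix(
    reference: pd.Series | list,
    predicted: pd.Series | list,
    classes: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate reference against predicted labels."""
    ref = list(reference)
    pred = list(predicted)
    if len(ref) == 0:
        raise ValueError("empty label vectors")
    if len(ref) != len(pred):
        raise ValueError("reference and predicted must have equal length")
    if classes is None:
        seen = set(ref) | set(pred)
        classes = tuple(c for c in PLU_CLASSES if c in seen)
        extra = seen - set(classes)
        if extra:
            classes = classes + tuple(sorted(extra))
    index = {c: i for i, c in enumerate(classes)}
    unseen = (set(ref) | set(pred)) - set(classes)
    if unseen:
        raise ValueError(f"labels outside the class set: {sorted(unseen)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(ref, pred):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


PEASANT_PLUS: tuple[str, ...] = ("PLU1", "PLU2", "PLU3")
CAPITALIST_PLUS: tuple[str, ...] = ("PLU4", "PLU5")


@dataclass
class PLUSummary:
    counts: dict[str, int]
    unmapped_count: int = 0
    peasant_classes: tuple[str, ...] = PEASANT_PLUS
    capitalist_classes: tuple[str, ...] = CAPITALIST_PLUS
    shares_pct: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError("no mapped cells to summarize")
        self.shares_pct = {k: v / total * 100.0 for k, v in self.counts.items()}

    @property
    def mapped_total(self) -> int:
        return sum(self.counts.values())

    @property
    def peasant_share_pct(self) -> float:
        return sum(self.shares_pct.get(c, 0.0) for c in self.peasant_classes)

    @property
    def capitalist_share_pct(self) -> float:
        return sum(self.shares_pct.get(c, 0.0) for c in self.capitalist_classes)

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = [
            {
                "plu": k,
                "cells": self.counts[k],
                "share_pct": round(self.shares_pct[k], decimals)
                if decimals is not None
                else self.shares_pct[k],
            }
            for k in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def summarize_plu(
    plu_map: dict[int, str] | pd.Series | dict[str, int],
    *,
    unmapped_count: int = 0,
) -> PLUSummary:
    """Cell counts and percentage shares per PLU over the mapped cells.

    Accepts either a cell_id -> label map (labels are tallied) or an
    already tallied label -> count dict.
    """
    if isinstance(plu_map, dict) and plu_map and all(
        isinstance(v, (int, np.integer)) for v in plu_map.values()
    ):
        counts = {str(k): int(v) for k, v in plu_map.items()}
    else:
        labels = plu_map.values() if isinstance(plu_map, dict) else list(plu_map)
        counts = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return PLUSummary(counts=counts, unmapped_count=unmapped_count)


def error_trajectory_report(model) -> pd.DataFrame:
    """Per-iteration training error of a boosted model, as percentages."""
    if not getattr(model, "trees", None):
        raise ValueError("model is untrained")
    frame = pd.DataFrame(
        {
            "iteration": np.arange(1, len(model.epsilons) + 1),
            "training_error_pct": [e * 100.0 for e in model.epsilons],
        }
    )
    frame.attrs["stopping_iteration"] = model.stopping_iteration
    frame.attrs["stopping_reason"] = model.stopping_reason
    return frame
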