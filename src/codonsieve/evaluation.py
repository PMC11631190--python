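"""Scoring of ORF predictions against a reference or a synthetic truth.

Two complementary views are implemented. Reference-based categories bin
each prediction by its best translated-search hit: ``full_length`` needs a
complete ORF whose alignment covers >= 98% of both the prediction and the
reference protein; ``useful`` relaxes the reference coverage to >= 66%
(still >= 98% of the prediction itself); hits in the wrong reading
orientation are ``out_of_frame``. Label-based metrics are the usual
per-class precision / recall / F1 and their unweighted (macro) mean, with
training sequences excluded from scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .gencode import OrfRecord
from .homology import AlignmentHit


class PredictionCategory(str, Enum):
    FULL_LENGTH = "full_length"
    USEFUL = "useful"
    IN_FRAME_OTHER = "in_frame_other"
    OUT_OF_FRAME = "out_of_frame"
    NO_HIT = "no_hit"


@dataclass(frozen=True)
class MetricCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def categorize_prediction(
    hit: AlignmentHit | None, orf: OrfRecord
) -> PredictionCategory:
    """Bin one predicted ORF by its best reference hit.

    The ORF's own reading is frame +1 of its nt_seq, so a hit in any other
    frame means the prediction reads the transcript out of frame.
    """
    if hit is None:
        return PredictionCategory.NO_HIT
    if hit.qframe != 1:
        return PredictionCategory.OUT_OF_FRAME
    if hit.qcov >= 0.98 and hit.scov >= 0.98 and orf.complete:
        return PredictionCategory.FULL_LENGTH
    if hit.qcov >= 0.98 and hit.scov >= 0.66:
        return PredictionCategory.USEFUL
    return PredictionCategory.IN_FRAME_OTHER


def _precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("zero predicted positives; precision set to 0", UserWarning, stacklevel=3)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("zero actual positives; recall set to 0", UserWarning, stacklevel=3)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def score_predictions(
    predicted: Mapping[str, str],
    truth: Mapping[str, str],
    training_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-class precision/recall/F1 plus a macro-average row.

    ``predicted`` and ``truth`` map sequence id to label; ids listed in
    ``training_ids`` are excluded before tallying (training sequences are
    never scored). Classes present in either mapping are scored.
    """
    if not truth:
        raise ValueError("empty truth mapping")
    excluded = set(training_ids)
    ids = [i for i in predicted if i in truth and i not in excluded]
    classes = sorted({truth[i] for i in ids} | {predicted[i] for i in ids})
    rows = []
    f1s = []
    for cls in classes:
        tp = sum(1 for i in ids if predicted[i] == cls and truth[i] == cls)
        fp = sum(1 for i in ids if predicted[i] == cls and truth[i] != cls)
        fn = sum(1 for i in ids if predicted[i] != cls and truth[i] == cls)
        p, r, f1 = _precision_recall_f1(tp, fp, fn)
        f1s.append(f1)
        rows.append(
            {"class": cls, "tp": tp, "fp": fp, "fn": fn, "precision": p, "recall": r, "f1": f1}
        )
    macro = sum(f1s) / len(f1s) if f1s else 0.0
    rows.append(
        {
            "class": "__macro__",
            "tp": sum(r["tp"] for r in rows),
            "fp": sum(r["fp"] for r in rows),
            "fn": sum(r["fn"] for r in rows),
            "precision": float("nan"),
            "recall": float("nan"),
            "f1": macro,
        }
    )
    return pd.DataFrame(rows)


def macro_f1(predicted: Mapping[str, str], truth: Mapping[str, str], training_ids: Sequence[str] = ()) -> float:
    table = score_predictions(predicted, truth, training_ids)
    return float(table.loc[table["class"] == "__macro__", "f1"].iloc[0])


def accuracy(predicted: Mapping[str, str], truth: Mapping[str, str], training_ids: Sequence[str] = ()) -> float:
    excluded = set(training_ids)
    ids = [i for i in predicted if i in truth and i not in excluded]
    if not ids:
        raise ValueError("no scorable ids")
    return sum(1 for i in ids if predicted[i] == truth[i]) / len(ids)


def confusion_matrix(
    predicted: Mapping[str, str], truth: Mapping[str, str], training_ids: Sequence[str] = ()
) -> pd.DataFrame:
    """Truth-by-prediction count table over scorable ids."""
    excluded = set(training_ids)
    ids = [i for i in predicted if i in truth and i not in excluded]
    classes = sorted({truth[i] for i in ids} | {predicted[i] for i in ids})
    table = pd.DataFrame(0, index=classes, columns=classes)
    for i in ids:
        table.loc[truth[i], predicted[i]] += 1
    table.index.name = "truth"
    table.columns.name = "predicted"
    return table


def unique_loci(hits: Sequence[AlignmentHit], in_frame_only: bool = True) -> int:
    """Count distinct reference proteins hit by (correctly framed) predictions."""
    return len({h.sid for h in hits if (h.qframe == 1 or not in_frame_only)})
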