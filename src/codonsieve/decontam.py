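"""Supervised multiclass ORF classification ("decontamination").

Mixed assemblies — predator plus prey, host plus symbiont or pathogen,
target plus co-cultured contaminant — can be partitioned by training a
codon-composition SVC on a small user-labelled subset of the ORFs (25-100
per class is typically enough when the fingerprints differ) and
classifying everything else. Labels can come from manual curation, from
composition-window selection, or from an external taxonomic read/sequence
classifier behind a minimal id -> category adapter contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierConfig,
    OrfClassifier,
    OrfClassifierResults,
    count_matrix,
    tokenize_sequence,
)
from .preprocess import TranscriptRecord, write_fasta

TRAINING_CAP = 100
TRAINING_FLOOR = 25


@dataclass(frozen=True)
class ClassTable:
    """Validated (orf_id, label) training assignments."""

    rows: tuple[tuple[str, str], ...]
    source: str = "user"

    def __post_init__(self) -> None:
        labels = {lab for _, lab in self.rows}
        if len(labels) < 2:
            raise ValueError(f"need >= 2 classes, got {sorted(labels)}")
        seen: dict[str, str] = {}
        conflicts = []
        for oid, lab in self.rows:
            if oid in seen and seen[oid] != lab:
                conflicts.append(oid)
            seen[oid] = lab
        if conflicts:
            raise ValueError(f"conflicting duplicate labels for: {sorted(set(conflicts))}")

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.rows)

    @property
    def classes(self) -> list[str]:
        return sorted({lab for _, lab in self.rows})


def load_class_table(path, orf_ids: Sequence[str], source: str = "user") -> ClassTable:
    """Read a 2-column TSV of (orf_id, label); '#' comments allowed.

    A header line is tolerated (detected as a first row whose id is not in
    the FASTA and whose label column looks like a column name). Rows
    naming ids absent from the query FASTA are an error.
    """
    known = set(orf_ids)
    rows: list[tuple[str, str]] = []
    unknown: list[str] = []
    first_data_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            oid, label = parts[0].strip(), parts[1].strip()
            if first_data_row:
                first_data_row = False
                if oid not in known and oid.lower() in ("orf_id", "id", "seqid"):
                    continue  # header
            if oid not in known:
                unknown.append(oid)
                continue
            rows.append((oid, label))
    if unknown:
        raise ValueError(f"class table names ids absent from the FASTA: {unknown[:5]}")
    return ClassTable(rows=tuple(rows), source=source)


def external_classifier_labels(
    raw_labels: Mapping[str, str],
    cap: int = TRAINING_CAP,
    floor: int = TRAINING_FLOOR,
    seed: int = 0,
) -> ClassTable:
    """Build a training table from external taxonomic-classifier output.

    Per category a seeded random sample of min(cap, available) ids is
    taken; categories with fewer than ``floor`` ids are dropped with a
    warning. At least two categories must survive.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[str]] = {}
    for oid in sorted(raw_labels):
        by_cat.setdefault(raw_labels[oid], []).append(oid)
    rows: list[tuple[str, str]] = []
    surviving = 0
    for cat in sorted(by_cat):
        ids = by_cat[cat]
        if len(ids) < floor:
            warnings.warn(
                f"category {cat!r} has only {len(ids)} sequences (< {floor}); dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        surviving += 1
        take = min(cap, len(ids))
        picked = rng.choice(len(ids), size=take, replace=False)
        rows.extend((ids[i], cat) for i in sorted(picked))
    if surviving < 2:
        raise ValueError(
            f"fewer than 2 categories with >= {floor} sequences; cannot train"
        )
    return ClassTable(rows=tuple(rows), source="external_classifier")


def classify_dataset(
    query_orfs: Sequence[TranscriptRecord],
    class_table: ClassTable | None = None,
    model: OrfClassifierResults | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    code_table_id: int = 1,
    outdir=None,
) -> tuple[pd.DataFrame, OrfClassifierResults]:
    """Label every query ORF; train first if given a class table.

    Returns (predictions, results). Predictions columns: orf_id, label,
    one probability column per class, and a ``training`` flag; training
    ORFs are echoed with their given labels. When ``outdir`` is set,
    writes ``predictions.tsv`` plus one FASTA per class (the per-class
    files partition the input).
    """
    if class_table is None and model is None:
        raise ValueError("provide a class table to train on, or a pre-trained model")
    vectors = [tokenize_sequence(r.id, r.seq) for r in query_orfs]
    by_id = {v.orf_id: i for i, v in enumerate(vectors)}
    if model is None:
        train_labels = class_table.labels
        missing = [oid for oid in train_labels if oid not in by_id]
        if missing:
            raise ValueError(f"training ids absent from query ORFs: {missing[:5]}")
        X_train = [vectors[by_id[oid]] for oid in train_labels]
        y_train = list(train_labels.values())
        model = OrfClassifier(
            X_train, y_train, config=config, code_table_id=code_table_id
        ).fit()
        training_ids = set(train_labels)
    else:
        training_ids = set(class_table.labels) if class_table is not None else set()
        train_labels = class_table.labels if class_table is not None else {}
    X_all = count_matrix(vectors)
    proba = model.predict_proba(X_all, code_table_id=code_table_id)
    classes = [str(c) for c in model.classes_]
    pred_labels = [classes[k] for k in np.argmax(proba, axis=1)]
    table = pd.DataFrame(
        {
            "orf_id": [v.orf_id for v in vectors],
            "label": [
                train_labels.get(v.orf_id, pred)
                for v, pred in zip(vectors, pred_labels)
            ],
            "training": [v.orf_id in training_ids for v in vectors],
        }
    )
    for j, cls in enumerate(classes):
        table[f"p_{cls}"] = proba[:, j]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "predictions.tsv", sep="\t", index=False, float_format="%.6f")
        rec_by_id = {r.id: r for r in query_orfs}
        for cls in sorted(set(table["label"])):
            members = table.loc[table["label"] == cls, "orf_id"]
            write_fasta([rec_by_id[oid] for oid in members], outdir / f"{cls}.fasta")
    return table, model
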