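"""End-to-end orchestration of the two run modes.

``run_predict`` takes assembled transcripts plus a reference proteome and
produces one best ORF per transcript: preprocess (length filter, optional
rRNA screen, optional isoform clustering), enumerate candidate ORFs in all
six orientations, seed a training pool from reference-proteome homology
(in-frame positives, randomly reoriented negatives), train the codon SVC,
score every candidate's in-frame probability and keep the argmax per
transcript (ties to the longer ORF). ``run_classify`` wraps supervised
multiclass classification of an existing ORF FASTA.

Every run writes a JSON manifest (config, package version, input hashes,
counts at each stage) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .classifier import (
    ClassifierConfig,
    OrfClassifier,
    OrfClassifierResults,
    count_matrix,
    select_best_orfs,
    tokenize_codons,
)
from .decontam import ClassTable, classify_dataset
from .gencode import GeneticCode, enumerate_orfs, enumerate_partial_orfs
from .homology import SearchParams, build_training_set, run_reference_search
from .orfio import orf_table, write_orf_fasta
from .preprocess import (
    ClusteringParams,
    TranscriptRecord,
    cluster_isoforms,
    filter_by_length,
    read_fasta,
    screen_rrna,
    write_cluster_map,
    write_fasta,
)

logger = logging.getLogger("codonsieve")

EXIT_INPUT_ERROR = 2
EXIT_BACKEND_MISSING = 3

IN_FRAME = "in-frame"
OUT_OF_FRAME = "out-of-frame"


@dataclass
class RunConfig:
    """Shared knobs for an end-to-end run."""

    mode: str = "predict"
    code_table_id: int = 1
    min_transcript_len: int = 300
    min_orf_len: int = 150
    partial: bool = False
    seed: int = 42
    cluster: bool = False
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    rrna_backend: object | None = None
    search_params: SearchParams = field(default_factory=SearchParams)
    classifier: ClassifierConfig | None = None

    def classifier_config(self) -> ClassifierConfig:
        if self.classifier is not None:
            return self.classifier
        return ClassifierConfig(seed=self.seed)


def _hash_records(records: Sequence) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(r.id.encode())
        h.update(r.seq.encode())
    return h.hexdigest()[:16]


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


@dataclass
class PredictResult:
    """Everything ``run_predict`` computes, before/after writing to disk."""

    selected: dict[str, object]  # transcript_id -> OrfRecord
    candidates: pd.DataFrame  # per-candidate table with in-frame probability
    model: OrfClassifierResults
    manifest: dict


def run_predict(
    transcripts: Sequence[TranscriptRecord] | str | Path,
    protein_db: Sequence[TranscriptRecord] | str | Path,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> PredictResult:
    """Predict one best ORF per transcript, training on the dataset itself."""
    t0 = time.time()
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts)
    if isinstance(protein_db, (str, Path)):
        protein_db = read_fasta(protein_db)
    if not protein_db:
        raise ValueError("reference proteome is empty")
    code = GeneticCode.from_table_id(config.code_table_id)
    counts = {"input": len(transcripts)}

    kept = filter_by_length(transcripts, config.min_transcript_len)
    counts["after_length_filter"] = len(kept)
    if config.rrna_backend is not None:
        kept, flagged = screen_rrna(kept, config.rrna_backend)
        counts["rrna_flagged"] = len(flagged)
    cluster_map = None
    if config.cluster and kept:
        kept, cluster_map = cluster_isoforms(kept, config.clustering)
    counts["processed"] = len(kept)
    logger.info("preprocess: %s", counts)

    enumerate_fn = enumerate_partial_orfs if config.partial else enumerate_orfs
    orfs_by_transcript = {
        tr.id: enumerate_fn(tr, code, config.min_orf_len) for tr in kept
    }
    counts["candidate_orfs"] = sum(len(v) for v in orfs_by_transcript.values())

    hits = run_reference_search(kept, protein_db, config.search_params, code=code)
    counts["reference_hits"] = len(hits)
    training = build_training_set(hits, kept, code, seed=config.seed, min_len_nt=config.min_orf_len)
    counts["training_pairs"] = len(training.positives)
    counts["training_skipped"] = training.n_skipped
    if not training.positives:
        raise ValueError(
            "no training positives: no transcript aligned to the reference "
            "proteome; supply a reference proteome closer to the dataset"
        )

    vectors = [tokenize_codons(o) for o in training.positives + training.negatives]
    labels = [IN_FRAME] * len(training.positives) + [OUT_OF_FRAME] * len(training.negatives)
    results = OrfClassifier(
        vectors, labels, config=config.classifier_config(), code_table_id=config.code_table_id
    ).fit()
    logger.info("classifier: C=%g cv_accuracy=%.4f", results.best_c, results.cv_accuracy)

    in_frame_col = int(np.where(results.classes_ == IN_FRAME)[0][0])
    probabilities: dict[str, list[float]] = {}
    all_rows = []
    for tid, orfs in orfs_by_transcript.items():
        if not orfs:
            probabilities[tid] = []
            continue
        X = count_matrix([tokenize_codons(o) for o in orfs])
        p = results.predict_proba(X)[:, in_frame_col]
        probabilities[tid] = p.tolist()
    selected, n_empty = select_best_orfs(orfs_by_transcript, probabilities)
    counts["transcripts_without_candidates"] = n_empty
    counts["selected_orfs"] = len(selected)

    all_orfs = [o for orfs in orfs_by_transcript.values() for o in orfs]
    candidates = orf_table(all_orfs)
    candidates["p_in_frame"] = [
        p for tid in orfs_by_transcript for p in probabilities[tid]
    ]
    sel_keys = {
        (o.transcript_id, o.frame, o.start, o.end) for o in selected.values()
    }
    candidates["selected"] = [
        (o.transcript_id, o.frame, o.start, o.end) in sel_keys for o in all_orfs
    ]

    manifest = {
        "mode": "predict",
        "version": _pkg_version,
        "seed": config.seed,
        "code_table_id": config.code_table_id,
        "min_transcript_len": config.min_transcript_len,
        "min_orf_len": config.min_orf_len,
        "partial": config.partial,
        "input_hash": _hash_records(transcripts),
        "db_hash": _hash_records(protein_db),
        "counts": counts,
        "selected_c": results.best_c,
        "cv_accuracy": results.cv_accuracy,
    }
    logger.info("predict finished in %.1fs", time.time() - t0)
    result = PredictResult(
        selected=selected, candidates=candidates, model=results, manifest=manifest
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ordered = [selected[tid] for tid in sorted(selected)]
        write_orf_fasta(ordered, outdir / "selected_orfs.nt.fasta")
        write_orf_fasta(ordered, outdir / "selected_orfs.aa.fasta", aa=True)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False, float_format="%.6f")
        results.save(outdir / "model.cosv")
        if cluster_map is not None:
            write_cluster_map(cluster_map, outdir / "clusters.tsv")
        _write_manifest(outdir, manifest)
    return result


def run_classify(
    orfs: Sequence[TranscriptRecord] | str | Path,
    class_table: ClassTable | None = None,
    model: OrfClassifierResults | None = None,
    config: RunConfig = RunConfig(mode="classify"),
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, OrfClassifierResults]:
    """Classify an ORF FASTA from a label table or a pre-trained model."""
    t0 = time.time()
    if isinstance(orfs, (str, Path)):
        orfs = read_fasta(orfs)
    if class_table is None and model is None:
        raise ValueError("run_classify requires a class table or a pre-trained model")
    table, results = classify_dataset(
        orfs,
        class_table=class_table,
        model=model,
        config=config.classifier_config(),
        code_table_id=config.code_table_id,
        outdir=outdir,
    )
    if outdir is not None:
        outdir = Path(outdir)
        results.save(outdir / "model.cosv")
        manifest = {
            "mode": "classify",
            "version": _pkg_version,
            "seed": config.seed,
            "code_table_id": config.code_table_id,
            "input_hash": _hash_records(orfs),
            "classes": [str(c) for c in results.classes_],
            "n_training": int(table["training"].sum()),
            "n_query": int(len(table)),
        }
        _write_manifest(outdir, manifest)
    logger.info("classify finished in %.1fs", time.time() - t0)
    return table, results
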