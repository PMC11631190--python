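"""Codon-composition support-vector classification of ORFs.

The statistical core of the package: ORFs are tokenized into in-frame
codon counts over a fixed 64-codon vocabulary, and an RBF-kernel support
vector classifier is fitted to labelled examples with a seeded log-uniform
random search over the regularisation constant C in [1e-8, 10], scored by
5-fold cross-validated accuracy. Class probabilities (per-fold Platt
calibration with pairwise coupling, as implemented inside libsvm) drive
both best-ORF selection in prediction mode and multiclass assignment in
decontamination mode.

The module follows the model/results idiom: :class:`OrfClassifier` holds
data and configuration; ``fit()`` returns an :class:`OrfClassifierResults`
carrying the fitted estimator, the CV search trace, provenance metadata,
``summary()``, prediction methods and archive persistence.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
import zipfile
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .gencode import CODONS, OrfRecord

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

MIN_TRAINING_PER_CLASS = 25  # below this, accuracy can approximate chance

_ARCHIVE_FORMAT = 1

# fitted-attribute names that fully determine libsvm RBF-SVC predictions
_SVC_ARRAY_ATTRS = (
    "support_",
    "support_vectors_",
    "_n_support",
    "_dual_coef_",
    "_intercept_",
    "_probA",
    "_probB",
    "classes_",
    "class_weight_",
)


@dataclass(frozen=True)
class CodonCountVector:
    """64 raw codon counts in fixed lexicographic order for one ORF."""

    orf_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("counts must have exactly 64 entries")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)


def tokenize_codons(orf) -> CodonCountVector:
    """Count non-overlapping in-frame codons of an ORF.

    Codons containing characters outside ACGT are dropped (never counted).
    Accepts an :class:`OrfRecord` or any object with ``nt_seq``; a bare
    (id, sequence) pair also works via ``tokenize_sequence``.
    """
    seq = orf.nt_seq.upper()
    if not seq:
        raise ValueError("cannot tokenize an empty sequence")
    if len(seq) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    orf_id = getattr(orf, "id", None) or f"{orf.transcript_id}:{orf.frame}:{orf.start}"
    return tokenize_sequence(orf_id, seq)


def tokenize_sequence(orf_id: str, nt_seq: str) -> CodonCountVector:
    seq = nt_seq.upper()
    if not seq:
        raise ValueError("cannot tokenize an empty sequence")
    counts = np.zeros(64, dtype=np.int64)
    for i in range(0, len(seq) - len(seq) % 3, 3):
        idx = _CODON_INDEX.get(seq[i : i + 3])
        if idx is not None:
            counts[idx] += 1
    return CodonCountVector(orf_id=orf_id, counts=counts)


def count_matrix(vectors: Sequence[CodonCountVector]) -> np.ndarray:
    return np.vstack([v.counts for v in vectors]).astype(np.float64)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameter-search and reproducibility settings."""

    c_range: tuple[float, float] = (1e-8, 10.0)
    folds: int = 5
    n_trials: int = 25
    seed: int = 42
    gamma: str | float = "scale"
    normalize_length: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.c_range[0] <= 0 or self.c_range[1] <= 0:
            raise ValueError("C range must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


class OrfClassifier:
    """RBF-SVC model over codon-count features.

    Parameters
    ----------
    X : sequence of CodonCountVector, or (n, 64) array
    y : sequence of labels (>= 2 distinct values)
    config : ClassifierConfig
    code_table_id : NCBI translation table the features were derived under
        (recorded as provenance; mismatches are warned about at predict
        time, not silently ignored).
    """

    def __init__(self, X, y, config: ClassifierConfig = ClassifierConfig(), code_table_id: int = 1):
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], CodonCountVector):
            X = count_matrix(X)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 64:
            raise ValueError("X must be n x 64 codon counts")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes, class_counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training requires at least 2 classes")
        if class_counts.min() < 2:
            small = classes[class_counts < 2]
            raise ValueError(f"classes with < 2 examples: {list(small)}")
        if class_counts.min() < MIN_TRAINING_PER_CLASS:
            warnings.warn(
                f"smallest class has {class_counts.min()} examples; below the "
                f"recommended minimum of {MIN_TRAINING_PER_CLASS} per class, "
                "accuracy can approximate chance",
                UserWarning,
                stacklevel=2,
            )
        self.X = X
        self.y = y
        self.classes = classes
        self.config = config
        self.code_table_id = code_table_id

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label", **kwargs) -> "OrfClassifier":
        """Build from a DataFrame with 64 codon-count columns plus a label column."""
        cols = [c for c in CODONS if c in frame.columns]
        if len(cols) != 64:
            raise ValueError("DataFrame must contain all 64 codon columns")
        return cls(frame[cols].to_numpy(), frame[label_col].to_numpy(), **kwargs)

    @classmethod
    def from_orfs(cls, orfs: Sequence, labels: Sequence, **kwargs) -> "OrfClassifier":
        return cls([tokenize_codons(o) for o in orfs], labels, **kwargs)

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.config.normalize_length:
            totals = X.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            return X / totals
        return X

    def fit(self) -> "OrfClassifierResults":
        """Random-search C by mean CV accuracy, refit on all data."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        lo, hi = np.log10(cfg.c_range[0]), np.log10(cfg.c_range[1])
        c_trials = np.unique(10.0 ** rng.uniform(lo, hi, size=cfg.n_trials))
        Xf = self._features(self.X)
        folds = min(cfg.folds, int(np.bincount(pd.factorize(self.y)[0]).min()))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
        trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            for c in c_trials:
                svc = SVC(kernel="rbf", C=c, gamma=cfg.gamma, random_state=cfg.seed)
                score = cross_val_score(svc, Xf, self.y, cv=cv, scoring="accuracy").mean()
                trace.append((float(c), float(score)))
            # best mean accuracy; exact ties resolved toward larger C — at
            # vanishing C the decision values degenerate and the Platt
            # calibration behind predict_proba collapses to one class even
            # though hard CV predictions look perfect
            best_c, best_score = max(trace, key=lambda t: (t[1], t[0]))
            svc = SVC(
                kernel="rbf", C=best_c, gamma=cfg.gamma, probability=True, random_state=cfg.seed
            ).fit(Xf, self.y)
        training_hash = hashlib.sha256(
            np.ascontiguousarray(self.X).tobytes() + "|".join(map(str, self.y)).encode()
        ).hexdigest()[:16]
        return OrfClassifierResults(
            model=self,
            svc=svc,
            best_c=best_c,
            cv_accuracy=best_score,
            search_trace=trace,
            provenance={
                "version": _pkg_version,
                "seed": cfg.seed,
                "code_table_id": self.code_table_id,
                "training_hash": training_hash,
                "n_training": int(len(self.y)),
                "normalize_length": cfg.normalize_length,
            },
        )


@dataclass
class OrfClassifierResults:
    """Fitted classifier with CV diagnostics, predictions and persistence."""

    model: OrfClassifier | None
    svc: SVC
    best_c: float
    cv_accuracy: float
    search_trace: list[tuple[float, float]]
    provenance: dict

    def __post_init__(self) -> None:
        self.classes_ = np.asarray(self.svc.classes_)
        self.vocabulary = CODONS

    @property
    def code_table_id(self) -> int:
        return int(self.provenance.get("code_table_id", 1))

    def _prepare(self, X, code_table_id: int | None = None) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], CodonCountVector):
            X = count_matrix(X)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 64:
            raise ValueError(
                f"feature matrix must have 64 codon columns, got shape {X.shape}"
            )
        if code_table_id is not None and code_table_id != self.code_table_id:
            warnings.warn(
                f"model was trained under translation table {self.code_table_id} "
                f"but is being applied under table {code_table_id}",
                UserWarning,
                stacklevel=3,
            )
        if self.provenance.get("normalize_length"):
            totals = X.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            X = X / totals
        return X

    def predict_proba(self, X, code_table_id: int | None = None) -> np.ndarray:
        """Per-class probability matrix; rows sum to 1, column order = classes_."""
        Xf = self._prepare(X, code_table_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return self.svc.predict_proba(Xf)

    def predict(self, X, code_table_id: int | None = None) -> np.ndarray:
        proba = self.predict_proba(X, code_table_id)
        return self.classes_[np.argmax(proba, axis=1)]

    def summary(self) -> str:
        lines = [
            "Codon-composition SVC results",
            "=============================",
            f"classes:            {', '.join(map(str, self.classes_))}",
            f"n training:         {self.provenance.get('n_training')}",
            f"selected C:         {self.best_c:.6g}",
            f"CV accuracy (mean): {self.cv_accuracy:.4f}",
            f"kernel:             rbf (gamma={self.svc.gamma})",
            f"support vectors:    {int(self.svc.support_vectors_.shape[0])}",
            f"translation table:  {self.code_table_id}",
            f"seed:               {self.provenance.get('seed')}",
            f"training hash:      {self.provenance.get('training_hash')}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write a portable archive: JSON metadata + raw numeric arrays.

        The archive stores no executable code; loading rehydrates a fresh
        estimator from the arrays alone.
        """
        meta = {
            "format": _ARCHIVE_FORMAT,
            "model": "rbf-svc-codon-counts",
            "classes": [str(c) for c in self.classes_],
            "vocabulary": list(self.vocabulary),
            "best_c": self.best_c,
            "cv_accuracy": self.cv_accuracy,
            "gamma_value": float(self.svc._gamma),
            "n_features": int(self.svc.n_features_in_),
            "search_trace": self.search_trace,
            "provenance": self.provenance,
        }
        arrays = {name: np.asarray(getattr(self.svc, name)) for name in _SVC_ARRAY_ATTRS}
        arrays["shape_fit_"] = np.asarray(self.svc.shape_fit_)
        class_arr = arrays.pop("classes_")
        entries = {"metadata.json": json.dumps(meta, indent=1, sort_keys=True).encode()}
        for name, arr in sorted(arrays.items()):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(arr))
            entries[f"arrays/{name}.npy"] = buf.getvalue()
        entries["classes.json"] = json.dumps([_json_scalar(c) for c in class_arr]).encode()
        # fixed per-entry timestamps keep same-seed reruns byte-identical
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, payload in entries.items():
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, payload)

    @classmethod
    def load(cls, path) -> "OrfClassifierResults":
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("metadata.json"))
                npz = {
                    name.split("/", 1)[1][: -len(".npy")]: np.lib.format.read_array(
                        io.BytesIO(zf.read(name))
                    )
                    for name in zf.namelist()
                    if name.startswith("arrays/")
                }
                classes = json.loads(zf.read("classes.json"))
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
            raise ModelArchiveError(f"corrupted or unreadable model archive: {exc}") from exc
        if meta.get("format") != _ARCHIVE_FORMAT:
            raise ModelArchiveError(
                f"unsupported archive format {meta.get('format')!r}; "
                f"this version reads format {_ARCHIVE_FORMAT}"
            )
        if len(meta.get("vocabulary", [])) != 64 or tuple(meta["vocabulary"]) != CODONS:
            raise ModelArchiveError("archive vocabulary does not match the 64-codon order")
        seed = int(meta["provenance"].get("seed", 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            svc = SVC(
                kernel="rbf",
                C=meta["best_c"],
                gamma="scale",
                probability=True,
                random_state=seed,
            )
        for name in _SVC_ARRAY_ATTRS:
            if name == "classes_":
                continue
            setattr(svc, name, npz[name])
        svc.classes_ = np.asarray(classes)
        svc.shape_fit_ = tuple(int(v) for v in npz["shape_fit_"])
        svc._gamma = meta["gamma_value"]
        svc._sparse = False
        svc.fit_status_ = 0
        svc.n_features_in_ = int(meta["n_features"])
        return cls(
            model=None,
            svc=svc,
            best_c=float(meta["best_c"]),
            cv_accuracy=float(meta["cv_accuracy"]),
            search_trace=[tuple(t) for t in meta["search_trace"]],
            provenance=dict(meta["provenance"]),
        )


class ModelArchiveError(RuntimeError):
    """Raised on corrupted, truncated or incompatible model archives."""


def _json_scalar(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return str(value)


# ---------------------------------------------------------------------------
# functional surface


def train_classifier(
    X: Sequence[CodonCountVector],
    y: Sequence,
    config: ClassifierConfig = ClassifierConfig(),
    code_table_id: int = 1,
) -> OrfClassifierResults:
    return OrfClassifier(X, y, config=config, code_table_id=code_table_id).fit()


def predict_probabilities(results: OrfClassifierResults, X) -> np.ndarray:
    return results.predict_proba(X)


def save_model(results: OrfClassifierResults, path) -> None:
    results.save(path)


def load_model(path) -> OrfClassifierResults:
    return OrfClassifierResults.load(path)


# ---------------------------------------------------------------------------
# best-ORF selection


def select_best_orfs(
    orfs_by_transcript: Mapping[str, Sequence[OrfRecord]],
    probabilities: Mapping[str, Sequence[float]] | Sequence[float],
) -> tuple[dict[str, OrfRecord], int]:
    """Pick one ORF per transcript by maximal in-frame probability.

    ``probabilities`` maps transcript id to the in-frame probability of
    each of its candidate ORFs (parallel sequences). Exact probability
    ties resolve to the longer ORF, then to the smaller start coordinate,
    then to the positive frame. Returns the selection and the number of
    transcripts skipped for having zero candidates.
    """
    selected: dict[str, OrfRecord] = {}
    n_empty = 0
    for tid, orfs in orfs_by_transcript.items():
        if not orfs:
            n_empty += 1
            continue
        probs = probabilities[tid]
        if len(probs) != len(orfs):
            raise ValueError(f"probability/candidate length mismatch for {tid}")
        best = max(
            zip(orfs, probs),
            key=lambda pair: (
                pair[1],
                pair[0].length_nt,
                -pair[0].start,
                pair[0].frame > 0,
                -abs(pair[0].frame),
            ),
        )[0]
        selected[tid] = best
    return selected, n_empty
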