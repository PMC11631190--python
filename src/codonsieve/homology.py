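"""Reference-proteome search and training-pool construction for ORF calling.

The classifier that picks the best ORF per transcript is trained on the
dataset itself: transcripts aligning to a reference proteome define
in-frame positive examples, and each positive is re-read in a randomly
drawn non-coding orientation (+2/+3 on the same strand or any reverse
frame) to form an equal-sized out-of-frame negative pool.

The default search backend is an internal translated seed-and-extend
search (exact 5-aa word seeds on all six query frames, ungapped extension,
BLOSUM62 scoring with a Karlin-Altschul-style bit-score/E-value estimate).
It is deliberately simple; an adapter around an external translated-search
tool (DIAMOND-compatible tabular output) can stand in where installed.
"""

from __future__ import annotations

import math
import shutil
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .gencode import GeneticCode, OrfRecord, reverse_complement, translate
from .preprocess import TranscriptRecord, read_fasta

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# Karlin-Altschul parameters for ungapped BLOSUM62 statistics
_KA_LAMBDA = 0.318
_KA_K = 0.13
_WORD = 5


@dataclass(frozen=True)
class SearchParams:
    evalue_cut: float = 1e-30
    max_hits_per_query: int = 1

    def __post_init__(self) -> None:
        if self.evalue_cut <= 0:
            raise ValueError("evalue_cut must be > 0")
        if self.max_hits_per_query < 1:
            raise ValueError("max_hits_per_query must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search hit (qframe in transcript frame convention)."""

    qid: str
    sid: str
    qlen: int
    slen: int
    aln_len: int
    pident: float
    qframe: int
    qcov: float
    scov: float
    bitscore: float = 0.0
    evalue: float = 0.0
    qstart: int = 0  # 1-based aa position in the translated query frame
    sstart: int = 0

    def __post_init__(self) -> None:
        if self.qframe not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid qframe {self.qframe}")
        if not (0 <= self.pident <= 100):
            raise ValueError("pident out of range")


def _score(a: str, b: str) -> float:
    try:
        return _BLOSUM62[a, b]
    except (KeyError, IndexError):
        return -4.0


def _frame_translations(seq: str, code: GeneticCode):
    """Yield (frame, aa-string, reading-strand sequence) for all six frames."""
    rc = reverse_complement(seq)
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            usable = (len(s) - offset) // 3 * 3
            if usable >= 3:
                yield strand * (offset + 1), translate(s[offset : offset + usable], code), s
            else:
                yield strand * (offset + 1), "", s


class InternalSearchBackend:
    """Exact-word seed-and-extend translated search against a protein DB.

    Reports hits with identity >= ``min_identity`` over >= ``min_aln_len``
    aligned residues; E-value is a Karlin-Altschul-style estimate from the
    ungapped BLOSUM62 score.
    """

    name = "internal-seed-extend"

    def __init__(self, proteins: Sequence, min_identity: float = 0.6, min_aln_len: int = 50):
        if not proteins:
            raise ValueError("empty protein database")
        self.proteins = [(p.id, p.seq.upper()) for p in proteins]
        self.min_identity = min_identity
        self.min_aln_len = min_aln_len
        self._db_residues = sum(len(s) for _, s in self.proteins)
        self._word_index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for pi, (_, pseq) in enumerate(self.proteins):
            for i in range(len(pseq) - _WORD + 1):
                self._word_index[pseq[i : i + _WORD]].append((pi, i))

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "InternalSearchBackend":
        return cls(read_fasta(path), **kwargs)

    def _extend(self, q: str, s: str, qi: int, si: int) -> tuple[int, int, int, float]:
        """Ungapped extension of a seed on one diagonal.

        Returns (qstart, sstart, length, score) of the maximal-scoring
        extension with X-drop 20 on each side.
        """
        xdrop = 20.0
        # right extension (seed included)
        best_right = -1
        score = 0.0
        best_score_r = 0.0
        i = 0
        while qi + i < len(q) and si + i < len(s):
            score += _score(q[qi + i], s[si + i])
            if score > best_score_r:
                best_score_r, best_right = score, i
            if best_score_r - score > xdrop:
                break
            i += 1
        # left extension
        best_left = 0
        score = 0.0
        best_score_l = 0.0
        i = 1
        while qi - i >= 0 and si - i >= 0:
            score += _score(q[qi - i], s[si - i])
            if score > best_score_l:
                best_score_l, best_left = score, i
            if best_score_l - score > xdrop:
                break
            i += 1
        start_q = qi - best_left
        start_s = si - best_left
        length = best_left + best_right + 1
        total = best_score_l + best_score_r
        return start_q, start_s, length, total

    def search(self, transcripts: Sequence[TranscriptRecord], params: SearchParams, code: GeneticCode) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        for tr in transcripts:
            candidates: list[AlignmentHit] = []
            for frame, aa, _ in _frame_translations(tr.seq, code):
                if len(aa) < _WORD:
                    continue
                seen_diag: set[tuple[int, int]] = set()
                for qi in range(len(aa) - _WORD + 1):
                    word = aa[qi : qi + _WORD]
                    if "*" in word or "X" in word:
                        continue
                    for pi, si in self._word_index.get(word, ()):
                        diag = (pi, si - qi)
                        if diag in seen_diag:
                            continue
                        seen_diag.add(diag)
                        sid, sseq = self.proteins[pi]
                        qs, ss, length, score = self._extend(aa, sseq, qi, si)
                        if length < self.min_aln_len:
                            continue
                        matches = sum(
                            1 for k in range(length) if aa[qs + k] == sseq[ss + k]
                        )
                        identity = matches / length
                        if identity < self.min_identity:
                            continue
                        bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
                        evalue = len(aa) * self._db_residues * 2.0 ** (-bits)
                        if evalue > params.evalue_cut:
                            continue
                        candidates.append(
                            AlignmentHit(
                                qid=tr.id,
                                sid=sid,
                                qlen=tr.length,
                                slen=len(sseq),
                                aln_len=length,
                                pident=100.0 * identity,
                                qframe=frame,
                                qcov=min(1.0, 3 * length / tr.length),
                                scov=length / len(sseq),
                                bitscore=bits,
                                evalue=evalue,
                                qstart=qs + 1,
                                sstart=ss + 1,
                            )
                        )
            candidates.sort(key=lambda h: (-h.bitscore, h.sid, h.qframe))
            # best hit per subject, then cap per query
            best_per_subject: dict[str, AlignmentHit] = {}
            for h in candidates:
                best_per_subject.setdefault(h.sid, h)
            top = sorted(best_per_subject.values(), key=lambda h: (-h.bitscore, h.sid))
            hits.extend(top[: params.max_hits_per_query])
        return hits


class DiamondBackend:
    """Adapter contract for an external translated-search tool.

    Requires the executable on PATH; output must be DIAMOND blastx tabular
    columns ``qseqid sseqid qlen slen length pident qframe``.
    """

    name = "diamond"

    def __init__(self, executable: str = "diamond"):
        if shutil.which(executable) is None:
            raise RuntimeError(
                f"external search backend {executable!r} not found on PATH"
            )
        self.executable = executable

    def search(self, transcripts, params, code):  # pragma: no cover - external tool
        raise NotImplementedError(
            "invoke via the command line adapter; not exercised in-library"
        )


def run_reference_search(
    transcripts: Sequence[TranscriptRecord],
    protein_db: Sequence,
    params: SearchParams = SearchParams(),
    backend=None,
    code: GeneticCode | None = None,
) -> list[AlignmentHit]:
    """Search transcripts against a reference proteome.

    ``backend`` defaults to the internal seed-and-extend search built over
    ``protein_db``; pass an adapter instance to use an external tool.
    """
    if not protein_db and backend is None:
        raise ValueError("empty protein database")
    if code is None:
        code = GeneticCode.from_table_id(1)
    if backend is None:
        backend = InternalSearchBackend(protein_db)
    return backend.search(transcripts, params, code)


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """Persist hits as the 7-column tabular dialect of translated search."""
    with open(path, "w") as fh:
        fh.write("qseqid\tsseqid\tqlen\tslen\tlength\tpident\tqframe\n")
        for h in hits:
            fh.write(
                f"{h.qid}\t{h.sid}\t{h.qlen}\t{h.slen}\t{h.aln_len}\t{h.pident:.1f}\t{h.qframe}\n"
            )


def read_hits_tsv(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            qid, sid, qlen, slen, length, pident, qframe = line.rstrip("\n").split("\t")
            qlen_i, slen_i, length_i = int(qlen), int(slen), int(length)
            hits.append(
                AlignmentHit(
                    qid=qid,
                    sid=sid,
                    qlen=qlen_i,
                    slen=slen_i,
                    aln_len=length_i,
                    pident=float(pident),
                    qframe=int(qframe),
                    qcov=min(1.0, 3 * length_i / qlen_i),
                    scov=length_i / slen_i,
                )
            )
    return hits


def build_reference_db(fasta_paths: Sequence, out_path) -> int:
    """Concatenate user protein FASTAs into one reference database.

    Ids are prefixed with the source file's stem when duplicated across
    inputs. Returns the number of sequences written. No database is
    bundled with the package: the reference proteome is always
    user-supplied.
    """
    from pathlib import Path

    from .preprocess import write_fasta

    records = []
    seen: set[str] = set()
    for path in fasta_paths:
        for rec in read_fasta(path):
            rid = rec.id
            if rid in seen:
                rid = f"{Path(path).stem}|{rec.id}"
            seen.add(rid)
            records.append(TranscriptRecord(id=rid, seq=rec.seq))
    if not records:
        raise ValueError("no sequences found in the input FASTAs")
    write_fasta(records, out_path)
    return len(records)


# ---------------------------------------------------------------------------
# Training-set construction


@dataclass
class TrainingSet:
    """Balanced in-frame / out-of-frame ORF pools for classifier training."""

    positives: list[OrfRecord]
    negatives: list[OrfRecord]
    seed: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be equal-sized")


_ALL_FRAMES = (1, 2, 3, -1, -2, -3)


def _read_in_orientation(tr_seq: str, start: int, end: int, new_frame: int) -> str:
    """Re-read the forward-strand span [start, end] in another orientation.

    The new frame's offset is applied relative to the span itself; the
    result is trimmed to a codon-multiple length.
    """
    span = tr_seq[start - 1 : end]
    if new_frame < 0:
        span = reverse_complement(span)
    offset = abs(new_frame) - 1
    usable = (len(span) - offset) // 3 * 3
    return span[offset : offset + usable]


def build_training_set(
    hits: Sequence[AlignmentHit],
    transcripts: Sequence[TranscriptRecord],
    code: GeneticCode,
    seed: int,
    min_len_nt: int = 150,
) -> TrainingSet:
    """Positives are the hits' aligned regions read in-frame; negatives by
    reorientation.

    For each hit, the in-frame reading of the hit's aligned region (the
    whole frame when the hit carries no alignment coordinates) is the
    positive; one negative per positive re-reads the same transcript span
    in an orientation drawn uniformly (seeded) from the five non-coding
    orientations relative to the positive.
    """
    by_id = {t.id: t for t in transcripts}
    missing = [h.qid for h in hits if h.qid not in by_id]
    if missing:
        raise ValueError(f"hits reference unknown transcripts: {missing[:3]}")
    rng = np.random.default_rng(seed)
    positives: list[OrfRecord] = []
    negatives: list[OrfRecord] = []
    n_skipped = 0
    for h in hits:
        tr = by_id[h.qid]
        n = tr.length
        frame = h.qframe
        offset = abs(frame) - 1
        if h.qstart > 0:
            # aligned region, in codons of the reading frame
            aa_begin = h.qstart - 1
            aa_len = h.aln_len
        else:
            aa_begin = 0
            aa_len = (n - offset) // 3
        span_nt = 3 * aa_len
        if span_nt < min_len_nt:
            n_skipped += 1
            continue
        # reading-strand nt offset of the region start
        read_off = offset + 3 * aa_begin
        if frame > 0:
            start, end = read_off + 1, read_off + span_nt
            nt = tr.seq[start - 1 : end]
        else:
            start, end = 1 + (n - read_off - span_nt), n - read_off
            nt = reverse_complement(tr.seq[start - 1 : end])
        aa = translate(nt, code)
        positives.append(
            OrfRecord(
                transcript_id=tr.id,
                frame=frame,
                start=start,
                end=end,
                complete=False,
                nt_seq=nt,
                aa_seq=aa,
            )
        )
        other = [f for f in _ALL_FRAMES if f != frame]
        neg_frame = other[int(rng.integers(len(other)))]
        neg_nt = _read_in_orientation(tr.seq, start, end, neg_frame)
        negatives.append(
            OrfRecord(
                transcript_id=tr.id,
                frame=neg_frame,
                start=start,
                end=start + len(neg_nt) - 1,
                complete=False,
                nt_seq=neg_nt,
                aa_seq=translate(neg_nt, code),
            )
        )
    return TrainingSet(positives=positives, negatives=negatives, seed=seed, n_skipped=n_skipped)
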