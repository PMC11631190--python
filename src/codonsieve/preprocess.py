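"""Transcript loading and first-stage filters.

De novo assemblies routinely carry short fragments, rRNA by-catch and
near-identical isoform redundancy (a known artefact of some assemblers).
This module applies the three optional filters in that order: a length
threshold, an rRNA screen, and greedy longest-first clustering that keeps
each cluster's longest member as representative.

The rRNA screen and the clustering each have two backends: an internal,
download-free implementation (exact 31-mer sharing against a user-supplied
rRNA reference; edlib-based greedy clustering) and thin adapters around the
external tools a production run would use (barrnap, cd-hit-est) when they
are on PATH.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gencode import reverse_complement


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript (uppercased on ingest)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for transcript {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ClusteringParams:
    """Greedy clustering thresholds (cd-hit-est-style semantics).

    ``identity``: minimum fractional identity of the local alignment;
    ``short_cov``/``long_cov``: minimum fraction of the shorter/longer
    sequence the alignment must cover.
    """

    identity: float = 0.97
    short_cov: float = 1.0
    long_cov: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")
        if not 0 < self.short_cov <= 1:
            raise ValueError("short_cov must be in (0, 1]")
        if not 0 <= self.long_cov <= 1:
            raise ValueError("long_cov must be in [0, 1]")


class ConfigurationError(ValueError):
    """A filter backend was requested without its required inputs."""


class BackendMissingError(RuntimeError):
    """An external program backend is not available on PATH."""


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[TranscriptRecord]:
    """Read a nucleotide FASTA (any line-wrapping dialect); ids must be unique."""
    records = [
        TranscriptRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable, path, wrap: int = 60) -> None:
    """Write records (anything with .id/.seq) as 60-column wrapped FASTA."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Length filter


def filter_by_length(
    records: Sequence[TranscriptRecord], min_len: int = 300
) -> list[TranscriptRecord]:
    """Keep records at least ``min_len`` nt long, preserving input order."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in records if r.length >= min_len]


# ---------------------------------------------------------------------------
# rRNA screen


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:  # ambiguous k-mers never match
            yield kmer


class KmerRrnaScreen:
    """Reference-based rRNA screen: shared exact k-mer fraction.

    A transcript is flagged when at least ``min_fraction`` of its k-mers
    (either strand) occur in the rRNA reference. k = 31 keeps random
    31-mer collisions negligible while tolerating scattered mismatches in
    true rRNA copies.
    """

    name = "kmer-screen"

    def __init__(self, reference: Sequence[TranscriptRecord], k: int = 31, min_fraction: float = 0.25):
        if not reference:
            raise ConfigurationError("internal rRNA screen requires a non-empty rRNA reference")
        self.k = k
        self.min_fraction = min_fraction
        self._index: set[str] = set()
        for rec in reference:
            self._index.update(_kmers(rec.seq, k))

    @classmethod
    def from_fasta(cls, path, k: int = 31, min_fraction: float = 0.25) -> "KmerRrnaScreen":
        return cls(read_fasta(path), k=k, min_fraction=min_fraction)

    def is_rrna(self, record: TranscriptRecord) -> bool:
        n_total = 0
        n_hit = 0
        for strand_seq in (record.seq, reverse_complement(record.seq)):
            for kmer in _kmers(strand_seq, self.k):
                n_total += 1
                if kmer in self._index:
                    n_hit += 1
        if n_total == 0:
            return False
        return n_hit / n_total >= self.min_fraction


class BarrnapBackend:
    """Adapter around barrnap, run under all four of its kingdom models."""

    name = "barrnap"
    kingdoms = ("bac", "arc", "euk", "mito")

    def __init__(self, executable: str = "barrnap"):
        if shutil.which(executable) is None:
            raise BackendMissingError(
                f"external rRNA backend {executable!r} not found on PATH"
            )
        self.executable = executable

    def flagged_ids(self, records: Sequence[TranscriptRecord]) -> set[str]:
        flagged: set[str] = set()
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "in.fasta"
            write_fasta(records, fasta)
            for kingdom in self.kingdoms:
                proc = subprocess.run(
                    [self.executable, "--kingdom", kingdom, str(fasta)],
                    capture_output=True,
                    text=True,
                    check=True,
                )
                for line in proc.stdout.splitlines():
                    if line.startswith("#") or not line.strip():
                        continue
                    flagged.add(line.split("\t", 1)[0])
        return flagged

    def is_rrna(self, record: TranscriptRecord) -> bool:  # pragma: no cover
        return record.id in self.flagged_ids([record])


def screen_rrna(
    records: Sequence[TranscriptRecord], rrna_backend
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Partition records into (kept, flagged-as-rRNA) using the backend."""
    if hasattr(rrna_backend, "flagged_ids"):
        flagged_ids = rrna_backend.flagged_ids(records)
        kept = [r for r in records if r.id not in flagged_ids]
        flagged = [r for r in records if r.id in flagged_ids]
        return kept, flagged
    kept, flagged = [], []
    for rec in records:
        (flagged if rrna_backend.is_rrna(rec) else kept).append(rec)
    return kept, flagged


# ---------------------------------------------------------------------------
# Isoform clustering


def _alignment_identity(short_seq: str, long_seq: str) -> tuple[float, float]:
    """Identity of the best semi-global alignment of short into long.

    Returns (identity over the shorter sequence, fraction of the longer
    sequence covered). Semi-global (infix) alignment forces full coverage
    of the shorter sequence, mirroring cd-hit's -aS 1.0 default here.
    """
    res = edlib.align(short_seq, long_seq, mode="HW", task="locations")
    dist = res["editDistance"]
    identity = max(0.0, 1.0 - dist / len(short_seq))
    loc = res["locations"][0]
    span = loc[1] - loc[0] + 1
    return identity, span / len(long_seq)


def _shared_kmer_count(index: set[str], seq: str, k: int) -> int:
    return sum(1 for kmer in _kmers(seq, k) if kmer in index)


def cluster_isoforms(
    records: Sequence[TranscriptRecord],
    params: ClusteringParams = ClusteringParams(),
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Greedy longest-first clustering of redundant isoforms.

    Records are visited longest-first (ties broken lexicographically by
    id). A record joins the first existing cluster whose representative
    aligns to it at >= ``identity`` with the alignment covering
    >= ``short_cov`` of the shorter and >= ``long_cov`` of the longer
    sequence; otherwise it founds a new cluster. Representatives are each
    cluster's longest member by construction.
    """
    if not records:
        raise ValueError("cluster_isoforms requires at least one record")
    k = 11
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[TranscriptRecord] = []
    rep_indexes: list[set[str]] = []
    cluster_map: dict[str, str] = {}
    for rec in ordered:
        assigned = False
        # minimum shared k-mers implied by the identity threshold on the
        # shorter sequence: e mismatches destroy at most e*k k-mers
        max_mismatch = int(rec.length * (1 - params.identity))
        min_shared = max(1, rec.length - k + 1 - max_mismatch * k)
        for rep, index in zip(reps, rep_indexes):
            if _shared_kmer_count(index, rec.seq, k) < min_shared:
                continue
            identity, long_cov = _alignment_identity(rec.seq, rep.seq)
            if identity >= params.identity and long_cov >= params.long_cov:
                # HW mode fully covers the shorter sequence (short_cov=1);
                # an explicit short_cov < 1 can only be more permissive.
                cluster_map[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_indexes.append(set(_kmers(rec.seq, k)))
            cluster_map[rec.id] = rec.id
    rep_ids = {r.id for r in reps}
    representatives = [r for r in records if r.id in rep_ids]
    return representatives, cluster_map


def write_cluster_map(cluster_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\n")
        for member, rep in sorted(cluster_map.items()):
            fh.write(f"{member}\t{rep}\n")
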