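"""Genetic-code tables and exhaustive six-frame ORF enumeration.

Translation tables follow the NCBI numbering (Biopython's
``Bio.Data.CodonTable`` is the source of the codon-to-amino-acid maps), so
alternative nuclear codes such as the ciliate code (table 6, where TAA and
TAG encode glutamine and only TGA terminates) behave correctly throughout
the package: in translation, in ORF boundaries, and in the four-fold
degeneracy sets used by the composition metrics.

Coordinates are 1-based and inclusive on the forward strand of the
transcript; the sign of ``frame`` encodes the strand and its magnitude
(1-3) the offset of the reading frame on the reading strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: Fixed lexicographic codon order (AAA, AAC, ... TTT) shared package-wide.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SUPPORTED_TABLES = (1, 4, 6, 10, 12, 29, 30)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: total map from the 64 ACGT codons to residues.

    Stop codons map to ``'*'``. Start codons default to ATG only;
    alternative initiators listed by NCBI are deliberately not used unless
    the caller opts in.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str] = field(default_factory=lambda: frozenset({"ATG"}))

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            raise ValueError("codon_to_aa must be defined for all 64 ACGT codons")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @classmethod
    def from_table_id(
        cls, table_id: int, alternative_starts: bool = False
    ) -> "GeneticCode":
        """Build a code from its NCBI translation-table number."""
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise ValueError(f"unknown NCBI translation table: {table_id}") from exc
        mapping = {c: "*" for c in table.stop_codons}
        mapping.update(table.forward_table)
        starts = frozenset(table.start_codons) if alternative_starts else frozenset({"ATG"})
        return cls(table_id=table_id, codon_to_aa=dict(mapping), start_codons=starts)


def translate(nt_seq: str, code: GeneticCode) -> str:
    """Translate an in-frame nucleotide sequence; stops render as ``'*'``.

    Codons containing characters outside ACGT translate to ``'X'``.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    seq = nt_seq.upper()
    lookup = code.codon_to_aa
    return "".join(
        lookup.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3)
    )


@dataclass(frozen=True)
class OrfRecord:
    """One putative ORF, anchored to forward-strand transcript coordinates.

    ``nt_seq`` is in reading-strand orientation (reverse complement of the
    forward slice for negative frames) and includes the stop codon when the
    ORF is complete; ``aa_seq`` never includes the terminal stop.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    complete: bool
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span must be a codon multiple")
        if len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError("nt_seq length must equal the coordinate span")

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)

    def orf_id(self, index: int) -> str:
        return f"{self.transcript_id}.orf{index}"


def _scan_frame(
    seq: str,
    offset: int,
    code: GeneticCode,
    min_len_nt: int,
    include_partial: bool,
) -> list[tuple[int, int, bool]]:
    """Scan one reading frame of ``seq`` (already in reading orientation).

    Returns (start0, end0, complete) half-open-free 0-based inclusive codon
    spans on the reading strand. Complete ORFs run from the first start
    codon after the previous stop through the next in-frame stop. In
    partial mode, stop-bounded segments with no start codon are emitted
    whole, and the trailing stop-less segment is emitted from its first
    start codon (or whole, if it has none).
    """
    n = len(seq)
    out: list[tuple[int, int, bool]] = []
    seg_begin = offset  # first base of the current stop-delimited segment
    first_start = -1  # position of first start codon in current segment
    stops = code.stop_codons
    starts = code.start_codons
    i = offset
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in stops:
            if first_start >= 0:
                if i + 3 - first_start >= min_len_nt:
                    out.append((first_start, i + 2, True))
            elif include_partial and i + 3 - seg_begin >= min_len_nt:
                out.append((seg_begin, i + 2, False))
            seg_begin = i + 3
            first_start = -1
        elif first_start < 0 and codon in starts:
            first_start = i
        i += 3
    if include_partial:
        # trailing segment truncated by the transcript edge (no stop codon)
        tail_begin = first_start if first_start >= 0 else seg_begin
        tail_end = i - 1  # last complete codon boundary
        if tail_end >= tail_begin and tail_end - tail_begin + 1 >= min_len_nt:
            out.append((tail_begin, tail_end, False))
    return out


def _enumerate(
    transcript_id: str,
    seq: str,
    code: GeneticCode,
    min_len_nt: int,
    include_partial: bool,
) -> list[OrfRecord]:
    seq = seq.upper()
    n = len(seq)
    records: list[OrfRecord] = []
    rc = reverse_complement(seq)
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            for b0, e0, complete in _scan_frame(
                s, offset, code, min_len_nt, include_partial
            ):
                nt = s[b0 : e0 + 1]
                if strand == 1:
                    start, end = b0 + 1, e0 + 1
                else:
                    start, end = n - e0, n - b0
                aa = translate(nt, code)
                if aa.endswith("*"):  # stop-terminated (complete or partial)
                    aa = aa[:-1]
                records.append(
                    OrfRecord(
                        transcript_id=transcript_id,
                        frame=strand * (offset + 1),
                        start=start,
                        end=end,
                        complete=complete,
                        nt_seq=nt,
                        aa_seq=aa,
                    )
                )
    records.sort(key=lambda r: (r.start, r.end, -r.frame))
    return records


def enumerate_orfs(
    transcript, code: GeneticCode, min_len_nt: int = 150
) -> list[OrfRecord]:
    """Enumerate complete (start-to-stop) ORFs in all six orientations.

    Per frame, every maximal stretch from the first start codon after the
    previous stop through the next in-frame stop is returned, provided its
    length (stop included) is at least ``min_len_nt``.
    """
    _check_min_len(min_len_nt)
    return _enumerate(transcript.id, transcript.seq, code, min_len_nt, False)


def enumerate_partial_orfs(
    transcript, code: GeneticCode, min_len_nt: int = 150
) -> list[OrfRecord]:
    """Enumerate complete plus partial ORFs in all six orientations.

    Partial ORFs are stop-bounded stretches lacking a start codon and
    transcript-edge-truncated stretches lacking a terminal stop; they carry
    ``complete=False``.
    """
    _check_min_len(min_len_nt)
    return _enumerate(transcript.id, transcript.seq, code, min_len_nt, True)


def _check_min_len(min_len_nt: int) -> None:
    if min_len_nt < 3 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be >= 3 and divisible by 3")
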