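"""Reading and writing ORF records as FASTA + companion TSV."""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gencode import OrfRecord


def orf_header(orf: OrfRecord, index: int) -> str:
    return (
        f"frame={orf.frame:+d} start={orf.start} end={orf.end} "
        f"complete={'true' if orf.complete else 'false'}"
    )


def write_orf_fasta(orfs: Sequence[OrfRecord], path, aa: bool = False) -> None:
    """Write ORFs (nucleotide, or protein with aa=True) with coordinate headers.

    ORFs are numbered per transcript in input order: ``{transcript_id}.orf{n}``.
    """
    counter: dict[str, int] = {}
    records = []
    for orf in orfs:
        n = counter.get(orf.transcript_id, 0) + 1
        counter[orf.transcript_id] = n
        records.append(
            SeqRecord(
                Seq(orf.aa_seq if aa else orf.nt_seq),
                id=orf.orf_id(n),
                description=orf_header(orf, n),
            )
        )
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=60)
    writer.write_file(records)


def orf_table(orfs: Sequence[OrfRecord]) -> pd.DataFrame:
    counter: dict[str, int] = {}
    rows = []
    for orf in orfs:
        n = counter.get(orf.transcript_id, 0) + 1
        counter[orf.transcript_id] = n
        rows.append(
            {
                "orf_id": orf.orf_id(n),
                "transcript_id": orf.transcript_id,
                "frame": orf.frame,
                "start": orf.start,
                "end": orf.end,
                "complete": orf.complete,
                "length_nt": orf.length_nt,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["orf_id", "transcript_id", "frame", "start", "end", "complete", "length_nt"],
    )


def write_orf_table(orfs: Sequence[OrfRecord], path) -> None:
    orf_table(orfs).to_csv(path, sep="\t", index=False)
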