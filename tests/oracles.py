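"""Independent reference implementations used only to check the package.

These deliberately take different routes from the library code: protein-
string segmentation instead of codon-walking for ORF enumeration, direct
dictionary lookups for translation, stride slicing for codon counting.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def table_lookup_translate(nt: str, table_id: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table.get(codon, "X"))
    return "".join(out)


def sixframe_orfs(seq: str, table_id: int, min_len_nt: int, partial: bool = False):
    """Brute-force six-frame scan via protein-string segmentation.

    Returns a set of (frame, start, end, complete) tuples in forward-strand
    1-based inclusive coordinates, matching the package's conventions.
    """
    n = len(seq)
    found = set()
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for offset in range(3):
            usable = (n - offset) // 3 * 3
            if usable < 3:
                continue
            aa = table_lookup_translate(s[offset : offset + usable], table_id)
            frame = strand * (offset + 1)
            # split protein into stop-terminated segments
            pos = 0  # codon index of segment start
            i = 0
            while i <= len(aa):
                if i == len(aa) or aa[i] == "*":
                    terminated = i < len(aa)
                    seg_first, seg_last = pos, i - 1  # codon indices, excl stop
                    # complete ORF: first M in segment .. stop
                    m = aa.find("M", seg_first, seg_last + 1 if terminated else seg_last + 1)
                    if terminated and m != -1:
                        b0, e0 = offset + 3 * m, offset + 3 * i + 2
                        if e0 - b0 + 1 >= min_len_nt:
                            found.add(_coords(strand, n, b0, e0, True))
                    elif partial and terminated:
                        b0, e0 = offset + 3 * seg_first, offset + 3 * i + 2
                        if e0 - b0 + 1 >= min_len_nt and seg_last >= seg_first - 1:
                            found.add(_coords(strand, n, b0, e0, False))
                    if partial and not terminated and seg_last >= seg_first:
                        start_codon = m if m != -1 else seg_first
                        b0, e0 = offset + 3 * start_codon, offset + 3 * (seg_last + 1) - 1
                        if e0 - b0 + 1 >= min_len_nt:
                            found.add(_coords(strand, n, b0, e0, False))
                    pos = i + 1
                i += 1
    return found


def _coords(strand: int, n: int, b0: int, e0: int, complete: bool):
    if strand == 1:
        start, end = b0 + 1, e0 + 1
        frame = strand * ((b0 % 3) + 1)
    else:
        start, end = n - e0, n - b0
        frame = strand * ((b0 % 3) + 1)
    return (frame, start, end, complete)


def stride3_codon_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if set(codon) <= set("ACGT"):
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def fourfold_set(table_id: int) -> set[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]

    def aa_of(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    out = set()
    for c1 in "ACGT":
        for c2 in "ACGT":
            family = {aa_of(c1 + c2 + c3) for c3 in "ACGT"}
            if len(family) == 1 and "*" not in family:
                out.update(c1 + c2 + c3 for c3 in "ACGT")
    return out
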