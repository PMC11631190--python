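"""Codon-position G+C composition metrics and window-based selection.

GC12 (G+C at codon positions 1 and 2) against GC3 (position 3) is a
classic taxonomic "fingerprint": pooled sequence sets from different
organisms separate into visible clusters in the (GC12, GC3) plane, which
is the basis for picking composition windows of training sequences when
decontaminating a mixed assembly. GC3s restricts GC3 to four-fold
degenerate codons — sites free of protein-level constraint — and the
degenerate set is derived from the active translation table, so
alternative codes shift it correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gencode import CODONS, NUCLEOTIDES, GeneticCode

_GC = frozenset("GC")
_ACGT = frozenset(NUCLEOTIDES)


@dataclass(frozen=True)
class CompositionMetrics:
    """Per-ORF composition percentages; gc3s is None without 4-fold sites."""

    orf_id: str
    gc12: float
    gc3: float
    gc3s: float | None
    n_codons: int


def fourfold_codons(code: GeneticCode) -> frozenset[str]:
    """Codons whose amino acid is invariant to any third-position change."""
    out = set()
    for c in CODONS:
        aa = code.codon_to_aa[c]
        if aa == "*":
            continue
        family = {code.codon_to_aa[c[:2] + b] for b in NUCLEOTIDES}
        if family == {aa}:
            out.add(c)
    return frozenset(out)


def compute_composition(orf, code: GeneticCode) -> CompositionMetrics:
    """GC12 / GC3 / GC3s for one in-frame sequence.

    Codons containing non-ACGT characters are excluded from every tally.
    Accepts ORF records (``nt_seq``) or plain sequence records (``seq``).
    """
    seq = getattr(orf, "nt_seq", None) or orf.seq
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    ffold = fourfold_codons(code)
    n12 = gc12 = n3 = gc3 = n3s = gc3s = 0
    n_codons = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if not set(codon) <= _ACGT:
            continue
        n_codons += 1
        n12 += 2
        gc12 += (codon[0] in _GC) + (codon[1] in _GC)
        n3 += 1
        gc3 += codon[2] in _GC
        if codon in ffold:
            n3s += 1
            gc3s += codon[2] in _GC
    orf_id = getattr(orf, "id", None) or getattr(orf, "transcript_id", "seq")
    return CompositionMetrics(
        orf_id=orf_id,
        gc12=100.0 * gc12 / n12 if n12 else 0.0,
        gc3=100.0 * gc3 / n3 if n3 else 0.0,
        gc3s=100.0 * gc3s / n3s if n3s else None,
        n_codons=n_codons,
    )


def composition_table(seqs: Sequence, code: GeneticCode) -> pd.DataFrame:
    """Tidy per-ORF table (orf_id, n_codons, gc12, gc3, gc3s).

    ``gc3s`` is NaN where a sequence has no four-fold degenerate codons.
    Suitable both for writing as TSV and for scatter-style fingerprint
    plots of gc3 against gc12.
    """
    rows = []
    for s in seqs:
        m = compute_composition(s, code)
        rows.append(
            {
                "orf_id": m.orf_id,
                "n_codons": m.n_codons,
                "gc12": m.gc12,
                "gc3": m.gc3,
                "gc3s": np.nan if m.gc3s is None else m.gc3s,
            }
        )
    return pd.DataFrame(rows, columns=["orf_id", "n_codons", "gc12", "gc3", "gc3s"])


def select_by_composition(
    metrics: pd.DataFrame,
    gc12_window: tuple[float, float],
    gc3_window: tuple[float, float],
    n: int,
    seed: int,
) -> list[str]:
    """Seeded uniform sample of n ids inside both windows (inclusive bounds)."""
    for lo, hi in (gc12_window, gc3_window):
        if lo > hi:
            raise ValueError(f"window [{lo}, {hi}] has lo > hi")
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = (
        metrics["gc12"].between(*gc12_window) & metrics["gc3"].between(*gc3_window)
    )
    eligible = metrics.loc[mask, "orf_id"].tolist()
    if not eligible:
        raise ValueError(
            f"no sequences inside GC12 window {gc12_window} and GC3 window {gc3_window}"
        )
    if len(eligible) <= n:
        if len(eligible) < n:
            warnings.warn(
                f"only {len(eligible)} sequences inside the windows; requested {n}",
                UserWarning,
                stacklevel=2,
            )
        return list(eligible)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(picked)]
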