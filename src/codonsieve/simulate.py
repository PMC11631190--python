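"""Synthetic transcriptome and ORF-pool generation with codon fingerprints.

The generator is the package's test substrate: it produces multi-taxon
transcript mixtures with controllable codon-usage "fingerprints" (target
GC3, divergence between taxa) plus exact truth tables, without any
download. Each transcript is 5'UTR + one complete CDS + 3'UTR, optionally
emitted reverse-complemented; CDS codons are drawn from the taxon's codon
usage (a Dirichlet perturbation of a GC3-tilted base usage), which is what
lets two taxa range from compositionally "distinct" to "identical" — the
regimes that determine how much labelled training data a composition
classifier needs.

UTRs are i.i.d. draws from a base-frequency simplex; no secondary
structure, expression levels, sequencing error or isoform structure is
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gencode import CODONS, GeneticCode, OrfRecord, reverse_complement, translate
from .preprocess import TranscriptRecord

_DEFAULT_UTR = (0.3, 0.2, 0.2, 0.3)  # A, C, G, T

#: Divergence presets for the three composition-similarity regimes of a
#: two-taxon contamination mixture: "distinct" pairs are separable by eye
#: in the (GC12, GC3) plane, "dissimilar" pairs overlap partially, and
#: "identical" pairs show no perceptible fingerprint difference (equal
#: target GC3, mild codon-preference differences only) — the regime where
#: classification quality depends strongly on training-set size.
REGIME_DIVERGENCE = {"distinct": 1.0, "dissimilar": 0.35, "identical": 0.05}


@dataclass(frozen=True)
class TaxonModel:
    """Codon-usage model for one taxon; sums to 1 over sense codons."""

    name: str
    codon_usage: np.ndarray  # length 64, stops ~0
    gc3_target: float
    utr_base_freqs: tuple[float, float, float, float] = _DEFAULT_UTR
    seed: int = 0

    def __post_init__(self) -> None:
        usage = np.asarray(self.codon_usage, dtype=float)
        if usage.shape != (64,) or not np.isclose(usage.sum(), 1.0):
            raise ValueError("codon_usage must be a 64-simplex")
        object.__setattr__(self, "codon_usage", usage)


@dataclass(frozen=True)
class SimulationConfig:
    taxa: tuple[TaxonModel, ...]
    proportions: tuple[float, ...]
    n_transcripts: int = 500
    cds_len_range: tuple[int, int] = (100, 500)  # codons, excl. start/stop
    utr_len_range: tuple[int, int] = (20, 150)  # nt per UTR
    antisense_rate: float = 0.5
    seed: int = 0
    code_table_id: int = 1

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.proportions):
            raise ValueError("taxa and proportions must be parallel")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("proportions must sum to 1")
        if self.cds_len_range[0] < 1 or self.utr_len_range[0] < 0:
            raise ValueError("ranges must be positive")


def _gc3_tilted_base_usage(gc3_target: float, code: GeneticCode) -> np.ndarray:
    """Uniform position-1/2 usage with third-position base mass set by GC3."""
    g = gc3_target / 100.0
    third = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
    weights = np.array(
        [0.0 if code.codon_to_aa[c] == "*" else third[c[2]] for c in CODONS]
    )
    return weights / weights.sum()


def _rescale_gc3(usage: np.ndarray, gc3_target: float) -> np.ndarray:
    """Scale the GC-ending vs AT-ending codon mass to hit the GC3 target."""
    g = gc3_target / 100.0
    is_gc = np.array([c[2] in "GC" for c in CODONS])
    mass_gc = usage[is_gc].sum()
    mass_at = usage[~is_gc].sum()
    out = usage.copy()
    if mass_gc > 0 and g > 0:
        out[is_gc] *= g / mass_gc
    elif g == 0:
        out[is_gc] = 0.0
    if mass_at > 0 and (1 - g) > 0:
        out[~is_gc] *= (1 - g) / mass_at
    elif g == 1:
        out[~is_gc] = 0.0
    return out / out.sum()


def make_taxon_model(
    name: str,
    gc3_target: float,
    divergence: float,
    seed: int,
    code: GeneticCode | None = None,
    utr_base_freqs: tuple[float, float, float, float] = _DEFAULT_UTR,
) -> TaxonModel:
    """Build a codon-usage model at a target GC3 and a divergence level.

    ``divergence`` in [0, 1] interpolates between the shared GC3-tilted
    base usage (0: taxa with equal gc3_target are identical) and an
    independent seeded Dirichlet draw around it (1: fully distinct
    position-1/2 preferences). The third-position GC mass is re-pinned to
    ``gc3_target`` after perturbation, so the fingerprint axis stays
    controlled.
    """
    if not 0 <= gc3_target <= 100:
        raise ValueError("gc3_target must be in [0, 100]")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if code is None:
        code = GeneticCode.from_table_id(1)
    base = _gc3_tilted_base_usage(gc3_target, code)
    if divergence > 0:
        rng = np.random.default_rng(seed)
        sense = base > 0
        draw = np.zeros_like(base)
        # low concentration -> strongly idiosyncratic codon preferences
        draw[sense] = rng.dirichlet(np.full(sense.sum(), 2.0))
        usage = (1 - divergence) * base + divergence * draw
        usage = _rescale_gc3(usage, gc3_target)
    else:
        usage = base
    return TaxonModel(
        name=name,
        codon_usage=usage,
        gc3_target=gc3_target,
        utr_base_freqs=utr_base_freqs,
        seed=seed,
    )


def _sample_cds(
    model: TaxonModel, n_codons: int, rng: np.random.Generator, code: GeneticCode
) -> str:
    codon_idx = rng.choice(64, size=n_codons, p=model.codon_usage)
    body = "".join(CODONS[i] for i in codon_idx)
    stops = sorted(code.stop_codons)
    stop = stops[int(rng.integers(len(stops)))]
    return "ATG" + body + stop


def _sample_utr(
    freqs: Sequence[float], length: int, rng: np.random.Generator
) -> str:
    idx = rng.choice(4, size=length, p=np.asarray(freqs) / np.sum(freqs))
    return "".join("ACGT"[i] for i in idx)


def _sample_utr5(
    freqs: Sequence[float],
    length: int,
    rng: np.random.Generator,
    code: GeneticCode,
    max_tries: int = 50,
) -> str:
    """Sample a 5'UTR that keeps the planted CDS the maximal ORF of its frame.

    An upstream ATG in the CDS frame with no intervening stop would make
    the transcript's true maximal complete ORF longer than the planted
    CDS, leaving the truth table ill-posed (a maximal-ORF caller must
    prefer the longer ORF). Rejection sampling enforces that the nearest
    in-frame start-codon-free suffix of the UTR reaches back to an
    in-frame stop or to the transcript edge.
    """
    stops = code.stop_codons
    for _ in range(max_tries):
        utr = _sample_utr(freqs, length, rng)
        # walk in-frame codon slots upstream from the CDS junction
        aliased = False
        pos = len(utr) - 3
        while pos >= 0:
            codon = utr[pos : pos + 3]
            if codon in stops:
                break
            if codon in code.start_codons:
                aliased = True
                break
            pos -= 3
        if not aliased:
            return utr
    raise RuntimeError("could not sample a non-aliasing 5'UTR")  # pragma: no cover


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], "pd.DataFrame", list[TranscriptRecord]]:
    """Simulate a mixed transcriptome with truth table and proteome.

    Returns (transcripts, truth, proteome). Truth columns: transcript_id,
    taxon, frame, cds_start, cds_end (1-based forward-strand, stop codon
    included). The proteome holds every CDS translation (stop stripped)
    and doubles as the reference database for prediction-mode training.
    """
    import pandas as pd

    code = GeneticCode.from_table_id(config.code_table_id)
    rng = np.random.default_rng(config.seed)
    taxon_of = rng.choice(len(config.taxa), size=config.n_transcripts, p=config.proportions)
    transcripts: list[TranscriptRecord] = []
    proteome: list[TranscriptRecord] = []
    rows = []
    for i in range(config.n_transcripts):
        model = config.taxa[taxon_of[i]]
        n_codons = int(rng.integers(config.cds_len_range[0], config.cds_len_range[1] + 1))
        cds = _sample_cds(model, n_codons, rng, code)
        utr5 = _sample_utr5(
            model.utr_base_freqs, int(rng.integers(*_incl(config.utr_len_range))), rng, code
        )
        utr3 = _sample_utr(model.utr_base_freqs, int(rng.integers(*_incl(config.utr_len_range))), rng)
        fwd = utr5 + cds + utr3
        cds_start = len(utr5) + 1
        cds_end = len(utr5) + len(cds)
        frame = (cds_start - 1) % 3 + 1
        antisense = bool(rng.random() < config.antisense_rate)
        if antisense:
            seq = reverse_complement(fwd)
            n = len(seq)
            # the CDS reads on the reverse strand; its frame offset is its
            # position on the reading strand (= position in fwd)
            frame = -((cds_start - 1) % 3 + 1)
            cds_start, cds_end = n - cds_end + 1, n - cds_start + 1
        else:
            seq = fwd
        tid = f"tr{i:05d}"
        transcripts.append(TranscriptRecord(id=tid, seq=seq))
        proteome.append(
            TranscriptRecord(id=f"{tid}_p", seq=translate(cds, code)[:-1])
        )
        rows.append(
            {
                "transcript_id": tid,
                "taxon": model.name,
                "frame": frame,
                "cds_start": cds_start,
                "cds_end": cds_end,
            }
        )
    truth = pd.DataFrame(rows)
    return transcripts, truth, proteome


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def simulate_classified_orfs(
    taxa: Sequence[TaxonModel],
    n_per_taxon: Sequence[int],
    len_range: tuple[int, int],
    seed: int,
    code_table_id: int = 1,
) -> tuple[list[OrfRecord], dict[str, str]]:
    """Bare in-frame CDS pools with labels (decontamination substrate).

    Returns (orfs, labels) where labels maps orf transcript_id -> taxon
    name; counts follow ``n_per_taxon`` exactly.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(taxa) != len(n_per_taxon):
        raise ValueError("taxa and n_per_taxon must be parallel")
    code = GeneticCode.from_table_id(code_table_id)
    rng = np.random.default_rng(seed)
    orfs: list[OrfRecord] = []
    labels: dict[str, str] = {}
    for model, n in zip(taxa, n_per_taxon):
        for j in range(n):
            n_codons = int(rng.integers(len_range[0], len_range[1] + 1))
            cds = _sample_cds(model, n_codons, rng, code)
            oid = f"{model.name}_orf{j:05d}"
            orfs.append(
                OrfRecord(
                    transcript_id=oid,
                    frame=1,
                    start=1,
                    end=len(cds),
                    complete=True,
                    nt_seq=cds,
                    aa_seq=translate(cds, code)[:-1],
                )
            )
            labels[oid] = model.name
    return orfs, labels
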