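import numpy as np
import pytest

from codonsieve import GeneticCode, TranscriptRecord, make_taxon_model


@pytest.fixture(scope="session")
def code1() -> GeneticCode:
    return GeneticCode.from_table_id(1)


@pytest.fixture(scope="session")
def code6() -> GeneticCode:
    return GeneticCode.from_table_id(6)


def random_transcript(rng: np.random.Generator, length: int, tid: str = "t") -> TranscriptRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return TranscriptRecord(id=tid, seq=seq)


@pytest.fixture(scope="session")
def distinct_taxa():
    """Two taxa with well-separated composition fingerprints (GC3 20 vs 80)."""
    return (
        make_taxon_model("low_gc", gc3_target=20, divergence=1.0, seed=101),
        make_taxon_model("high_gc", gc3_target=80, divergence=1.0, seed=102),
    )
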