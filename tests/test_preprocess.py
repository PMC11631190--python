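"""Length filter, rRNA screen and isoform clustering."""

import numpy as np
import pytest

from codonsieve import (
    ClusteringParams,
    KmerRrnaScreen,
    TranscriptRecord,
    cluster_isoforms,
    filter_by_length,
    read_fasta,
    reverse_complement,
    screen_rrna,
    write_fasta,
)
from codonsieve.preprocess import BackendMissingError, BarrnapBackend, ConfigurationError


def _random_records(rng, n, lengths, prefix="r"):
    out = []
    for i in range(n):
        length = int(lengths[i]) if hasattr(lengths, "__len__") else int(lengths)
        out.append(
            TranscriptRecord(id=f"{prefix}{i}", seq="".join(rng.choice(list("ACGT"), size=length)))
        )
    return out


class TestLengthFilter:
    def test_threshold(self):
        rng = np.random.default_rng(0)
        short, long_ = _random_records(rng, 2, [100, 500])
        assert filter_by_length([short, long_], 300) == [long_]

    def test_min_len_zero_is_identity(self):
        rng = np.random.default_rng(1)
        records = _random_records(rng, 5, [60, 80, 100, 120, 140])
        assert filter_by_length(records, 0) == records

    def test_count_matches_bruteforce_on_random_lengths(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(50, 1001, size=1000)
        records = _random_records(rng, 1000, lengths)
        kept = filter_by_length(records, 300)
        assert len(kept) == int((lengths >= 300).sum())

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        records = _random_records(rng, 20, rng.integers(100, 600, size=20))
        once = filter_by_length(records, 300)
        assert filter_by_length(once, 300) == once


class TestRrnaScreen:
    def test_reference_sequence_is_flagged(self):
        rng = np.random.default_rng(4)
        (ref,) = _random_records(rng, 1, 800, prefix="rrna")
        screen = KmerRrnaScreen([ref])
        kept, flagged = screen_rrna([TranscriptRecord(id="q", seq=ref.seq)], screen)
        assert kept == [] and len(flagged) == 1

    def test_unrelated_transcript_kept(self):
        rng = np.random.default_rng(5)
        (ref,) = _random_records(rng, 1, 800, prefix="rrna")
        (query,) = _random_records(rng, 1, 500, prefix="q")
        kept, flagged = screen_rrna([query], KmerRrnaScreen([ref]))
        assert flagged == [] and kept == [query]

    def test_planted_mutated_copies_recovered(self):
        rng = np.random.default_rng(6)
        (ref,) = _random_records(rng, 1, 1500, prefix="rrna")
        screen = KmerRrnaScreen([ref])
        planted = []
        for i in range(10):
            seq = list(ref.seq[200:900])
            n_mut = int(rng.integers(0, int(0.02 * len(seq)) + 1))
            for pos in rng.choice(len(seq), size=n_mut, replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            planted.append(TranscriptRecord(id=f"p{i}", seq="".join(seq)))
        background = _random_records(rng, 90, 700, prefix="bg")
        kept, flagged = screen_rrna(planted + background, screen)
        flagged_ids = {r.id for r in flagged}
        assert sum(1 for r in planted if r.id in flagged_ids) >= 9
        assert not any(r.id.startswith("bg") for r in flagged)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(7)
        (ref,) = _random_records(rng, 1, 600, prefix="rrna")
        records = _random_records(rng, 20, 400) + [TranscriptRecord(id="hit", seq=ref.seq)]
        kept, flagged = screen_rrna(records, KmerRrnaScreen([ref]))
        assert sorted(r.id for r in kept + flagged) == sorted(r.id for r in records)
        assert not {r.id for r in kept} & {r.id for r in flagged}

    def test_empty_reference_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            KmerRrnaScreen([])

    def test_missing_external_backend_names_it(self):
        with pytest.raises(BackendMissingError, match="definitely-not-barrnap"):
            BarrnapBackend(executable="definitely-not-barrnap")

    def test_n_kmers_never_match(self):
        ref = TranscriptRecord(id="r", seq="A" * 100)
        screen = KmerRrnaScreen([TranscriptRecord(id="x", seq="N" * 31 + "A" * 69)])
        # index built from N-containing reference contributes nothing
        assert screen.is_rrna(ref) is False or len(screen._index) > 0


class TestClustering:
    def test_identical_pair_collapses(self):
        rng = np.random.default_rng(8)
        (a,) = _random_records(rng, 1, 600, prefix="a")
        b = TranscriptRecord(id="b", seq=a.seq)
        reps, cmap = cluster_isoforms([a, b])
        assert len(reps) == 1
        assert cmap[a.id] == cmap["b"] == reps[0].id

    def test_exact_substring_clusters_under_defaults(self):
        # B is half of A: identity 1.0, full short coverage, long_cov 0.5
        rng = np.random.default_rng(9)
        (a,) = _random_records(rng, 1, 800, prefix="A")
        b = TranscriptRecord(id="B", seq=a.seq[200:600])
        reps, cmap = cluster_isoforms([a, b])
        assert len(reps) == 1 and cmap["B"] == "A0"

    def test_unrelated_records_stay_singletons(self):
        rng = np.random.default_rng(10)
        records = _random_records(rng, 50, 600)
        reps, cmap = cluster_isoforms(records)
        assert len(reps) == 50
        assert all(cmap[r.id] == r.id for r in records)
        # independent confirmation on a sample of pairs: identities far
        # below the 0.97 threshold
        import edlib

        for i, j in [(0, 1), (5, 20), (30, 49)]:
            res = edlib.align(records[i].seq, records[j].seq, mode="NW")
            assert 1 - res["editDistance"] / 600 < 0.97

    def test_representatives_map_to_themselves_and_map_is_total(self):
        rng = np.random.default_rng(11)
        base = _random_records(rng, 10, 500)
        isoforms = [
            TranscriptRecord(id=f"iso{i}", seq=r.seq[: 400 + i]) for i, r in enumerate(base)
        ]
        records = base + isoforms
        reps, cmap = cluster_isoforms(records)
        assert set(cmap) == {r.id for r in records}
        for rep in reps:
            assert cmap[rep.id] == rep.id

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(12)
        base = _random_records(rng, 8, 500)
        isoforms = [TranscriptRecord(id=f"iso{i}", seq=r.seq[:450]) for i, r in enumerate(base)]
        records = base + isoforms
        reps1, _ = cluster_isoforms(records)
        reps2, _ = cluster_isoforms(reps1)
        assert {r.id for r in reps1} == {r.id for r in reps2}
        shuffled = list(records)
        np.random.default_rng(0).shuffle(shuffled)
        reps3, _ = cluster_isoforms(shuffled)
        assert {r.id for r in reps1} == {r.id for r in reps3}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_isoforms([])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusteringParams(identity=0.0)
        with pytest.raises(ValueError):
            ClusteringParams(short_cov=1.5)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        records = _random_records(rng, 5, 130)
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_lowercase_uppercased_on_ingest(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">a\nacgtacgt\n")
        (rec,) = read_fasta(path)
        assert rec.seq == "ACGTACGT"
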