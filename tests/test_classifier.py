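"""Codon tokenization, SVC training, selection and model persistence."""

import warnings

import numpy as np
import pytest

from codonsieve import (
    ClassifierConfig,
    CodonCountVector,
    GeneticCode,
    OrfClassifier,
    OrfRecord,
    load_model,
    select_best_orfs,
    simulate_classified_orfs,
    tokenize_codons,
    train_classifier,
)
from codonsieve.classifier import CODONS, ModelArchiveError, tokenize_sequence
from codonsieve.simulate import make_taxon_model

from .oracles import stride3_codon_counts


def _orf(nt, tid="t", frame=1, start=1):
    return OrfRecord(
        transcript_id=tid,
        frame=frame,
        start=start,
        end=start + len(nt) - 1,
        complete=False,
        nt_seq=nt,
        aa_seq="X" * (len(nt) // 3),
    )


class TestTokenize:
    def test_hand_count(self):
        v = tokenize_codons(_orf("ATGAAATAG"))
        expected = np.zeros(64, dtype=int)
        for codon in ("ATG", "AAA", "TAG"):
            expected[CODONS.index(codon)] = 1
        assert np.array_equal(v.counts, expected)

    def test_ambiguous_codon_dropped(self):
        v = tokenize_sequence("x", "ATGNNAAAA")
        assert v.counts.sum() == 2
        assert v.counts[CODONS.index("ATG")] == 1
        assert v.counts[CODONS.index("AAA")] == 1

    def test_matches_stride3_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(200):
            n = int(rng.integers(1, 200)) * 3
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            v = tokenize_sequence(f"s{i}", seq)
            oracle = stride3_codon_counts(seq)
            assert {CODONS[k]: int(c) for k, c in enumerate(v.counts) if c} == oracle

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tokenize_sequence("x", "")

    def test_count_vector_validates_shape(self):
        with pytest.raises(ValueError):
            CodonCountVector(orf_id="x", counts=np.zeros(63))


def _training_pool(n_per_class, seed, gc3=(20, 80), divergence=1.0, len_range=(100, 400)):
    taxa = [
        make_taxon_model(f"c{i}", g, divergence, seed=seed * 100 + i)
        for i, g in enumerate(gc3)
    ]
    orfs, labels = simulate_classified_orfs(taxa, [n_per_class] * len(taxa), len_range, seed=seed)
    X = [tokenize_codons(o) for o in orfs]
    y = [labels[o.transcript_id] for o in orfs]
    return X, y


class TestTraining:
    def test_distinct_fingerprints_beat_centroid_oracle(self):
        X, y = _training_pool(200, seed=1)
        idx = np.random.default_rng(0).permutation(len(X))
        tr, te = idx[:200], idx[200:]
        Xtr, ytr = [X[i] for i in tr], [y[i] for i in tr]
        Xte, yte = [X[i] for i in te], [y[i] for i in te]

        # nearest-centroid oracle on codon frequencies
        def freq(v):
            c = v.counts.astype(float)
            return c / c.sum()

        cents = {
            lab: np.mean([freq(x) for x, l in zip(Xtr, ytr) if l == lab], axis=0)
            for lab in set(ytr)
        }
        oracle_pred = [
            min(cents, key=lambda lab: np.abs(freq(x) - cents[lab]).sum()) for x in Xte
        ]
        oracle_acc = np.mean([p == t for p, t in zip(oracle_pred, yte)])
        assert oracle_acc >= 0.99

        res = train_classifier(Xtr, ytr, ClassifierConfig(seed=5))
        svc_acc = np.mean(res.predict(Xte) == np.asarray(yte))
        assert svc_acc >= oracle_acc

    def test_duplicating_training_points_preserves_model(self):
        X, y = _training_pool(50, seed=2)
        res1 = train_classifier(X, y, ClassifierConfig(seed=3))
        res2 = train_classifier(X + X, y + y, ClassifierConfig(seed=3))
        assert res2.best_c == res1.best_c
        Xq, _ = _training_pool(30, seed=9)
        assert np.array_equal(res1.predict(Xq), res2.predict(Xq))

    def test_shuffled_labels_give_chance_cv(self):
        X, y = _training_pool(100, seed=4)
        rng = np.random.default_rng(8)
        y_shuf = list(rng.permutation(y))
        res = train_classifier(X, y_shuf, ClassifierConfig(seed=6))
        # binomial s.e. of CV accuracy around 1/2 over 200 samples
        se = np.sqrt(0.25 / len(y_shuf))
        assert abs(res.cv_accuracy - 0.5) <= 3 * se + 0.05

    def test_determinism_given_seed(self):
        X, y = _training_pool(60, seed=5)
        r1 = train_classifier(X, y, ClassifierConfig(seed=7))
        r2 = train_classifier(X, y, ClassifierConfig(seed=7))
        assert r1.best_c == r2.best_c
        assert np.array_equal(r1.predict_proba(X), r2.predict_proba(X))

    def test_single_class_rejected(self):
        X, _ = _training_pool(30, seed=6)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(X, ["same"] * len(X))

    def test_tiny_class_rejected(self):
        X, y = _training_pool(30, seed=7)
        y = ["a"] + ["b"] * (len(X) - 1)
        with pytest.raises(ValueError, match="< 2 examples"):
            train_classifier(X, y)

    def test_below_minimum_training_size_warns(self):
        X, y = _training_pool(10, seed=8)
        with pytest.warns(UserWarning, match="minimum"):
            OrfClassifier(X, y)


@pytest.fixture(scope="module")
def fitted():
    X, y = _training_pool(100, seed=10)
    return train_classifier(X, y, ClassifierConfig(seed=11))


class TestPrediction:
    def test_rows_sum_to_one(self, fitted):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 10, size=(1000, 64))
        proba = fitted.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_rows_identical_outputs(self, fitted):
        row = np.arange(64)[None, :]
        proba = fitted.predict_proba(np.vstack([row, row, row]))
        assert np.array_equal(proba[0], proba[1]) and np.array_equal(proba[1], proba[2])

    def test_training_point_confidently_classified(self, fitted):
        X, y = _training_pool(100, seed=10)
        proba = fitted.predict_proba(X[:10])
        cls = list(fitted.classes_)
        for p, lab in zip(proba, y[:10]):
            assert p[cls.index(lab)] > 0.9

    def test_wrong_feature_width_rejected(self, fitted):
        with pytest.raises(ValueError, match="64"):
            fitted.predict_proba(np.zeros((3, 63)))


class TestSelection:
    def test_argmax_wins(self):
        a, b = _orf("ATG" * 50, "t"), _orf("ATG" * 30, "t", start=7)
        sel, _ = select_best_orfs({"t": [a, b]}, {"t": [0.97, 0.61]})
        assert sel["t"] is a

    def test_probability_tie_prefers_longer(self):
        short = _orf("A" * 150, "t", start=1)
        long_ = _orf("A" * 300, "t", start=31)
        sel, _ = select_best_orfs({"t": [short, long_]}, {"t": [0.90, 0.90]})
        assert sel["t"] is long_

    def test_full_tie_prefers_smaller_start_then_positive_frame(self):
        a = _orf("A" * 150, "t", frame=1, start=10)
        b = _orf("A" * 150, "t", frame=2, start=40)
        sel, _ = select_best_orfs({"t": [b, a]}, {"t": [0.5, 0.5]})
        assert sel["t"] is a
        c = _orf("A" * 150, "t", frame=-1, start=10)
        sel, _ = select_best_orfs({"t": [c, a]}, {"t": [0.5, 0.5]})
        assert sel["t"] is a

    def test_empty_candidates_counted(self):
        sel, n_empty = select_best_orfs({"t": []}, {"t": []})
        assert sel == {} and n_empty == 1


class TestPersistence:
    def test_round_trip_is_bit_identical(self, tmp_path):
        X, y = _training_pool(60, seed=13)
        res = train_classifier(X, y, ClassifierConfig(seed=14))
        path = tmp_path / "model.cosv"
        res.save(path)
        loaded = load_model(path)
        Xq = np.random.default_rng(15).integers(0, 12, size=(100, 64))
        assert np.array_equal(res.predict_proba(Xq), loaded.predict_proba(Xq))
        assert list(loaded.classes_) == [str(c) for c in res.classes_]
        assert loaded.provenance["seed"] == 14

    def test_corrupted_archive_raises(self, tmp_path):
        path = tmp_path / "bad.cosv"
        path.write_bytes(b"this is not a zip archive")
        with pytest.raises(ModelArchiveError):
            load_model(path)

    def test_truncated_archive_raises(self, tmp_path):
        X, y = _training_pool(40, seed=16)
        res = train_classifier(X, y, ClassifierConfig(seed=17))
        path = tmp_path / "model.cosv"
        res.save(path)
        (tmp_path / "trunc.cosv").write_bytes(path.read_bytes()[:200])
        with pytest.raises(ModelArchiveError):
            load_model(tmp_path / "trunc.cosv")

    def test_code_table_mismatch_warns(self, tmp_path):
        X, y = _training_pool(40, seed=18)
        res = train_classifier(X, y, ClassifierConfig(seed=19), code_table_id=6)
        with pytest.warns(UserWarning, match="table 6"):
            res.predict_proba(np.zeros((1, 64)), code_table_id=1)
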