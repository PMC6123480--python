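"""Unit and property tests for reading, k-mer extraction and sketching."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gepmi
from gepmi import (
    KmerSet,
    SequenceSample,
    SketchCompatibilityError,
    UndefinedSimilarityError,
    downsample_bases,
    estimate_jaccard,
    extract_kmers,
    minhash_sketch,
    pairwise_similarity,
    read_sequences,
    trim_low_abundance,
)
from gepmi._kmers import decode_kmer, encode_kmer, reverse_complement

from conftest import brute_force_canonical_kmers, brute_force_jaccard


# ---------------------------------------------------------------------- reads


class TestReadSequences:
    def test_fasta_reads_and_bases(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">r1\nACGT\n>r2\nGG\n")
        s = read_sequences(p, sample_id="x", individual_id="i")
        assert s.reads == ["ACGT", "GG"]
        assert s.total_bases == 6

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        s = read_sequences(p)
        assert s.reads == [] and s.total_bases == 0

    def test_gzip_and_lowercase(self, tmp_path):
        p = tmp_path / "x.fq.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("@r1\nacgt\n+\nIIII\n")
        s = read_sequences(p)
        assert s.reads == ["ACGT"]

    def test_malformed_fastq_names_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="record #1"):
            read_sequences(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            read_sequences(tmp_path / "nope.fa")


# ---------------------------------------------------------------- downsample


class TestDownsample:
    def test_budget_exceeds_supply_returns_sample_unchanged(self):
        s = SequenceSample("a", "i", ["A" * 100])
        assert downsample_bases(s, 1000, seed=0) is s

    def test_stopping_rule_keeps_exactly_three_reads(self):
        s = SequenceSample("a", "i", ["A" * 100 for _ in range(10)])
        out = downsample_bases(s, 250, seed=3)
        assert len(out.reads) == 3 and out.total_bases == 300

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        reads = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(40)]
        s = SequenceSample("a", "i", reads)
        out1 = downsample_bases(s, 500, seed=11)
        out2 = downsample_bases(s, 500, seed=11)
        assert out1.reads == out2.reads

    def test_rejects_nonpositive_budget(self):
        s = SequenceSample("a", "i", ["ACGT"])
        with pytest.raises(ValueError):
            downsample_bases(s, 0, seed=0)


# ------------------------------------------------------------------- k-mers


class TestExtractKmers:
    def test_hand_enumerated_example(self):
        s = SequenceSample("a", "i", ["ACGTA"])
        assert extract_kmers(s, 3).as_dict() == {"ACG": 2, "GTA": 1}

    def test_read_shorter_than_k(self):
        assert len(extract_kmers(SequenceSample("a", "i", ["AC"]), 3)) == 0

    def test_n_windows_skipped(self):
        assert len(extract_kmers(SequenceSample("a", "i", ["ACNGT"]), 3)) == 0

    def test_windows_never_span_reads(self):
        merged = extract_kmers(SequenceSample("a", "i", ["ACG", "TAC"]), 3).as_dict()
        split = brute_force_canonical_kmers(["ACG", "TAC"], 3)
        assert merged == split

    @pytest.mark.parametrize("k", [1, 3, 7, 18])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        reads = [
            "".join(rng.choice(list("ACGTN"), rng.integers(1, 80), p=[0.24] * 4 + [0.04]))
            for _ in range(20)
        ]
        sample = SequenceSample("a", "i", reads)
        assert extract_kmers(sample, k).as_dict() == brute_force_canonical_kmers(reads, k)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        fwd = extract_kmers(SequenceSample("a", "i", [seq]), 5).as_dict()
        rev = extract_kmers(
            SequenceSample("a", "i", [reverse_complement(seq)]), 5
        ).as_dict()
        assert fwd == rev

    def test_encode_decode_roundtrip(self):
        for kmer in ["A", "ACGT", "TTTTTTTTTTTTTTTTTT", "GATTACAGATTACAGATT"]:
            assert decode_kmer(int(encode_kmer(kmer)), len(kmer)) == kmer


class TestTrimLowAbundance:
    def test_threshold(self):
        t = extract_kmers(SequenceSample("a", "i", ["ACGTA"]), 3)
        assert trim_low_abundance(t, 2).to_strings() == {"ACG"}

    def test_cutoff_one_keeps_all(self):
        t = extract_kmers(SequenceSample("a", "i", ["ACGTA"]), 3)
        assert trim_low_abundance(t, 1).to_strings() == {"ACG", "GTA"}

    def test_empty_table(self):
        t = extract_kmers(SequenceSample("a", "i", []), 3)
        assert len(trim_low_abundance(t, 2)) == 0

    def test_rejects_nonpositive_cutoff(self):
        t = extract_kmers(SequenceSample("a", "i", ["ACGTA"]), 3)
        with pytest.raises(ValueError):
            trim_low_abundance(t, 0)


# ------------------------------------------------------------------- sketch


def _random_kmer_sets(rng, size_a, size_b, shared, k=31):
    """Random packed k-mer sets with a prescribed overlap (test helper)."""
    total = size_a + size_b - shared
    universe = np.unique(rng.integers(0, 4**20, size=2 * total + 16, dtype=np.uint64))
    rng.shuffle(universe)
    universe = universe[:total]
    a = universe[:size_a]
    b = np.concatenate([universe[:shared], universe[size_a:]])
    return KmerSet(k=k, packed=np.sort(a)), KmerSet(k=k, packed=np.sort(b))


class TestMinhashSketch:
    def test_small_set_keeps_all_hashes(self):
        ks = minhash_sketch(["ACG", "GTA", "AAA", "CCC", "TAG"], n=10_000)
        assert ks.hashes.size == 5
        assert np.all(ks.hashes[1:] > ks.hashes[:-1])  # sorted, distinct

    def test_determinism(self):
        a = minhash_sketch(["ACG", "GTA"], n=10, hash_seed=42)
        b = minhash_sketch(["ACG", "GTA"], n=10, hash_seed=42)
        assert np.array_equal(a.hashes, b.hashes)

    def test_set_semantics(self):
        a = minhash_sketch(["ACG", "GTA"], n=10)
        b = minhash_sketch(["ACG", "GTA", "ACG", "GTA"], n=10)
        assert np.array_equal(a.hashes, b.hashes)

    def test_seed_changes_hashes(self):
        a = minhash_sketch(["ACG", "GTA"], n=10, hash_seed=1)
        b = minhash_sketch(["ACG", "GTA"], n=10, hash_seed=2)
        assert not np.array_equal(a.hashes, b.hashes)


class TestEstimateJaccard:
    def test_identical_sketches(self):
        a = minhash_sketch(["ACG", "GTA", "AAA"], n=100, sample_id="a")
        b = minhash_sketch(["ACG", "GTA", "AAA"], n=100, sample_id="b")
        assert estimate_jaccard(a, b) == 1.0

    def test_disjoint_sets(self):
        a = minhash_sketch(["AAA"], n=100)
        b = minhash_sketch(["GGG"], n=100)
        assert estimate_jaccard(a, b) == 0.0

    def test_small_regime_exact_fraction(self):
        rng = np.random.default_rng(0)
        a, b = _random_kmer_sets(rng, 6, 6, 3)
        sa = minhash_sketch(a, n=100)
        sb = minhash_sketch(b, n=100)
        assert estimate_jaccard(sa, sb) == pytest.approx(3 / 9, abs=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_in_small_regime_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        size_a, size_b = rng.integers(5, 200, size=2)
        shared = int(rng.integers(0, min(size_a, size_b) + 1))
        a, b = _random_kmer_sets(rng, int(size_a), int(size_b), shared)
        sa, sb = minhash_sketch(a, n=500), minhash_sketch(b, n=500)
        expected = brute_force_jaccard(a.packed.tolist(), b.packed.tolist())
        assert estimate_jaccard(sa, sb) == pytest.approx(expected, abs=1e-15)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = _random_kmer_sets(rng, 500, 400, 100)
        sa, sb = minhash_sketch(a, n=50), minhash_sketch(b, n=50)
        assert estimate_jaccard(sa, sb) == estimate_jaccard(sb, sa)

    def test_incompatible_sketches_rejected(self):
        a = minhash_sketch(["ACG"], n=10, hash_seed=1)
        b = minhash_sketch(["ACG"], n=10, hash_seed=2)
        with pytest.raises(SketchCompatibilityError):
            estimate_jaccard(a, b)

    def test_both_empty_undefined(self):
        empty = KmerSet(k=3, packed=np.empty(0, dtype=np.uint64))
        a = minhash_sketch(empty, n=10, sample_id="a")
        b = minhash_sketch(empty, n=10, sample_id="b")
        with pytest.raises(UndefinedSimilarityError):
            estimate_jaccard(a, b)


class TestPairwiseSimilarity:
    def test_identical_sketches_all_ones(self):
        sketches = [
            minhash_sketch(["ACG", "GTA"], n=10, sample_id=f"s{i}") for i in range(3)
        ]
        m = pairwise_similarity(sketches)
        assert np.array_equal(m.values, np.ones((3, 3)))

    def test_disjoint_sets_identity_matrix(self):
        sketches = [
            minhash_sketch([km], n=10, sample_id=f"s{i}")
            for i, km in enumerate(["AAA", "GGG", "ATA"])
        ]
        m = pairwise_similarity(sketches)
        assert np.array_equal(m.values, np.eye(3))

    def test_entries_match_single_pair_calls(self):
        rng = np.random.default_rng(2)
        sets = [_random_kmer_sets(rng, 300, 300, 150)[0] for _ in range(4)]
        sketches = [minhash_sketch(s, n=50, sample_id=f"s{i}") for i, s in enumerate(sets)]
        m = pairwise_similarity(sketches)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert m.values[i, j] == estimate_jaccard(sketches[i], sketches[j])

    def test_duplicate_ids_rejected(self):
        s = minhash_sketch(["ACG"], n=10, sample_id="dup")
        with pytest.raises(ValueError):
            pairwise_similarity([s, s])


# ---------------------------------------------------------------------- I/O


class TestRoundTrips:
    def test_sketch_json_bit_identical(self, tmp_path):
        ks = minhash_sketch(["ACG", "GTA", "TTT"], n=10, sample_id="s1")
        p1, p2 = tmp_path / "a.sig", tmp_path / "b.sig"
        ks.save(p1)
        gepmi.KmerSketch.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_similarity_csv_bit_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        ids = ["a", "b", "c"]
        v = rng.random((3, 3))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        m = gepmi.SimilarityMatrix(sample_ids=ids, values=v)
        p1, p2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        m.to_csv(p1)
        gepmi.SimilarityMatrix.from_csv(p1).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_header_is_sample_ids(self, tmp_path):
        m = gepmi.SimilarityMatrix(sample_ids=["x", "y"], values=np.eye(2))
        p = tmp_path / "m.csv"
        m.to_csv(p)
        assert p.read_text().splitlines()[0] == "x,y"
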