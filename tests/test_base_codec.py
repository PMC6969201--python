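import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fqpack.base_codec import (ReadBaseCoder, decode_base, encode_base,
                               maybe_correct, pack_prefix, predict,
                               unpack_prefix)
from fqpack.kmer_dicts import Config, TieredDictionaries, seq_to_codes
from fqpack.rangecoder import RangeDecoder, RangeEncoder
from fqpack.rank_model import RankModel

FIG_CFG = Config(genome_size=10_000, tier_sizes=(4, 6, 9, 12))


class TestPackPrefix:
    def test_worked_examples(self):
        assert pack_prefix("ATACCG") == 790
        assert pack_prefix("ATACAT") == 787
        assert pack_prefix("ATACCG") - pack_prefix("ATACAT") == 3
        assert pack_prefix("AAAAAA") == 0

    @given(st.text(st.sampled_from("ACGT"), min_size=1, max_size=16))
    def test_bijective(self, pmer):
        assert unpack_prefix(pack_prefix(pmer), len(pmer)) == pmer

    def test_n_signals_fallback(self):
        with pytest.raises(ValueError):
            pack_prefix("ATANCG")


class TestMaybeCorrect:
    def test_dominant_counter_replaces(self):
        assert maybe_correct((0, 5, 0, 0), "A") == "C"

    def test_threshold_three(self):
        assert maybe_correct((0, 2, 0, 0), "A") == "A"
        assert maybe_correct((0, 3, 0, 0), "A") == "C"

    def test_nonzero_current_count_keeps_symbol(self):
        assert maybe_correct((1, 5, 0, 0), "A") == "A"

    def test_ambiguous_maximum_keeps_symbol(self):
        assert maybe_correct((0, 5, 5, 0), "A") == "A"

    def test_n_never_corrected(self):
        assert maybe_correct((0, 9, 0, 0), "N") == "N"


class TestPredictCascade:
    """The worked tier-cascade scenarios with e=4, p=6, s=9, b=12."""

    def test_midread_uses_p_tier(self):
        d = TieredDictionaries(FIG_CFG)
        for base, n in zip("ACGT", (31, 10, 454, 5)):
            for _ in range(n):
                d.insert_read("ATACC" + base)
        ans = predict(d, "ATACC")
        assert (ans.tier, ans.counts, ans.missing) == ("p", (31, 10, 454, 5), 0)

    def test_partial_s_query_with_one_missing(self):
        d = TieredDictionaries(FIG_CFG)
        for pre, base, n in (("A", "A", 2), ("C", "C", 155), ("G", "G", 54),
                             ("T", "T", 12)):
            for _ in range(n):
                d.insert_read(pre + "ATACCGT" + base)
        ans = predict(d, "ATACCGT")
        assert (ans.tier, ans.counts, ans.missing) == ("s", (2, 155, 54, 12), 1)

    def test_empty_b_falls_back_to_s(self):
        d = TieredDictionaries(FIG_CFG)
        for base, n in (("A", 15), ("G", 15)):
            for _ in range(n):
                d.insert_read("GTCAGGTA" + base)
        ans = predict(d, "ATACCGTCAGGTA")
        assert (ans.tier, ans.counts) == ("s", (15, 0, 15, 0))

    def test_too_short_history_is_order0(self):
        d = TieredDictionaries(FIG_CFG)
        d.insert_read("ACGTACGTACGT")
        ans = predict(d, "AC")  # fewer than e-1 symbols
        assert ans.tier == "order0"

    def test_n_blocked_context_is_order0(self):
        d = TieredDictionaries(FIG_CFG)
        d.insert_read("ACGTACGTACGT")
        assert predict(d, "ACGN").tier == "order0"

    def test_all_zero_returns_smallest_usable_tier(self):
        d = TieredDictionaries(FIG_CFG)
        ans = predict(d, "ACGTACGTACGTACG")
        assert ans.tier == "e" and ans.counts == (0, 0, 0, 0)


def _roundtrip_reads(cfg, seqs, reo=False):
    enc_b, enc_p = RangeEncoder(), RangeEncoder()
    coder = ReadBaseCoder(cfg)
    coder.start_block()
    marks = [0]
    for s in seqs:
        codes = seq_to_codes(s)
        if reo:
            coder.encode_prefixed_read(enc_p, enc_b, codes)
        else:
            coder.encode_read(enc_b, codes)
        marks.append(enc_b.tell())
    data_b, data_p = enc_b.flush(), enc_p.flush()
    dec_b, dec_p = RangeDecoder(data_b), RangeDecoder(data_p)
    dcoder = ReadBaseCoder(cfg)
    dcoder.start_block()
    out = []
    from fqpack.kmer_dicts import codes_to_seq
    for s in seqs:
        if reo:
            got = dcoder.decode_prefixed_read(dec_p, dec_b, len(s))
        else:
            got = dcoder.decode_read(dec_b, len(s))
        out.append(codes_to_seq(got))
    return out, marks, len(data_b) + len(data_p), coder, dcoder


class TestReadRoundTrip:
    @pytest.mark.parametrize("reo", [False, True])
    def test_random_reads(self, reo):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGTN"), rng.integers(5, 80),
                                   p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                for _ in range(60)]
        if reo:
            seqs.sort()
        cfg = Config(genome_size=10_000, reordered=reo)
        out, _, _, c, d = _roundtrip_reads(cfg, seqs, reo)
        assert out == seqs
        assert c.digest() == d.digest()

    def test_all_n_read(self):
        seqs = ["N" * 40, "N" * 10]
        out, _, _, _, _ = _roundtrip_reads(Config(genome_size=10_000), seqs)
        assert out == seqs

    def test_reads_shorter_than_prefix_in_reo(self):
        cfg = Config(genome_size=10_000, reordered=True)
        seqs = sorted(["ACG", "GT", "ACGTACGTACGTACGT", "NNAACGTT"])
        out, _, _, _, _ = _roundtrip_reads(cfg, seqs, reo=True)
        assert out == seqs

    def test_second_identical_read_costs_less(self):
        read = "ACGTTGCAGGCTTACCGATACGATCGGATCATTACGGATC" * 3
        _, marks, _, _, _ = _roundtrip_reads(
            Config(genome_size=10_000), [read, read])
        first = marks[1] - marks[0]
        second = marks[2] - marks[1]
        assert second < first

    def test_corrections_stay_lossless(self):
        # one read with a lone substitution against a well-supported context:
        # the decoder must still reproduce the erroneous base.
        base = "ATACCGTCAGGTAGGATCCATTACGGATCCATTAAGGCAT"
        err = base[:20] + "ACGT"[(("ACGT".index(base[20])) + 1) % 4] + base[21:]
        seqs = [base] * 10 + [err]
        out, _, _, c, d = _roundtrip_reads(Config(genome_size=10_000), seqs)
        assert out == seqs
        assert c.digest() == d.digest()


class TestPrefixDelta:
    def test_worked_delta_example(self):
        cfg = Config(genome_size=10_000, tier_sizes=(4, 6, 9, 12),
                     reordered=True)
        enc_b, enc_p = RangeEncoder(), RangeEncoder()
        coder = ReadBaseCoder(cfg)
        coder.encode_prefixed_read(enc_p, enc_b, seq_to_codes("ATACAT"))
        assert coder.prev_packed == 787
        coder.encode_prefixed_read(enc_p, enc_b, seq_to_codes("ATACCG"))
        assert coder.prev_packed == 790

    def test_unsorted_input_is_contract_violation(self):
        cfg = Config(genome_size=10_000, tier_sizes=(4, 6, 9, 12),
                     reordered=True)
        enc_b, enc_p = RangeEncoder(), RangeEncoder()
        coder = ReadBaseCoder(cfg)
        coder.encode_prefixed_read(enc_p, enc_b, seq_to_codes("ATACCG"))
        with pytest.raises(RuntimeError, match="sort"):
            coder.encode_prefixed_read(enc_p, enc_b, seq_to_codes("ATACAT"))

    def test_sorted_random_prefixes_round_trip(self):
        rng = np.random.default_rng(23)
        seqs = sorted("".join(rng.choice(list("ACGT"), 30)) for _ in range(100))
        cfg = Config(genome_size=10_000, reordered=True)
        out, _, _, _, _ = _roundtrip_reads(cfg, seqs, reo=True)
        assert out == seqs


class TestSingleBasePath:
    def test_encode_decode_base_mirror(self):
        d = TieredDictionaries(FIG_CFG)
        for base, n in zip("ACGT", (31, 10, 454, 5)):
            for _ in range(n):
                d.insert_read("ATACC" + base)
        ans = predict(d, "ATACC")
        menc, mdec = RankModel(), RankModel()
        enc = RangeEncoder()
        ranks = [encode_base(enc, menc, ans, 5, sym) for sym in "GGAN"]
        assert ranks[0] == 0  # G is rank 0 under (31,10,454,5)
        assert ranks[3] == 4  # N always rank 4
        dec = RangeDecoder(enc.flush())
        got = [decode_base(dec, mdec, ans, 5) for _ in range(4)]
        assert "".join(got) == "GGAN"
        assert np.array_equal(menc.freqs, mdec.freqs)

    def test_zero_counts_rank_is_lexicographic(self):
        from fqpack.base_codec import TierAnswer
        menc = RankModel()
        enc = RangeEncoder()
        ans = TierAnswer("order0", (0, 0, 0, 0), 0)
        assert encode_base(enc, menc, ans, 0, "A") == 0
        assert encode_base(enc, menc, ans, 0, "T") == 3
        enc.flush()


class TestLearningBehaviour:
    def test_coverage_monotonicity(self):
        """Mean bits/base non-increasing (within noise) as coverage grows."""
        from fqpack.archive import compress_records
        from fqpack.simdata import SimSpec, sample_reads, simulate_genome

        genome = simulate_genome(30_000, 31)
        bpb = []
        for cov in (1, 5, 20):
            reads = sample_reads(genome, SimSpec(
                genome_length=30_000, coverage=cov, read_length=100,
                error_rate=0.001, seed=31))
            cfg = Config(genome_size=30_000, quality_mode="none", id_mode="none")
            _, stats = compress_records(reads, cfg)
            bpb.append(stats.bits_per_base)
        assert bpb[1] <= bpb[0] * 1.05
        assert bpb[2] <= bpb[1] * 1.05
        assert bpb[2] < 2.0  # far below naive 2-bit packing at high coverage
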