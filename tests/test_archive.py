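import numpy as np
import pytest

from fqpack.archive import (ArchiveError, compress, compress_records,
                            decompress, decompress_records, read_header,
                            sort_for_reo)
from fqpack.fastq_io import ReadRecord, read_fastq, write_fastq
from fqpack.kmer_dicts import Config


def fastq_text(records):
    return "".join(r.to_fastq() for r in records)


class TestSortForReo:
    def test_lexicographic(self):
        recs = [ReadRecord("a", s, "I" * len(s)) for s in ["T", "A", "C"]]
        assert [r.sequence for r in sort_for_reo(recs)] == ["A", "C", "T"]

    def test_stability(self):
        recs = [ReadRecord(f"r{i}", "ACGT", "IIII") for i in range(5)]
        assert [r.id for r in sort_for_reo(recs)] == [f"r{i}" for i in range(5)]

    def test_pe_sorts_by_first_mate(self):
        pairs = [(ReadRecord("x", "TTT", "III"), ReadRecord("x", "AAA", "III")),
                 (ReadRecord("y", "AAA", "III"), ReadRecord("y", "TTT", "III"))]
        assert [p[0].sequence for p in sort_for_reo(pairs)] == ["AAA", "TTT"]

    def test_sorted_prefix_deltas_nonnegative(self):
        from fqpack.base_codec import pack_prefix
        rng = np.random.default_rng(0)
        recs = [ReadRecord("r", "".join(rng.choice(list("ACGT"), 20)), "I" * 20)
                for _ in range(200)]
        packed = [pack_prefix(r.sequence[:7]) for r in sort_for_reo(recs)]
        assert all(b - a >= 0 for a, b in zip(packed, packed[1:]))


class TestRoundTrips:
    def test_oo_lossless_byte_identical(self, small_sim):
        _, reads = small_sim
        cfg = Config(genome_size=50_000)
        data, stats = compress_records(reads, cfg)
        cfg2, out = decompress_records(data)
        assert fastq_text(out) == fastq_text(reads)
        assert stats.bits_per_base < 2.0
        assert cfg2.tier_sizes == cfg.tier_sizes

    def test_reo_is_sorted_content_multiset(self, small_sim):
        _, reads = small_sim
        cfg = Config(genome_size=50_000, reordered=True)
        data, _ = compress_records(reads, cfg)
        _, out = decompress_records(data)
        key = lambda r: (r.id, r.sequence, r.quality)
        assert sorted(map(key, out)) == sorted(map(key, reads))
        assert [r.sequence for r in out] == sorted(r.sequence for r in out)

    def test_empty_input(self):
        data, stats = compress_records([], Config(genome_size=10_000))
        cfg, out = decompress_records(data)
        assert out == [] and stats.n_records == 0

    def test_deterministic_archives(self, small_sim):
        _, reads = small_sim
        cfg = Config(genome_size=50_000, quality_mode="8")
        assert compress_records(reads, cfg)[0] == compress_records(reads, cfg)[0]

    def test_multi_block_with_digests(self, small_sim):
        _, reads = small_sim
        cfg = Config(genome_size=50_000, block_size=1 << 18)
        tr_e, tr_d = [], []
        data, stats = compress_records(reads, cfg, trace=tr_e)
        _, out = decompress_records(data, trace=tr_d)
        assert stats.n_blocks > 1
        assert tr_e == tr_d                     # state digests match per block
        assert fastq_text(out) == fastq_text(reads)

    def test_pe_round_trip(self, small_pairs):
        _, pairs = small_pairs
        cfg = Config(genome_size=30_000, paired=True)
        data, stats = compress_records(pairs, cfg)
        _, out = decompress_records(data)
        assert fastq_text([r for p in out for r in p]) == \
            fastq_text([r for p in pairs for r in p])
        assert stats.pe_hits > 0

    def test_lossy_quality_mode_idempotent(self, small_sim):
        _, reads = small_sim
        cfg = Config(genome_size=50_000, quality_mode="2")
        data, _ = compress_records(reads, cfg)
        _, out = decompress_records(data)
        assert all(set(r.quality) <= {"'", "F"} for r in out)  # Q6/Q37 chars
        data2, _ = compress_records(out, cfg)
        _, out2 = decompress_records(data2)
        assert fastq_text(out2) == fastq_text(out)


class TestHeaderAndErrors:
    def _archive(self, small_sim, **kw):
        _, reads = small_sim
        cfg = Config(genome_size=50_000, **kw)
        data, _ = compress_records(reads, cfg)
        return data

    def test_header_round_trip(self, small_sim):
        data = self._archive(small_sim, quality_mode="8", reordered=True)
        info = read_header(data)
        assert info.config.reordered and info.config.quality_mode == "8"
        assert info.config.genome_size == 50_000
        assert info.n_records == 5000
        assert len(info.bin_table) == 8

    def test_bad_magic(self):
        with pytest.raises(ArchiveError, match="magic"):
            read_header(b"NOPE" + b"\x00" * 64)

    def test_truncated_payload(self, small_sim):
        data = self._archive(small_sim)
        with pytest.raises(ArchiveError, match="truncated"):
            decompress_records(data[:len(data) // 2])

    def test_corruption_names_block(self, small_sim):
        data = bytearray(self._archive(small_sim))
        data[-100] ^= 0xFF  # flip a payload byte in the last stream
        with pytest.raises(ArchiveError):
            decompress_records(bytes(data))


class TestFileApi:
    def test_se_files(self, tmp_path, small_sim):
        _, reads = small_sim
        fin = tmp_path / "in.fastq"
        write_fastq(reads[:500], str(fin))
        cfg = Config(genome_size=50_000)
        data, _ = compress(str(fin), cfg, output=str(tmp_path / "a.fqpk"))
        fout = tmp_path / "out.fastq"
        decompress(str(tmp_path / "a.fqpk"), [str(fout)])
        assert fout.read_bytes() == fin.read_bytes()

    def test_pe_files(self, tmp_path, small_pairs):
        _, pairs = small_pairs
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq([p[0] for p in pairs[:300]], str(f1))
        write_fastq([p[1] for p in pairs[:300]], str(f2))
        cfg = Config(genome_size=30_000, paired=True)
        arc = tmp_path / "a.fqpk"
        compress([str(f1), str(f2)], cfg, output=str(arc))
        o1, o2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        decompress(str(arc), [str(o1), str(o2)])
        assert o1.read_bytes() == f1.read_bytes()
        assert o2.read_bytes() == f2.read_bytes()

    def test_wrong_file_counts(self, tmp_path):
        cfg = Config(genome_size=10_000, paired=True)
        with pytest.raises(ValueError, match="two input"):
            compress(str(tmp_path / "x.fastq"), cfg)
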