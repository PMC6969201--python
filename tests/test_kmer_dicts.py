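from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fqpack.kmer_dicts import (Config, TieredDictionaries, canonical,
                               derive_tier_sizes, revcomp)

kmers = st.text(st.sampled_from("ACGT"), min_size=1, max_size=25)

FIG_TIERS = (4, 6, 9, 12)  # small illustrative tier sizes


def make_dicts(tiers=FIG_TIERS):
    return TieredDictionaries(Config(genome_size=10_000, tier_sizes=tiers))


def brute_successors(reads, k, context):
    """Naive recount: canonical k-mer occurrences over all inserted reads."""
    bag = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i:i + k]
            if "N" not in km:
                bag[canonical(km)] += 1
    return tuple(bag[canonical(context + c)] for c in "ACGT")


class TestCanonical:
    def test_examples(self):
        assert canonical("ACG") == "ACG"
        assert canonical("TTT") == "AAA"

    @given(kmers)
    def test_idempotent_and_strand_invariant(self, km):
        c = canonical(km)
        assert canonical(c) == c
        assert canonical(revcomp(km)) == c
        assert c <= revcomp(c)

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            canonical("ANA")


class TestDeriveTierSizes:
    def test_bacterial_scale(self):
        assert derive_tier_sizes(430_000_000) == (11, 15, 18, 21)

    def test_clamp_floor(self):
        assert derive_tier_sizes(1000) == (4, 7, 10, 13)

    @pytest.mark.parametrize("g", [1000, 10_000, 5 * 10 ** 6, 3 * 10 ** 9, 10 ** 12])
    def test_ordering_invariant(self, g):
        e, p, s, b = derive_tier_sizes(g)
        assert 0 < e < p < s < b <= 31

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            derive_tier_sizes(999)


class TestInsertQuery:
    def test_insert_short_read_counts_e_mers(self):
        d = make_dicts(tiers=(3, 6, 9, 12))
        d.insert_read("ACGT")
        # 3-mers ACG and CGT; canonical(ACG)=ACG, canonical(CGT)=ACG
        assert d.get_count("e", "ACG") == 2
        assert d.tiers["e"].n_inserted == 2

    def test_n_excluded(self):
        d = make_dicts(tiers=(3, 6, 9, 12))
        d.insert_read("ANGT")
        assert d.tiers["e"].n_inserted == 0
        assert tuple(d.query_successors("e", "GT")) == (0, 0, 0, 0)

    def test_revcomp_read_doubles_counters(self):
        d1, d2 = make_dicts(), make_dicts()
        read = "ATACCGTCAGGTAGGA"
        d1.insert_read(read)
        d2.insert_read(read)
        d2.insert_read(revcomp(read))
        for tier in "bspe":
            k = d1.tiers[tier].k
            for i in range(len(read) - k + 1):
                km = read[i:i + k]
                assert d2.get_count(tier, km) == 2 * d1.get_count(tier, km)

    def test_paper_style_successor_counts(self):
        d = make_dicts()
        for base, n in zip("ACGT", (31, 10, 454, 5)):
            for _ in range(n):
                d.insert_read("ATACC" + base)
        assert tuple(d.query_successors("p", "ATACC")) == (31, 10, 454, 5)

    def test_unseen_context_is_zero(self):
        d = make_dicts()
        assert tuple(d.query_successors("p", "GGGGG")) == (0, 0, 0, 0)
        assert tuple(d.query_partial("s", "ATACCGT", 1)) == (0, 0, 0, 0)

    def test_partial_query_aggregates_completions(self):
        d = make_dicts()
        for pre, base, n in (("A", "A", 2), ("C", "C", 155), ("G", "G", 54),
                             ("T", "T", 12)):
            for _ in range(n):
                d.insert_read(pre + "ATACCGT" + base)
        assert tuple(d.query_partial("s", "ATACCGT", 1)) == (2, 155, 54, 12)

    def test_partial_equals_sum_of_exact(self):
        rng = np.random.default_rng(3)
        reads = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(30)]
        d = make_dicts()
        for r in reads:
            d.insert_read(r)
        suffix = reads[0][5:12]  # 7 symbols; s-tier context is 8
        total = np.zeros(4, np.int64)
        for x in "ACGT":
            total += d.query_successors("s", x + suffix)
        assert tuple(d.query_partial("s", suffix, 1)) == tuple(total)

    def test_contract_errors(self):
        d = make_dicts()
        with pytest.raises(ValueError):
            d.query_successors("p", "AC")  # wrong length
        with pytest.raises(ValueError):
            d.query_partial("s", "ATACC", 3)  # missing > 2
        with pytest.raises(ValueError):
            d.query_partial("s", "ATANCGT", 1)  # N in context


class TestOracleEquivalence:
    """Every query equals a brute-force recount on small instances."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_and_partial_queries(self, seed):
        rng = np.random.default_rng(seed)
        reads = ["".join(rng.choice(list("ACGTN"), rng.integers(15, 60),
                                    p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                 for _ in range(40)]
        d = make_dicts()
        for r in reads:
            d.insert_read(r)
        for tier in "espb":
            k = d.tiers[tier].k
            # exact queries over contexts drawn from the reads
            for r in reads[:10]:
                for i in range(0, max(len(r) - k, 0), 7):
                    ctx = r[i:i + k - 1]
                    if "N" in ctx:
                        continue
                    assert tuple(d.query_successors(tier, ctx)) == \
                        brute_successors(reads, k, ctx), (tier, ctx)
            # partial queries: sum of brute counts over completions
            for r in reads[10:14]:
                for missing in (1, 2):
                    if len(r) < k:
                        continue
                    suffix = r[:k - 1 - missing]
                    if "N" in suffix:
                        continue
                    exp = np.zeros(4, np.int64)
                    for pv in range(4 ** missing):
                        pre = "".join("ACGT"[(pv >> (2 * (missing - 1 - j))) & 3]
                                      for j in range(missing))
                        exp += np.array(brute_successors(reads, k, pre + suffix))
                    assert tuple(d.query_partial(tier, suffix, missing)) == tuple(exp)

    def test_conservation(self):
        rng = np.random.default_rng(4)
        reads = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(50)]
        d = make_dicts()
        for r in reads:
            d.insert_read(r)
        for tier in "espb":
            t = d.tiers[tier]
            assert t.total_count() == t.n_inserted == 50 * (50 - t.k + 1)
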