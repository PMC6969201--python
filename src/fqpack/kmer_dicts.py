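"""Tiered canonical k-mer count dictionaries D_e, D_p, D_s, D_b.

Each tier k counts occurrences of canonical k-mers seen in the processed
reads.  Successor statistics for a (k-1)-symbol context are materialized on
demand by four canonical lookups, so a read and its reverse complement
reinforce exactly the same entries.  Counters saturate at 2**16 - 1; they
feed only rank ordering and the correction rule, both order-based.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels as K

_COMP = str.maketrans("ACGT", "TGCA")
_CODE_LUT = np.full(256, 4, np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE_LUT[ord(_ch)] = _i
_CHAR_LUT = np.frombuffer(b"ACGTN", np.uint8)

QUALITY_MODES = ("96", "8", "4", "2", "none")
ID_MODES = ("lossless", "instrument", "none")

DEFAULT_BLOCK_SIZE = 16 * 1024 * 1024
COUNT_CAP = (1 << 16) - 1


def seq_to_codes(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CHAR_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    if "N" in kmer:
        raise ValueError("canonical() is undefined for k-mers containing N")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def derive_tier_sizes(genome_size: int) -> Tuple[int, int, int, int]:
    """Map a declared approximate genome size to tier k-mer lengths (e,p,s,b).

    b grows with log4 of the genome so that b-mers are mostly unique in it;
    the lower tiers are fixed offsets below.  Always satisfies e < p < s < b.
    """
    if genome_size < 1000:
        raise ValueError("genome_size must be at least 1000")
    b = min(31, max(13, math.ceil(math.log(genome_size, 4)) + 6))
    s = b - 3
    p = min(16, s - 3)
    e = max(4, p - 4)
    assert e < p < s < b
    return e, p, s, b


@dataclass(frozen=True)
class Config:
    """Compression configuration; tier sizes derive from genome_size unless
    overridden."""

    genome_size: int = 1_000_000
    tier_sizes: Optional[Tuple[int, int, int, int]] = None
    block_size: int = DEFAULT_BLOCK_SIZE
    paired: bool = False
    reordered: bool = False
    quality_mode: str = "96"
    id_mode: str = "lossless"
    max_corrections: int = 8

    def __post_init__(self):
        if self.quality_mode not in QUALITY_MODES:
            raise ValueError(f"quality_mode must be one of {QUALITY_MODES}")
        if self.id_mode not in ID_MODES:
            raise ValueError(f"id_mode must be one of {ID_MODES}")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        if self.tier_sizes is None:
            object.__setattr__(self, "tier_sizes",
                               derive_tier_sizes(self.genome_size))
        e, p, s, b = self.tier_sizes
        if not (0 < e < p < s < b <= 31):
            raise ValueError("tier sizes must satisfy 0 < e < p < s < b <= 31")

    @property
    def e(self) -> int:
        return self.tier_sizes[0]

    @property
    def p(self) -> int:
        return self.tier_sizes[1]

    @property
    def s(self) -> int:
        return self.tier_sizes[2]

    @property
    def b(self) -> int:
        return self.tier_sizes[3]


class KmerCounter:
    """Open-addressing map canonical-k-mer -> saturating count for one tier."""

    __slots__ = ("k", "keys", "vals", "n_entries", "n_inserted")

    def __init__(self, k: int, initial_capacity: int = 1 << 12):
        cap = 1
        while cap < initial_capacity:
            cap <<= 1
        self.k = k
        self.keys = np.full(cap, -1, np.int64)
        self.vals = np.zeros(cap, np.uint16)
        self.n_entries = 0   # distinct canonical k-mers
        self.n_inserted = 0  # total insertions (pre-saturation mass)

    def ensure(self, upcoming: int) -> None:
        """Grow so that ``upcoming`` further inserts keep load factor < 2/3."""
        need = self.n_entries + upcoming
        cap = self.keys.shape[0]
        if 3 * need < 2 * cap:
            return
        while 3 * need >= 2 * cap:
            cap <<= 1
        nk = np.full(cap, -1, np.int64)
        nv = np.zeros(cap, np.uint16)
        K.hm_rehash(self.keys, self.vals, nk, nv)
        self.keys, self.vals = nk, nv

    def add_packed(self, key: int) -> None:
        self.ensure(1)
        self.n_entries += int(K.hm_add(self.keys, self.vals, key))
        self.n_inserted += 1

    def get_packed(self, key: int) -> int:
        return int(K.hm_get(self.keys, self.vals, key))

    def total_count(self) -> int:
        return int(self.vals.sum())


def _pack(kmer: str) -> int:
    v = 0
    for ch in kmer:
        v = (v << 2) | int(_CODE_LUT[ord(ch)])
    return v


class TieredDictionaries:
    """The four successor-count dictionaries keyed by canonical k-mers."""

    def __init__(self, config: Config):
        self.config = config
        e, p, s, b = config.tier_sizes
        # tier order mirrors the PPM cascade: index 0 = b (largest)
        self.tiers = {"b": KmerCounter(b), "s": KmerCounter(s),
                      "p": KmerCounter(p), "e": KmerCounter(e)}

    def _counter(self, tier: str) -> KmerCounter:
        try:
            return self.tiers[tier]
        except KeyError:
            raise KeyError(f"unknown tier {tier!r}; expected one of b,s,p,e")

    def kernel_arrays(self):
        t = self.tiers
        return (t["b"].keys, t["b"].vals, t["s"].keys, t["s"].vals,
                t["p"].keys, t["p"].vals, t["e"].keys, t["e"].vals)

    def ensure(self, upcoming: int) -> None:
        for c in self.tiers.values():
            c.ensure(upcoming)

    def insert_read(self, sequence) -> None:
        """Count every N-free canonical k-mer of the read in all tiers."""
        codes = sequence if isinstance(sequence, np.ndarray) else seq_to_codes(sequence)
        self.ensure(len(codes))
        e, p, s, b = self.config.tier_sizes
        new = np.zeros(4, np.int64)
        K.insert_read_kmers(codes, e, p, s, b, *self.kernel_arrays(), new)
        for i, name in enumerate(("b", "s", "p", "e")):
            t = self.tiers[name]
            t.n_entries += int(new[i])
            t.n_inserted += _count_nfree_kmers(codes, t.k)

    def insert_read_fast(self, codes: np.ndarray) -> None:
        """insert_read without the insertion-mass bookkeeping (hot path)."""
        self.ensure(len(codes))
        e, p, s, b = self.config.tier_sizes
        new = np.zeros(4, np.int64)
        K.insert_read_kmers(codes, e, p, s, b, *self.kernel_arrays(), new)
        self.bump_entries(new)

    def bump_entries(self, new_counts: np.ndarray) -> None:
        """Account new distinct k-mers reported by a kernel (b,s,p,e order)."""
        self.tiers["b"].n_entries += int(new_counts[0])
        self.tiers["s"].n_entries += int(new_counts[1])
        self.tiers["p"].n_entries += int(new_counts[2])
        self.tiers["e"].n_entries += int(new_counts[3])

    def query_successors(self, tier: str, context: str) -> np.ndarray:
        """CountVector (A,C,G,T) of successors observed after ``context``."""
        c = self._counter(tier)
        if len(context) != c.k - 1:
            raise ValueError(
                f"context length {len(context)} != k-1 = {c.k - 1} for tier {tier}")
        return self.query_partial(tier, context, 0)

    def query_partial(self, tier: str, known_suffix: str, missing: int) -> np.ndarray:
        """Element-wise sum of exact queries over all completions of the
        ``missing`` unknown leading symbols (missing <= 2)."""
        c = self._counter(tier)
        if not 0 <= missing <= 2:
            raise ValueError("missing must be 0, 1 or 2")
        if len(known_suffix) + missing != c.k - 1:
            raise ValueError("known_suffix length + missing must equal k-1")
        if "N" in known_suffix:
            raise ValueError("context must not contain N")
        codes = seq_to_codes(known_suffix)
        counts = np.zeros(4, np.int64)
        K.tier_query(c.keys, c.vals, codes, len(codes), c.k, missing, counts)
        return counts

    def get_count(self, tier: str, kmer: str) -> int:
        c = self._counter(tier)
        if len(kmer) != c.k:
            raise ValueError(f"k-mer length {len(kmer)} != {c.k}")
        return c.get_packed(_pack(canonical(kmer)))

    def digest(self) -> bytes:
        h = hashlib.blake2b(digest_size=16)
        for name in ("b", "s", "p", "e"):
            t = self.tiers[name]
            h.update(t.keys.tobytes())
            h.update(t.vals.tobytes())
        return h.digest()


def _count_nfree_kmers(codes: np.ndarray, k: int) -> int:
    """Number of length-k windows without an N (vectorized run-length sum)."""
    if len(codes) < k:
        return 0
    is_n = np.concatenate(([True], codes == 4, [True]))
    bounds = np.flatnonzero(is_n)
    runs = np.diff(bounds) - 1
    return int(np.maximum(runs - k + 1, 0).sum())
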