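"""Paired-end second-read prediction via co-occurring minimizer pairs.

For each pair, the minimizer m1 (smallest canonical (b-2)-mer) of the first
read keys a dictionary M_b of second-read canonical b-mers previously seen
with m1, kept sorted by count (at most 8 candidates).  If one of the
candidates occurs verbatim (in either orientation) in the second read, only
its rank in the list, its position and an orientation bit are stored and
the b-mer's bases are skipped by the base codec; otherwise the second read
is coded like a single-end read.  The mechanism is identical in original-
order and reordered modes.
"""

from __future__ import annotations

import hashlib
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels as K
from .kmer_dicts import seq_to_codes, codes_to_seq

MAX_CANDIDATES = K.MB_MAX_CANDIDATES
MISS = MAX_CANDIDATES  # rank symbol meaning "no candidate matched"


def find_minimizer(sequence, L: int) -> Tuple[str, int]:
    """Lexicographically smallest canonical L-mer over all N-free windows of
    the read, with its leftmost window position."""
    codes = sequence if isinstance(sequence, np.ndarray) else seq_to_codes(sequence)
    if len(codes) < L:
        raise ValueError(f"sequence shorter than minimizer length {L}")
    packed, pos = K.find_minimizer(codes, L)
    if packed < 0:
        raise ValueError("no N-free window; minimizer undefined")
    out = np.zeros(L, np.uint8)
    K.unpack_kmer(int(packed), L, out, 0)
    return codes_to_seq(out), int(pos)


class MinimizerPairDict:
    """M_b: first-read minimizer -> counted, capped second-read b-mer list."""

    def __init__(self, b: int, initial_capacity: int = 1 << 10):
        self.b = b
        self.m1_len = b - 2
        cap = 1
        while cap < initial_capacity:
            cap <<= 1
        self._alloc(cap)
        self.n_entries = 0

    def _alloc(self, cap: int):
        self.keys = np.full(cap, -1, np.int64)
        self.cand = np.zeros((cap, MAX_CANDIDATES), np.int64)
        self.cnt = np.zeros((cap, MAX_CANDIDATES), np.uint16)
        self.ncand = np.zeros(cap, np.uint8)

    def ensure(self, upcoming: int = 1) -> None:
        need = self.n_entries + upcoming
        cap = self.keys.shape[0]
        if 3 * need < 2 * cap:
            return
        while 3 * need >= 2 * cap:
            cap <<= 1
        old = (self.keys, self.cand, self.cnt, self.ncand)
        self._alloc(cap)
        K.mb_rehash(*old, self.keys, self.cand, self.cnt, self.ncand)

    def record(self, m1_packed: int, c2_packed: int) -> None:
        self.ensure(1)
        self.n_entries += int(K.mb_record(self.keys, self.cand, self.cnt,
                                          self.ncand, m1_packed, c2_packed))

    def candidates_packed(self, m1_packed: int) -> List[int]:
        slot = int(K.mb_find_slot(self.keys, m1_packed))
        if slot < 0:
            return []
        n = int(self.ncand[slot])
        return [int(v) for v in self.cand[slot, :n]]

    def candidates(self, m1: str) -> List[str]:
        """Candidate b-mers for a minimizer, ordered by descending count."""
        packed = _pack_str(m1)
        out = np.zeros(self.b, np.uint8)
        result = []
        for c in self.candidates_packed(packed):
            K.unpack_kmer(c, self.b, out, 0)
            result.append(codes_to_seq(out))
        return result

    def digest(self) -> bytes:
        h = hashlib.blake2b(digest_size=16)
        h.update(self.keys.tobytes())
        h.update(self.cand.tobytes())
        h.update(self.cnt.tobytes())
        return h.digest()


def _pack_str(kmer: str) -> int:
    v = 0
    for c in seq_to_codes(kmer):
        if c == 4:
            raise ValueError("k-mer contains N")
        v = (v << 2) | int(c)
    return v


class PairedEndCoder:
    """Stateful second-read coder wired into a ReadBaseCoder."""

    def __init__(self, b: int):
        self.b = b
        self.mb = MinimizerPairDict(b)
        self.rank_freqs = np.ones(MAX_CANDIDATES + 1, np.uint32)
        self.pos_bl = np.ones(34, np.uint32)
        self.orient_freqs = np.ones(2, np.uint32)

    def _m1(self, codes1: np.ndarray) -> int:
        packed, _ = K.find_minimizer(codes1, self.mb.m1_len)
        return int(packed)

    def encode_second(self, pe_enc, base_coder, bases_enc,
                      codes1: np.ndarray, codes2: np.ndarray) -> bool:
        """Encode the second mate; returns True on a candidate HIT."""
        m1 = self._m1(codes1)
        cands = self.mb.candidates_packed(m1) if m1 >= 0 else []
        hit = False
        pe_enc.reserve(32)
        st, out, pos = pe_enc.buffers
        if cands:
            rank = MISS
            mpos = -1
            orient = 0
            for r, cand in enumerate(cands):
                j, o = K.match_candidate(codes2, cand, self.b)
                if j >= 0:
                    rank, mpos, orient = r, int(j), int(o)
                    break
            K.adaptive_encode(self.rank_freqs, rank, st, out, pos)
            if rank != MISS:
                K.encode_varint(self.pos_bl, st, out, pos, mpos)
                K.adaptive_encode(self.orient_freqs, orient, st, out, pos)
                base_coder.encode_read(bases_enc, codes2,
                                       skip=(mpos, mpos + self.b))
                hit = True
        if not hit:
            base_coder.encode_read(bases_enc, codes2)
        self._record(m1, codes2)
        return hit

    def decode_second(self, pe_dec, base_coder, bases_dec,
                      codes1: np.ndarray, length: int) -> np.ndarray:
        m1 = self._m1(codes1)
        cands = self.mb.candidates_packed(m1) if m1 >= 0 else []
        st, inp, pos = pe_dec.buffers
        codes2 = None
        if cands:
            rank = int(K.adaptive_decode(self.rank_freqs, st, inp, pos))
            if rank != MISS:
                mpos = int(K.decode_varint(self.pos_bl, st, inp, pos))
                orient = int(K.adaptive_decode(self.orient_freqs, st, inp, pos))
                window = np.zeros(self.b, np.uint8)
                K.unpack_kmer(cands[rank], self.b, window, orient)
                codes2 = base_coder.decode_read(
                    bases_dec, length, known=(mpos, mpos + self.b, window))
        if codes2 is None:
            codes2 = base_coder.decode_read(bases_dec, length)
        self._record(m1, codes2)
        return codes2

    def _record(self, m1: int, codes2: np.ndarray) -> None:
        if m1 < 0:
            return
        c2, _ = K.find_minimizer(codes2, self.b)
        if c2 >= 0:
            self.mb.record(m1, int(c2))

    def digest(self) -> bytes:
        h = hashlib.blake2b(digest_size=16)
        h.update(self.mb.digest())
        h.update(self.rank_freqs.tobytes())
        h.update(self.pos_bl.tobytes())
        h.update(self.orient_freqs.tobytes())
        return h.digest()
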