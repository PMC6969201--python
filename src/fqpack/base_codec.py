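"""Base (DNA symbol) codec.

Per position, the longest usable context (at most b-1 symbols, at most two
of them unknown at a read's start) is looked up in the tier dictionaries,
the symbol's rank in the count-ordered alphabet is coded under the adaptive
rank model, and an in-stream error-correction rule may replace the symbol
in the *history* (never in the emitted data) so that likely sequencing
errors do not pollute the dictionaries.  In reordered (REO) mode the first
p bases are instead packed into a 2p-bit integer and delta-coded against
the previous read's prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels as K
from .kmer_dicts import Config, TieredDictionaries, seq_to_codes, codes_to_seq
from .rank_model import RankModel, rank_symbols

TIER_NAMES = ("b", "s", "p", "e", "order0")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TierAnswer:
    """Outcome of the PPM cascade for one position."""

    tier: str                 # which dictionary answered ('order0' if none)
    counts: Tuple[int, int, int, int]
    missing: int              # unknown leading symbols of the partial query


def predict(dicts: TieredDictionaries, history: str, position: Optional[int] = None
            ) -> TierAnswer:
    """Cascade the tiers largest-first for the context ending at ``position``.

    ``history`` is the already-processed (corrected) prefix of the read;
    ``position`` defaults to len(history), i.e. the next symbol.
    """
    if position is None:
        position = len(history)
    if position < 0 or position > len(history):
        raise ValueError("position must lie within the processed prefix")
    hist = seq_to_codes(history)
    counts = np.zeros(4, np.int64)
    n_pos = np.flatnonzero(hist[:position] == 4)
    last_n = int(n_pos[-1]) if len(n_pos) else -1
    e, p, s, b = dicts.config.tier_sizes
    tier, missing = K.predict_tier(hist, position, last_n, e, p, s, b,
                                   *dicts.kernel_arrays(), counts)
    return TierAnswer(TIER_NAMES[tier], tuple(int(c) for c in counts),
                      int(missing))


def maybe_correct(counts, symbol: str) -> str:
    """Error-correction rule: replace a zero-count symbol by the unique
    maximum when that maximum is at least 3; N is never involved."""
    if symbol == "N":
        return symbol
    arr = np.asarray(counts, np.int64)
    fixed = int(K._maybe_correct.py_func(arr, _BASE_INDEX[symbol]))
    return "ACGT"[fixed]


def pack_prefix(pmer: str) -> int:
    """Big-endian 2-bit packing (A=00, C=01, G=10, T=11) of an ACGT string."""
    v = 0
    for ch in pmer:
        try:
            v = (v << 2) | _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"prefix contains {ch!r}; packing needs pure ACGT")
    return v


def unpack_prefix(value: int, p: int) -> str:
    return "".join("ACGT"[(value >> (2 * (p - 1 - j))) & 3] for j in range(p))


class ReadBaseCoder:
    """Stateful encoder/decoder for the bases of successive reads.

    Owns the tier dictionaries and the rank model; the same call sequence on
    the encoding and the decoding side replays identical state.
    """

    PREFIX_ESCAPE_OFFSET = 1  # bit-length alphabet shifted by 1; symbol 0 = escape

    def __init__(self, config: Config):
        self.config = config
        self.dicts = TieredDictionaries(config)
        self.model = RankModel()
        self._counts = np.zeros(4, np.int64)
        self._order = np.zeros(5, np.uint8)
        self._new = np.zeros(4, np.int64)
        # REO prefix: adaptive bit-length alphabet 0..2p -> symbols 1..2p+1,
        # symbol 0 escapes to plain base coding (N in prefix).
        self.prefix_blfreqs = np.ones(2 * config.p + 2, np.uint32)
        self.prev_packed = 0

    def start_block(self) -> None:
        self.prev_packed = 0

    # -- whole-read paths -------------------------------------------------

    def encode_read(self, enc, codes: np.ndarray, skip: Tuple[int, int] = (0, 0),
                    insert: bool = True) -> np.ndarray:
        """Encode bases outside ``skip``; returns the corrected history that
        was inserted into the dictionaries."""
        enc.reserve(3 * len(codes) + 16)
        st, out, pos = enc.buffers
        hist = codes.copy()
        e, p, s, b = self.config.tier_sizes
        if insert:
            self.dicts.ensure(len(codes))
        new = self._new
        new[:] = 0
        K.encode_read_bases(codes, hist, skip[0], skip[1], e, p, s, b,
                            *self.dicts.kernel_arrays(), self.model.freqs,
                            st, out, pos, self.config.max_corrections,
                            self._counts, self._order, insert, new)
        if insert:
            self.dicts.bump_entries(new)
        return hist

    def decode_read(self, dec, length: int, known: Optional[Tuple[int, int, np.ndarray]] = None,
                    insert: bool = True) -> np.ndarray:
        """Decode a read of ``length`` bases; ``known`` pre-fills a
        (start, end, symbols) region the stream does not carry."""
        st, inp, pos = dec.buffers
        orig = np.zeros(length, np.uint8)
        hist = np.zeros(length, np.uint8)
        skip_s, skip_e = 0, 0
        if known is not None:
            skip_s, skip_e, sym = known
            orig[skip_s:skip_e] = sym
            hist[skip_s:skip_e] = sym
        e, p, s, b = self.config.tier_sizes
        if insert:
            self.dicts.ensure(length)
        new = self._new
        new[:] = 0
        K.decode_read_bases(orig, hist, skip_s, skip_e, e, p, s, b,
                            *self.dicts.kernel_arrays(), self.model.freqs,
                            st, inp, pos, self.config.max_corrections,
                            self._counts, self._order, insert, new)
        if insert:
            self.dicts.bump_entries(new)
        return orig

    # -- REO prefix path --------------------------------------------------

    def encode_prefixed_read(self, prefix_enc, bases_enc, codes: np.ndarray) -> None:
        """REO mode: pack+delta-code the first p bases, base-code the rest."""
        p = self.config.p
        prefix_enc.reserve(16)
        st, out, pos = prefix_enc.buffers
        if len(codes) >= p and not np.any(codes[:p] == 4):
            packed = 0
            for c in codes[:p]:
                packed = (packed << 2) | int(c)
            delta = packed - self.prev_packed
            if delta < 0:
                raise RuntimeError(
                    "REO sorting contract violated: prefix smaller than predecessor")
            bl = delta.bit_length()
            K.adaptive_encode(self.prefix_blfreqs, bl + self.PREFIX_ESCAPE_OFFSET,
                              st, out, pos)
            if bl > 1:
                K.rc_encode_bits(st, out, pos, delta - (1 << (bl - 1)), bl - 1)
            self.prev_packed = packed
            self.encode_read(bases_enc, codes, skip=(0, p))
        else:
            if len(codes) >= p:
                K.adaptive_encode(self.prefix_blfreqs, 0, st, out, pos)
            self.encode_read(bases_enc, codes)

    def decode_prefixed_read(self, prefix_dec, bases_dec, length: int) -> np.ndarray:
        p = self.config.p
        st, inp, pos = prefix_dec.buffers
        if length >= p:
            sym = K.adaptive_decode(self.prefix_blfreqs, st, inp, pos)
            if sym != 0:
                bl = sym - self.PREFIX_ESCAPE_OFFSET
                if bl == 0:
                    delta = 0
                elif bl == 1:
                    delta = 1
                else:
                    delta = (1 << (bl - 1)) + int(
                        K.rc_decode_bits(st, inp, pos, bl - 1))
                packed = self.prev_packed + delta
                self.prev_packed = packed
                pref = np.zeros(p, np.uint8)
                K.unpack_kmer(packed, p, pref, 0)
                return self.decode_read(bases_dec, length, known=(0, p, pref))
        return self.decode_read(bases_dec, length)

    def digest(self) -> bytes:
        import hashlib
        h = hashlib.blake2b(digest_size=16)
        h.update(self.dicts.digest())
        h.update(self.model.digest())
        h.update(self.prefix_blfreqs.tobytes())
        return h.digest()


def encode_base(enc, model: RankModel, answer: TierAnswer, position: int,
                symbol: str, corrected_prev: bool = False) -> int:
    """Single-base path of the codec (the fused kernels do this in bulk):
    rank-transform the symbol, code the rank, update the model.  Returns the
    emitted rank."""
    from .rank_model import context_id
    order = rank_symbols(answer.counts)
    rank = order.index(symbol)
    ctx = context_id(answer.tier, position, answer.counts, corrected_prev)
    row = model.freqs[ctx]
    cum = int(row[:rank].sum())
    enc.encode_symbol(cum, cum + int(row[rank]), int(row.sum()))
    model.update(ctx, rank)
    return rank


def decode_base(dec, model: RankModel, answer: TierAnswer, position: int,
                corrected_prev: bool = False) -> str:
    from .rank_model import context_id
    order = rank_symbols(answer.counts)
    ctx = context_id(answer.tier, position, answer.counts, corrected_prev)
    row = model.freqs[ctx]
    total = int(row.sum())
    c = dec.decode_symbol(total)
    cum = 0
    rank = 4
    for i in range(5):
        if c < cum + int(row[i]):
            rank = i
            break
        cum += int(row[i])
    dec.decode_update(cum, cum + int(row[rank]), total)
    model.update(ctx, rank)
    return order[rank]
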