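"""Byte-oriented range coder.

A carry-counting coder in the classic 64-bit-low / 32-bit-range design:
renormalization emits bytes whenever the range drops below 2**24, so the
range is always at least 2**24 when a symbol is coded and cumulative
frequency totals must not exceed 2**24.  Identical inputs produce
byte-identical output; the decoder consumes the same frequency tables in
the same order.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K

MAX_TOTAL = 1 << 24


class RangeEncoder:
    """Encodes symbols given explicit (cum_lo, cum_hi, total) intervals."""

    def __init__(self, initial_capacity: int = 4096):
        self._st = np.zeros(4, np.int64)
        K.rc_enc_init(self._st)
        self._out = np.zeros(max(64, initial_capacity), np.uint8)
        self._pos = np.zeros(1, np.int64)
        self._finished = False

    def reserve(self, nbytes: int) -> None:
        """Guarantee room for ``nbytes`` more output bytes (plus any pending
        carry-run bytes the coder may flush in one burst)."""
        need = int(self._pos[0]) + int(self._st[2]) + nbytes + 8
        if need > self._out.shape[0]:
            cap = self._out.shape[0]
            while cap < need:
                cap *= 2
            grown = np.zeros(cap, np.uint8)
            grown[:self._pos[0]] = self._out[:self._pos[0]]
            self._out = grown

    @property
    def buffers(self):
        """(state, out, pos) arrays for direct kernel calls."""
        return self._st, self._out, self._pos

    def tell(self) -> int:
        return int(self._pos[0])

    def encode_symbol(self, cum_lo: int, cum_hi: int, total: int) -> None:
        if self._finished:
            raise RuntimeError("encoder already flushed")
        if not 0 <= cum_lo < cum_hi <= total <= MAX_TOTAL:
            raise ValueError(
                f"invalid interval: need 0 <= {cum_lo} < {cum_hi} <= {total} <= 2**24")
        self.reserve(8)
        K.rc_encode(self._st, self._out, self._pos,
                    cum_lo, cum_hi - cum_lo, total)

    def encode_bits(self, value: int, nbits: int) -> None:
        if self._finished:
            raise RuntimeError("encoder already flushed")
        if nbits < 0 or value < 0 or value >> max(nbits, 0) != 0:
            raise ValueError("value does not fit in nbits")
        self.reserve(nbits // 8 + 8)
        K.rc_encode_bits(self._st, self._out, self._pos, value, nbits)

    def flush(self) -> bytes:
        """Emit the tail bytes and return the complete payload."""
        if self._finished:
            raise RuntimeError("flush() called twice")
        self.reserve(8)
        K.rc_enc_flush(self._st, self._out, self._pos)
        self._finished = True
        return self._out[:self._pos[0]].tobytes()


class RangeDecoder:
    """Mirror of RangeEncoder; must see the identical table sequence."""

    def __init__(self, data: bytes):
        # 5-byte tail guard: a well-formed payload is >= 5 bytes, and the
        # decoder may legitimately read a few bytes past the payload while
        # renormalizing at the end of the stream.
        self._inp = np.frombuffer(bytes(data) + b"\x00" * 8, np.uint8).copy()
        self._payload_len = len(data)
        if self._payload_len < 5:
            raise ValueError("range-coded payload shorter than 5 bytes")
        self._pos = np.zeros(1, np.int64)
        self._st = np.zeros(2, np.int64)
        K.rc_dec_init(self._st, self._inp, self._pos)

    @property
    def buffers(self):
        return self._st, self._inp, self._pos

    def decode_symbol(self, total: int) -> int:
        """Scaled count c with cum_lo <= c < cum_hi for the encoded symbol."""
        if not 1 <= total <= MAX_TOTAL:
            raise ValueError("total out of range")
        return int(K.rc_dec_getfreq(self._st, total))

    def decode_update(self, cum_lo: int, cum_hi: int, total: int) -> None:
        if not 0 <= cum_lo < cum_hi <= total <= MAX_TOTAL:
            raise ValueError("invalid interval")
        K.rc_dec_update(self._st, self._inp, self._pos,
                        cum_lo, cum_hi - cum_lo, total)

    def decode_bits(self, nbits: int) -> int:
        return int(K.rc_decode_bits(self._st, self._inp, self._pos, nbits))
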