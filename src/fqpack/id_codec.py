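"""Read-ID codec: tokenized differential compression (lossless), an
instrument-name-only move-to-front mode, and a discard mode.

IDs are tokenized into maximal alphanumeric runs with the separator
characters preserved.  Runs of digits are *numeric* tokens (coded as an
integer delta against the previous read) unless they carry a leading zero
or are too long for 64-bit arithmetic -- those stay literal so their width
survives.  When the token structure (count, types, separators) differs
from the previous ID, the whole ID is stored character by character.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels as K

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

NUMERIC = "num"
LITERAL = "lit"

_MTF_CAPACITY = 64          # positions 0..62 codable, symbol 63 = escape
_MAX_NUMERIC_DIGITS = 18


@dataclass(frozen=True)
class TokenList:
    """Tokens plus the separator strings around them.

    ``separators`` has one more element than ``tokens``: the text before
    the first token, between consecutive tokens, and after the last.
    Concatenating separators and tokens in order reproduces the ID exactly.
    """

    tokens: Tuple[Tuple[str, str], ...]   # (type, text)
    separators: Tuple[str, ...]

    @property
    def signature(self) -> Tuple:
        return (tuple(t for t, _ in self.tokens), self.separators)

    def reassemble(self) -> str:
        parts = [self.separators[0]]
        for (_, text), sep in zip(self.tokens, self.separators[1:]):
            parts.append(text)
            parts.append(sep)
        return "".join(parts)


def tokenize(id_text: str) -> TokenList:
    tokens = []
    seps = []
    last = 0
    for m in _TOKEN_RE.finditer(id_text):
        seps.append(id_text[last:m.start()])
        text = m.group()
        if (text.isdigit() and len(text) <= _MAX_NUMERIC_DIGITS
                and (len(text) == 1 or text[0] != "0")):
            tokens.append((NUMERIC, text))
        else:
            tokens.append((LITERAL, text))
        last = m.end()
    seps.append(id_text[last:])
    return TokenList(tuple(tokens), tuple(seps))


class IdCoder:
    """Stateful ID encoder/decoder (modes: lossless, instrument, none)."""

    FLAG_LITERAL = 0
    FLAG_STRUCT = 1

    def __init__(self, mode: str = "lossless"):
        if mode not in ("lossless", "instrument", "none"):
            raise ValueError(f"unknown id mode {mode!r}")
        self.mode = mode
        self.prev: Optional[TokenList] = None
        self.read_no = 0
        self.mtf: List[str] = []
        self.struct_flag = np.ones(2, np.uint32)
        self.tok_flag = np.ones(2, np.uint32)
        self.char_same = np.ones(2, np.uint32)
        self.chars = np.ones(128, np.uint32)
        self.delta_bl = np.ones(65, np.uint32)
        self.len_bl = np.ones(34, np.uint32)
        self.mtf_pos = np.ones(_MTF_CAPACITY, np.uint32)

    def start_block(self) -> None:
        # block independence: the first ID of a block is stored literally
        self.prev = None

    # -- primitives --------------------------------------------------------

    def _enc_chars(self, st, out, pos, text: str) -> None:
        K.encode_varint(self.len_bl, st, out, pos, len(text))
        for ch in text:
            K.adaptive_encode(self.chars, ord(ch) & 0x7F, st, out, pos)

    def _dec_chars(self, st, inp, pos) -> str:
        n = int(K.decode_varint(self.len_bl, st, inp, pos))
        return "".join(chr(int(K.adaptive_decode(self.chars, st, inp, pos)))
                       for _ in range(n))

    # -- lossless path ------------------------------------------------------

    def encode_id(self, enc, id_text: str) -> None:
        self.read_no += 1
        if self.mode == "none":
            return
        enc.reserve(4 * len(id_text) + 64)
        st, out, pos = enc.buffers
        if self.mode == "instrument":
            self._encode_instrument(st, out, pos, id_text)
            return
        cur = tokenize(id_text)
        prev = self.prev
        if prev is None or cur.signature != prev.signature:
            K.adaptive_encode(self.struct_flag, self.FLAG_LITERAL, st, out, pos)
            self._enc_chars(st, out, pos, id_text)
        else:
            K.adaptive_encode(self.struct_flag, self.FLAG_STRUCT, st, out, pos)
            for (ttype, text), (_, ptext) in zip(cur.tokens, prev.tokens):
                if ttype == NUMERIC:
                    K.encode_svarint(self.delta_bl, st, out, pos,
                                     int(text) - int(ptext))
                elif text == ptext:
                    K.adaptive_encode(self.tok_flag, 0, st, out, pos)
                else:
                    K.adaptive_encode(self.tok_flag, 1, st, out, pos)
                    K.encode_varint(self.len_bl, st, out, pos, len(text))
                    for j, ch in enumerate(text):
                        same = j < len(ptext) and ptext[j] == ch
                        K.adaptive_encode(self.char_same, 1 if same else 0,
                                          st, out, pos)
                        if not same:
                            K.adaptive_encode(self.chars, ord(ch) & 0x7F,
                                              st, out, pos)
        self.prev = cur

    def decode_id(self, dec) -> str:
        self.read_no += 1
        if self.mode == "none":
            return f"r{self.read_no}"
        st, inp, pos = dec.buffers
        if self.mode == "instrument":
            return self._decode_instrument(st, inp, pos)
        flag = int(K.adaptive_decode(self.struct_flag, st, inp, pos))
        if flag == self.FLAG_LITERAL:
            id_text = self._dec_chars(st, inp, pos)
            self.prev = tokenize(id_text)
            return id_text
        prev = self.prev
        tokens = []
        for (ttype, ptext) in prev.tokens:
            if ttype == NUMERIC:
                value = int(ptext) + int(K.decode_svarint(self.delta_bl, st, inp, pos))
                tokens.append((NUMERIC, str(value)))
            else:
                if int(K.adaptive_decode(self.tok_flag, st, inp, pos)) == 0:
                    tokens.append((LITERAL, ptext))
                else:
                    n = int(K.decode_varint(self.len_bl, st, inp, pos))
                    chars = []
                    for j in range(n):
                        same = int(K.adaptive_decode(self.char_same, st, inp, pos))
                        if same:
                            chars.append(ptext[j])
                        else:
                            chars.append(chr(int(
                                K.adaptive_decode(self.chars, st, inp, pos))))
                    tokens.append((LITERAL, "".join(chars)))
        cur = TokenList(tuple(tokens), prev.separators)
        self.prev = cur
        return cur.reassemble()

    # -- instrument (move-to-front) path ------------------------------------

    @staticmethod
    def instrument_name(id_text: str) -> str:
        m = _TOKEN_RE.search(id_text)
        return m.group() if m else ""

    def _encode_instrument(self, st, out, pos, id_text: str) -> None:
        name = self.instrument_name(id_text)
        if name in self.mtf:
            idx = self.mtf.index(name)
            K.adaptive_encode(self.mtf_pos, idx, st, out, pos)
            self.mtf.insert(0, self.mtf.pop(idx))
        else:
            K.adaptive_encode(self.mtf_pos, _MTF_CAPACITY - 1, st, out, pos)
            self._enc_chars(st, out, pos, name)
            self.mtf.insert(0, name)
            del self.mtf[_MTF_CAPACITY - 1:]

    def _decode_instrument(self, st, inp, pos) -> str:
        sym = int(K.adaptive_decode(self.mtf_pos, st, inp, pos))
        if sym == _MTF_CAPACITY - 1:
            name = self._dec_chars(st, inp, pos)
            self.mtf.insert(0, name)
            del self.mtf[_MTF_CAPACITY - 1:]
        else:
            name = self.mtf[sym]
            self.mtf.insert(0, self.mtf.pop(sym))
        return name

    def output_id(self, id_text: str, read_no: int) -> str:
        """The ID the decoder will emit for this input ID (mode-dependent);
        ``read_no`` is the 1-based global record number."""
        if self.mode == "none":
            return f"r{read_no}"
        if self.mode == "instrument":
            return self.instrument_name(id_text)
        return id_text

    def digest(self) -> bytes:
        import hashlib
        h = hashlib.blake2b(digest_size=16)
        for arr in (self.struct_flag, self.tok_flag, self.char_same,
                    self.chars, self.delta_bl, self.len_bl, self.mtf_pos):
            h.update(arr.tobytes())
        h.update("\x00".join(self.mtf).encode("ascii", "replace"))
        return h.digest()
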