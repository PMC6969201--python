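"""Quality-score codec with five resolutions: 96, 8, 4, 2 values, or none.

Lossy modes first bin the Phred score (0..93) into the mode's alphabet;
the 8-level table follows the de-facto Illumina binning representatives.
Scores are then coded under adaptive per-context tables whose context is
the read position (bucketed) combined with the last h binned scores, with
h = 2, 6, 9 or 10 for the 96/8/4/2-value alphabets -- longer memory for
coarser alphabets.  Binning is idempotent, so re-compressing an already
binned file is lossless; mode "none" stores nothing and regenerates a
constant placeholder score (Q40, 'I') on decompression.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import _kernels as K

MAX_PHRED = 93
PLACEHOLDER_PHRED = 40  # 'I'

# (lower bound of bin, representative value) pairs, per mode
BIN_TABLES = {
    "96": tuple((q, q) for q in range(96)),
    "8": ((0, 0), (2, 6), (10, 15), (20, 22), (25, 27), (30, 33),
          (35, 37), (40, 40)),
    "4": ((0, 6), (10, 15), (20, 25), (30, 37)),
    "2": ((0, 6), (20, 37)),
}

HISTORY_LEN = {"96": 2, "8": 6, "4": 9, "2": 10}
POS_BUCKET_MAX = {"96": 63, "8": 15, "4": 15, "2": 15}


@dataclass(frozen=True)
class QualityMode:
    """Resolution plus the derived alphabet/context geometry."""

    name: str

    @property
    def alphabet_size(self) -> int:
        return len(BIN_TABLES[self.name])

    @property
    def history(self) -> int:
        return HISTORY_LEN[self.name]

    @property
    def pos_bucket_max(self) -> int:
        return POS_BUCKET_MAX[self.name]

    @property
    def n_contexts(self) -> int:
        return (self.pos_bucket_max + 1) * self.alphabet_size ** self.history


def _luts(mode_name: str, table=None) -> Tuple[np.ndarray, np.ndarray]:
    """(phred -> bin index, bin index -> representative phred) tables."""
    table = BIN_TABLES[mode_name] if table is None else table
    lo = np.array([t[0] for t in table], np.int64)
    rep = np.array([t[1] for t in table], np.uint8)
    phred = np.arange(MAX_PHRED + 1)
    idx = (np.searchsorted(lo, phred, side="right") - 1).astype(np.uint8)
    return idx, rep


def bin_quality(q: int, mode: str) -> int:
    """Representative value of q's bin in the given mode (identity for 96)."""
    if not 0 <= q <= MAX_PHRED:
        raise ValueError(f"quality {q} outside 0..{MAX_PHRED}")
    idx, rep = _luts(mode)
    return int(rep[idx[q]])


def context_of(position: int, history: Tuple[int, ...], mode: str) -> int:
    """Dense context id: position bucket combined with the last h binned
    scores packed radix-|alphabet| (most recent score last)."""
    m = QualityMode(mode)
    if len(history) != m.history:
        raise ValueError(f"history must hold {m.history} previous scores")
    pb = min(position, m.pos_bucket_max)
    packed = 0
    for h in history:
        packed = packed * m.alphabet_size + h
    return pb * m.alphabet_size ** m.history + packed


class QualityCoder:
    """Stateful block-wise encoder/decoder for one archive."""

    def __init__(self, mode: str, bin_table=None):
        if mode not in ("96", "8", "4", "2", "none"):
            raise ValueError(f"unknown quality mode {mode!r}")
        self.mode = mode
        if mode == "none":
            return
        self.qmode = QualityMode(mode)
        self.bin_table = tuple(BIN_TABLES[mode] if bin_table is None else bin_table)
        self.phred_to_bin, self.bin_to_phred = _luts(mode, self.bin_table)
        R = self.qmode.alphabet_size
        self.hspace = R ** self.qmode.history
        n_rows = (self.qmode.pos_bucket_max + 1) * self.hspace
        self.freqs = np.ones((n_rows, R), np.uint16)
        self.totals = np.full(n_rows, R, np.uint32)
        # char-level LUTs for the hot path
        self._char_to_bin = np.zeros(256, np.uint8)
        q = np.arange(33, 127) - 33
        self._char_to_bin[33:127] = self.phred_to_bin[np.minimum(q, MAX_PHRED)]
        self._bin_to_char = (self.bin_to_phred + 33).astype(np.uint8)

    # quality strings <-> binned symbol arrays -----------------------------

    def to_symbols(self, quality: str) -> np.ndarray:
        q = np.frombuffer(quality.encode("ascii"), np.uint8).astype(np.int64) - 33
        if q.min(initial=0) < 0 or q.max(initial=0) > MAX_PHRED:
            raise ValueError("quality characters outside [33, 126]")
        return self.phred_to_bin[q]

    def to_string(self, syms: np.ndarray) -> str:
        return (self.bin_to_phred[syms] + 33).tobytes().decode("ascii")

    def apply_binning(self, quality: str) -> str:
        """The lossy transform the decoder will reproduce."""
        if self.mode == "none":
            return chr(PLACEHOLDER_PHRED + 33) * len(quality)
        arr = np.frombuffer(quality.encode("ascii"), np.uint8)
        return self._bin_to_char[self._char_to_bin[arr]].tobytes().decode("ascii")

    # block coding ---------------------------------------------------------

    def encode_block(self, enc, qualities: List[str]) -> None:
        if self.mode == "none":
            return
        lens = np.array([len(q) for q in qualities], np.int64)
        total = int(lens.sum())
        if total == 0:
            return
        syms = self._char_to_bin[
            np.frombuffer("".join(qualities).encode("ascii"), np.uint8)]
        enc.reserve(3 * total + 64)
        st, out, pos = enc.buffers
        K.encode_quals_block(syms, lens, self.qmode.alphabet_size, self.hspace,
                             self.qmode.pos_bucket_max, self.freqs, self.totals,
                             st, out, pos)

    def decode_block(self, dec, lengths: List[int]) -> List[str]:
        if self.mode == "none":
            return [chr(PLACEHOLDER_PHRED + 33) * n for n in lengths]
        lens = np.asarray(lengths, np.int64)
        total = int(lens.sum())
        qout = np.zeros(total, np.uint8)
        if total:
            st, inp, pos = dec.buffers
            K.decode_quals_block(lens, self.qmode.alphabet_size, self.hspace,
                                 self.qmode.pos_bucket_max, self.freqs,
                                 self.totals, st, inp, pos, qout)
        result = []
        off = 0
        for n in lengths:
            result.append(self.to_string(qout[off:off + n]))
            off += n
        return result

    def digest(self) -> bytes:
        if self.mode == "none":
            return b"\x00" * 16
        h = hashlib.blake2b(digest_size=16)
        h.update(self.totals.tobytes())
        return h.digest()
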