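"""The adaptive rank model ("Model" dictionary).

A symbol is not coded directly: the candidate alphabet is reordered by
descending successor count (ties lexicographic, N always last) and the
symbol's *rank* in that order is coded instead, concentrating probability
mass on rank 0.  Per context-descriptor frequency tables over the five
ranks adapt with a DMC-like additive update that learns aggressively: the
increment (32) is large relative to the initial frequencies (16,8,4,2,1),
so a single observation already shifts the implied probability of its rank
substantially; halving at total 2**16 keeps the statistics recent.

The context descriptor combines which tier answered, a position bucket, a
quantization of the top two counts and whether the previous base was
corrected -- every property the prediction step exposes.
"""

from __future__ import annotations

import hashlib
from typing import Sequence, Tuple

import numpy as np

from . import _kernels as K

SYMBOLS = "ACGTN"
INIT_FREQS = (16, 8, 4, 2, 1)
INCREMENT = K.MODEL_INC
RESCALE_LIMIT = K.MODEL_LIMIT
N_CONTEXTS = K.N_MODEL_CTX

TIER_IDS = {"b": K.TIER_B, "s": K.TIER_S, "p": K.TIER_P,
            "e": K.TIER_E, "order0": K.TIER_ORDER0}


def rank_symbols(counts: Sequence[int]) -> str:
    """Permutation of ACGTN by descending count; ties lexicographic, N last."""
    if len(counts) != 4:
        raise ValueError("expected 4 counts (A,C,G,T)")
    order = sorted(range(4), key=lambda i: (-int(counts[i]), i))
    return "".join(SYMBOLS[i] for i in order) + "N"


def context_id(tier: str, position: int, counts: Sequence[int],
               corrected_prev: bool = False) -> int:
    """Dense index of the model context descriptor."""
    order = sorted(range(4), key=lambda i: (-int(counts[i]), i))
    top = int(counts[order[0]])
    second = int(counts[order[1]])
    return int(K._model_ctx.py_func(TIER_IDS[tier], position, top, second,
                                    int(bool(corrected_prev))))


class RankModel:
    """Dense table of adaptive rank frequencies, one row per context."""

    def __init__(self):
        self.freqs = np.empty((N_CONTEXTS, 5), np.uint32)
        self.freqs[:] = np.asarray(INIT_FREQS, np.uint32)

    def get_freqs(self, ctx: int) -> Tuple[int, ...]:
        return tuple(int(v) for v in self.freqs[ctx])

    def update(self, ctx: int, observed_rank: int) -> None:
        """freq[rank] += 32; halve everything (floor 1) past total 2**16."""
        if not 0 <= observed_rank <= 4:
            raise ValueError("rank must be in 0..4")
        row = self.freqs[ctx]
        row[observed_rank] += INCREMENT
        if int(row.sum()) > RESCALE_LIMIT:
            np.maximum(row >> 1, 1, out=row)

    def probability(self, ctx: int, rank: int) -> float:
        row = self.freqs[ctx]
        return float(row[rank]) / float(row.sum())

    def digest(self) -> bytes:
        return hashlib.blake2b(self.freqs.tobytes(), digest_size=16).digest()
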