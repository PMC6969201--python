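"""Synthetic FASTQ generator for testing the codecs without downloads.

Emulates the data the compressor targets: a random genome, uniformly
placed reads from either strand at a chosen coverage with substitution
errors (no indels -- the Illumina short-read error profile), optional
paired-end sampling with a normal insert-size distribution and FR
orientation, Illumina-like IDs and position-decaying quality strings.
Identical spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .fastq_io import ReadRecord
from .kmer_dicts import codes_to_seq

_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset."""

    genome_length: int = 100_000
    coverage: float = 10.0
    read_length: Union[int, Tuple[int, int]] = 100   # fixed or (min, max)
    error_rate: float = 0.001
    n_rate: float = 0.0                              # fraction of bases masked to N
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    quality_start: float = 38.0                      # mean Phred at position 0
    quality_decay: float = 0.04                      # mean Phred lost per position
    quality_sd: float = 3.0
    seed: int = 0


def simulate_genome(length: int, seed: int) -> str:
    """I.i.d. uniform ACGT string from a seeded generator."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return codes_to_seq(rng.integers(0, 4, length).astype(np.uint8))


def _read_lengths(spec: SimSpec, n: int, rng) -> np.ndarray:
    if isinstance(spec.read_length, tuple):
        lo, hi = spec.read_length
        return rng.integers(lo, hi + 1, n)
    return np.full(n, spec.read_length, np.int64)


def _qualities(lengths: np.ndarray, spec: SimSpec, rng) -> List[str]:
    out = []
    for L in lengths:
        mean = spec.quality_start - spec.quality_decay * np.arange(L)
        q = np.clip(np.rint(mean + rng.normal(0.0, spec.quality_sd, L)),
                    2, 41).astype(np.uint8)
        out.append((q + 33).tobytes().decode("ascii"))
    return out


def _mutate(codes: np.ndarray, spec: SimSpec, rng) -> np.ndarray:
    if spec.error_rate > 0:
        hit = rng.random(len(codes)) < spec.error_rate
        shift = rng.integers(1, 4, len(codes))
        codes = np.where(hit, (codes + shift) % 4, codes).astype(np.uint8)
    if spec.n_rate > 0:
        codes = np.where(rng.random(len(codes)) < spec.n_rate,
                         np.uint8(4), codes).astype(np.uint8)
    return codes


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def sample_reads(genome: str, spec: SimSpec
                 ) -> Union[List[ReadRecord], List[Tuple[ReadRecord, ReadRecord]]]:
    """Draw reads (or FR-oriented pairs) from the genome per the spec."""
    rng = np.random.default_rng(spec.seed + 1)
    G = len(genome)
    gcodes = np.frombuffer(genome.encode("ascii"), np.uint8)
    lut = np.full(256, 4, np.uint8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    gcodes = lut[gcodes]
    mean_len = (sum(spec.read_length) / 2 if isinstance(spec.read_length, tuple)
                else spec.read_length)
    if mean_len > G:
        raise ValueError("read length exceeds genome length")
    n_reads = int(round(spec.coverage * G / mean_len))

    if not spec.paired:
        lengths = _read_lengths(spec, n_reads, rng)
        starts = rng.integers(0, np.maximum(G - lengths + 1, 1))
        strands = rng.integers(0, 2, n_reads)
        quals = _qualities(lengths, spec, rng)
        records = []
        for i in range(n_reads):
            frag = gcodes[starts[i]:starts[i] + lengths[i]]
            if strands[i]:
                frag = _revcomp_codes(frag)
            seq = codes_to_seq(_mutate(frag.copy(), spec, rng))
            records.append(ReadRecord(
                f"sim.{i + 1} {i + 1} length={lengths[i]}", seq, quals[i]))
        return records

    n_pairs = max(1, n_reads // 2)
    lengths = _read_lengths(spec, n_pairs, rng)
    inserts = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs))
    inserts = np.clip(inserts, lengths, G).astype(np.int64)
    starts = rng.integers(0, G - inserts + 1)
    strands = rng.integers(0, 2, n_pairs)
    quals1 = _qualities(lengths, spec, rng)
    quals2 = _qualities(lengths, spec, rng)
    pairs = []
    for i in range(n_pairs):
        L = int(lengths[i])
        f0, f1 = int(starts[i]), int(starts[i] + inserts[i])
        fwd = gcodes[f0:f0 + L]
        rev = _revcomp_codes(gcodes[f1 - L:f1])
        r1c, r2c = (fwd, rev) if strands[i] == 0 else (rev, fwd)
        s1 = codes_to_seq(_mutate(r1c.copy(), spec, rng))
        s2 = codes_to_seq(_mutate(r2c.copy(), spec, rng))
        pairs.append((
            ReadRecord(f"sim.{i + 1} {i + 1} length={L}", s1, quals1[i]),
            ReadRecord(f"sim.{i + 1} {i + 1} length={L}", s2, quals2[i]),
        ))
    return pairs
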