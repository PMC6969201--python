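"""Archive container and the top-level compress/decompress pipeline.

Binary format "FQPK" (little-endian, versioned, documented in
docs/format.md): a self-describing header (modes, genome size, tier sizes,
quality binning table) followed by per-block entries and the concatenated
per-block streams (bases, lengths, IDs, qualities, PE, REO-prefix).
Dictionaries and adaptive models persist across blocks -- single-threaded
semantics -- so decompression replays exactly the prediction/update/
correction sequence of the compressor.  Reads are processed in original
order (OO) or pre-sorted lexicographically by sequence (REO; first mate in
PE mode).  Each block carries a 64-bit content checksum of the text the
decoder must reproduce.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels as K
from .base_codec import ReadBaseCoder
from .fastq_io import ReadRecord, blocks, pair, read_fastq, write_fastq
from .id_codec import IdCoder
from .kmer_dicts import Config, QUALITY_MODES, ID_MODES, seq_to_codes, codes_to_seq
from .pe_codec import PairedEndCoder
from .qual_codec import QualityCoder

MAGIC = b"FQPK"
VERSION = 1

_STREAMS = ("bases", "lengths", "ids", "quals", "pe", "prefix")


class ArchiveError(ValueError):
    """Malformed or corrupt archive."""


@dataclass
class CompressionStats:
    """Byte accounting of one compression run."""

    n_records: int = 0
    total_bases: int = 0
    raw_bytes: int = 0
    stream_bytes: dict = field(default_factory=lambda: {s: 0 for s in _STREAMS})
    n_blocks: int = 0
    pe_hits: int = 0
    pe_tries: int = 0

    @property
    def archive_bytes(self) -> int:
        return sum(self.stream_bytes.values())

    @property
    def bits_per_base(self) -> float:
        """Bases-stream cost: 8 * (bases+prefix stream bytes) / input bases."""
        if self.total_bases == 0:
            return 0.0
        payload = self.stream_bytes["bases"] + self.stream_bytes["prefix"]
        return 8.0 * payload / self.total_bases


class _CodecState:
    """All cross-block adaptive state, shared by compressor and decompressor."""

    def __init__(self, config: Config, bin_table=None):
        self.config = config
        self.base = ReadBaseCoder(config)
        self.qual = QualityCoder(config.quality_mode, bin_table)
        self.ids = IdCoder(config.id_mode)
        self.pe = PairedEndCoder(config.b) if config.paired else None
        self.len_bl = np.ones(65, np.uint32)
        self.read_no = 0

    def digest(self) -> bytes:
        h = hashlib.blake2b(digest_size=16)
        h.update(self.base.digest())
        h.update(self.ids.digest())
        h.update(self.qual.digest())
        h.update(self.len_bl.tobytes())
        if self.pe is not None:
            h.update(self.pe.digest())
        return h.digest()


def sort_for_reo(records: Sequence) -> List:
    """Stable lexicographic sort by sequence (first mate's sequence in PE)."""
    if records and isinstance(records[0], tuple):
        return sorted(records, key=lambda pr: pr[0].sequence)
    return sorted(records, key=lambda r: r.sequence)


def _block_checksum(texts: List[str]) -> int:
    h = hashlib.blake2b("".join(texts).encode("ascii"), digest_size=8)
    return int.from_bytes(h.digest(), "little")


def _expected_output(state: _CodecState, rec: ReadRecord, read_no: int) -> ReadRecord:
    """The record the decoder will emit for this input record."""
    return ReadRecord(state.ids.output_id(rec.id, read_no), rec.sequence,
                      state.qual.apply_binning(rec.quality))


def _expected_text(state: _CodecState, rec: ReadRecord, read_no: int) -> str:
    """Serialized form of _expected_output (hot path, skips validation)."""
    ids = state.ids
    if ids.mode == "lossless":
        oid = rec.id
    elif ids.mode == "instrument":
        oid = IdCoder.instrument_name(rec.id)
    else:
        oid = f"r{read_no}"
    q = rec.quality if state.qual.mode == "96" else state.qual.apply_binning(rec.quality)
    return f"@{oid}\n{rec.sequence}\n+\n{q}\n"


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def compress_records(records: Sequence, config: Config,
                     trace: Optional[list] = None
                     ) -> Tuple[bytes, CompressionStats]:
    """Compress ReadRecords (SE) or (mate1, mate2) tuples (PE).

    Returns (archive bytes, stats).  ``trace``, if given, collects the
    16-byte codec-state digest after every block (for symmetry checks).
    """
    from .rangecoder import RangeEncoder

    paired = config.paired
    records = list(records)
    if paired and records and not isinstance(records[0], tuple):
        raise ValueError("paired config requires (mate1, mate2) tuples")
    if not paired and records and isinstance(records[0], tuple):
        raise ValueError("unpaired config got tuples")
    if config.reordered:
        records = sort_for_reo(records)

    if paired:
        unit_size = lambda u: u[0].raw_size + u[1].raw_size
    else:
        unit_size = lambda u: u.raw_size
    blocks_list: List[List] = []
    cur: List = []
    cur_bytes = 0
    for unit in records:
        sz = unit_size(unit)
        if cur and cur_bytes + sz > config.block_size:
            blocks_list.append(cur)
            cur, cur_bytes = [], 0
        cur.append(unit)
        cur_bytes += sz
    if cur:
        blocks_list.append(cur)

    state = _CodecState(config)
    stats = CompressionStats()
    block_entries = []
    payload = bytearray()

    for block in blocks_list:
        encs = {s: RangeEncoder() for s in _STREAMS}
        state.base.start_block()
        state.ids.start_block()

        units = block
        if paired:
            flat = [r for u in units for r in u]
        else:
            flat = units
        lens = np.array([len(r.sequence) for r in flat], np.int64)
        encs["lengths"].reserve(10 * len(flat) + 64)
        st, out, lpos = encs["lengths"].buffers
        K.encode_lengths_block(lens, state.len_bl, st, out, lpos)

        out_texts = []
        for unit in units:
            if paired:
                r1, r2 = unit
                c1 = seq_to_codes(r1.sequence)
                c2 = seq_to_codes(r2.sequence)
                if config.reordered:
                    state.base.encode_prefixed_read(encs["prefix"], encs["bases"], c1)
                else:
                    state.base.encode_read(encs["bases"], c1)
                stats.pe_tries += 1
                if state.pe.encode_second(encs["pe"], state.base, encs["bases"],
                                          c1, c2):
                    stats.pe_hits += 1
                for r in (r1, r2):
                    state.read_no += 1
                    state.ids.encode_id(encs["ids"], r.id)
                    out_texts.append(_expected_text(state, r, state.read_no))
                stats.total_bases += len(r1.sequence) + len(r2.sequence)
                stats.raw_bytes += unit_size(unit)
                stats.n_records += 2
            else:
                rec = unit
                codes = seq_to_codes(rec.sequence)
                if config.reordered:
                    state.base.encode_prefixed_read(encs["prefix"], encs["bases"],
                                                    codes)
                else:
                    state.base.encode_read(encs["bases"], codes)
                state.read_no += 1
                state.ids.encode_id(encs["ids"], rec.id)
                out_texts.append(_expected_text(state, rec, state.read_no))
                stats.total_bases += len(rec.sequence)
                stats.raw_bytes += rec.raw_size
                stats.n_records += 1

        state.qual.encode_block(encs["quals"], [r.quality for r in flat])

        stream_data = {s: encs[s].flush() for s in _STREAMS}
        for s in _STREAMS:
            stats.stream_bytes[s] += len(stream_data[s])
        block_raw = sum(unit_size(u) for u in units)
        block_entries.append((len(units), block_raw, _block_checksum(out_texts),
                              tuple(len(stream_data[s]) for s in _STREAMS)))
        for s in _STREAMS:
            payload.extend(stream_data[s])
        stats.n_blocks += 1
        if trace is not None:
            trace.append(state.digest())

    header = _pack_header(config, stats.n_records, block_entries, state)
    return bytes(header) + bytes(payload), stats


def _pack_header(config: Config, n_records: int, block_entries, state) -> bytearray:
    h = bytearray()
    h += MAGIC
    flags = (1 if config.paired else 0) | (2 if config.reordered else 0)
    h += struct.pack("<BBBB", VERSION, flags,
                     QUALITY_MODES.index(config.quality_mode),
                     ID_MODES.index(config.id_mode))
    e, p, s, b = config.tier_sizes
    h += struct.pack("<QBBBBQQB", config.genome_size, e, p, s, b,
                     config.block_size, n_records, config.max_corrections)
    if config.quality_mode != "none":
        table = state.qual.bin_table
        h += struct.pack("<H", len(table))
        for lo, rep in table:
            h += struct.pack("<BB", lo, rep)
    else:
        h += struct.pack("<H", 0)
    h += struct.pack("<I", len(block_entries))
    for n_units, raw_bytes, checksum, sizes in block_entries:
        h += struct.pack("<IQQ6Q", n_units, raw_bytes, checksum, *sizes)
    return h


@dataclass(frozen=True)
class ArchiveInfo:
    """Parsed archive header."""

    config: Config
    n_records: int
    bin_table: tuple
    block_entries: tuple     # (n_units, checksum, stream sizes)
    payload_offset: int

    @property
    def n_blocks(self) -> int:
        return len(self.block_entries)


def read_header(data: bytes) -> ArchiveInfo:
    if len(data) < 8 or data[:4] != MAGIC:
        raise ArchiveError("not an FQPK archive (bad magic)")
    version, flags, qmode_i, idmode_i = struct.unpack_from("<BBBB", data, 4)
    if version != VERSION:
        raise ArchiveError(f"unsupported archive version {version}")
    off = 8
    try:
        (genome_size, e, p, s, b, block_size, n_records,
         max_corr) = struct.unpack_from("<QBBBBQQB", data, off)
        off += struct.calcsize("<QBBBBQQB")
        (n_bins,) = struct.unpack_from("<H", data, off)
        off += 2
        table = []
        for _ in range(n_bins):
            lo, rep = struct.unpack_from("<BB", data, off)
            table.append((lo, rep))
            off += 2
        (n_blocks,) = struct.unpack_from("<I", data, off)
        off += 4
        entries = []
        for _ in range(n_blocks):
            vals = struct.unpack_from("<IQQ6Q", data, off)
            off += struct.calcsize("<IQQ6Q")
            entries.append((vals[0], vals[1], vals[2], tuple(vals[3:])))
    except struct.error as exc:
        raise ArchiveError(f"truncated archive header: {exc}") from None
    config = Config(genome_size=genome_size, tier_sizes=(e, p, s, b),
                    block_size=block_size, paired=bool(flags & 1),
                    reordered=bool(flags & 2),
                    quality_mode=QUALITY_MODES[qmode_i],
                    id_mode=ID_MODES[idmode_i], max_corrections=max_corr)
    return ArchiveInfo(config, n_records, tuple(table), tuple(entries), off)


# ---------------------------------------------------------------------------
# decompression
# ---------------------------------------------------------------------------

def decompress_records(data: bytes, trace: Optional[list] = None
                       ) -> Tuple[Config, List]:
    """Reconstruct the records (SE) or mate tuples (PE) from archive bytes."""
    from .rangecoder import RangeDecoder

    info = read_header(data)
    config = info.config
    bin_table = info.bin_table if info.bin_table else None
    state = _CodecState(config, bin_table)
    expected_payload = sum(sum(sizes) for _, _, _, sizes in info.block_entries)
    if len(data) < info.payload_offset + expected_payload:
        raise ArchiveError("truncated archive: payload shorter than header promises")

    out_units: List = []
    off = info.payload_offset
    for bi, (n_units, raw_bytes, checksum, sizes) in enumerate(info.block_entries):
        streams = {}
        for s, sz in zip(_STREAMS, sizes):
            streams[s] = data[off:off + sz]
            off += sz
        decs = {s: (RangeDecoder(streams[s]) if len(streams[s]) >= 5 else None)
                for s in _STREAMS}
        state.base.start_block()
        state.ids.start_block()

        try:
            n_flat = n_units * 2 if config.paired else n_units
            lens = np.zeros(n_flat, np.int64)
            if n_flat:
                st, inp, pos = decs["lengths"].buffers
                K.decode_lengths_block(n_flat, state.len_bl, st, inp, pos, lens)
            if n_flat and (lens.min() < 0 or int(lens.sum()) > raw_bytes):
                raise ArchiveError(
                    f"implausible read lengths in block {bi}: archive corrupt")

            seqs: List[np.ndarray] = []
            for ui in range(n_units):
                if config.paired:
                    l1, l2 = int(lens[2 * ui]), int(lens[2 * ui + 1])
                    if config.reordered:
                        c1 = state.base.decode_prefixed_read(decs["prefix"],
                                                             decs["bases"], l1)
                    else:
                        c1 = state.base.decode_read(decs["bases"], l1)
                    c2 = state.pe.decode_second(decs["pe"], state.base,
                                                decs["bases"], c1, l2)
                    seqs.extend((c1, c2))
                else:
                    L = int(lens[ui])
                    if config.reordered:
                        c = state.base.decode_prefixed_read(decs["prefix"],
                                                            decs["bases"], L)
                    else:
                        c = state.base.decode_read(decs["bases"], L)
                    seqs.append(c)

            quals = state.qual.decode_block(decs["quals"], [len(c) for c in seqs])
            flat_records = []
            for c, q in zip(seqs, quals):
                state.read_no += 1
                rid = state.ids.decode_id(decs["ids"])
                flat_records.append(ReadRecord(rid, codes_to_seq(c), q))
        except ArchiveError:
            raise
        except (ValueError, IndexError, OverflowError) as exc:
            # a corrupt stream desynchronizes the models; surface it cleanly
            raise ArchiveError(f"block {bi} undecodable: archive corrupt "
                               f"({exc})") from None

        got = _block_checksum([r.to_fastq() for r in flat_records])
        if got != checksum:
            raise ArchiveError(f"checksum mismatch in block {bi}: archive corrupt")
        if config.paired:
            units = [(flat_records[2 * i], flat_records[2 * i + 1])
                     for i in range(n_units)]
        else:
            units = flat_records
        out_units.extend(units)
        if trace is not None:
            trace.append(state.digest())

    return config, out_units


# ---------------------------------------------------------------------------
# file-level API
# ---------------------------------------------------------------------------

def compress(inputs: Union[str, Sequence[str]], config: Config,
             output: Optional[str] = None,
             trace: Optional[list] = None) -> Tuple[bytes, CompressionStats]:
    """Compress one FASTQ file (SE) or two (PE) into an archive."""
    if isinstance(inputs, (str, bytes)):
        inputs = [inputs]
    inputs = list(inputs)
    if config.paired:
        if len(inputs) != 2:
            raise ValueError("paired mode requires exactly two input files")
        records = pair(list(read_fastq(inputs[0])), list(read_fastq(inputs[1])))
    else:
        if len(inputs) != 1:
            raise ValueError("single-end mode requires exactly one input file")
        records = list(read_fastq(inputs[0]))
    data, stats = compress_records(records, config, trace=trace)
    if output is not None:
        with open(output, "wb") as fh:
            fh.write(data)
    return data, stats


def decompress(archive: Union[str, bytes], outputs: Optional[Sequence[str]] = None,
               trace: Optional[list] = None):
    """Decompress an archive (path or bytes) to records and optionally files."""
    if isinstance(archive, str):
        with open(archive, "rb") as fh:
            data = fh.read()
    else:
        data = archive
    config, units = decompress_records(data, trace=trace)
    if outputs is not None:
        outputs = list(outputs)
        if config.paired:
            if len(outputs) != 2:
                raise ValueError("paired archive needs two output paths")
            write_fastq([u[0] for u in units], outputs[0])
            write_fastq([u[1] for u in units], outputs[1])
        else:
            if len(outputs) != 1:
                raise ValueError("single-end archive needs one output path")
            write_fastq(units, outputs[0])
    return config, units
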