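"""Reading, writing, pairing and blocking of 4-line FASTQ records.

Only the plain 4-line dialect is supported (no wrapped sequences), which is
what sequencing instruments emit and what keeps the decoder deterministic.
Two normalizations are applied on input and are *not* reversed:

* lowercase bases are uppercased (any non-ACGTN character is an error);
* an ID repeated on the ``+`` line is discarded and regenerated as bare ``+``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Sequence, Tuple

_VALID_BASES = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the failing record index."""


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One FASTQ record: ID without the leading '@', bases over {A,C,G,T,N},
    and a quality string of equal length with characters in [33, 126]."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"sequence/quality length mismatch ({len(self.sequence)} vs "
                f"{len(self.quality)}) in record {self.id!r}")

    @property
    def raw_size(self) -> int:
        """Byte count of the serialized 4-line record."""
        return len(self.id) + len(self.sequence) + len(self.quality) + 6

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        probe = source
        if isinstance(probe, io.TextIOBase):
            return probe
        data = probe.read()
        if isinstance(data, str):
            return io.StringIO(data)
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        return io.StringIO(data.decode("ascii"))
    path = str(source)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(source) -> Iterator[ReadRecord]:
    """Yield ReadRecords from a path, text stream or (gzip) byte stream."""
    fh = _open_text(source)
    idx = 0
    while True:
        header = fh.readline()
        if header == "":
            return
        lines = [header, fh.readline(), fh.readline(), fh.readline()]
        if "" in lines[1:]:
            raise FastqParseError(f"record {idx}: truncated record")
        lines = [ln.rstrip("\n").rstrip("\r") for ln in lines]
        if not lines[0].startswith("@"):
            raise FastqParseError(f"record {idx}: header does not start with '@'")
        if not lines[2].startswith("+"):
            raise FastqParseError(f"record {idx}: separator line does not start with '+'")
        seq = lines[1].upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastqParseError(
                f"record {idx}: invalid base(s) {sorted(bad)} in sequence")
        if len(seq) != len(lines[3]):
            raise FastqParseError(
                f"record {idx}: sequence and quality lengths differ "
                f"({len(seq)} vs {len(lines[3])})")
        for ch in lines[3]:
            if not 33 <= ord(ch) <= 126:
                raise FastqParseError(
                    f"record {idx}: quality character {ch!r} outside [33,126]")
        yield ReadRecord(lines[0][1:], seq, lines[3])
        idx += 1


def write_fastq(records: Iterable[ReadRecord], sink) -> None:
    """Write records as 4-line FASTQ to a path or text stream."""
    own = not hasattr(sink, "write")
    fh = open(str(sink), "wt", encoding="ascii") if own else sink
    try:
        fh.write("".join(r.to_fastq() for r in records))
    finally:
        if own:
            fh.close()


def blocks(records: Sequence[ReadRecord],
           block_size_bytes: int) -> List[List[ReadRecord]]:
    """Greedy partition so each block's raw FASTQ byte count stays within
    ``block_size_bytes``; a single oversized record forms its own block."""
    if block_size_bytes <= 0:
        raise ValueError("block_size_bytes must be positive")
    out: List[List[ReadRecord]] = []
    cur: List[ReadRecord] = []
    cur_bytes = 0
    for rec in records:
        sz = rec.raw_size
        if cur and cur_bytes + sz > block_size_bytes:
            out.append(cur)
            cur = []
            cur_bytes = 0
        cur.append(rec)
        cur_bytes += sz
    if cur:
        out.append(cur)
    return out


def pair(records1: Sequence[ReadRecord],
         records2: Sequence[ReadRecord]) -> List[Tuple[ReadRecord, ReadRecord]]:
    """Positionally zip two mate streams; lengths must agree."""
    if len(records1) != len(records2):
        raise ValueError(
            f"paired inputs differ in read count ({len(records1)} vs {len(records2)})")
    return list(zip(records1, records2))
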