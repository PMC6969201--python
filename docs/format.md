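# FQPK archive layout

All integers little-endian.  One header, then the concatenated per-block
streams in block order.

## Header

| field | type | notes |
|---|---|---|
| magic | 4 bytes | `"FQPK"` |
| version | u8 | 1 |
| flags | u8 | bit 0 = paired, bit 1 = reordered |
| quality mode | u8 | index into (96, 8, 4, 2, none) |
| id mode | u8 | index into (lossless, instrument, none) |
| genome size | u64 | declared genome size (bases) |
| e, p, s, b | 4 × u8 | tier k-mer lengths |
| block size | u64 | raw bytes per block |
| n records | u64 | total FASTQ records (both mates counted) |
| max corrections | u8 | per-read correction cap |
| n bins | u16 | 0 for quality mode `none` |
| bin table | n × (u8 lo, u8 rep) | bin lower bounds and representative Phred values |
| n blocks | u32 | |

Then one entry per block:

| field | type |
|---|---|
| n units | u32 (reads, or pairs in PE mode) |
| raw bytes | u64 (serialized FASTQ size of the block) |
| checksum | u64 (BLAKE2b-64 of the decoder's output text) |
| stream sizes | 6 × u64 |

The six streams per block, in order: bases, lengths, ids, qualities,
pe, prefix.  Unused streams (e.g. `pe` in SE mode) are present as a bare
5-byte coder flush.  Every stream is an independent range-coded payload;
the adaptive models and dictionaries behind them persist across blocks,
so blocks must be decoded in order.
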