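# Methods

## Model

fqpack treats a FASTQ file as four interleaved streams — DNA bases, read
lengths, read IDs, quality strings (plus pair-prediction and prefix
streams in the respective modes) — and codes each under its own
probability model with a shared range coder.  The core assumption is the
one that holds for high-coverage short-read sequencing: every genomic
position is seen by many reads, so the distribution of the next base given
its preceding context concentrates sharply once enough data has been
processed.

### Base prediction

Four hash-map dictionaries count canonical k-mers at tier lengths
`e < p < s < b`.  A *canonical* k-mer is the lexicographic minimum of the
k-mer and its reverse complement, so reads from either strand reinforce
the same counters.  Internally each tier stores one saturating 16-bit
counter per canonical k-mer; the successor CountVector of a context is
materialized by four (or, for partial queries, up to 64) canonical
lookups.  Counters saturate at 2^16 − 1 rather than rescaling — they feed
only the rank ordering and the correction rule, which are order
statistics.

At position `i` the cascade tries tiers largest-first.  A tier with
context length `k − 1` is usable when at least `e − 1` symbols of history
exist, at most two leading context symbols are missing (those are summed
over all 4^m completions), and the known context contains no `N`.  The
first tier with a non-zero CountVector answers; if all usable tiers are
zero the smallest usable tier answers with zeros; with no usable tier an
order-0 context is used.  The coded symbol is the *rank* of the base in
the count-descending order (ties lexicographic, `N` fixed at rank 4, so
`N` is always codable without an escape).

### Rank model

Ranks are coded under adaptive frequency vectors indexed by a context
descriptor packed from: answering tier (5 values), position bucket
(`min(position, 15)`, 16 values), a quantization of the top two counts
(six magnitude levels for the top count × four top/second ratio levels),
and whether the previous base was corrected — 3 840 contexts of 5
frequencies.  Initialization is (16, 8, 4, 2, 1), increment 32, and all
five values are halved (floor 1) when the total would exceed 2^16.  The
increment is deliberately large relative to the initial mass: a single
observation moves its rank's probability by ~48 % (rank 0) to several
hundred percent (ranks 1–4), the "learn aggressively" behaviour the
cascade needs because each context descriptor aggregates many concrete
contexts.

### Error correction

After a base is coded, if the answering tier was `D_b`, the current
symbol's counter is 0, and the maximum counter is unique and ≥ 3, the
symbol is replaced by the dominant base *in the history and the
dictionaries only* — the emitted rank already encoded the original
symbol, so decompression is exact.  The decoder applies the same rule to
the same counts, keeping both sides' dictionaries identical.  Corrections
are capped at 8 per read and never involve `N`; corrections are applied
only on `D_b` answers because only near-unique long contexts give reliable
evidence of a sequencing error.  (A second, rarely effective correction
pass is deliberately not implemented.)

### Reordering and prefixes

In REO mode reads (first mates in PE mode) are stably sorted by sequence.
For ACGT lexicographic order the big-endian 2-bit packing is
order-isomorphic, so the packed `p`-length prefixes of the sorted stream
are non-decreasing and their deltas are coded as an adaptive bit-length
symbol plus raw low bits; prefixes containing `N` (or reads shorter than
`p`) escape to plain base coding.  The suffix is coded exactly as in OO
mode, with the prefix serving as context history.  Sorting is what makes
neighbouring reads maximally similar, collapsing the expensive early
positions of every read (short contexts, weak statistics) into near-zero
deltas — measured at 20× coverage this removes ~30 % of the base-stream
cost.

### Paired ends

`M_b` maps the minimizer of read 1 (smallest canonical (b−2)-mer over all
N-free windows, leftmost on ties) to up to 8 candidate second-read
canonical b-mers ordered by co-occurrence count (ties keep insertion
order; a full list evicts its weakest tail entry).  Candidates are probed
in rank order against all windows of read 2 in both orientations; a hit
stores (rank, 0-based position, orientation bit) and the matched window is
excluded from base coding.  A miss, an empty candidate list, or an
all-`N` read 1 falls back to single-end coding.  After each pair the
(minimizer-1, minimizer-b of read 2) pair is counted — on both sides, so
the dictionary stays synchronized.

### IDs and qualities

IDs: maximal alphanumeric runs are tokens, everything else separators.
Digit runs without leading zeros (≤ 18 digits) are numeric and coded as
zigzag deltas against the previous ID's corresponding token; literal
tokens are coded as equal/mismatch flags with per-character comparison;
any structural change stores the ID verbatim.  The first ID of each block
is always verbatim.  Instrument mode keeps only the first token, coded by
position in a move-to-front list (capacity 63 + escape).  Discard mode
stores nothing and regenerates `r1, r2, …`.

Qualities: five resolutions.  The 8-level table follows the de-facto
Illumina bins with representatives (0, 6, 15, 22, 27, 33, 37, 40); the
4- and 2-level tables quantize by decades (representatives 6/15/25/37 and
6/37).  Binning is idempotent, so already-binned input rounds-trip
losslessly, and the tables travel in the archive header.  Scores are
coded per context = position bucket (64 buckets at full resolution, 16
otherwise) × the last h binned scores (h = 2, 6, 9, 10 for alphabets of
96, 8, 4, 2) — context spaces are sized to at most 2^22 rows so the
tables stay dense arrays.  Mode `none` stores nothing and regenerates
Q40 (`I`).

### Range coder

A carry-counting byte-oriented coder: 64-bit low with a cache/pending-run
carry mechanism, 32-bit range, renormalization whenever the range drops
below 2^24 (so totals up to 2^24 are exact), 5 tail bytes on flush.  The
per-symbol overhead is ≈ log2(1 + total/range) bits, i.e. ≤ 0.006 bits at
the model sizes used here — measured against the Shannon bound in the
tests.  Adaptive tables keep totals ≤ 2^16.

## Container

Blocks of (by default) 16 MiB of raw FASTQ are coded with per-block
streams but *continuous* dictionaries and models — the single-threaded
semantics that give the best ratios; the block boundaries remain in the
format so a future parallel implementation with synchronization-point
merging would not need a format change.  Each block entry carries a
64-bit BLAKE2b checksum of the exact text the decoder must produce; any
stream corruption is caught there (the decoder also clamps implausible
read lengths and feeds zero bytes past a truncated stream so that it
fails cleanly rather than reading out of bounds).  All mode flags,
tier sizes, binning tables and counts are in the header — archives are
self-contained.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `genome_size` | — | declared approximate genome size (bases); sets tiers |
| `(e,p,s,b)` | derived | tier k-mer lengths, `b = clamp(⌈log4 G⌉+6, 13, 31)`, `s=b−3`, `p=min(16,s−3)`, `e=max(4,p−4)` |
| `block_size` | 16 MiB | raw bytes per block |
| `quality_mode` | `96` | 96 / 8 / 4 / 2 / none |
| `id_mode` | `lossless` | lossless / instrument / none |
| `max_corrections` | 8 | per-read cap on error corrections |

The tier-size formula makes b-mers mostly unique in the declared genome
(`4^(b−6) ≥ G`) while keeping `e` short enough to give non-zero statistics
within the first few bases of a read.  All adaptive-model constants are
module-level and serialized semantics, not tunables.

## Synthetic data

`fqpack.simdata` generates the conditions the codec is designed for: an
i.i.d. uniform random genome, uniformly placed fixed- or variable-length
reads from either strand, substitution errors at a stated rate (no
indels — the short-read error profile), optional `N` masking, FR-oriented
pairs with normal insert sizes, Illumina-like IDs (`sim.<n> <n>
length=<L>`) and position-decaying Gaussian qualities.  It does *not*
emulate repeat structure, coverage bias, PCR duplicates, adapter
contamination or realistic error spectra; passing tests therefore
demonstrate correctness (losslessness, symmetry, determinism) under
realistic volume and redundancy, and the *direction* of the compression
effects (coverage learning, reordering gain, pair prediction), not the
absolute ratios achievable on real instruments' data.

## Test problem sizes

The randomized round-trip suite draws 200 datasets with genomes
log-uniform in 10–200 kbp and coverage log-uniform in 2–30× (~130 Mbases
in total), cycling through all mode combinations; learning behaviour is
measured at 20× coverage of a 100 kbp genome.  These sizes were chosen so
the whole suite exercises multi-block archives and well-warmed
dictionaries while remaining a desk-scale run; the mechanisms scale to
server-scale data by construction (hash maps grow by doubling), but
memory of order the distinct-k-mer count is then required.

## Known limitations

* Single-threaded; no parallel block processing.
* REO mode emits reads in sorted order (the permutation is not stored).
* Lowercase bases are uppercased and `+`-line comments dropped on read —
  archives reproduce the normalized file, not arbitrary input bytes.
* `b ≤ 31` so packed k-mers fit a signed 64-bit word.
* Streaming decompression of an individual block requires replaying all
  preceding blocks (dictionaries are cumulative).
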