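"""Numba-compiled inner loops shared by all codecs.

Everything here operates on plain numpy arrays so that encoder and decoder
can replay byte-identical state transitions.  Conventions:

* DNA symbols are uint8 codes A=0, C=1, G=2, T=3, N=4.
* k-mers are packed big-endian, 2 bits per base, into non-negative int64
  (hence k <= 31); the packed value of a k-mer compares exactly like the
  lexicographic order of its string form.
* The range coder is a carry-counting byte-oriented coder: 64-bit low,
  32-bit range, renormalization keeps range >= 2**24, cumulative totals
  must stay <= 2**24.
* Adaptive frequency tables use additive increment + halving-with-floor-1
  rescale; encoder and decoder update in lockstep.
"""

import numpy as np
from numba import njit

RC_TOP = 1 << 24
MODEL_INC = 32
MODEL_LIMIT = 1 << 16

# model-context geometry: 5 tiers x 16 position buckets x 24 count patterns x 2
N_POS_BUCKETS = 16
N_COUNT_QUANT = 24
N_MODEL_CTX = 5 * N_POS_BUCKETS * N_COUNT_QUANT * 2
TIER_B, TIER_S, TIER_P, TIER_E, TIER_ORDER0 = 0, 1, 2, 3, 4

_JIT = dict(cache=True, nogil=True)


# ---------------------------------------------------------------------------
# range coder
# ---------------------------------------------------------------------------

@njit(**_JIT)
def rc_enc_init(st):
    # st: int64[4] = (low, cache, pending, range)
    st[0] = 0
    st[1] = 0
    st[2] = 1
    st[3] = 0xFFFFFFFF


@njit(inline="always")
def _rc_shift_low(st, out, pos):
    low = st[0]
    if low < 0xFF000000 or low > 0xFFFFFFFF:
        carry = low >> 32
        p = pos[0]
        out[p] = (st[1] + carry) & 0xFF
        p += 1
        n = st[2] - 1
        while n > 0:
            out[p] = (0xFF + carry) & 0xFF
            p += 1
            n -= 1
        pos[0] = p
        st[2] = 0
        st[1] = (low >> 24) & 0xFF
    st[2] += 1
    st[0] = (low << 8) & 0xFFFFFFFF


@njit(**_JIT)
def rc_encode(st, out, pos, cum, freq, tot):
    r = st[3] // tot
    st[0] += cum * r
    st[3] = r * freq
    while st[3] < RC_TOP:
        _rc_shift_low(st, out, pos)
        st[3] <<= 8


@njit(**_JIT)
def rc_enc_flush(st, out, pos):
    for _ in range(5):
        _rc_shift_low(st, out, pos)


@njit(**_JIT)
def rc_encode_bits(st, out, pos, value, nbits):
    # most-significant chunk first, <=16 bits per coding step
    while nbits > 0:
        c = nbits if nbits <= 16 else 16
        nbits -= c
        chunk = (value >> nbits) & ((1 << c) - 1)
        r = st[3] >> c
        st[0] += chunk * r
        st[3] = r
        while st[3] < RC_TOP:
            _rc_shift_low(st, out, pos)
            st[3] <<= 8


@njit(**_JIT)
def rc_dec_init(st, inp, pos):
    # st: int64[2] = (range, code)
    st[0] = 0xFFFFFFFF
    code = 0
    p = pos[0]
    for _ in range(5):
        code = ((code << 8) | inp[p]) & 0xFFFFFFFF
        p += 1
    pos[0] = p
    st[1] = code


@njit(**_JIT)
def rc_dec_getfreq(st, tot):
    r = st[0] // tot
    c = st[1] // r
    if c >= tot:
        c = tot - 1
    return c


@njit(**_JIT)
def rc_dec_update(st, inp, pos, cum, freq, tot):
    r = st[0] // tot
    st[1] -= cum * r
    st[0] = r * freq
    p = pos[0]
    n = inp.shape[0]
    while st[0] < RC_TOP:
        # corrupt streams may demand more bytes than exist: feed zeros so the
        # decode terminates and the block checksum can reject the result
        byte = inp[p] if p < n else 0
        st[1] = ((st[1] << 8) | byte) & 0xFFFFFFFF
        p += 1
        st[0] <<= 8
    pos[0] = p


@njit(**_JIT)
def rc_decode_bits(st, inp, pos, nbits):
    value = 0
    p = pos[0]
    while nbits > 0:
        c = nbits if nbits <= 16 else 16
        nbits -= c
        r = st[0] >> c
        chunk = st[1] // r
        if chunk >= (1 << c):
            chunk = (1 << c) - 1
        st[1] -= chunk * r
        st[0] = r
        n = inp.shape[0]
        while st[0] < RC_TOP:
            byte = inp[p] if p < n else 0
            st[1] = ((st[1] << 8) | byte) & 0xFFFFFFFF
            p += 1
            st[0] <<= 8
        value = (value << c) | chunk
    pos[0] = p
    return value


# ---------------------------------------------------------------------------
# adaptive frequency tables (uint32 rows)
# ---------------------------------------------------------------------------

@njit(**_JIT)
def adaptive_encode(freqs, sym, st, out, pos):
    tot = 0
    cum = 0
    n = freqs.shape[0]
    for i in range(n):
        f = freqs[i]
        if i < sym:
            cum += f
        tot += f
    rc_encode(st, out, pos, cum, freqs[sym], tot)
    freqs[sym] += MODEL_INC
    if tot + MODEL_INC > MODEL_LIMIT:
        for i in range(n):
            h = freqs[i] >> 1
            freqs[i] = h if h > 0 else 1


@njit(**_JIT)
def adaptive_decode(freqs, st, inp, pos):
    tot = 0
    n = freqs.shape[0]
    for i in range(n):
        tot += freqs[i]
    c = rc_dec_getfreq(st, tot)
    cum = 0
    sym = n - 1
    for i in range(n):
        nxt = cum + freqs[i]
        if c < nxt:
            sym = i
            break
        cum = nxt
    rc_dec_update(st, inp, pos, cum, freqs[sym], tot)
    freqs[sym] += MODEL_INC
    if tot + MODEL_INC > MODEL_LIMIT:
        for i in range(n):
            h = freqs[i] >> 1
            freqs[i] = h if h > 0 else 1
    return sym


@njit(inline="always")
def _bit_length(v):
    n = 0
    while v > 0:
        v >>= 1
        n += 1
    return n


@njit(**_JIT)
def encode_varint(blfreqs, st, out, pos, value):
    """Non-negative integer as adaptive bit-length symbol + raw low bits."""
    bl = _bit_length(value)
    adaptive_encode(blfreqs, bl, st, out, pos)
    if bl > 1:
        rc_encode_bits(st, out, pos, value - (1 << (bl - 1)), bl - 1)


@njit(**_JIT)
def decode_varint(blfreqs, st, inp, pos):
    bl = adaptive_decode(blfreqs, st, inp, pos)
    if bl == 0:
        return 0
    if bl == 1:
        return 1
    return (1 << (bl - 1)) + rc_decode_bits(st, inp, pos, bl - 1)


@njit(inline="always")
def _zigzag(v):
    return (v << 1) ^ (v >> 63)


@njit(inline="always")
def _unzigzag(z):
    return (z >> 1) ^ -(z & 1)


@njit(**_JIT)
def encode_svarint(blfreqs, st, out, pos, value):
    encode_varint(blfreqs, st, out, pos, _zigzag(value))


@njit(**_JIT)
def decode_svarint(blfreqs, st, inp, pos):
    return _unzigzag(decode_varint(blfreqs, st, inp, pos))


# ---------------------------------------------------------------------------
# open-addressing hash map: int64 key -> uint16 saturating count
# ---------------------------------------------------------------------------

_U = np.uint64


@njit(inline="always")
def _slot_of(key, mask):
    z = _U(key)
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    z = z ^ (z >> _U(31))
    return np.int64(z & _U(mask))


@njit(**_JIT)
def hm_get(keys, vals, key):
    mask = keys.shape[0] - 1
    i = _slot_of(key, mask)
    while keys[i] != -1:
        if keys[i] == key:
            return np.int64(vals[i])
        i = (i + 1) & mask
    return np.int64(0)


@njit(**_JIT)
def hm_add(keys, vals, key):
    """Increment (saturating at 65535); returns 1 if the key is new."""
    mask = keys.shape[0] - 1
    i = _slot_of(key, mask)
    while keys[i] != -1:
        if keys[i] == key:
            if vals[i] < 0xFFFF:
                vals[i] += 1
            return 0
        i = (i + 1) & mask
    keys[i] = key
    vals[i] = 1
    return 1


@njit(**_JIT)
def hm_rehash(keys, vals, nkeys, nvals):
    mask = nkeys.shape[0] - 1
    for j in range(keys.shape[0]):
        k = keys[j]
        if k != -1:
            i = _slot_of(k, mask)
            while nkeys[i] != -1:
                i = (i + 1) & mask
            nkeys[i] = k
            nvals[i] = vals[j]


# ---------------------------------------------------------------------------
# k-mer packing and tier queries
# ---------------------------------------------------------------------------

@njit(inline="always")
def _pack_fwd_rc(hist, start, length):
    f = 0
    r = 0
    for j in range(length):
        c = hist[start + j]
        f = (f << 2) | c
        r |= (3 - c) << (2 * j)
    return f, r


@njit(**_JIT)
def tier_query(keys, vals, hist, i, k, missing, counts):
    """Accumulate successor counts for the tier-k context ending at i-1.

    ``missing`` leading symbols of the k-1 context are unknown and summed
    over.  Returns 1 if any successor count is non-zero.
    """
    known = k - 1 - missing
    kf, kr = _pack_fwd_rc(hist, i - known, known)
    nz = 0
    top = k - 1
    for pf in range(1 << (2 * missing)):
        pr = 0
        for j in range(missing):
            sj = (pf >> (2 * (missing - 1 - j))) & 3
            pr |= (3 - sj) << (2 * j)
        base_f = ((pf << (2 * known)) | kf) << 2
        base_r = (kr << (2 * missing)) | pr
        for c in range(4):
            fwd = base_f | c
            rc = ((3 - c) << (2 * top)) | base_r
            key = fwd if fwd < rc else rc
            cnt = hm_get(keys, vals, key)
            if cnt > 0:
                counts[c] += cnt
                nz = 1
    return nz


@njit(inline="always")
def _tier_try(keys, vals, hist, i, k, last_n, e, counts):
    """Returns missing count if tier usable (-1 otherwise); fills counts."""
    if i < e - 1:
        return -1, 0
    missing = k - 1 - i if i < k - 1 else 0
    if missing > 2:
        return -1, 0
    known = k - 1 - missing
    if last_n >= i - known:
        return -1, 0
    nz = tier_query(keys, vals, hist, i, k, missing, counts)
    return missing, nz


@njit(**_JIT)
def predict_tier(hist, i, last_n, e, p, s, b,
                 kb, vb, ks, vs, kp, vp, ke, ve, counts):
    """PPM cascade: largest tier first, first non-zero answer wins.

    Returns (tier_id, missing); counts holds the answering tier's
    CountVector (zeros for an all-zero or order-0 answer).
    """
    counts[0] = 0
    counts[1] = 0
    counts[2] = 0
    counts[3] = 0
    last_tier = TIER_ORDER0
    last_missing = 0

    m, nz = _tier_try(kb, vb, hist, i, b, last_n, e, counts)
    if m >= 0:
        if nz:
            return TIER_B, m
        last_tier, last_missing = TIER_B, m
    m, nz = _tier_try(ks, vs, hist, i, s, last_n, e, counts)
    if m >= 0:
        if nz:
            return TIER_S, m
        last_tier, last_missing = TIER_S, m
    m, nz = _tier_try(kp, vp, hist, i, p, last_n, e, counts)
    if m >= 0:
        if nz:
            return TIER_P, m
        last_tier, last_missing = TIER_P, m
    m, nz = _tier_try(ke, ve, hist, i, e, last_n, e, counts)
    if m >= 0:
        if nz:
            return TIER_E, m
        last_tier, last_missing = TIER_E, m
    return last_tier, last_missing


@njit(inline="always")
def _rank_order4(counts, order):
    # stable insertion sort of A,C,G,T by (-count, symbol)
    order[0] = 0
    order[1] = 1
    order[2] = 2
    order[3] = 3
    for a in range(1, 4):
        x = order[a]
        cx = counts[x]
        j = a - 1
        while j >= 0 and counts[order[j]] < cx:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = x
    order[4] = 4


@njit(inline="always")
def _count_quant(top, second):
    if top == 0:
        lvl = 0
    elif top == 1:
        lvl = 1
    elif top == 2:
        lvl = 2
    elif top <= 4:
        lvl = 3
    elif top <= 16:
        lvl = 4
    else:
        lvl = 5
    if second == 0:
        ratio = 0
    elif second * 8 <= top:
        ratio = 1
    elif second * 2 <= top:
        ratio = 2
    else:
        ratio = 3
    return lvl * 4 + ratio


@njit(inline="always")
def _model_ctx(tier, position, top, second, corrected):
    posb = position if position < N_POS_BUCKETS - 1 else N_POS_BUCKETS - 1
    return ((tier * N_POS_BUCKETS + posb) * N_COUNT_QUANT
            + _count_quant(top, second)) * 2 + corrected


@njit(inline="always")
def _maybe_correct(counts, sym):
    """Correction rule: current counter 0, unique maximum >= 3 -> argmax."""
    if sym == 4 or counts[sym] != 0:
        return sym
    mx = -1
    arg = 0
    ties = 0
    for c in range(4):
        if counts[c] > mx:
            mx = counts[c]
            arg = c
            ties = 1
        elif counts[c] == mx:
            ties += 1
    if mx >= 3 and ties == 1:
        return arg
    return sym


@njit(**_JIT)
def encode_read_bases(orig, hist, skip_s, skip_e, e, p, s, b,
                      kb, vb, ks, vs, kp, vp, ke, ve,
                      model, st, out, pos, max_corr, counts, order,
                      do_insert, new_counts):
    """Encode one read's bases; ``hist`` (a copy of orig) receives corrections.

    Positions in [skip_s, skip_e) are treated as already known to the
    decoder (REO prefix, PE matched b-mer) and are not coded.  When
    ``do_insert`` the corrected read is counted into all tiers afterwards
    (the caller must have reserved hash-map capacity).
    """
    last_n = -1
    corr_prev = 0
    ncorr = 0
    n = orig.shape[0]
    for i in range(n):
        if skip_s <= i < skip_e:
            if hist[i] == 4:
                last_n = i
            corr_prev = 0
            continue
        tier, _missing = predict_tier(hist, i, last_n, e, p, s, b,
                                      kb, vb, ks, vs, kp, vp, ke, ve, counts)
        _rank_order4(counts, order)
        sym = orig[i]
        if sym == 4:
            rank = 4
        else:
            rank = 0
            for j in range(4):
                if order[j] == sym:
                    rank = j
                    break
        ctx = _model_ctx(tier, i, counts[order[0]], counts[order[1]], corr_prev)
        adaptive_encode(model[ctx], rank, st, out, pos)
        corr_prev = 0
        if tier == TIER_B and ncorr < max_corr:
            fixed = _maybe_correct(counts, sym)
            if fixed != sym:
                hist[i] = fixed
                ncorr += 1
                corr_prev = 1
        if hist[i] == 4:
            last_n = i
    if do_insert:
        insert_read_kmers(hist, e, p, s, b, kb, vb, ks, vs, kp, vp, ke, ve,
                          new_counts)
    return ncorr


@njit(**_JIT)
def decode_read_bases(orig, hist, skip_s, skip_e, e, p, s, b,
                      kb, vb, ks, vs, kp, vp, ke, ve,
                      model, st, inp, pos, max_corr, counts, order,
                      do_insert, new_counts):
    """Decoder mirror of encode_read_bases.

    ``orig`` receives the decoded original symbols; ``hist`` the corrected
    sequence used for context formation (skip regions must be pre-filled in
    both arrays).
    """
    last_n = -1
    corr_prev = 0
    ncorr = 0
    n = orig.shape[0]
    for i in range(n):
        if skip_s <= i < skip_e:
            if hist[i] == 4:
                last_n = i
            corr_prev = 0
            continue
        tier, _missing = predict_tier(hist, i, last_n, e, p, s, b,
                                      kb, vb, ks, vs, kp, vp, ke, ve, counts)
        _rank_order4(counts, order)
        ctx = _model_ctx(tier, i, counts[order[0]], counts[order[1]], corr_prev)
        rank = adaptive_decode(model[ctx], st, inp, pos)
        sym = 4 if rank == 4 else order[rank]
        orig[i] = sym
        hist[i] = sym
        corr_prev = 0
        if tier == TIER_B and ncorr < max_corr:
            fixed = _maybe_correct(counts, sym)
            if fixed != sym:
                hist[i] = fixed
                ncorr += 1
                corr_prev = 1
        if hist[i] == 4:
            last_n = i
    if do_insert:
        insert_read_kmers(hist, e, p, s, b, kb, vb, ks, vs, kp, vp, ke, ve,
                          new_counts)
    return ncorr


@njit(**_JIT)
def insert_read_kmers(hist, e, p, s, b,
                      kb, vb, ks, vs, kp, vp, ke, ve, new_counts):
    """Count every N-free canonical k-mer of the read in all four tiers."""
    n = hist.shape[0]
    fe = 0
    re_ = 0
    fp = 0
    rp = 0
    fs = 0
    rs = 0
    fb = 0
    rb = 0
    me = (1 << (2 * e)) - 1
    mp = (1 << (2 * p)) - 1
    ms = (1 << (2 * s)) - 1
    mb_ = (1 << (2 * b)) - 1
    valid = 0
    for i in range(n):
        c = hist[i]
        if c == 4:
            valid = 0
            fe = re_ = fp = rp = fs = rs = fb = rb = 0
            continue
        comp = 3 - c
        fe = ((fe << 2) | c) & me
        re_ = (re_ >> 2) | (comp << (2 * (e - 1)))
        fp = ((fp << 2) | c) & mp
        rp = (rp >> 2) | (comp << (2 * (p - 1)))
        fs = ((fs << 2) | c) & ms
        rs = (rs >> 2) | (comp << (2 * (s - 1)))
        fb = ((fb << 2) | c) & mb_
        rb = (rb >> 2) | (comp << (2 * (b - 1)))
        valid += 1
        if valid >= e:
            new_counts[3] += hm_add(ke, ve, fe if fe < re_ else re_)
        if valid >= p:
            new_counts[2] += hm_add(kp, vp, fp if fp < rp else rp)
        if valid >= s:
            new_counts[1] += hm_add(ks, vs, fs if fs < rs else rs)
        if valid >= b:
            new_counts[0] += hm_add(kb, vb, fb if fb < rb else rb)


# ---------------------------------------------------------------------------
# quality codec (dense per-context uint16 tables, pre-halve rescale)
# ---------------------------------------------------------------------------

@njit(**_JIT)
def encode_quals_block(qsyms, lens, R, hspace, pb_max, qf, qtot,
                       st, out, pos):
    idx = 0
    for li in range(lens.shape[0]):
        ctxh = 0
        for j in range(lens[li]):
            q = qsyms[idx]
            idx += 1
            pb = j if j < pb_max else pb_max
            row = pb * hspace + ctxh
            tot = qtot[row]
            if tot + MODEL_INC > MODEL_LIMIT:
                nt = 0
                for x in range(R):
                    h = qf[row, x] >> 1
                    if h == 0:
                        h = 1
                    qf[row, x] = h
                    nt += h
                qtot[row] = nt
                tot = nt
            cum = 0
            for x in range(q):
                cum += qf[row, x]
            rc_encode(st, out, pos, cum, qf[row, q], tot)
            qf[row, q] += MODEL_INC
            qtot[row] = tot + MODEL_INC
            ctxh = (ctxh * R + q) % hspace


@njit(**_JIT)
def decode_quals_block(lens, R, hspace, pb_max, qf, qtot,
                       st, inp, pos, qout):
    idx = 0
    for li in range(lens.shape[0]):
        ctxh = 0
        for j in range(lens[li]):
            pb = j if j < pb_max else pb_max
            row = pb * hspace + ctxh
            tot = qtot[row]
            if tot + MODEL_INC > MODEL_LIMIT:
                nt = 0
                for x in range(R):
                    h = qf[row, x] >> 1
                    if h == 0:
                        h = 1
                    qf[row, x] = h
                    nt += h
                qtot[row] = nt
                tot = nt
            c = rc_dec_getfreq(st, tot)
            cum = 0
            q = R - 1
            for x in range(R):
                nxt = cum + qf[row, x]
                if c < nxt:
                    q = x
                    break
                cum = nxt
            rc_dec_update(st, inp, pos, cum, qf[row, q], tot)
            qf[row, q] += MODEL_INC
            qtot[row] = tot + MODEL_INC
            qout[idx] = q
            idx += 1
            ctxh = (ctxh * R + q) % hspace


# ---------------------------------------------------------------------------
# read-length stream
# ---------------------------------------------------------------------------

@njit(**_JIT)
def encode_lengths_block(lens, blfreqs, st, out, pos):
    prev = 0
    for i in range(lens.shape[0]):
        encode_svarint(blfreqs, st, out, pos, lens[i] - prev)
        prev = lens[i]


@njit(**_JIT)
def decode_lengths_block(n, blfreqs, st, inp, pos, lens_out):
    prev = 0
    for i in range(n):
        prev = prev + decode_svarint(blfreqs, st, inp, pos)
        lens_out[i] = prev


# ---------------------------------------------------------------------------
# minimizers and the M_b pair dictionary
# ---------------------------------------------------------------------------

@njit(**_JIT)
def find_minimizer(codes, L):
    """Smallest canonical L-mer over all N-free windows; leftmost on ties.

    Returns (packed, position); packed == -1 when no N-free window exists.
    """
    n = codes.shape[0]
    if n < L:
        return np.int64(-1), np.int64(-1)
    mask = (1 << (2 * L)) - 1
    f = 0
    r = 0
    valid = 0
    best = np.int64(0x7FFFFFFFFFFFFFFF)
    bestpos = np.int64(-1)
    for i in range(n):
        c = codes[i]
        if c == 4:
            valid = 0
            f = 0
            r = 0
            continue
        f = ((f << 2) | c) & mask
        r = (r >> 2) | ((3 - c) << (2 * (L - 1)))
        valid += 1
        if valid >= L:
            key = f if f < r else r
            if key < best:
                best = key
                bestpos = i - L + 1
    if bestpos < 0:
        return np.int64(-1), np.int64(-1)
    return best, bestpos


@njit(**_JIT)
def match_candidate(codes, cand, b):
    """First position where canonical(b-window) == cand.

    Returns (pos, orient) with orient 0 if the window equals the stored
    candidate itself, 1 if it equals the reverse complement; (-1, 0) when
    absent.
    """
    n = codes.shape[0]
    mask = (1 << (2 * b)) - 1
    f = 0
    r = 0
    valid = 0
    for i in range(n):
        c = codes[i]
        if c == 4:
            valid = 0
            f = 0
            r = 0
            continue
        f = ((f << 2) | c) & mask
        r = (r >> 2) | ((3 - c) << (2 * (b - 1)))
        valid += 1
        if valid >= b:
            key = f if f < r else r
            if key == cand:
                orient = 0 if f == cand else 1
                return np.int64(i - b + 1), np.int64(orient)
    return np.int64(-1), np.int64(0)


@njit(**_JIT)
def unpack_kmer(packed, k, out, orient):
    """Write the k-mer (or its reverse complement when orient==1) to out."""
    for j in range(k):
        c = (packed >> (2 * (k - 1 - j))) & 3
        if orient == 0:
            out[j] = c
        else:
            out[k - 1 - j] = 3 - c


MB_MAX_CANDIDATES = 8


@njit(**_JIT)
def mb_find_slot(keys, key):
    mask = keys.shape[0] - 1
    i = _slot_of(key, mask)
    while keys[i] != -1:
        if keys[i] == key:
            return i
        i = (i + 1) & mask
    return np.int64(-1)


@njit(**_JIT)
def mb_record(keys, cand, cnt, ncand, key, c2):
    """Count (minimizer, second-read b-mer); keep list sorted by count desc.

    Ties keep insertion order; a full list evicts its last (weakest) entry.
    Returns 1 if a new key slot was consumed.
    """
    mask = keys.shape[0] - 1
    i = _slot_of(key, mask)
    while keys[i] != -1:
        if keys[i] == key:
            nc = np.int64(ncand[i])
            for j in range(nc):
                if cand[i, j] == c2:
                    if cnt[i, j] < 0xFFFF:
                        cnt[i, j] += 1
                    # bubble up while strictly greater (stable for ties)
                    k = np.int64(j)
                    while k > 0 and cnt[i, k] > cnt[i, k - 1]:
                        tv = cand[i, k]
                        cand[i, k] = cand[i, k - 1]
                        cand[i, k - 1] = tv
                        tc = cnt[i, k]
                        cnt[i, k] = cnt[i, k - 1]
                        cnt[i, k - 1] = tc
                        k -= 1
                    return 0
            if nc < MB_MAX_CANDIDATES:
                cand[i, nc] = c2
                cnt[i, nc] = 1
                ncand[i] = nc + 1
            else:
                cand[i, MB_MAX_CANDIDATES - 1] = c2
                cnt[i, MB_MAX_CANDIDATES - 1] = 1
            return 0
        i = (i + 1) & mask
    keys[i] = key
    cand[i, 0] = c2
    cnt[i, 0] = 1
    ncand[i] = 1
    return 1


@njit(**_JIT)
def mb_rehash(keys, cand, cnt, ncand, nkeys, ncand_arr, ncnt, nncand):
    mask = nkeys.shape[0] - 1
    for j in range(keys.shape[0]):
        k = keys[j]
        if k != -1:
            i = _slot_of(k, mask)
            while nkeys[i] != -1:
                i = (i + 1) & mask
            nkeys[i] = k
            for q in range(MB_MAX_CANDIDATES):
                ncand_arr[i, q] = cand[j, q]
                ncnt[i, q] = cnt[j, q]
            nncand[i] = ncand[j]
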