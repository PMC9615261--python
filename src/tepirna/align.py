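"""Minimal internal read aligner: seed-and-extend against a consensus library.

Two modes, both ungapped:

``genomic``
    Local seed-and-extend on both strands; one best-scoring hit per read
    (score = matches - mismatches, ties broken by lowest target id, then
    lowest target start, then + strand).  Hits below ``min_score`` are
    discarded, which suppresses chance seed extensions from background
    sequence.  This is the workhorse behind skim quantification and the
    divergence landscapes.

``smallrna``
    End-to-end alignment of the full read on both strands, reporting every
    target position in the best mismatch stratum with count <=
    ``max_mismatch`` (the behaviour of ``bowtie -v N -a``).  Sensitivity is
    guaranteed by pigeonhole seeding: the read is cut into
    ``max_mismatch + 1`` disjoint segments, at least one of which must be
    mismatch-free in any qualifying alignment.

Alignment columns where either side is N never count as matches; they are
excluded from the per-hit base counts (see :class:`~tepirna.records.AlignmentHit`).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .records import AlignmentHit, SequenceRecord, TERecord, revcomp

__all__ = ["map_reads", "substitution_profile", "GenomicIndex", "SmallRNAIndex"]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

_POW_CACHE: dict[int, np.ndarray] = {}


def encode(seq: str) -> np.ndarray:
    """2-bit encode A,C,G,T -> 0..3; N -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(vals: np.ndarray) -> np.ndarray:
    return np.where(vals < 4, 3 - vals, 4)[::-1].copy()


def _powers(k: int) -> np.ndarray:
    if k not in _POW_CACHE:
        _POW_CACHE[k] = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return _POW_CACHE[k]


def _kmer_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes and a validity mask (False where a window has N)."""
    if vals.size < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    win = sliding_window_view(vals, k)
    codes = win.astype(np.int64) @ _powers(k)
    valid = win.max(axis=1) < 4
    return codes, valid


class GenomicIndex:
    """Exact k-mer index over the forward strand of a consensus library."""

    def __init__(self, library: Sequence[TERecord | SequenceRecord], k: int):
        self.k = k
        self.records = list(library)
        self.encoded = [encode(r.seq) for r in self.records]
        index: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for ti, vals in enumerate(self.encoded):
            codes, valid = _kmer_codes(vals, k)
            for pos in np.nonzero(valid)[0]:
                index[int(codes[pos])].append((ti, int(pos)))
        self.index = dict(index)
        self.code_arr = np.sort(np.fromiter(self.index.keys(), np.int64, len(self.index)))


def _extend(q: np.ndarray, t: np.ndarray, qpos: int, tpos: int, k: int):
    """Max-scoring ungapped window through the seed on one diagonal.

    Returns (score, q_start, q_end, t_start, t_end, matches, transitions,
    transversions, aligned_len) or None when the overlap is degenerate.
    """
    d = tpos - qpos
    qlo = max(0, -d)
    qhi = min(q.size, t.size - d)
    if qhi - qlo < k:
        return None
    a = q[qlo:qhi]
    b = t[qlo + d : qhi + d]
    eq = (a == b) & (a < 4)
    step = np.where(eq, 1, -1).astype(np.int32)
    prefix = np.concatenate(([0], np.cumsum(step)))
    s0 = qpos - qlo
    s1 = s0 + k
    j = s1 + int(np.argmax(prefix[s1:]))
    i = int(np.argmin(prefix[: s0 + 1]))
    score = int(prefix[j] - prefix[i])
    aw = a[i:j]
    bw = b[i:j]
    usable = (aw < 4) & (bw < 4)
    matches = int(np.count_nonzero((aw == bw) & usable))
    mm = usable & (aw != bw)
    transitions = int(np.count_nonzero(mm & ((aw ^ bw) == 2)))
    transversions = int(np.count_nonzero(mm)) - transitions
    aligned = matches + transitions + transversions
    if aligned == 0:
        return None
    return (score, qlo + i, qlo + j, qlo + i + d, qlo + j + d,
            matches, transitions, transversions, aligned)


def _member(codes: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Membership test against a sorted array (searchsorted beats isin here)."""
    if sorted_arr.size == 0:
        return np.zeros(codes.shape, dtype=bool)
    pos = np.searchsorted(sorted_arr, codes).clip(max=sorted_arr.size - 1)
    return sorted_arr[pos] == codes


def _candidate_rows(mat: np.ndarray, index: GenomicIndex) -> np.ndarray:
    """Row indices of a read matrix that contain at least one indexed seed."""
    k = index.k
    if mat.shape[1] < k:
        return np.empty(0, np.intp)
    win = sliding_window_view(mat, k, axis=1)
    codes = win.astype(np.int64) @ _powers(k)
    valid = win.max(axis=2) < 4
    member = _member(codes, index.code_arr) & valid
    return np.nonzero(member.any(axis=1))[0]


def _genomic_hits_one(read: SequenceRecord, index: GenomicIndex,
                      min_score: int) -> AlignmentHit | None:
    best_key = None
    best = None
    for strand in "+-":
        oriented = read.seq if strand == "+" else revcomp(read.seq)
        q = encode(oriented)
        codes, valid = _kmer_codes(q, index.k)
        if codes.size == 0:
            continue
        cand = np.nonzero(valid)[0]
        if cand.size:
            cand = cand[_member(codes[cand], index.code_arr)]
        seen: set[tuple[int, int]] = set()
        for qpos in cand:
            postings = index.index.get(int(codes[qpos]))
            if postings is None:
                continue
            for ti, tpos in postings:
                diag = (ti, tpos - int(qpos))
                if diag in seen:
                    continue
                seen.add(diag)
                res = _extend(q, index.encoded[ti], int(qpos), tpos, index.k)
                if res is None or res[0] < min_score:
                    continue
                score, qs, qe, ts, te, mat, tsn, tvn, alen = res
                key = (-score, index.records[ti].id, ts, strand)
                if best_key is None or key < best_key:
                    best_key = key
                    best = AlignmentHit(read.id, index.records[ti].id, strand,
                                        qs, qe, ts, te, alen, mat, tsn, tvn)
    return best


def _map_genomic(reads: Sequence[SequenceRecord], index: GenomicIndex,
                 min_score: int) -> list[AlignmentHit]:
    # Batch the seeding for same-length reads: background reads without any
    # indexed seed are rejected in one vectorized pass per strand.
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        by_len[len(r.seq)].append(i)
    hits: list[AlignmentHit] = []
    for length, idxs in by_len.items():
        if length < index.k:
            raise ValueError(
                f"seed length {index.k} exceeds read length {length}"
            )
        fwd = np.empty((len(idxs), length), dtype=np.uint8)
        for row, i in enumerate(idxs):
            fwd[row] = encode(reads[i].seq)
        rev = np.where(fwd < 4, 3 - fwd, 4)[:, ::-1]
        cand_rows = set(_candidate_rows(fwd, index).tolist())
        cand_rows.update(_candidate_rows(rev, index).tolist())
        for row in sorted(cand_rows):
            hit = _genomic_hits_one(reads[idxs[row]], index, min_score)
            if hit is not None:
                hits.append(hit)
    return hits


class SmallRNAIndex:
    """Concatenated library with per-segment-length exact-match postings."""

    SEP = 64  # spacer length between targets; spacer value 4 never matches

    def __init__(self, library: Sequence[TERecord | SequenceRecord]):
        self.records = list(library)
        parts = []
        offsets = []
        pos = 0
        for r in self.records:
            offsets.append(pos)
            parts.append(encode(r.seq))
            pos += len(r.seq)
            parts.append(np.full(self.SEP, 4, dtype=np.uint8))
            pos += self.SEP
        self.concat = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([len(r.seq) for r in self.records], dtype=np.int64)
        self._postings: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def postings(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        """(sorted codes, positions) for exact q-mer lookup via searchsorted."""
        if q not in self._postings:
            codes, valid = _kmer_codes(self.concat, q)
            pos = np.nonzero(valid)[0]
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            self._postings[q] = (codes[order], pos[order])
        return self._postings[q]

    def locate(self, gpos: int) -> int:
        """Target index containing global position ``gpos``."""
        return int(np.searchsorted(self.offsets, gpos, side="right") - 1)


def _smallrna_hits_one(read: SequenceRecord, index: SmallRNAIndex,
                       max_mismatch: int) -> list[AlignmentHit]:
    L = len(read.seq)
    nseg = max_mismatch + 1
    q = max(L // nseg, 1)
    codes_sorted, positions = index.postings(q)
    raw: list[tuple[int, str, int, int, np.ndarray, np.ndarray]] = []
    for strand in "+-":
        oriented = read.seq if strand == "+" else revcomp(read.seq)
        rv = encode(oriented)
        starts: set[int] = set()
        for si in range(nseg):
            off = si * q
            seg = rv[off : off + q]
            if seg.max() > 3:
                continue
            code = int(seg.astype(np.int64) @ _powers(q))
            lo = int(np.searchsorted(codes_sorted, code, side="left"))
            hi = int(np.searchsorted(codes_sorted, code, side="right"))
            for gpos in positions[lo:hi]:
                starts.add(int(gpos) - off)
        if not starts:
            continue
        arr = np.fromiter(starts, np.int64, len(starts))
        arr = arr[(arr >= 0) & (arr + L <= index.concat.size)]
        if arr.size == 0:
            continue
        windows = index.concat[arr[:, None] + np.arange(L)]
        mism = np.count_nonzero((windows != rv) | (windows > 3) | (rv > 3), axis=1)
        for gstart, mm in zip(arr[mism <= max_mismatch],
                              mism[mism <= max_mismatch]):
            ti = index.locate(int(gstart))
            tstart = int(gstart) - int(index.offsets[ti])
            if tstart + L > int(index.lengths[ti]):
                continue  # window straddles the spacer (cannot happen with mm filter)
            raw.append((int(mm), strand, ti, tstart, rv,
                        index.concat[gstart : gstart + L]))
    if not raw:
        return []
    best_mm = min(r[0] for r in raw)
    raw = [r for r in raw if r[0] == best_mm]
    # dedupe identical placements reached through several seeds/strand listings
    seen: set[tuple[str, int, int]] = set()
    hits: list[AlignmentHit] = []
    per_target: dict[int, int] = defaultdict(int)
    kept = []
    for mm, strand, ti, tstart, rv, tw in raw:
        key = (strand, ti, tstart)
        if key in seen:
            continue
        seen.add(key)
        kept.append((mm, strand, ti, tstart, rv, tw))
        per_target[ti] += 1
    n_targets = len(per_target)
    for mm, strand, ti, tstart, rv, tw in kept:
        usable = (rv < 4) & (tw < 4)
        matches = int(np.count_nonzero((rv == tw) & usable))
        diff = usable & (rv != tw)
        tsn = int(np.count_nonzero(diff & ((rv ^ tw) == 2)))
        tvn = int(np.count_nonzero(diff)) - tsn
        weight = 1.0 / (n_targets * per_target[ti])
        hits.append(
            AlignmentHit(read.id, index.records[ti].id, strand, 0, L,
                         tstart, tstart + L, matches + tsn + tvn,
                         matches, tsn, tvn, weight)
        )
    return hits


def map_reads(
    reads: Sequence[SequenceRecord],
    library: Sequence[TERecord | SequenceRecord],
    mode: str,
    max_mismatch: int = 3,
    seed_k: int | None = None,
    min_score: int = 20,
    index: GenomicIndex | SmallRNAIndex | None = None,
) -> list[AlignmentHit]:
    """Align reads against a consensus library.

    Parameters
    ----------
    mode
        ``"genomic"`` (local, single best hit per read) or ``"smallrna"``
        (end-to-end, all best-stratum hits, read length <= 50).
    max_mismatch
        Mismatch budget in smallrna mode (N columns count against it).
    seed_k
        Genomic seed length (default 12).  In smallrna mode seeds are the
        ``max_mismatch + 1`` pigeonhole segments of each read and
        ``seed_k`` is ignored.
    min_score
        Genomic mode only: minimum ``matches - mismatches`` for a hit to
        be reported.
    index
        Pre-built index to reuse across calls with the same library.
    """
    library = list(library)
    if not library:
        raise ValueError("library must be non-empty")
    if mode == "genomic":
        k = 12 if seed_k is None else seed_k
        shortest = min(len(r.seq) for r in reads) if reads else k
        if k > shortest:
            raise ValueError(f"seed_k {k} larger than shortest read ({shortest})")
        gidx = index if isinstance(index, GenomicIndex) else GenomicIndex(library, k)
        return _map_genomic(reads, gidx, min_score)
    if mode == "smallrna":
        too_long = [r.id for r in reads if len(r.seq) > 50]
        if too_long:
            raise ValueError(
                f"smallrna mode requires read length <= 50 (violated by {too_long[0]})"
            )
        sidx = index if isinstance(index, SmallRNAIndex) else SmallRNAIndex(library)
        out: list[AlignmentHit] = []
        for read in reads:
            out.extend(_smallrna_hits_one(read, sidx, max_mismatch))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def substitution_profile(
    hit: AlignmentHit,
    query: SequenceRecord,
    target: TERecord | SequenceRecord,
) -> tuple[float, float]:
    """Transition and transversion fractions (P, Q) of one hit.

    Recomputed from the sequences: transitions are A<->G and C<->T, all
    other substitutions are transversions, and columns containing N are
    excluded from the denominator.
    """
    oriented = query.seq if hit.strand == "+" else revcomp(query.seq)
    if not (0 <= hit.q_start < hit.q_end <= len(oriented)):
        raise ValueError("hit query interval outside query sequence")
    if not (0 <= hit.t_start < hit.t_end <= len(target.seq)):
        raise ValueError("hit target interval outside target sequence")
    if hit.q_end - hit.q_start != hit.t_end - hit.t_start:
        raise ValueError("query and target intervals differ in length (ungapped contract)")
    a = encode(oriented[hit.q_start : hit.q_end])
    b = encode(target.seq[hit.t_start : hit.t_end])
    usable = (a < 4) & (b < 4)
    n = int(np.count_nonzero(usable))
    if n == 0:
        raise ValueError("no usable (non-N) columns in alignment")
    diff = usable & (a != b)
    transitions = int(np.count_nonzero(diff & ((a ^ b) == 2)))
    transversions = int(np.count_nonzero(diff)) - transitions
    return transitions / n, transversions / n
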