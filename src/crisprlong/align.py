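"""Semi-global read-to-amplicon alignment with a large-gap mechanism.

Long amplicon reads differ from their reference by substitution errors plus
(at most a few) editing events, which can be kilobase-scale. Full dynamic
programming over multi-kb reads is unnecessary for this structure; instead
reads are aligned by chaining exact 15-mer anchors (unique in the
reference), aligning same-diagonal stretches positionally, and resolving
inter-segment junctions with a restricted model: paired substitution
columns flanking a single deletion and/or insertion block.

The junction model never aligns inserted read sequence against deleted
reference sequence, so a combined deletion+insertion is reported verbatim
as one deletion and one insertion - the representation the event signature
is defined on. Scoring within junctions: match +2, mismatch -4, gap of
length L costs 6 + L. Read ends that fail to align (e.g. reads truncated
inside a repeat) are soft-clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ReferenceLocus
from .events import DELETION, INSERTION, CompositeEvent, EditEvent

K = 15
MATCH = 2.0
MISMATCH = -4.0
GAP_OPEN = 6.0
GAP_EXT = 1.0
MAX_ANCHOR_GAP = 120      # read-coordinate gap tolerated inside one segment
FAST_PATH_MISMATCH = 0.05

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_POW = (4 ** np.arange(K - 1, -1, -1)).astype(np.int64)
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid) for every k-mer start; valid = no N in the window."""
    if codes.size < K:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = sliding_window_view(codes, K)
    hashes = win.astype(np.int64) @ _POW
    valid = ~(win == 4).any(axis=1)
    return hashes, valid


@lru_cache(maxsize=64)
def _ref_index(locus: ReferenceLocus) -> tuple[np.ndarray, np.ndarray]:
    """Sorted hashes of k-mers unique in the locus, with their positions."""
    hashes, valid = _kmer_hashes(_codes(locus.sequence))
    pos = np.nonzero(valid)[0]
    h = hashes[pos]
    uh, first, counts = np.unique(h, return_index=True, return_counts=True)
    keep = counts == 1
    return uh[keep], pos[first[keep]]


@dataclass(frozen=True)
class ReadAlignment:
    """Alignment of one read against its amplicon reference."""

    read_id: str
    locus: str
    ref_start: int
    ref_end: int
    events: tuple[EditEvent, ...]
    n_substitutions: int
    aligned_read_bases: int
    read_length: int
    clip_left: int
    clip_right: int

    @property
    def aligned_fraction(self) -> float:
        if self.read_length == 0:
            return 0.0
        return self.aligned_read_bases / self.read_length


def _column_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a == b, MATCH, MISMATCH)


def _resolve_junction(read_gap: np.ndarray, ref_gap: np.ndarray, ref_off: int
                      ) -> tuple[list[EditEvent], int, int]:
    """Best (p, q) split of a junction into flanking substitution columns
    plus one insertion and/or one deletion block.

    Returns (events, n_substitutions, n_aligned_read_bases)."""
    gr, gf = len(read_gap), len(ref_gap)
    lim = min(gr, gf)
    if lim == 0:
        best_p = best_q = 0
    else:
        pref = np.concatenate(([0.0], np.cumsum(
            _column_scores(read_gap[:lim], ref_gap[:lim]))))
        suf = np.concatenate(([0.0], np.cumsum(
            _column_scores(read_gap[::-1][:lim], ref_gap[::-1][:lim]))))
        best_score, best_p, best_q = -np.inf, 0, 0
        for p in range(lim + 1):
            q = np.arange(lim + 1 - p)
            mid_r = gr - p - q
            mid_f = gf - p - q
            gap_r = np.where(mid_r > 0, -(GAP_OPEN + GAP_EXT * mid_r), 0.0)
            gap_f = np.where(mid_f > 0, -(GAP_OPEN + GAP_EXT * mid_f), 0.0)
            tot = pref[p] + suf[q] + gap_r + gap_f
            j = int(np.argmax(tot))
            if tot[j] > best_score:
                best_score, best_p, best_q = float(tot[j]), p, j
    events: list[EditEvent] = []
    mid_f = gf - best_p - best_q
    mid_r = gr - best_p - best_q
    junction = ref_off + best_p
    if mid_f > 0:
        events.append(EditEvent(DELETION, junction, junction + mid_f))
    if mid_r > 0:
        seq = _DECODE[read_gap[best_p:gr - best_q]].tobytes().decode()
        events.append(EditEvent(INSERTION, junction, junction, seq))
    n_sub = 0
    if best_p:
        n_sub += int((read_gap[:best_p] != ref_gap[:best_p]).sum())
    if best_q:
        n_sub += int((read_gap[gr - best_q:] != ref_gap[gf - best_q:]).sum())
    return events, n_sub, best_p + best_q + mid_r


def _best_prefix(cols: np.ndarray) -> int:
    """Length of the prefix maximizing cumulative column score (soft clip)."""
    if cols.size == 0:
        return 0
    cum = np.cumsum(cols)
    best = int(np.argmax(cum))
    return best + 1 if cum[best] > 0 else 0


def _segments(anchors_i: np.ndarray, anchors_j: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Group anchors into same-diagonal segments: (i_start, i_end, diag, n)."""
    diag = anchors_j - anchors_i
    brk = np.nonzero((np.diff(diag) != 0) |
                     (np.diff(anchors_i) > MAX_ANCHOR_GAP))[0] + 1
    segs = []
    for chunk in np.split(np.arange(anchors_i.size), brk):
        i0, i1 = int(anchors_i[chunk[0]]), int(anchors_i[chunk[-1]]) + K
        segs.append((i0, i1, int(diag[chunk[0]]), len(chunk)))
    # merge adjacent same-diagonal segments (split only by anchor gaps)
    merged = [segs[0]]
    for s in segs[1:]:
        last = merged[-1]
        if s[2] == last[2]:
            merged[-1] = (last[0], s[1], last[2], last[3] + s[3])
        else:
            merged.append(s)
    return [s for s in merged if s[3] >= 2] or merged[:1]


def _chain(segs: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Best colinear subset (i and j both increasing), by anchor weight."""
    n = len(segs)
    if n <= 1:
        return segs
    best = list(segs[i][3] for i in range(n))
    prev = [-1] * n
    for i in range(n):
        for h in range(i):
            if (segs[h][1] <= segs[i][0] + K and
                    segs[h][1] + segs[h][2] <= segs[i][0] + segs[i][2] + K and
                    best[h] + segs[i][3] > best[i]):
                best[i] = best[h] + segs[i][3]
                prev[i] = h
    end = int(np.argmax(best))
    out = []
    while end != -1:
        out.append(segs[end])
        end = prev[end]
    return out[::-1]


def align_to_amplicon(read: str, locus: ReferenceLocus,
                      read_id: str = "read") -> ReadAlignment:
    """Align one read to its amplicon reference.

    Deterministic; reads whose anchors cannot be chained come back with zero
    aligned bases (classified unassigned downstream).
    """
    ref = locus.sequence
    rc = _codes(read)
    fc = _codes(ref)
    # fast path: equal length, nearly identical -> substitution-only
    if len(read) == len(ref):
        mism = int((rc != fc).sum())
        if mism <= FAST_PATH_MISMATCH * len(ref):
            return ReadAlignment(read_id, locus.name, 0, len(ref), (),
                                 mism, len(read), len(read), 0, 0)
    uh, upos = _ref_index(locus)
    rh, rvalid = _kmer_hashes(rc)
    ridx = np.nonzero(rvalid)[0]
    h = rh[ridx]
    loc = np.searchsorted(uh, h)
    loc_c = np.minimum(loc, len(uh) - 1) if len(uh) else loc
    hit = np.zeros(h.size, dtype=bool) if not len(uh) else (uh[loc_c] == h)
    ai = ridx[hit]
    aj = upos[loc_c[hit]]
    if ai.size == 0:
        return ReadAlignment(read_id, locus.name, 0, 0, (), 0, 0,
                             len(read), 0, len(read))
    segs = _chain(_segments(ai, aj))
    events: list[EditEvent] = []
    n_sub = 0
    aligned = 0
    # head
    i0, _, d0, _ = segs[0]
    j0 = i0 + d0
    head_len = min(i0, j0)
    clip_left = i0 - head_len
    if head_len:
        cols = _column_scores(rc[i0 - head_len:i0], fc[j0 - head_len:j0])
        keep = _best_prefix(cols[::-1])
        clip_left = i0 - keep
        if keep:
            n_sub += int((rc[i0 - keep:i0] != fc[j0 - keep:j0]).sum())
            aligned += keep
    ref_start = (i0 + d0) - (i0 - clip_left)
    # segments and junctions
    prev_i_end, prev_j_end = i0, j0
    for idx, (s_i0, s_i1, d, _n) in enumerate(segs):
        s_j0, s_j1 = s_i0 + d, s_i1 + d
        if idx > 0:
            gr, gf = s_i0 - prev_i_end, s_j0 - prev_j_end
            trim = max(-gr, -gf, 0)
            s_i0 += trim
            s_j0 += trim
            gr, gf = s_i0 - prev_i_end, s_j0 - prev_j_end
            ev, js, ja = _resolve_junction(
                rc[prev_i_end:s_i0], fc[prev_j_end:s_j0], prev_j_end)
            events.extend(ev)
            n_sub += js
            aligned += ja
        seg_len = s_i1 - s_i0
        n_sub += int((rc[s_i0:s_i1] != fc[s_j0:s_j1]).sum())
        aligned += seg_len
        prev_i_end, prev_j_end = s_i1, s_j1
    # tail
    tail_read = len(read) - prev_i_end
    tail_room = len(ref) - prev_j_end
    tail_len = min(tail_read, tail_room)
    keep = 0
    if tail_len:
        cols = _column_scores(rc[prev_i_end:prev_i_end + tail_len],
                              fc[prev_j_end:prev_j_end + tail_len])
        keep = _best_prefix(cols)
        if keep:
            n_sub += int((rc[prev_i_end:prev_i_end + keep]
                          != fc[prev_j_end:prev_j_end + keep]).sum())
            aligned += keep
    clip_right = tail_read - keep
    ref_end = prev_j_end + keep
    # events stay in raw junction form; left-alignment is applied jointly
    # at the composite level so delins sub-events cannot be shifted apart
    events = sorted(events)
    return ReadAlignment(read_id, locus.name, ref_start, ref_end,
                         tuple(events), n_sub, aligned, len(read),
                         clip_left, clip_right)


def extract_events(aln: ReadAlignment, cut_position: int,
                   attribution_window: int = 25) -> CompositeEvent | None:
    """Indels attributable to Cas9 activity at the cut.

    An indel qualifies when its reference interval (insertion point for
    insertions) intersects ``[cut - w, cut + w)``; a deletion spanning the
    cut qualifies regardless of its endpoints (such deletions always
    intersect the window). Substitutions never qualify. Returns ``None``
    when no indel qualifies.
    """
    lo, hi = cut_position - attribution_window, cut_position + attribution_window
    picked = []
    for e in aln.events:
        if e.kind == DELETION:
            if e.start < hi and e.end > lo:
                picked.append(e)
        elif lo <= e.start < hi:
            picked.append(e)
    return CompositeEvent(tuple(picked)) if picked else None
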