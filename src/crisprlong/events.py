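"""Editing-outcome events: indels, composite events, normalization.

An editing outcome on one read is a :class:`CompositeEvent`: an ordered list
of deletions and insertions near the cleavage site. A combined
deletion+insertion (delins) is classified as a deletion or an insertion by
whichever sub-event involves more nucleotides; the reported size is signed
(negative for deletions). Sub-events are left-aligned (VCF-style) so that
the text signature is a stable allele identity across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

from .core import ReferenceLocus

DELETION = "deletion"
INSERTION = "insertion"


@total_ordering
@dataclass(frozen=True)
class EditEvent:
    """One indel sub-event in reference coordinates.

    Deletions remove the half-open reference interval ``[start, end)``.
    Insertions add ``seq`` before reference position ``start`` (``end ==
    start``).
    """

    kind: str
    start: int
    end: int
    seq: str = ""

    def __post_init__(self):
        if self.kind == DELETION:
            if self.end - self.start < 1:
                raise ValueError("deletion length must be >= 1")
            if self.seq:
                raise ValueError("deletion carries no inserted sequence")
        elif self.kind == INSERTION:
            if self.end != self.start:
                raise ValueError("insertion interval must be empty")
            if len(self.seq) < 1:
                raise ValueError("inserted sequence must be >= 1 nt")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start if self.kind == DELETION else len(self.seq)

    def _key(self):
        return (self.start, self.end, self.kind, self.seq)

    def __lt__(self, other: "EditEvent") -> bool:
        return self._key() < other._key()


def normalize_event(event: EditEvent, locus: ReferenceLocus) -> EditEvent:
    """Shift an indel to its leftmost equivalent position (VCF left-align).

    A deletion of ``[s, e)`` may shift one base left whenever the base before
    it equals the last deleted base; an insertion shifts left whenever the
    base before the insertion point equals the last inserted base (the
    inserted sequence rotates accordingly). Idempotent by construction.
    """
    ref = locus.sequence
    if event.kind == DELETION:
        s, e = event.start, event.end
        while s > 0 and ref[s - 1] == ref[e - 1]:
            s -= 1
            e -= 1
        return EditEvent(DELETION, s, e) if s != event.start else event
    s = event.start
    seq = event.seq
    moved = False
    while s > 0 and ref[s - 1] == seq[-1]:
        seq = ref[s - 1] + seq[:-1]
        s -= 1
        moved = True
    return EditEvent(INSERTION, s, s, seq) if moved else event


@dataclass(frozen=True)
class CompositeEvent:
    """A per-read editing outcome: one or more indel sub-events.

    ``event_class`` follows the larger-sub-event rule: deletion when total
    deleted nt >= total inserted nt (ties break to deletion), insertion
    otherwise. ``reported_size`` is -total_del for deletions, +total_ins for
    insertions.
    """

    sub_events: tuple[EditEvent, ...]

    def __post_init__(self):
        if not self.sub_events:
            raise ValueError("composite event must contain >= 1 sub-event")
        object.__setattr__(self, "sub_events", tuple(sorted(self.sub_events)))

    @property
    def total_del(self) -> int:
        return sum(e.length for e in self.sub_events if e.kind == DELETION)

    @property
    def total_ins(self) -> int:
        return sum(e.length for e in self.sub_events if e.kind == INSERTION)

    @property
    def event_class(self) -> str:
        return DELETION if self.total_del >= self.total_ins else INSERTION

    @property
    def reported_size(self) -> int:
        if self.event_class == DELETION:
            return -self.total_del
        return self.total_ins

    def normalized(self, locus: ReferenceLocus) -> "CompositeEvent":
        """Left-align sub-events jointly.

        Sub-events are shifted independently unless shifting would make
        them overlap (e.g. a delins whose deletion would slide across the
        shared junction): in that case the composite keeps its original
        junction form, which both the generator and the aligner emit with
        the insertion at the deletion start.
        """
        shifted = tuple(normalize_event(e, locus) for e in self.sub_events)
        if len(shifted) > 1:
            spans = sorted((e.start, e.end) for e in shifted)
            for (_, a_end), (b_start, _) in zip(spans, spans[1:]):
                if b_start < a_end:
                    return self
        return CompositeEvent(shifted)

    # Insertions longer than this are identified by position+length rather
    # than exact sequence: at CCS-grade error rates the inserted bases of a
    # long insertion almost always carry at least one substitution error,
    # so exact-sequence identity would split one allele into many.
    INS_EXACT_MAX = 12

    def signature(self, locus: ReferenceLocus) -> str:
        """Canonical text key after left alignment; allele identity."""
        parts = []
        for e in self.normalized(locus).sub_events:
            if e.kind == DELETION:
                ref = locus.sequence[e.start:e.end]
                parts.append(f"{locus.name}:{e.start}:{ref}>-")
            elif len(e.seq) <= self.INS_EXACT_MAX:
                parts.append(f"{locus.name}:{e.start}:->{e.seq}")
            else:
                parts.append(f"{locus.name}:{e.start}:-><INS:{len(e.seq)}>")
        return ";".join(parts)

    def apply(self, sequence: str, offset: int = 0) -> str:
        """Apply the sub-events to a sequence (coordinates shifted by -offset)."""
        out = sequence
        for e in sorted(self.sub_events, reverse=True):
            s, t = e.start - offset, e.end - offset
            if not (0 <= s <= t <= len(out)):
                raise ValueError(f"event {e} outside sequence of length {len(out)}")
            out = out[:s] + e.seq + out[t:]
        return out


WT_SIGNATURE = "WT"


def classify_composite(c: CompositeEvent) -> CompositeEvent:
    """Validate and return a composite with class/size defined.

    The class and reported size are derived properties; this entry point
    exists so callers can treat classification as an explicit step and get a
    clear error on an empty composite.
    """
    if not isinstance(c, CompositeEvent):
        raise TypeError("expected a CompositeEvent")
    return c
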