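"""Per-read outcome classification and per-sample event tables.

A read is *edited* when it carries at least one indel whose footprint
intersects the attribution window around the cut; reads with substitutions
only are *snv_only* and count as unedited (efficiency is indel-based).
Reads aligning poorly (<50% of bases) or ending inside the attribution
window (e.g. molecules truncated at a repeat during amplification) are
*unassigned* and excluded from all denominators; their fraction is a QC
metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .align import align_to_amplicon, extract_events
from .core import ReferenceLocus
from .events import CompositeEvent

WILD_TYPE = "wild_type"
SNV_ONLY = "snv_only"
EDITED = "edited"
CONTROL_ARTIFACT = "control_artifact"
UNASSIGNED = "unassigned"

UNEDITED_ROW = "unedited"

MIN_ALIGNED_FRACTION = 0.5
ATTRIBUTION_WINDOW = 25


@dataclass(frozen=True)
class ReadOutcome:
    read_id: str
    category: str
    composite: CompositeEvent | None = None
    signature: str = ""


def classify_read(read_id: str, sequence: str, locus: ReferenceLocus,
                  attribution_window: int = ATTRIBUTION_WINDOW) -> ReadOutcome:
    aln = align_to_amplicon(sequence, locus, read_id)
    if aln.aligned_fraction < MIN_ALIGNED_FRACTION:
        return ReadOutcome(read_id, UNASSIGNED)
    cut = locus.cut_position
    lo, hi = cut - attribution_window, cut + attribution_window
    if aln.ref_start > lo or aln.ref_end < hi:
        return ReadOutcome(read_id, UNASSIGNED)
    composite = extract_events(aln, cut, attribution_window)
    if composite is not None:
        norm = composite.normalized(locus)
        return ReadOutcome(read_id, EDITED, norm, norm.signature(locus))
    if aln.n_substitutions > 0:
        return ReadOutcome(read_id, SNV_ONLY)
    return ReadOutcome(read_id, WILD_TYPE)


def classify_reads(reads: list[tuple[str, str]], locus: ReferenceLocus,
                   attribution_window: int = ATTRIBUTION_WINDOW
                   ) -> list[ReadOutcome]:
    """Classify a read set; identical sequences share one alignment."""
    memo: dict[str, ReadOutcome] = {}
    out = []
    for read_id, seq in reads:
        hit = memo.get(seq)
        if hit is None:
            hit = classify_read(read_id, seq, locus, attribution_window)
            memo[seq] = hit
        out.append(replace(hit, read_id=read_id))
    return out


@dataclass
class EventTable:
    """Per-sample, per-site aggregation of read outcomes.

    ``df`` has one row per event signature plus one pooled ``unedited`` row
    (wild-type and snv-only reads), with columns signature, count,
    frequency, reported_size, event_class, control_flag. Frequencies are
    over assigned reads and sum to 1.
    """

    sample_id: str
    site: str
    df: pd.DataFrame
    total_assigned: int
    n_unassigned: int = 0
    composites: dict[str, CompositeEvent] = field(default_factory=dict)
    collapsed: dict[str, str] = field(default_factory=dict)

    COLUMNS = ["signature", "count", "frequency", "reported_size",
               "event_class", "control_flag"]

    def copy(self) -> "EventTable":
        return EventTable(self.sample_id, self.site, self.df.copy(),
                          self.total_assigned, self.n_unassigned,
                          dict(self.composites))

    @property
    def unassigned_fraction(self) -> float:
        denom = self.total_assigned + self.n_unassigned
        return self.n_unassigned / denom if denom else 0.0

    def event_rows(self, include_flagged: bool = True) -> pd.DataFrame:
        rows = self.df[self.df["signature"] != UNEDITED_ROW]
        if not include_flagged:
            rows = rows[~rows["control_flag"]]
        return rows


def _event_shape(c: CompositeEvent) -> tuple:
    """Kind pattern plus per-event (position, length) for scatter matching."""
    return tuple((e.kind, e.start, e.length) for e in c.sub_events)


def _shape_distance(a: tuple, b: tuple) -> int | None:
    """Total position+length perturbation between two composites of the
    same kind pattern; None when patterns differ."""
    if len(a) != len(b) or any(x[0] != y[0] for x, y in zip(a, b)):
        return None
    return sum(abs(x[1] - y[1]) + abs(x[2] - y[2]) for x, y in zip(a, b))


# A read whose junction is hit by a sequencing error can resolve to a
# slightly perturbed event (shifted by a base, one base longer/shorter, or
# with a corrupted inserted base). Such scatter is collapsed into a
# dominant near-identical allele; genuine co-occurring alleles are
# protected by the count-ratio requirement.
COLLAPSE_MAX_DISTANCE = 4
COLLAPSE_MIN_RATIO = 20


def _collapse_scatter(counts: dict[str, int],
                      composites: dict[str, CompositeEvent],
                      total: int) -> dict[str, str]:
    """Map scatter signatures onto their dominant allele; '' stays put."""
    order = sorted(counts, key=lambda s: (-counts[s], s))
    mapping: dict[str, str] = {}
    shapes = {s: _event_shape(composites[s]) for s in order}
    low_cut = max(3, int(0.005 * total))
    for sig in reversed(order):
        if counts[sig] > low_cut:
            continue
        for target in order:
            if target == sig or target in mapping:
                continue
            if counts[target] < max(COLLAPSE_MIN_RATIO,
                                    COLLAPSE_MIN_RATIO * counts[sig]):
                break  # rows sorted by count: no later row is bigger
            d = _shape_distance(shapes[sig], shapes[target])
            if d is not None and d <= COLLAPSE_MAX_DISTANCE:
                mapping[sig] = target
                break
    return mapping


def tabulate(outcomes: list[ReadOutcome], sample_id: str,
             locus: ReferenceLocus, collapse: bool = True) -> EventTable:
    """Group outcomes by signature into an event table.

    Rows are ordered by descending count, then signature, with the pooled
    unedited row participating in the same ordering; the layout is fully
    deterministic for a given outcome list. With ``collapse`` (default),
    rare signatures that differ from a far more frequent allele only by a
    small positional/length perturbation are merged into it (sequencing
    errors at event junctions produce exactly this scatter).
    """
    counts: dict[str, int] = {}
    composites: dict[str, CompositeEvent] = {}
    n_unedited = 0
    n_unassigned = 0
    for o in outcomes:
        if o.category == UNASSIGNED:
            n_unassigned += 1
        elif o.category == EDITED:
            counts[o.signature] = counts.get(o.signature, 0) + 1
            composites.setdefault(o.signature, o.composite)
        else:
            n_unedited += 1
    total = sum(counts.values()) + n_unedited
    collapsed: dict[str, str] = {}
    if collapse and counts:
        collapsed = _collapse_scatter(counts, composites, total)
        for src, dst in collapsed.items():
            counts[dst] += counts.pop(src)
            composites.pop(src)
    rows = []
    if n_unedited:
        rows.append((UNEDITED_ROW, n_unedited, 0, "", False))
    for sig, cnt in counts.items():
        c = composites[sig]
        rows.append((sig, cnt, c.reported_size, c.event_class, False))
    rows.sort(key=lambda r: (-r[1], r[0]))
    df = pd.DataFrame(rows, columns=["signature", "count", "reported_size",
                                     "event_class", "control_flag"])
    df["frequency"] = df["count"] / total if total else 0.0
    df = df[EventTable.COLUMNS]
    table = EventTable(sample_id, locus.name, df, total, n_unassigned, composites)
    table.collapsed = collapsed
    return table
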