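"""Control-based filtering and per-sample editing metrics.

Two control rules guard against germline variation and systematic
artifacts: (i) a *site* is excluded when the uninjected-control samples
show at least 0.5% indel reads there; (ii) any event *signature* observed
in a control sample is flagged and its reads counted as unedited
everywhere. Editing efficiency is the fraction of assigned reads carrying
an (unflagged) indel at the cut; structural variants are events with
|reported size| >= 50 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .classify import UNEDITED_ROW, EventTable

SITE_FILTER_THRESHOLD = 0.005
SV_MIN = 50


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    site: str
    editing_efficiency: float
    sv_fraction_of_edits: float          # NaN when no edited reads
    n_distinct_alleles: int
    size_points: tuple[tuple[int, float], ...]
    unassigned_fraction: float = 0.0


def control_indel_frequency(control: EventTable) -> float:
    """Fraction of assigned control reads carrying any indel event."""
    if control.total_assigned == 0:
        return 0.0
    return control.event_rows()["count"].sum() / control.total_assigned


def filter_sites_by_control(site_control_freqs: dict[str, float | None],
                            threshold: float = SITE_FILTER_THRESHOLD
                            ) -> tuple[set[str], set[str]]:
    """Sites to retain; a site is removed iff its control indel frequency is
    at least the threshold (inclusive). Sites with no control data are
    retained but returned in the warning set."""
    retained, warned = set(), set()
    for site, freq in site_control_freqs.items():
        if freq is None or (isinstance(freq, float) and math.isnan(freq)):
            retained.add(site)
            warned.add(site)
        elif freq < threshold:
            retained.add(site)
    return retained, warned


def flag_control_events(table: EventTable, control: EventTable) -> EventTable:
    """Flag every signature present in the control table (>=1 read).

    Flagged signatures are considered unedited in all downstream metrics;
    their rows stay in the table for transparency.
    """
    if table.site != control.site:
        raise ValueError("tables must share a site")
    control_sigs = set(control.event_rows()["signature"])
    out = table.copy()
    out.df["control_flag"] = out.df["signature"].isin(control_sigs) & \
        (out.df["signature"] != UNEDITED_ROW)
    return out


def editing_efficiency(table: EventTable) -> float:
    """(edited, non-flagged reads) / (assigned reads); NaN when no reads."""
    if table.total_assigned == 0:
        return float("nan")
    edited = table.event_rows(include_flagged=False)["count"].sum()
    return edited / table.total_assigned


def sv_metrics(table: EventTable, sv_min: int = SV_MIN
               ) -> tuple[float, list[tuple[int, float]]]:
    """SV share among edited reads, plus per-signature (size, frequency)
    points (deletions negative, insertions positive)."""
    rows = table.event_rows(include_flagged=False)
    edited = rows["count"].sum()
    sizes = [(int(s), float(f)) for s, f in
             zip(rows["reported_size"], rows["frequency"])]
    if edited == 0:
        return float("nan"), sizes
    sv_reads = rows.loc[rows["reported_size"].abs() >= sv_min, "count"].sum()
    return sv_reads / edited, sizes


def summarize_sample(table: EventTable, sv_min: int = SV_MIN) -> SampleSummary:
    eff = editing_efficiency(table)
    sv_frac, size_points = sv_metrics(table, sv_min)
    n_alleles = len(table.event_rows(include_flagged=False))
    return SampleSummary(table.sample_id, table.site, eff,
                         sv_frac, n_alleles, tuple(size_points),
                         table.unassigned_fraction)


def size_distribution(tables: list[EventTable], sv_min: int = SV_MIN) -> pd.DataFrame:
    """Long-form size/frequency table across samples (plot-ready)."""
    rows = []
    for t in tables:
        for size, freq in sv_metrics(t, sv_min)[1]:
            rows.append((t.sample_id, t.site, size, freq))
    return pd.DataFrame(rows, columns=["sample", "site", "size", "frequency"])
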