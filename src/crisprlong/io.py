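"""File formats: FASTA/FASTQ, event tables, termini (TSV/SAM), BED, VCF,
depth tracks and pedigree sheets.

Every table this package writes declares its coordinate convention in a
header comment (# coords=0-based,half-open). Event-table and VCF output
round-trip losslessly through the matching readers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import EventTable
from .core import ReferenceLocus
from .events import DELETION, INSERTION, CompositeEvent, EditEvent

COORD_COMMENT = "# coords=0-based,half-open"


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_fasta(path, records: list[tuple[str, str]]) -> None:
    SeqIO.write((SeqRecord(Seq(s), id=n, description="") for n, s in records),
                str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path, reads: list[tuple[str, str]], quality: int = 30) -> None:
    """Phred+33 FASTQ with a uniform placeholder quality."""
    qc = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qc * len(seq)}\n")


def read_reads(path) -> list[tuple[str, str]]:
    """Reads from FASTQ or FASTA (by extension)."""
    fmt = "fastq" if str(path).endswith((".fq", ".fastq")) else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# event tables

def write_event_table(table: EventTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{COORD_COMMENT}\n")
        fh.write(f"# sample_id={table.sample_id}\n")
        fh.write(f"# site={table.site}\n")
        fh.write(f"# total_assigned={table.total_assigned}\n")
        fh.write(f"# n_unassigned={table.n_unassigned}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def read_event_table(path) -> EventTable:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" in line:
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t",
                     dtype={"signature": str, "event_class": str},
                     keep_default_na=False,
                     converters={"control_flag": lambda v: v == "True"})
    df["count"] = df["count"].astype(int)
    df["reported_size"] = df["reported_size"].astype(int)
    df["frequency"] = df["frequency"].astype(float)
    return EventTable(meta.get("sample_id", ""), meta.get("site", ""),
                      df[EventTable.COLUMNS],
                      int(meta.get("total_assigned", 0)),
                      int(meta.get("n_unassigned", 0)))


# ---------------------------------------------------------------------------
# termini records

def write_termini_tsv(records: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{COORD_COMMENT}\n")
        records.to_csv(fh, sep="\t", index=False)


def read_termini_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"locus": str, "coordinate": int, "orientation": str})
    missing = {"locus", "coordinate", "orientation"} - set(df.columns)
    if missing:
        raise ValueError(f"termini TSV missing columns: {sorted(missing)}")
    return df


def read_termini_sam(path) -> pd.DataFrame:
    """Read termini from alignments: each aligned record contributes its
    reference start (orientation '+') and end ('-') as termini."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rows.append((rec.reference_name, rec.reference_start, "+"))
            rows.append((rec.reference_name, rec.reference_end, "-"))
    return pd.DataFrame(rows, columns=["locus", "coordinate", "orientation"])


# ---------------------------------------------------------------------------
# BED

def write_bed(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{COORD_COMMENT}\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][:len(df.columns)]
    return df


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=COMPOSITE,Number=1,Type=String,Description='
    '"Composite event ID grouping delins sub-events">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed event length">',
]


def write_events_vcf(path, events: list[tuple[str, str, CompositeEvent]],
                     loci: dict[str, ReferenceLocus]) -> None:
    """One record per sub-event, left-aligned with an anchor base, grouped
    by a COMPOSITE id. ``events`` holds (locus_name, composite_id, event);
    records are coordinate-sorted per contig."""
    rows = []
    for locus_name, comp_id, comp in events:
        for e in comp.sub_events:
            ref_seq = loci[locus_name].sequence
            if e.kind == DELETION:
                if e.start > 0:
                    pos, ref, alt = e.start - 1, ref_seq[e.start - 1:e.end], ref_seq[e.start - 1]
                else:
                    pos, ref, alt = 0, ref_seq[:e.end + 1], ref_seq[e.end]
                svlen = -(e.end - e.start)
            else:
                if e.start > 0:
                    pos, ref = e.start - 1, ref_seq[e.start - 1]
                    alt = ref + e.seq
                else:
                    pos, ref = 0, ref_seq[0]
                    alt = e.seq + ref
                svlen = len(e.seq)
            rows.append((locus_name, pos, ref, alt, comp_id, svlen))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for line in VCF_HEADER:
            fh.write(line + "\n")
        for name in sorted({r[0] for r in rows} | set(loci)):
            fh.write(f"##contig=<ID={name},length={len(loci[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, cid, svlen in rows:
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"COMPOSITE={cid};SVLEN={svlen}\n")


def read_events_vcf(path) -> list[tuple[str, str, EditEvent]]:
    """(chrom, composite_id, event) triples from a VCF this package wrote."""
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, *rest = line.split("\t")
        info = rest[2]
        cid = [f for f in info.split(";") if f.startswith("COMPOSITE=")][0][10:]
        p = int(pos) - 1
        if len(ref) > len(alt):          # deletion, anchored
            if ref.startswith(alt):
                ev = EditEvent(DELETION, p + len(alt), p + len(ref))
            else:                        # start-of-contig anchor after the event
                ev = EditEvent(DELETION, p, p + len(ref) - len(alt))
        else:                            # insertion, anchored
            if alt.startswith(ref):
                ev = EditEvent(INSERTION, p + len(ref), p + len(ref), alt[len(ref):])
            else:
                ev = EditEvent(INSERTION, p, p, alt[:len(alt) - len(ref)])
        out.append((chrom, cid, ev))
    return out


# ---------------------------------------------------------------------------
# depth tracks and pedigree

def write_depth_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{COORD_COMMENT}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)


def read_depth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


PEDIGREE_COLUMNS = ["sample_id", "generation", "stage", "type", "founder_pair"]


def write_pedigree(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree sheet missing columns: {sorted(missing)}")
    return df
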