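"""Cross-generation analysis: F1 genotype calls, founder germline
mosaicism from transmitted alleles, sibling validation and allelic-dropout
reconciliation.

F1 individuals carry exactly two alleles per locus, so allele frequencies
near 0.5 mark heterozygotes; an allele is reported when it reaches 20% of
the reads (inclusive). When a single non-wild-type event holds more than
98% of the reads the individual is either homozygous or suffers allelic
dropout; classification of amplification-free (WGS-mode) reads decides
which. A founder pair transmitting more than four unique alleles to its
offspring proves germline mosaicism (two parents carry at most four
alleles at one locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .classify import UNEDITED_ROW, EventTable
from .events import WT_SIGNATURE


@dataclass(frozen=True)
class Thresholds:
    het_threshold: float = 0.20
    hom_threshold: float = 0.98
    f0_moderate_offtarget: float = 0.10
    pool_presence_min_freq: float = 0.01
    pool_presence_min_reads: int = 5
    min_unamplified_depth: int = 10

    def __post_init__(self):
        if not 0 < self.het_threshold < self.hom_threshold < 1:
            raise ValueError("need 0 < het_threshold < hom_threshold < 1")


class GenotypeInconsistency(ValueError):
    """More than two alleles above the het threshold in one individual."""


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    site: str
    alleles: tuple[tuple[str, float], ...]   # (signature, frequency)
    zygosity: str      # hom_ref | het | hom_alt | compound_het | suspect_dropout | unresolved
    dropout_flag: bool = False
    recovered_allele: str = ""
    resolution: str = ""                     # '', 'het_recovered', 'hom_confirmed', 'unresolved'


@dataclass(frozen=True)
class TransmissionReport:
    founder_pair: str
    transmitted: tuple[str, ...]             # union of present alleles
    presence: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unique_allele_count: int = 0
    germline_mosaic_flag: bool = False


def _allele_frequencies(table: EventTable) -> list[tuple[str, float]]:
    """Signature frequencies with control-flagged events folded into WT."""
    wt = 0.0
    out = []
    for sig, freq, flag in zip(table.df["signature"], table.df["frequency"],
                               table.df["control_flag"]):
        if sig == UNEDITED_ROW or flag:
            wt += freq
        else:
            out.append((sig, float(freq)))
    if wt > 0:
        out.append((WT_SIGNATURE, wt))
    out.sort(key=lambda x: (-x[1], x[0]))
    return out


def call_individual_genotype(table: EventTable, th: Thresholds = Thresholds()
                             ) -> GenotypeCall:
    """Genotype one F1 (or later) individual from its event table.

    Alleles at frequency >= het_threshold are reported (wild type counts as
    an allele). A single allele above hom_threshold yields a homozygous
    call, with the dropout flag raised when that allele is an editing
    event; a single allele below hom_threshold is ambiguous
    (suspect_dropout).
    """
    freqs = _allele_frequencies(table)
    called = [(s, f) for s, f in freqs if f >= th.het_threshold]
    if len(called) > 2:
        raise GenotypeInconsistency(
            f"{table.sample_id}@{table.site}: {len(called)} alleles above "
            f"{th.het_threshold:.2f}; individuals carry at most 2")
    if not called:
        return GenotypeCall(table.sample_id, table.site, (), "unresolved")
    if len(called) == 2:
        non_wt = [s for s, _ in called if s != WT_SIGNATURE]
        zyg = "compound_het" if len(non_wt) == 2 else "het"
        return GenotypeCall(table.sample_id, table.site, tuple(called), zyg)
    sig, freq = called[0]
    if freq > th.hom_threshold:
        if sig == WT_SIGNATURE:
            return GenotypeCall(table.sample_id, table.site, tuple(called), "hom_ref")
        return GenotypeCall(table.sample_id, table.site, tuple(called),
                            "hom_alt", dropout_flag=True)
    return GenotypeCall(table.sample_id, table.site, tuple(called),
                        "suspect_dropout")


def present_alleles(table: EventTable, sample_type: str,
                    th: Thresholds = Thresholds()) -> set[str]:
    """Alleles present in a sample: individuals use the genotype (het)
    threshold, pools the pool presence rule (>=1% and >=5 reads)."""
    if sample_type == "individual":
        return {s for s, _ in call_individual_genotype(table, th).alleles}
    out = set()
    total = table.total_assigned
    for sig, cnt, freq, flag in zip(table.df["signature"], table.df["count"],
                                    table.df["frequency"], table.df["control_flag"]):
        if flag:
            continue
        name = WT_SIGNATURE if sig == UNEDITED_ROW else sig
        if freq >= th.pool_presence_min_freq and cnt >= th.pool_presence_min_reads:
            out.add(name)
    return out


def count_transmitted_alleles(f1_tables: list[tuple[EventTable, str]],
                              founder_pair: str,
                              th: Thresholds = Thresholds()) -> TransmissionReport:
    """Union of alleles transmitted to the offspring of one founder pair.

    More than four unique alleles (wild type included) cannot come from two
    non-mosaic parents, so the germline-mosaic flag is raised above four.
    """
    if not f1_tables:
        raise ValueError("at least one offspring sample required")
    presence: dict[str, list[str]] = {}
    for table, sample_type in f1_tables:
        for allele in sorted(present_alleles(table, sample_type, th)):
            presence.setdefault(allele, []).append(table.sample_id)
    transmitted = tuple(sorted(presence))
    return TransmissionReport(
        founder_pair, transmitted,
        {k: tuple(v) for k, v in presence.items()},
        len(transmitted), len(transmitted) > 4)


@dataclass(frozen=True)
class ValidationResult:
    signature: str
    status: str                      # validated | unvalidated
    reason: str = ""
    supporting_samples: tuple[str, ...] = ()
    contamination_warnings: tuple[str, ...] = ()


def verify_event_in_relatives(signature: str,
                              sibling_tables: list[tuple[EventTable, str]],
                              unrelated_tables: list[tuple[EventTable, str]] = (),
                              th: Thresholds = Thresholds()) -> ValidationResult:
    """Validate an event called in a focal F1 against its relatives.

    A true inherited event must also appear in at least one sibling sample
    (individual or pooled larvae) from the same founder pair; presence in
    offspring of unrelated founders is reported as a contamination warning.
    """
    if not sibling_tables:
        return ValidationResult(signature, "unvalidated", "no_relatives")
    support = tuple(t.sample_id for t, typ in sibling_tables
                    if signature in present_alleles(t, typ, th))
    warnings = tuple(t.sample_id for t, typ in unrelated_tables
                     if signature in present_alleles(t, typ, th))
    status = "validated" if support else "unvalidated"
    reason = "" if support else "absent_in_relatives"
    return ValidationResult(signature, status, reason, support, warnings)


def reconcile_with_unamplified(genotype: GenotypeCall,
                               unamplified_table: EventTable,
                               th: Thresholds = Thresholds()) -> GenotypeCall:
    """Re-examine a dropout-suspect homozygote with amplification-free reads.

    WGS-mode reads are not subject to PCR dropout, so a second allele
    reaching the het threshold there revises the call to heterozygous and
    records the recovered allele (typically a dinucleotide-repeat
    insertion); otherwise homozygosity is confirmed.
    """
    if not genotype.dropout_flag:
        raise ValueError("reconciliation applies to dropout-flagged calls only")
    if unamplified_table.total_assigned < th.min_unamplified_depth:
        return replace(genotype, resolution="unresolved")
    wgs = call_individual_genotype(unamplified_table, th)
    if len(wgs.alleles) == 2:
        original = {s for s, _ in genotype.alleles}
        recovered = [s for s, _ in wgs.alleles if s not in original]
        return GenotypeCall(genotype.sample_id, genotype.site, wgs.alleles,
                            wgs.zygosity, dropout_flag=False,
                            recovered_allele=recovered[0] if recovered else "",
                            resolution="het_recovered")
    return replace(genotype, resolution="hom_confirmed")


def founder_offtarget_moderate(efficiencies: dict[str, float],
                               th: Thresholds = Thresholds()) -> bool:
    """F0 individuals are mosaic and never genotyped; they are annotated as
    moderate off-target carriers when any off-target site reaches 10%."""
    return any(e >= th.f0_moderate_offtarget for e in efficiencies.values())
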