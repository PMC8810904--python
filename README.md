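# crisprlong

Long-read analysis of CRISPR-Cas9 editing outcomes across generations.

CRISPR-Cas9 editing of one-cell embryos produces *mosaic* founders: each
animal carries many distinct repair alleles, both in somatic tissue and in
its germ cells, at the intended target and at partially complementary
off-target sites. Short-read or Sanger assays miss two important outcome
classes: structural variants (SVs — insertions and deletions ≥ 50 bp, up
to several kilobases) and alleles lost to PCR dropout (e.g. long
AT-dinucleotide repeat insertions that resist long-range amplification and
masquerade as homozygosity). `crisprlong` implements the long-amplicon
analysis needed to see both: per-read editing-outcome classification from
multi-kilobase reads, off-target cleavage-site confirmation, uninjected-
control filtering, cross-generation genotype and germline-mosaicism
inference, and a windowed read-depth CNV screen — together with a
synthetic-data generator that reproduces the statistical structure of a
two-generation zebrafish editing study, so the entire pipeline is testable
without any sequencing data.

It is written for genome-editing researchers quantifying editing outcomes
from PacBio CCS / nanopore amplicon data, and for methodologists who need
a transparent, fully seeded simulation of mosaic inheritance.

## The analysis in brief

**Off-target confirmation.** Candidate cut sites are read-terminus pileups
(cleavage assays leave blunt ends at the cut bond, supported on both
orientations). Each candidate is confirmed by aligning the 23-nt query
(20-nt protospacer + NGG) inside an 80-bp window (±40 bp around the cut)
with a Needleman–Wunsch/Gotoh alignment that is global in the query and
free-ended in the window: match +5, mismatch −4, a gap of length *L* costs
10 + 0.5·*L*. A gapless site with *k* substitutions scores 115 − 9*k*;
sites scoring strictly above 55 are accepted, so up to six substitutions
pass. PAM status is annotated `canonical` (NGG), `adjacent` (expected PAM
mismatched at the first G, with an NGG starting 1 bp downstream) or
`absent`.

**Per-read outcomes.** Reads are aligned to their amplicon by exact 15-mer
anchor chaining with a junction model that represents any single event —
deletions to ~4.8 kb, insertions to ~1.4 kb, and combined
deletion+insertions (delins) — as one composite event. Indels whose
footprint intersects a ±25 bp attribution window around the cut define an
*edited* read; substitutions never do. A delins is classified by its
larger component (reported size = −total_del or +total_ins). Events are
VCF-style left-aligned and keyed by a text signature that defines allele
identity across samples.

**Control filtering.** A site is dropped when uninjected controls show
≥ 0.5% indel reads there; any event signature observed in a control is
flagged and counted as unedited everywhere (germline variants, systematic
artifacts).

**Quantification.** Editing efficiency = edited, unflagged reads /
assigned reads. SV fraction = edited reads with |size| ≥ 50 bp / edited
reads. Size–frequency tables feed dot plots of the outcome spectrum.

**Generations.** F1 individuals carry exactly two alleles: alleles at
≥ 20% of reads are genotyped; a single non-wild-type event above 98%
raises a dropout suspicion that amplification-free (WGS-mode) reads
resolve — recovering, in the simulated study, a 64–66 bp insertion of
32–33 AT units. A founder pair transmitting more than four unique alleles
to its offspring proves germline mosaicism. Called events are validated by
their presence in siblings and checked for absence in unrelated families.
A 50-kb-window read-depth screen excludes large CNVs.

## Worked example

Simulate a pooled founder sample at a 2-kb amplicon (92.6% planted
efficiency, 6% SV tail, 0.5% read error), classify its reads and
quantify:

```python
from crisprlong import (SimConfig, make_locus, draw_editing_outcomes,
                        emit_amplicon_reads, classify_reads, tabulate,
                        editing_efficiency, sv_metrics)

locus = make_locus(length=2000, gc_fraction=0.5, cut_offset=1000,
                   seed=7, name="ldlra_amp")
cfg = SimConfig(seed=7, error_rate=0.005, sv_fraction=0.06,
                sv_max_del=700, sv_max_ins=400)
pool = draw_editing_outcomes(cfg, n_alleles=40, seed=8, locus=locus,
                             include_wt=1 - 0.926)
reads, truth = emit_amplicon_reads(pool, locus, cfg, seed=9,
                                   sample_id="founder_pool", depth=2000)
table = tabulate(classify_reads(reads, locus), "founder_pool", locus)
print(f"editing efficiency: {editing_efficiency(table):.3f}")
print(f"SV share of edited reads: {sv_metrics(table)[0]:.3f}")
print(table.df.head(5).to_string(index=False))
```

```
editing efficiency: 0.934
SV share of edited reads: 0.091
                                     signature  count  frequency  reported_size event_class  control_flag
                             ldlra_amp:999:A>-    319     0.1595             -1    deletion         False
                           ldlra_amp:998:TAT>-    190     0.0950             -3    deletion         False
ldlra_amp:996:-><INS:13>;ldlra_amp:996:TATAT>-    172     0.0860             13   insertion         False
                            ldlra_amp:996:TA>-    170     0.0850             -2    deletion         False
                    ldlra_amp:1000:-><INS:224>    132     0.0660            224   insertion         False
```

The efficiency estimate (93.4%) recovers the planted 92.6% within one
binomial standard error at depth 2000; the most frequent alleles are small
deletions at the cut, with a 224-bp insertion SV at 6.6% — the outcome
spectrum the size model encodes. The delins row (third) shows the
larger-component rule: 5 bp deleted, 13 bp inserted, class `insertion`,
reported size +13.

A single command runs the full two-generation synthetic study (off-target
mapping, founders, F1 cross, dropout reconciliation, CNV screen):

```bash
crisprlong run-all --seed 42 --out-dir results/demo
```

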