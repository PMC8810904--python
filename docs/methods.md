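# Methods

This note documents the models, numerical choices and limitations behind
`crisprlong`. Coordinates are 0-based, half-open everywhere; cut sites are
bond coordinates (a cut at `c` falls between bases `c-1` and `c`). The
blunt SpCas9 cut is placed 3 nt 5′ of the PAM, between protospacer
positions 17 and 18 — the standard SpCas9 geometry, fixed here as a
package convention.

## Guide-alignment scoring

The off-target confirmation step scores a 23-nt query (protospacer + PAM
pattern, IUPAC codes allowed and matched as wildcards at +5) against an
80-bp window with a Gotoh affine-gap alignment: match +5, mismatch −4, a
gap of length *L* costs `10 + 0.5·L` (the EMBOSS-style convention of one
opening charge plus a per-column extension). The alignment is global in
the query with free end gaps on the window side only; both window strands
are scored and the maximum kept (forward wins ties). Traceback ties break
substitution-over-gap, then leftmost. The implementation is checked
exactly, score for score, against an independent brute-force oracle that
recurses over whole gap runs rather than per-column gap states.

Two consequences of this scheme are worth knowing:

* A gapless site with *k* substitutions scores `115 − 9k`, so the >55
  acceptance rule admits at most six substitutions gaplessly. A site with
  seven substitutions scores 52 and cannot pass; reports of more-divergent
  off-target sites under the same threshold imply a different effective
  query or scoring, so the threshold is exposed as a parameter rather
  than hard-coded.
* Affine gaps can partially rescue *clustered* substitutions: a bulge of
  2 columns costs 11, less than two mismatches (18). High-divergence
  decoys therefore only stay below threshold when their substitutions are
  spread out and their PAM is also divergent; the synthetic planting
  utility exposes a `min_mismatch_spacing` control for exactly this
  reason.

PAM annotation is anchored at the protospacer 3′ end of the *gapless*
placement of the query (PAM geometry is rigid with respect to the bound
protospacer; an alignment that gaps across to a downstream NGG does not
move the expected PAM). `adjacent` status reproduces the situation where
the expected NGG is mismatched at its first G but an NGG begins 1 bp
downstream.

## Cleavage-candidate detection

Terminus records (read start `+` / end `−`) are clustered within a 5-bp
merge radius; a cluster is a candidate when each orientation contributes
at least 5 termini and the minority orientation holds at least 20% of the
total. The candidate coordinate is the support-weighted modal position
(leftmost on ties). These three thresholds are package choices — the
upstream cleavage-site callers used in practice do not publish their
internals — and are exposed as parameters.

## Read-to-amplicon alignment

Amplicon reads differ from their reference by sparse substitution errors
plus at most a few editing events, which may be kilobase-scale. Full DP
over multi-kb reads is unnecessary for this structure, so the aligner:

1. indexes the reference's unique 15-mers and matches the read's 15-mers
   against them (vectorized rolling hash);
2. merges co-diagonal anchors into segments and chains the best colinear
   segment subset (weighted by anchor count);
3. aligns within-segment stretches positionally (substitution columns
   only) and resolves each between-segment junction with a restricted
   model: `p` substitution columns, one deletion block, one insertion
   block, `q` substitution columns, maximizing score under match +2,
   mismatch −4, gap `6 + L`;
4. soft-clips read ends whose best prefix/suffix score is non-positive
   (this is how molecules truncated inside a repeat lose their tail).

The junction model never aligns inserted read sequence against deleted
reference sequence, so a delins is reported verbatim as one deletion plus
one insertion at a shared junction — the representation event signatures
are defined on. Under a full DP, part of a delins insertion can be
absorbed into mismatch columns whenever it resembles the deleted
sequence, making the decomposition (and hence allele identity)
representation-dependent; the restricted model makes it canonical. The
synthetic generator draws delins insert bases to mismatch the deleted
region at the prefix- and suffix-aligned offsets, so planted delins
alleles are recovered exactly. For reads equal in length to the reference
with <5% mismatches, a positional fast path skips anchoring entirely.

An equal-scoring caveat: when a substitution error lands within a couple
of bases of a small event's junction, an alternative decomposition can
genuinely score higher than the planted one (e.g. the error base absorbed
into the insertion with the junction shifted by 1). These reads are
"scatter": rare signatures differing from a dominant allele only by a
small positional/length perturbation. Tabulation collapses a signature
into a dominant one when its count is ≤ max(3, 0.5% of reads), the
dominant row has ≥ 20× its count, the sub-event kind patterns match and
the total position+length perturbation is ≤ 4. The ratio requirement
protects genuinely co-occurring similar alleles (e.g. a true 3-bp and a
true 5-bp deletion in one heterozygote are never merged, since both are
abundant).

Insertions longer than 12 bp are identified by position and length
(`<INS:n>`) rather than exact sequence: at CCS-grade error rates the
inserted bases of a long insertion almost always carry an error, so
exact-sequence identity would split one allele into many. Distinct
same-length insertions at one position would collide under this rule; at
amplicon scale this is vanishingly rare and accepted as a limitation.

## Outcome classification and tabulation

A read is *edited* when at least one indel intersects the ±25 bp
attribution window around the cut (any deletion spanning the cut
qualifies automatically — it necessarily intersects the window);
substitution-only reads are `snv_only` and count as unedited, since
efficiency is defined on indels. Reads with <50% aligned bases, or whose
alignment does not span the attribution window (dropout-truncated
molecules), are `unassigned` and excluded from all denominators; their
fraction is a QC metric. The ±25 bp window is a package choice — the
event-caller internals this mirrors are unpublished — and delins ties
(total_del = total_ins) classify as deletion.

## Control-based filtering

Both control rules are implemented with the stated inclusivity: the site
filter removes at control indel frequency ≥ 0.5% exactly (0.5% removed,
0.49% retained), and control-event flagging is signature-exact after
normalization, triggered by a single control read. Flagged reads move to
the unedited side of every downstream metric, including genotyping.

## Generational analysis

Genotype calls report alleles at ≥ 20% of assigned reads (inclusive),
wild type counting as an allele; more than two is an error for an F1
individual. A single allele above 98% (strict) yields a homozygous call,
flagged as a dropout suspect when the allele is an editing event; a
single allele at or below 98% is ambiguous (`suspect_dropout`).
Reconciliation reruns classification on amplification-free reads
(minimum 10; fewer → unresolved) and revises to heterozygous when a
second allele reaches 20% there. Pool presence requires ≥ 1% frequency
and ≥ 5 reads — the detection limit is a package choice. Transmission
counting takes the union of present alleles (wild type included) across a
pair's offspring; more than four proves germline mosaicism. Founders are
never genotyped (they are mosaic); they receive frequency summaries with
a 10% moderate-off-target annotation.

## CNV screen

Mean depth in 50-kb tiling windows (trailing partial window reported but
excluded), median-normalized to copy ratios, then maximal runs of ≥ 3
consecutive windows below 0.75 or above 1.25 are emitted as loss/gain
segments. The thresholds are package choices calibrated for half-ratio
(heterozygous-deletion-scale) events at window noise CV ≤ 0.1; the screen
is a coarse exclusion tool, not a breakpoint caller.

## Synthetic study design

The generator is first-class code, and its defaults are the study
conditions the analysis is tested under:

* **Read error** 0.5% per base, substitutions only (CCS-grade). No
  homopolymer indel errors, chimeras or quality dependence — hence a
  green suite bounds alignment/classification behaviour only under this
  error model.
* **Outcome size model**: with probability `sv_fraction` (default 0.06)
  an event is an SV with log-uniform size in [50, 4800] for deletions and
  [50, 1400] for insertions; otherwise a small indel with geometric
  (p = 0.3) size on 1–49 bp. Deletions are twice as likely as insertions;
  10% of small events are delins. Deletions always span the cut bond;
  insertions occur at it.
* **Pools**: allele frequencies are Dirichlet(1) over i.i.d. drawn
  outcomes, duplicates merged by summing (recurrent repair products), so
  the SV share of a pool is unbiased for `sv_fraction`. The true founder
  allele-frequency law is unknown; the Dirichlet is a stand-in.
* **Founders and crosses**: somatic and germline pools are drawn
  independently per site; each F1 draws one germline allele per parent
  i.i.d. Germline pools default to 3 alleles, so a pair can transmit up
  to 6 — the mosaic-germline signature.
* **Dropout**: an allele is dropout-liable when it contains ≥ 25 tandem
  dinucleotide units (two distinct bases); the canonical example is a
  32–33 unit AT insertion at the cut. Liable alleles amplify with
  probability 0.02, and 80% of surviving molecules are truncated at the
  repeat. When a germline repeat allele is requested it is pinned at 40%
  of the pool so crosses reliably produce affected heterozygotes.
* **Demo scale**: amplicons are 1.2 kb (real amplicons run 2.6–7.7 kb;
  the classifier is exercised up to 7 kb and ±4.8 kb/+1.4 kb events in
  the test suite), with SVs capped at 400/250 bp in the demo, depths of
  500 (founder/larvae pools), 250 (F1 individuals), 40 (WGS mode), six
  pooled-larvae samples of 100 allele draws each, two founder pairs with
  10 offspring plus a 20-larvae pool. Pool-level quantities such as the
  SV share are computed from the pooled-larvae samples, where many
  independent alleles contribute. The parameter-recovery checks use
  300-bp loci with the SV tail capped at 120 bp across 100 replicates —
  binomial recovery does not depend on amplicon length, which keeps the
  replicated runs small.

All randomness flows from one root seed through named substreams
(`numpy` `SeedSequence`); reruns are byte-identical, and every emitted
read maps to exactly one truth-table allele.

## Known limitations

* Per-technology error profiles, chimeric reads and base-quality-aware
  consensus are out of scope; the error model is i.i.d. substitutions.
* Allele identity for long insertions is positional+length, not
  sequence-resolved.
* The CNV screen has no GC correction or changepoint statistics.
* Off-target scoring admits bulge alignments that can rescue clustered
  substitutions past the threshold; this mirrors the underlying affine
  scoring scheme and is documented rather than suppressed.
* Translocations, inversions and whole-chromosome aberrations are not
  modelled or detected.
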