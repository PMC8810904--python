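"""Synthetic study generator: loci, planted off-target sites, mosaic
founders, F1 crosses, amplicon reads, cleavage-terminus tracks and coverage
profiles.

The generator emulates the structure of a mosaic-zebrafish editing study:
founders edited at the one-cell stage carry many distinct alleles per site
(somatic and germline pools drawn separately), F1 individuals inherit one
germline allele from each parent, editing outcomes mix a small-indel core
with a structural-variant tail (>=50 bp), and AT-dinucleotide repeat
insertions cause allelic dropout during long-range PCR.

All draws flow from explicit seeds; identical seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GuideSpec, ReferenceLocus, longest_dinucleotide_run, random_dna
from .events import DELETION, INSERTION, WT_SIGNATURE, CompositeEvent, EditEvent

Allele = CompositeEvent | None  # None marks the wild-type allele


def allele_signature(allele: Allele, locus: ReferenceLocus) -> str:
    return WT_SIGNATURE if allele is None else allele.signature(locus)


@dataclass(frozen=True)
class AllelePool:
    """Alleles with frequencies; origin tags somatic vs germline pools."""

    alleles: tuple[tuple[Allele, float], ...]
    origin: str = "somatic"
    locus_name: str = ""

    def __post_init__(self):
        freqs = [f for _, f in self.alleles]
        if any(f < 0 for f in freqs):
            raise ValueError("allele frequencies must be >= 0")
        if self.alleles and not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
            raise ValueError("allele frequencies must sum to 1")

    def signatures(self, locus: ReferenceLocus) -> list[str]:
        return [allele_signature(a, locus) for a, _ in self.alleles]


@dataclass(frozen=True)
class SiteSim:
    """Per-site simulation settings for one amplicon locus."""

    locus: ReferenceLocus
    efficiency: float = 0.9
    germline_efficiency: float | None = None
    n_somatic_alleles: int = 8
    n_germline_alleles: int = 3
    at_repeat_germline: bool = False
    on_target: bool = True

    @property
    def name(self) -> str:
        return self.locus.name


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the long-read amplicon study the generator emulates:
    CCS-grade substitution error (0.5%/base), an SV tail holding 6% of
    edited alleles with deletions up to 4.8 kb and insertions up to 1.4 kb,
    a 2:1 deletion:insertion small-indel core, and near-total amplification
    dropout of long AT-repeat insertion alleles.
    """

    seed: int = 0
    depth: int = 2000
    error_rate: float = 0.005
    small_indel_p: float = 0.3        # geometric core over 1-49 bp
    deletion_share: float = 2 / 3     # deletions twice as likely as insertions
    sv_fraction: float = 0.06
    sv_max_del: int = 4800
    sv_max_ins: int = 1400
    delins_fraction: float = 0.10
    dirichlet_alpha: float = 1.0
    n_offspring: int = 12
    p_amplify_dropout: float = 0.02
    dropout_truncate_fraction: float = 0.8
    dropout_min_units: int = 25
    flank_margin: int = 50            # event-free flank kept inside primer span
    sites: tuple[SiteSim, ...] = ()

    def __post_init__(self):
        for p in (self.error_rate, self.sv_fraction, self.deletion_share,
                  self.delins_fraction, self.p_amplify_dropout,
                  self.dropout_truncate_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sv_max_del < 50 or self.sv_max_ins < 50:
            raise ValueError("SV tail sizes must be >= 50 bp")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class FounderTruth:
    """Ground truth for one mosaic founder: somatic and germline pools per site."""

    founder_id: str
    somatic_pools: dict[str, AllelePool]
    germline_pools: dict[str, AllelePool]


@dataclass(frozen=True)
class F1Truth:
    """Ground truth for one F1 individual: two alleles per site."""

    sample_id: str
    founder_pair: str
    alleles: dict[str, tuple[Allele, Allele]]  # site -> (maternal, paternal)

    def dropout_liable(self, site: str, min_units: int) -> tuple[bool, bool]:
        return tuple(_liable(a, min_units) for a in self.alleles[site])  # type: ignore[return-value]


def _liable(allele: Allele, min_units: int) -> bool:
    if allele is None:
        return False
    return any(longest_dinucleotide_run(e.seq) >= min_units
               for e in allele.sub_events if e.kind == INSERTION)


# ---------------------------------------------------------------------------
# loci and planted sites

def make_locus(length: int, gc_fraction: float, cut_offset: int, seed: int,
               name: str = "locus") -> ReferenceLocus:
    """A random amplicon locus with i.i.d. bases at the requested GC."""
    if not 200 <= length <= 10_000:
        raise ValueError("locus length must be within [200, 10000]")
    if not 0 < cut_offset < length:
        raise ValueError(f"cut_offset {cut_offset} outside (0, {length})")
    rng = np.random.default_rng(seed)
    return ReferenceLocus(name, random_dna(rng, length, gc_fraction), cut_offset)


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for an embedded protospacer+PAM copy."""

    locus_name: str
    start: int               # protospacer start on the forward strand
    cut_position: int        # bond coordinate of the expected cut
    n_mismatches: int
    pam_mode: str            # canonical | adjacent | absent
    embedded: str            # the 23-nt embedded sequence (+ 1 downstream base)


def _realize_pam(guide: GuideSpec, pam_mode: str, rng: np.random.Generator) -> tuple[str, str]:
    """Concrete 3-nt PAM plus the base that follows it."""
    non_g = "ACT"
    n = rng.choice(list("ACGT"))
    if pam_mode == "canonical":
        return n + "GG", rng.choice(list("ACGT"))
    if pam_mode == "adjacent":
        # mismatch at NGG position 1, but an NGG starts 1 bp downstream
        return n + rng.choice(list(non_g)) + "G", "G"
    if pam_mode == "absent":
        return n + rng.choice(list(non_g)) + rng.choice(list(non_g)), rng.choice(list(non_g))
    raise ValueError(f"unknown pam_mode {pam_mode!r}")


def plant_offtarget_sites(loci: list[ReferenceLocus], guide: GuideSpec,
                          mismatch_counts: list[int],
                          pam_modes: list[str] | None = None,
                          seed: int = 0,
                          min_mismatch_spacing: int = 0
                          ) -> tuple[list[ReferenceLocus], list[PlantedSite]]:
    """Embed one protospacer+PAM copy per locus, at the locus cut position.

    Each embedded copy carries exactly the requested number of protospacer
    substitutions; the PAM is written according to ``pam_modes`` (canonical
    NGG, adjacent = NGG shifted 1 bp downstream with a mismatch at NGG
    position 1, or absent). The planted cut bond coincides with the locus
    ``cut_position`` so downstream modules agree on coordinates.

    ``min_mismatch_spacing`` keeps substitution positions at least that far
    apart: clustered substitutions can be bypassed by a single alignment
    gap, which changes a site's effective score.
    """
    if pam_modes is None:
        pam_modes = ["canonical"] * len(loci)
    if not len(loci) == len(mismatch_counts) == len(pam_modes):
        raise ValueError("loci, mismatch_counts and pam_modes must align")
    rng = np.random.default_rng(seed)
    out_loci, truth = [], []
    for locus, k, pam_mode in zip(loci, mismatch_counts, pam_modes):
        if not 0 <= k <= 8:
            raise ValueError("mismatch count must lie in [0, 8]")
        start = locus.cut_position - GuideSpec.CUT_OFFSET
        if start < 0 or start + 24 > len(locus):
            raise ValueError(f"locus {locus.name} too short to host a site")
        proto = list(guide.protospacer)
        while True:
            positions = sorted(rng.choice(20, size=k, replace=False))
            if min_mismatch_spacing <= 1 or all(
                    b - a >= min_mismatch_spacing
                    for a, b in zip(positions, positions[1:])):
                break
        for pos in positions:
            proto[pos] = rng.choice([b for b in "ACGT" if b != proto[pos]])
        pam, nxt = _realize_pam(guide, pam_mode, rng)
        embedded = "".join(proto) + pam + nxt
        seq = locus.sequence[:start] + embedded + locus.sequence[start + 24:]
        out_loci.append(replace(locus, sequence=seq))
        truth.append(PlantedSite(locus.name, start, locus.cut_position, k,
                                 pam_mode, embedded))
    return out_loci, truth


# ---------------------------------------------------------------------------
# editing outcomes

def _draw_small_size(cfg: SimConfig, rng: np.random.Generator) -> int:
    while True:
        size = int(rng.geometric(cfg.small_indel_p))
        if 1 <= size <= 49:
            return size


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    if hi <= lo:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _delins_insert(rng: np.random.Generator, ref: str, del_start: int,
                   del_end: int, length: int) -> str:
    """Inserted sequence for a delins, mismatching the deleted region at
    prefix- and suffix-aligned offsets so the del+ins decomposition is the
    unique optimal junction alignment and the planted signature is
    recoverable."""
    d = del_end - del_start
    out = []
    for i in range(length):
        forbidden = set()
        if i < d:
            forbidden.add(ref[del_start + i])
        j = length - 1 - i
        if j < d:
            forbidden.add(ref[del_end - 1 - (length - 1 - i)])
        out.append(rng.choice([b for b in "ACGT" if b not in forbidden]))
    return "".join(out)


def _draw_one_event(cfg: SimConfig, locus: ReferenceLocus,
                    rng: np.random.Generator) -> CompositeEvent:
    cut = locus.cut_position
    lo, hi = locus.primer_span
    room_left = cut - (lo + cfg.flank_margin)
    room_right = (hi - cfg.flank_margin) - cut
    if room_left < 2 or room_right < 2:
        raise ValueError(f"locus {locus.name} leaves no room for events at the cut")
    is_sv = rng.random() < cfg.sv_fraction
    is_del = rng.random() < cfg.deletion_share
    if not is_sv and rng.random() < cfg.delins_fraction:
        d = min(_draw_small_size(cfg, rng) + 4, 49)
        i = min(_draw_small_size(cfg, rng) + 4, 49)
        if d == i:
            d += 1
        left = int(rng.integers(1, max(2, min(d, room_left))))
        s = cut - left
        e = min(s + d, hi - cfg.flank_margin)
        ins = _delins_insert(rng, locus.sequence, s, e, i)
        return CompositeEvent((EditEvent(DELETION, s, e),
                               EditEvent(INSERTION, s, s, ins)))
    if is_del:
        max_size = min(cfg.sv_max_del if is_sv else 49, room_left + room_right)
        size = (_log_uniform(rng, 50, max_size) if is_sv
                else _draw_small_size(cfg, rng))
        size = max(50, min(size, max_size)) if is_sv else min(size, max_size)
        left_lo = max(1, size - room_right)
        left_hi = min(size - 1, room_left) if size > 1 else 1
        left = int(rng.integers(left_lo, left_hi + 1)) if size > 1 else 1
        s = cut - left
        return CompositeEvent((EditEvent(DELETION, s, s + size),))
    max_size = cfg.sv_max_ins if is_sv else 49
    size = _log_uniform(rng, 50, max_size) if is_sv else _draw_small_size(cfg, rng)
    seq = random_dna(rng, size)
    return CompositeEvent((EditEvent(INSERTION, cut, cut, seq),))


def draw_events(config: SimConfig, n: int, seed: int,
                locus: ReferenceLocus) -> list[CompositeEvent]:
    """n i.i.d. editing outcomes from the size model (no dedup): the SV
    share of this stream is Bernoulli(sv_fraction) per draw."""
    rng = np.random.default_rng(seed)
    return [_draw_one_event(config, locus, rng) for _ in range(n)]


def at_repeat_allele(locus: ReferenceLocus, n_units: int = 32) -> CompositeEvent:
    """A dinucleotide-repeat insertion allele (AT units) at the cut site."""
    cut = locus.cut_position
    return CompositeEvent((EditEvent(INSERTION, cut, cut, "AT" * n_units),))


def draw_editing_outcomes(config: SimConfig, n_alleles: int, seed: int,
                          locus: ReferenceLocus, origin: str = "somatic",
                          include_at_repeat: bool = False,
                          include_wt: float = 0.0) -> AllelePool:
    """Draw a pool of ``n_alleles`` i.i.d. editing outcomes with Dirichlet
    frequencies; identical outcomes (recurrent repair products) are merged
    by summing their frequencies, so signatures stay unique without
    biasing the size model.

    ``include_wt`` > 0 reserves that frequency for the wild-type allele and
    scales the edited alleles into the remainder (the editing efficiency).
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    rng = np.random.default_rng(seed)
    drawn = [_draw_one_event(config, locus, rng).normalized(locus)
             for _ in range(n_alleles)]
    freqs = rng.dirichlet(np.full(n_alleles, config.dirichlet_alpha))
    if include_at_repeat:
        n_units = int(rng.integers(32, 34))
        drawn[-1] = at_repeat_allele(locus, n_units).normalized(locus)
        if n_alleles > 1 and freqs[-1] < 1:
            # give the repeat allele a fixed share so crosses reliably
            # produce dropout-liable heterozygotes
            freqs = freqs * (1 - 0.4) / (1 - freqs[-1])
            freqs[-1] = 0.4
    merged: dict[str, tuple[Allele, float]] = {}
    for ev, f in zip(drawn, freqs.tolist()):
        sig = ev.signature(locus)
        prev = merged.get(sig)
        merged[sig] = (ev, f if prev is None else prev[1] + f)
    pairs: list[tuple[Allele, float]] = []
    scale = 1.0 - include_wt if include_wt > 0 else 1.0
    if include_wt > 0:
        pairs.append((None, include_wt))
    pairs.extend((a, f * scale) for a, f in merged.values())
    return AllelePool(tuple(pairs), origin=origin, locus_name=locus.name)


# ---------------------------------------------------------------------------
# founders and crosses

def simulate_founder(config: SimConfig, seed: int,
                     founder_id: str = "F0") -> FounderTruth:
    """One mosaic founder: independent somatic and germline pools per site."""
    somatic, germline = {}, {}
    ss = np.random.SeedSequence(seed)
    for i, site in enumerate(config.sites):
        s_seed, g_seed = ss.spawn(1)[0].generate_state(2) >> np.uint32(1)
        g_eff = (site.efficiency if site.germline_efficiency is None
                 else site.germline_efficiency)
        somatic[site.name] = draw_editing_outcomes(
            config, site.n_somatic_alleles, int(s_seed) + i, site.locus,
            origin="somatic", include_wt=1.0 - site.efficiency)
        germline[site.name] = draw_editing_outcomes(
            config, site.n_germline_alleles, int(g_seed) + i, site.locus,
            origin="germline", include_at_repeat=site.at_repeat_germline,
            include_wt=1.0 - g_eff)
    return FounderTruth(founder_id, somatic, germline)


def cross(f0a: FounderTruth, f0b: FounderTruth, n_offspring: int, seed: int,
          pair_id: str | None = None) -> list[F1Truth]:
    """In-cross two founders: each F1 draws one germline allele per parent."""
    if not f0a.germline_pools or not f0b.germline_pools:
        raise ValueError("germline pools must be non-empty")
    pair = pair_id or f"{f0a.founder_id}x{f0b.founder_id}"
    rng = np.random.default_rng(seed)
    offspring = []
    sites = sorted(set(f0a.germline_pools) & set(f0b.germline_pools))
    for i in range(n_offspring):
        alleles = {}
        for site in sites:
            pa = f0a.germline_pools[site]
            pb = f0b.germline_pools[site]
            m = pa.alleles[rng.choice(len(pa.alleles), p=[f for _, f in pa.alleles])][0]
            p = pb.alleles[rng.choice(len(pb.alleles), p=[f for _, f in pb.alleles])][0]
            alleles[site] = (m, p)
        offspring.append(F1Truth(f"{pair}_F1_{i:03d}", pair, alleles))
    return offspring


def f1_pool(truth: F1Truth | list[F1Truth], site: str,
            locus: ReferenceLocus) -> AllelePool:
    """The allele pool a sample presents to PCR: an F1 individual is a
    50/50 two-allele pool; a larvae pool averages its members."""
    members = [truth] if isinstance(truth, F1Truth) else list(truth)
    weights: dict[str, tuple[Allele, float]] = {}
    w = 1.0 / (2 * len(members))
    for m in members:
        for allele in m.alleles[site]:
            sig = allele_signature(allele, locus)
            prev = weights.get(sig, (allele, 0.0))
            weights[sig] = (allele, prev[1] + w)
    return AllelePool(tuple(weights.values()), origin="somatic",
                      locus_name=locus.name)


# ---------------------------------------------------------------------------
# read emission

def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _event_pool(truth, site: str, locus: ReferenceLocus) -> AllelePool:
    if isinstance(truth, AllelePool):
        return truth
    if isinstance(truth, FounderTruth):
        return truth.somatic_pools[site]
    return f1_pool(truth, site, locus)


def emit_amplicon_reads(truth, locus: ReferenceLocus, config: SimConfig,
                        seed: int, sample_id: str = "S",
                        depth: int | None = None
                        ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate amplicon reads for one sample at one locus.

    Returns ``(reads, truth_table)`` where reads are ``(read_id, sequence)``
    and the truth table records the source allele per read. Dropout-liable
    alleles (long dinucleotide-repeat insertions) survive amplification with
    probability ``p_amplify_dropout``; a fraction of their surviving reads
    is truncated at the repeat.
    """
    depth = config.depth if depth is None else depth
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pool = _event_pool(truth, locus.name, locus)
    lo, hi = locus.primer_span
    for allele, _ in pool.alleles:
        if allele is None:
            continue
        for e in allele.sub_events:
            if not (lo <= e.start and e.end <= hi):
                raise ValueError(
                    f"event {e} outside primer span {locus.primer_span}: not amplifiable")
    rng = np.random.default_rng(seed)
    alleles = [a for a, _ in pool.alleles]
    freqs = np.array([f for _, f in pool.alleles])
    freqs = freqs / freqs.sum()
    liable = [_liable(a, config.dropout_min_units) for a in alleles]
    seq_cache = [a.apply(locus.amplicon, offset=lo) if a is not None
                 else locus.amplicon for a in alleles]
    reads, rows = [], []
    draws = rng.choice(len(alleles), size=depth, p=freqs)
    for i, ai in enumerate(draws):
        truncated = False
        if liable[ai]:
            if rng.random() >= config.p_amplify_dropout:
                continue  # allele fails to amplify
            if rng.random() < config.dropout_truncate_fraction:
                truncated = True
        seq = seq_cache[ai]
        if truncated:
            rep_start = min(e.start for e in alleles[ai].sub_events
                            if e.kind == INSERTION) - lo
            seq = seq[:rep_start + int(rng.integers(0, 21))]
        seq = _add_errors(seq, config.error_rate, rng)
        rid = f"{sample_id}:{locus.name}:{i:06d}"
        reads.append((rid, seq))
        rows.append((rid, sample_id, allele_signature(alleles[ai], locus), truncated))
    table = pd.DataFrame(rows, columns=["read_id", "sample_id",
                                        "allele_signature", "truncated"])
    return reads, table


def emit_cleavage_reads(loci: list[ReferenceLocus], true_sites: list[PlantedSite],
                        depth: int, background_fraction: float, seed: int,
                        reads_per_site: int = 20) -> pd.DataFrame:
    """Terminus records for a cleavage assay: per true site,
    ``reads_per_site`` termini exactly at the cut (both orientations);
    background termini uniform over each locus."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    by_locus: dict[str, list[PlantedSite]] = {}
    for s in true_sites:
        by_locus.setdefault(s.locus_name, []).append(s)
    for locus in loci:
        for site in by_locus.get(locus.name, []):
            for j in range(reads_per_site):
                rows.append((locus.name, site.cut_position, "+" if j % 2 == 0 else "-"))
        n_bg = int(round(depth * background_fraction))
        if n_bg:
            pos = rng.integers(0, len(locus), size=n_bg)
            ori = rng.choice(["+", "-"], size=n_bg)
            rows.extend(zip([locus.name] * n_bg, pos.tolist(), ori.tolist()))
    return pd.DataFrame(rows, columns=["locus", "coordinate", "orientation"])


def emit_depth_track(genome_length: int,
                     cnv_segments: list[tuple[tuple[int, int], float]],
                     mean_depth: float, noise_cv: float,
                     window: int = 50_000, seed: int = 0):
    """Windowed coverage: depth ~ mean * copy_ratio * (1 + N(0, cv)), >= 0."""
    from .cnv import CoverageProfile

    if window > genome_length:
        raise ValueError("window larger than genome")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    ivs = sorted(iv for iv, _ in cnv_segments)
    for (a, b), (c, d) in zip(ivs, ivs[1:]):
        if c < b:
            raise ValueError("cnv segments must be non-overlapping")
    rng = np.random.default_rng(seed)
    n_win = genome_length // window
    starts = np.arange(n_win) * window
    ratios = np.ones(n_win)
    for (a, b), r in cnv_segments:
        overlap = (np.minimum(b, starts + window) - np.maximum(a, starts)).clip(0)
        ratios += (r - 1.0) * overlap / window
    depth = mean_depth * ratios * (1.0 + rng.normal(0.0, noise_cv, size=n_win))
    return CoverageProfile(label="sim", window=window,
                           depths=np.maximum(depth, 0.0))
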