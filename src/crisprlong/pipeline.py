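"""End-to-end orchestration: one config drives the full synthetic study.

The demo experiment mirrors a two-generation editing study: a guide with
one on-target and three off-target sites (plus a high-mismatch decoy that
must be rejected), two founder pairs edited at the one-cell stage,
uninjected control pools, F1 individuals and pooled F1 larvae, WGS-mode
reconciliation of dropout-suspect homozygotes, and a windowed CNV screen.
All randomness flows from one root seed through named per-stage
substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import EventTable, classify_reads, tabulate
from .cnv import call_cnv, normalize_profile, segments_to_bed
from .core import GuideSpec, ReferenceLocus, random_dna
from .events import INSERTION, WT_SIGNATURE, CompositeEvent, EditEvent
from .generational import (GenotypeCall, Thresholds, call_individual_genotype,
                           count_transmitted_alleles, reconcile_with_unamplified,
                           verify_event_in_relatives)
from .io import (write_bed, write_depth_tsv, write_event_table,
                 write_events_vcf, write_fasta, write_pedigree,
                 write_termini_tsv)
from .offtarget import (call_sites, detect_cleavage_candidates, sites_to_bed)
from .quantify import (control_indel_frequency, editing_efficiency,
                       filter_sites_by_control, flag_control_events,
                       summarize_sample, sv_metrics)
from .simulate import (AllelePool, F1Truth, FounderTruth, SimConfig, SiteSim,
                       cross, draw_editing_outcomes, emit_amplicon_reads,
                       emit_cleavage_reads, emit_depth_track,
                       plant_offtarget_sites, simulate_founder)


class StageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        self.stage, self.sample, self.cause = stage, sample, cause
        super().__init__(f"stage {stage!r} failed for {sample!r}: {cause}")


@dataclass(frozen=True)
class AnalysisConfig:
    """One flat, YAML-serializable description of a full run."""

    seed: int = 42
    out_dir: str = "results/run"
    # thresholds (named study constants)
    score_threshold: float = 55.0
    site_filter_threshold: float = 0.005
    sv_min: int = 50
    het_threshold: float = 0.20
    hom_threshold: float = 0.98
    window_half_width: int = 40
    attribution_window: int = 25
    cnv_window: int = 50_000
    # synthetic study shape
    locus_length: int = 1200
    sv_max_del: int = 400
    sv_max_ins: int = 250
    error_rate: float = 0.005
    sv_fraction: float = 0.06
    on_target_efficiency: float = 0.926
    offtarget_efficiencies: tuple[float, ...] = (0.018, 0.024, 0.063)
    offtarget_mismatches: tuple[int, ...] = (2, 4, 6)
    offtarget_pam_modes: tuple[str, ...] = ("canonical", "adjacent", "canonical")
    decoy_mismatches: int = 8
    n_pairs: int = 2
    n_offspring: int = 10
    pool_members: int = 20
    n_f0_pools: int = 6
    f0_pool_depth: int = 500
    f0_pool_alleles: int = 100
    control_depth: int = 600
    founder_depth: int = 500
    f1_depth: int = 250
    pool_depth: int = 500
    wgs_depth: int = 40
    cleavage_depth: int = 400
    cleavage_background: float = 0.5
    reads_per_site: int = 20
    artifact_rate: float = 0.003
    cnv_genome_length: int = 2_000_000
    cnv_mean_depth: float = 30.0
    cnv_noise_cv: float = 0.05

    def validate(self) -> None:
        for name in ("control_depth", "founder_depth", "f1_depth",
                     "pool_depth", "wgs_depth", "cleavage_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (len(self.offtarget_efficiencies) == len(self.offtarget_mismatches)
                == len(self.offtarget_pam_modes)):
            raise ValueError("off-target efficiency/mismatch/PAM lists must align")
        Thresholds(het_threshold=self.het_threshold,
                   hom_threshold=self.hom_threshold)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for k in ("offtarget_efficiencies", "offtarget_mismatches",
                  "offtarget_pam_modes"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    @property
    def config_hash(self) -> str:
        """Hash over analysis parameters (the output path is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(het_threshold=self.het_threshold,
                          hom_threshold=self.hom_threshold)


@dataclass
class RunReport:
    config: AnalysisConfig
    guide: GuideSpec
    loci: dict[str, ReferenceLocus]
    site_table: pd.DataFrame
    tables: dict[tuple[str, str], EventTable]
    wgs_tables: dict[tuple[str, str], EventTable]
    summaries: pd.DataFrame
    genotypes: pd.DataFrame
    transmission: list
    validations: pd.DataFrame
    cnv_profiles: list
    cnv_segments: list
    pedigree: pd.DataFrame
    retained_sites: set[str]
    termini: pd.DataFrame

    def headline(self) -> dict[str, float]:
        """The run's summary quantities (fractions in [0, 1])."""
        on = self.loci["on_target"].name
        # efficiencies and the SV share come from pooled founder larvae
        # (many larvae, hence many independent edited alleles per pool)
        f0 = self.pedigree[(self.pedigree["generation"] == "F0")
                           & (self.pedigree["type"] == "pool")]["sample_id"]
        if f0.empty:
            f0 = self.pedigree[self.pedigree["generation"] == "F0"]["sample_id"]
        f1_ind = self.pedigree[(self.pedigree["generation"] == "F1")
                               & (self.pedigree["type"] == "individual")]["sample_id"]
        off_sites = [s for s in self.retained_sites if s != on]
        out: dict[str, float] = {}
        effs = [editing_efficiency(self.tables[(s, on)]) for s in f0]
        out["on_target_efficiency"] = float(np.mean(effs))
        for site in sorted(off_sites):
            effs = [editing_efficiency(self.tables[(s, site)]) for s in f0]
            out[f"{site}_efficiency"] = float(np.mean(effs))
        # SV share pooled over founder reads at all retained sites
        edited = sv = 0
        for s in f0:
            for site in sorted(self.retained_sites):
                t = self.tables[(s, site)]
                rows = t.event_rows(include_flagged=False)
                edited += rows["count"].sum()
                sv += rows.loc[rows["reported_size"].abs()
                               >= self.config.sv_min, "count"].sum()
        out["sv_share_of_edits"] = sv / edited if edited else float("nan")
        carriers = 0
        sv_carriers = 0
        for s in f1_ind:
            if any(editing_efficiency(self.tables[(s, site)]) >= self.config.het_threshold
                   for site in off_sites):
                carriers += 1
            gt = self.genotypes[(self.genotypes["sample_id"] == s)
                                & (self.genotypes["site"] == on)]
            if not gt.empty and gt.iloc[0]["max_allele_size"] >= self.config.sv_min:
                sv_carriers += 1
        n_f1 = max(len(f1_ind), 1)
        out["f1_offtarget_carrier_fraction"] = carriers / n_f1
        out["f1_on_target_sv_carrier_fraction"] = sv_carriers / n_f1
        out["n_sites_called"] = float(len(self.site_table))
        out["germline_mosaic_pairs"] = float(
            sum(1 for r in self.transmission if r.germline_mosaic_flag))
        out["dropout_flagged_f1"] = float(
            (self.genotypes["dropout_flag"]).sum())
        out["dropout_resolved_het"] = float(
            (self.genotypes["resolution"] == "het_recovered").sum())
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        write_fasta(out / "loci.fa", [(n, l.sequence) for n, l in
                                      sorted(self.loci.items())])
        self.site_table.to_csv(out / "sites.tsv", sep="\t", index=False)
        write_termini_tsv(self.termini, out / "termini.tsv")
        for (sample, site), table in sorted(self.tables.items()):
            write_event_table(table, out / "tables" / f"{sample}__{site}.tsv")
        self.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        self.genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        with open(out / "transmission.json", "w") as fh:
            json.dump([{"founder_pair": r.founder_pair,
                        "unique_allele_count": r.unique_allele_count,
                        "germline_mosaic_flag": r.germline_mosaic_flag,
                        "transmitted": list(r.transmitted)}
                       for r in self.transmission], fh, indent=2, sort_keys=True)
        self.validations.to_csv(out / "validation.tsv", sep="\t", index=False)
        for profile in self.cnv_profiles:
            write_depth_tsv(profile, out / f"cnv_profile_{profile.label}.tsv")
        write_bed(segments_to_bed(self.cnv_segments), out / "cnv_segments.bed")
        write_pedigree(self.pedigree, out / "pedigree.tsv")
        events = []
        seen = set()
        for (sample, site), table in sorted(self.tables.items()):
            for sig, comp in sorted(table.composites.items()):
                if sig not in seen:
                    seen.add(sig)
                    events.append((site, sig, comp))
        write_events_vcf(out / "events.vcf", events, self.loci)
        self.config.to_yaml(out / "config.yaml")
        head = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in self.headline().items()}
        with open(out / "run.json", "w") as fh:
            json.dump({"version": __version__, "seed": self.config.seed,
                       "config_hash": self.config.config_hash,
                       "headline": head}, fh, indent=2, sort_keys=True)


def _with_artifact(pool: AllelePool, artifact: CompositeEvent,
                   rate: float) -> AllelePool:
    """Mix a shared artifact allele (e.g. homopolymer misalignment) into a
    pool at a fixed rate; emulates systematic errors present in every
    sample including controls."""
    if rate <= 0:
        return pool
    pairs = [(a, f * (1 - rate)) for a, f in pool.alleles]
    pairs.append((artifact, rate))
    return AllelePool(tuple(pairs), pool.origin, pool.locus_name)


def build_study(cfg: AnalysisConfig):
    """Deterministically construct guide, loci and planted truth."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in ss.generate_state(8) >> np.uint32(1)]
    rng = np.random.default_rng(seeds[0])
    protospacer = random_dna(rng, 20)
    cut = cfg.locus_length // 2
    names = (["on_target"]
             + [f"offtarget_{i + 1}" for i in range(len(cfg.offtarget_efficiencies))]
             + ["decoy"])
    raw = [ReferenceLocus(n, random_dna(rng, cfg.locus_length), cut)
           for n in names]
    mismatches = [0, *cfg.offtarget_mismatches, cfg.decoy_mismatches]
    pam_modes = ["canonical", *cfg.offtarget_pam_modes, "canonical"]
    loci_list, planted = plant_offtarget_sites(raw, GuideSpec("guide", protospacer),
                                               mismatches, pam_modes, seed=seeds[1])
    loci = {l.name: l for l in loci_list}
    guide = GuideSpec("guide", protospacer, intended_locus="on_target",
                      intended_cut=cut)
    return guide, loci, planted, seeds


def run_experiment(cfg: AnalysisConfig) -> RunReport:
    cfg.validate()
    th = cfg.thresholds
    guide, loci, planted, seeds = build_study(cfg)
    on = "on_target"
    analysis_loci = {n: l for n, l in loci.items() if n != "decoy"}

    # --- off-target mapping from the cleavage assay -----------------------
    try:
        termini = emit_cleavage_reads(list(loci.values()), planted,
                                      cfg.cleavage_depth, cfg.cleavage_background,
                                      seed=seeds[2], reads_per_site=cfg.reads_per_site)
        candidates = detect_cleavage_candidates(termini)
        sites = call_sites(candidates, loci, guide, cfg.score_threshold,
                           cfg.window_half_width)
        site_table = pd.DataFrame(
            [(s.locus, s.position, s.strand, s.alignment_score,
              s.n_substitutions, s.n_gap_columns, s.pam_status,
              s.classification, s.support) for s in sites],
            columns=["locus", "position", "strand", "score", "n_substitutions",
                     "n_gap_columns", "pam_status", "classification", "support"])
    except Exception as exc:                       # pragma: no cover
        raise StageError("offtarget_map", "cleavage_assay", exc) from exc

    # --- simulate founders, crosses and reads -----------------------------
    site_sims = []
    for name, locus in analysis_loci.items():
        if name == on:
            eff, g_eff = cfg.on_target_efficiency, 1.0
        else:
            idx = int(name.split("_")[1]) - 1
            eff = g_eff = cfg.offtarget_efficiencies[idx]
        site_sims.append(SiteSim(locus, efficiency=eff, germline_efficiency=g_eff,
                                 at_repeat_germline=False))
    sim = SimConfig(seed=cfg.seed, error_rate=cfg.error_rate,
                    sv_fraction=cfg.sv_fraction, sv_max_del=cfg.sv_max_del,
                    sv_max_ins=cfg.sv_max_ins, sites=tuple(site_sims))
    artifact = CompositeEvent((EditEvent(
        INSERTION, loci[on].cut_position + 10, loci[on].cut_position + 10, "G"),))

    pairs = [f"pair{chr(ord('A') + i)}" for i in range(cfg.n_pairs)]
    founders: dict[str, FounderTruth] = {}
    offspring: dict[str, list[F1Truth]] = {}
    pool_truth: dict[str, list[F1Truth]] = {}
    for pi, pair in enumerate(pairs):
        for fi in (1, 2):
            fid = f"F0_{pair[-1]}{fi}"
            f_sim = sim
            if pi == len(pairs) - 1 and fi == 1:
                # last pair, first parent: germline AT-repeat allele at the
                # on-target site (exercises the dropout path)
                f_sim = dataclasses.replace(
                    sim, sites=tuple(
                        dataclasses.replace(s, at_repeat_germline=(s.name == on))
                        for s in sim.sites))
            founders[fid] = simulate_founder(f_sim, seeds[3] + 97 * pi + fi, fid)
        a, b = f"F0_{pair[-1]}1", f"F0_{pair[-1]}2"
        offspring[pair] = cross(founders[a], founders[b], cfg.n_offspring,
                                seeds[4] + 13 * pi, pair_id=pair)
        pool_truth[pair] = cross(founders[a], founders[b], cfg.pool_members,
                                 seeds[4] + 13 * pi + 7, pair_id=f"{pair}_pool")

    tables: dict[tuple[str, str], EventTable] = {}
    ped_rows = []
    read_seed = seeds[5]

    def emit_and_classify(truth, sample_id, depth, sim_cfg):
        nonlocal read_seed
        for name, locus in sorted(analysis_loci.items()):
            read_seed += 1
            try:
                src = truth if not isinstance(truth, dict) else truth[name]
                reads, _ = emit_amplicon_reads(src, locus, sim_cfg, read_seed,
                                               sample_id, depth=depth)
                outcomes = classify_reads(reads, locus, cfg.attribution_window)
                tables[(sample_id, name)] = tabulate(outcomes, sample_id, locus)
            except Exception as exc:
                raise StageError("classification", f"{sample_id}@{name}", exc) from exc

    # uninjected control pool: wild type plus the shared artifact
    control_pools = {n: _with_artifact(
        AllelePool(((None, 1.0),), "somatic", n), artifact,
        cfg.artifact_rate if n == on else 0.0) for n in analysis_loci}
    emit_and_classify(control_pools, "F0wt_pool_1", cfg.control_depth, sim)
    ped_rows.append(("F0wt_pool_1", "F0_wt", "larvae", "pool", ""))

    # pooled founder larvae: many larvae per pool, hence many distinct
    # alleles - the sample type the study's efficiency and SV-size
    # figures are computed from
    for pi in range(cfg.n_f0_pools):
        pool_id = f"F0_larvae_pool_{pi + 1}"
        pools = {}
        for li, (name, locus) in enumerate(sorted(analysis_loci.items())):
            site = next(s for s in site_sims if s.name == name)
            pools[name] = _with_artifact(
                draw_editing_outcomes(sim, cfg.f0_pool_alleles,
                                      seeds[7] + 31 * pi + li, locus,
                                      include_wt=1 - site.efficiency),
                artifact, cfg.artifact_rate if name == on else 0.0)
        emit_and_classify(pools, pool_id, cfg.f0_pool_depth, sim)
        ped_rows.append((pool_id, "F0", "larvae", "pool", ""))

    for fid, truth in sorted(founders.items()):
        pools = {n: _with_artifact(truth.somatic_pools[n], artifact,
                                   cfg.artifact_rate if n == on else 0.0)
                 for n in analysis_loci}
        emit_and_classify(pools, fid, cfg.founder_depth, sim)
        ped_rows.append((fid, "F0", "adult", "individual", ""))
    for pair in pairs:
        for f1 in offspring[pair]:
            emit_and_classify(f1, f1.sample_id, cfg.f1_depth, sim)
            ped_rows.append((f1.sample_id, "F1", "juvenile", "individual", pair))
        pool_id = f"{pair}_larvae_pool"
        emit_and_classify({n: pool_truth[pair] for n in analysis_loci},
                          pool_id, cfg.pool_depth, sim)
        ped_rows.append((pool_id, "F1", "larvae", "pool", pair))
    pedigree = pd.DataFrame(ped_rows, columns=["sample_id", "generation",
                                               "stage", "type", "founder_pair"])

    # --- control-based filtering and per-sample summaries ------------------
    try:
        control_freqs = {n: control_indel_frequency(tables[("F0wt_pool_1", n)])
                         for n in analysis_loci}
        retained, _warned = filter_sites_by_control(control_freqs,
                                                    cfg.site_filter_threshold)
        for key in list(tables):
            sample, site = key
            if sample != "F0wt_pool_1":
                tables[key] = flag_control_events(tables[key],
                                                  tables[("F0wt_pool_1", site)])
        summaries = pd.DataFrame(
            [(s.sample_id, s.site, s.editing_efficiency, s.sv_fraction_of_edits,
              s.n_distinct_alleles, s.unassigned_fraction)
             for s in (summarize_sample(t, cfg.sv_min)
                       for (sm, st), t in sorted(tables.items()) if st in retained)],
            columns=["sample_id", "site", "editing_efficiency",
                     "sv_fraction_of_edits", "n_distinct_alleles",
                     "unassigned_fraction"])
    except Exception as exc:
        raise StageError("quantify", "all", exc) from exc

    # --- generational analysis --------------------------------------------
    wgs_tables: dict[tuple[str, str], EventTable] = {}
    geno_rows = []
    validations = []
    transmission = []
    wgs_sim = dataclasses.replace(sim, p_amplify_dropout=1.0,
                                  dropout_truncate_fraction=0.0)
    try:
        f1_by_pair = {p: [f1.sample_id for f1 in offspring[p]] for p in pairs}
        for pair in pairs:
            for f1 in offspring[pair]:
                for site in sorted(retained):
                    call = call_individual_genotype(tables[(f1.sample_id, site)], th)
                    if call.dropout_flag:
                        read_seed += 1
                        reads, _ = emit_amplicon_reads(
                            f1, analysis_loci[site], wgs_sim, read_seed,
                            f"{f1.sample_id}__wgs", depth=cfg.wgs_depth)
                        outc = classify_reads(reads, analysis_loci[site],
                                              cfg.attribution_window)
                        wtab = tabulate(outc, f"{f1.sample_id}__wgs",
                                        analysis_loci[site])
                        wgs_tables[(f1.sample_id, site)] = wtab
                        call = reconcile_with_unamplified(call, wtab, th)
                    sizes = [abs(tables[(f1.sample_id, site)].composites[s].reported_size)
                             for s, _ in call.alleles if s != WT_SIGNATURE
                             and s in tables[(f1.sample_id, site)].composites]
                    geno_rows.append((f1.sample_id, site, call.zygosity,
                                      ",".join(f"{s}:{f:.3f}" for s, f in call.alleles),
                                      call.dropout_flag, call.resolution,
                                      call.recovered_allele,
                                      max(sizes, default=0)))
                    # sibling validation of called edited alleles
                    sibs = ([(tables[(s, site)], "individual")
                             for s in f1_by_pair[pair] if s != f1.sample_id]
                            + [(tables[(f"{pair}_larvae_pool", site)], "pool")])
                    unrelated = [(tables[(s, site)], "individual")
                                 for q in pairs if q != pair
                                 for s in f1_by_pair[q]]
                    for sig, _f in call.alleles:
                        if sig == WT_SIGNATURE:
                            continue
                        v = verify_event_in_relatives(sig, sibs, unrelated, th)
                        validations.append((f1.sample_id, site, sig, v.status,
                                            v.reason, len(v.supporting_samples),
                                            len(v.contamination_warnings)))
            pair_tables = ([(tables[(s, on)], "individual") for s in f1_by_pair[pair]]
                           + [(tables[(f"{pair}_larvae_pool", on)], "pool")])
            transmission.append(count_transmitted_alleles(pair_tables, pair, th))
        genotypes = pd.DataFrame(
            geno_rows, columns=["sample_id", "site", "zygosity", "alleles",
                                "dropout_flag", "resolution", "recovered_allele",
                                "max_allele_size"])
        validation_df = pd.DataFrame(
            validations, columns=["sample_id", "site", "signature", "status",
                                  "reason", "n_supporting", "n_contamination"])
    except Exception as exc:
        raise StageError("generational", "F1", exc) from exc

    # --- CNV screen (WGS-mode individuals) ---------------------------------
    try:
        profiles, segments = [], []
        for i in range(2):
            prof = emit_depth_track(cfg.cnv_genome_length, [],
                                    cfg.cnv_mean_depth, cfg.cnv_noise_cv,
                                    window=cfg.cnv_window, seed=seeds[6] + i)
            prof.label = f"wgs_{i + 1}"
            profiles.append(prof)
            segments.extend(call_cnv(normalize_profile(prof)))
    except Exception as exc:
        raise StageError("cnv_screen", "wgs", exc) from exc

    report = RunReport(cfg, guide, analysis_loci, site_table, tables,
                       wgs_tables, summaries, genotypes, transmission,
                       validation_df, profiles, segments, pedigree,
                       retained, termini)
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report
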