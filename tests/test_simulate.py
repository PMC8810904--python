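"""Synthetic-data generator: determinism, planted truth, sampling laws."""

import numpy as np
import pandas as pd
import pytest

from crisprlong.core import GuideSpec, longest_dinucleotide_run
from crisprlong.events import DELETION, INSERTION, WT_SIGNATURE
from crisprlong.simulate import (AllelePool, SimConfig, at_repeat_allele, cross,
                                 draw_editing_outcomes, emit_amplicon_reads,
                                 emit_cleavage_reads, emit_depth_track,
                                 make_locus, plant_offtarget_sites,
                                 simulate_founder, SiteSim, FounderTruth)


class TestMakeLocus:
    def test_constructor_contract(self):
        loc = make_locus(1000, 0.5, 500, seed=1)
        assert len(loc) == 1000 and loc.cut_position == 500

    def test_deterministic(self):
        assert make_locus(500, 0.4, 100, seed=9).sequence == \
            make_locus(500, 0.4, 100, seed=9).sequence

    def test_gc_zero_gives_at_only(self):
        loc = make_locus(200, 0.0, 100, seed=2)
        assert set(loc.sequence) <= {"A", "T"}

    def test_cut_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="cut_offset"):
            make_locus(500, 0.5, 500, seed=0)


class TestPlantSites:
    def test_zero_mismatch_embeds_query_exactly(self, guide):
        loci = [make_locus(600, 0.5, 300, seed=3)]
        out, truth = plant_offtarget_sites(loci, guide, [0], ["canonical"], seed=1)
        t = truth[0]
        embedded = out[0].sequence[t.start:t.start + 20]
        assert embedded == guide.protospacer
        pam = out[0].sequence[t.start + 20:t.start + 23]
        assert pam[1:] == "GG"

    @pytest.mark.parametrize("k", [2, 7])
    def test_hamming_distance_matches_request(self, guide, k):
        loci = [make_locus(600, 0.5, 300, seed=4)]
        out, truth = plant_offtarget_sites(loci, guide, [k], seed=7)
        site = out[0].sequence[truth[0].start:truth[0].start + 20]
        assert sum(a != b for a, b in zip(site, guide.protospacer)) == k

    def test_adjacent_pam_geometry(self, guide):
        loci = [make_locus(600, 0.5, 300, seed=5)]
        out, truth = plant_offtarget_sites(loci, guide, [1], ["adjacent"], seed=2)
        s = truth[0].start
        seq = out[0].sequence
        assert seq[s + 21] != "G"            # mismatch at NGG position 1
        assert seq[s + 22] == "G" and seq[s + 23] == "G"  # NGG 1 bp downstream

    def test_too_short_locus_rejected(self, guide):
        from crisprlong.core import ReferenceLocus
        tiny = ReferenceLocus("t", "ACGT" * 100, 5)
        with pytest.raises(ValueError, match="too short"):
            plant_offtarget_sites([tiny], guide, [0], seed=0)


class TestDrawOutcomes:
    def test_sv_fraction_zero_switches_off_tail(self, locus600):
        cfg = SimConfig(sv_fraction=0.0, sv_max_del=200, sv_max_ins=200)
        pool = draw_editing_outcomes(cfg, 30, seed=1, locus=locus600)
        assert all(abs(a.reported_size) < 50 for a, _ in pool.alleles)

    def test_sv_fraction_one_forces_tail(self, locus600):
        cfg = SimConfig(sv_fraction=1.0, delins_fraction=0.0,
                        sv_max_del=200, sv_max_ins=200)
        pool = draw_editing_outcomes(cfg, 50, seed=2, locus=locus600)
        sizes = [abs(a.reported_size) for a, _ in pool.alleles]
        assert all(50 <= s <= 200 for s in sizes)

    def test_sv_share_matches_bernoulli_oracle(self, locus600):
        # the SV/small choice is a per-draw Bernoulli(sv_fraction): the
        # empirical share over 10,000 i.i.d. draws must sit within 3
        # binomial SE of an independent Bernoulli sampling oracle
        from crisprlong.simulate import draw_events
        cfg = SimConfig(sv_fraction=0.06, sv_max_del=200, sv_max_ins=200)
        events = draw_events(cfg, 10_000, seed=100, locus=locus600)
        share = np.mean([abs(e.reported_size) >= 50 for e in events])
        oracle = np.random.default_rng(555).random(10_000) < 0.06
        se = (0.06 * 0.94 / 10_000) ** 0.5
        assert abs(share - 0.06) <= 3 * se
        assert abs(oracle.mean() - 0.06) <= 3 * se  # oracle sanity

    def test_single_allele_degenerate(self, locus600):
        pool = draw_editing_outcomes(SimConfig(sv_max_del=200, sv_max_ins=200),
                                     1, seed=3, locus=locus600)
        assert len(pool.alleles) == 1
        assert pool.alleles[0][1] == pytest.approx(1.0)

    def test_signatures_unique_within_pool(self, locus600):
        cfg = SimConfig(sv_max_del=200, sv_max_ins=200)
        pool = draw_editing_outcomes(cfg, 25, seed=4, locus=locus600)
        sigs = pool.signatures(locus600)
        assert len(sigs) == len(set(sigs))

    def test_frequencies_form_simplex(self, locus600):
        cfg = SimConfig(sv_max_del=200, sv_max_ins=200)
        pool = draw_editing_outcomes(cfg, 10, seed=5, locus=locus600,
                                     include_wt=0.3)
        freqs = [f for _, f in pool.alleles]
        assert all(f >= 0 for f in freqs)
        assert sum(freqs) == pytest.approx(1.0)
        assert pool.alleles[0][0] is None and pool.alleles[0][1] == pytest.approx(0.3)


def _pool(alleles):
    return AllelePool(tuple(alleles), origin="germline", locus_name="amp")


def _founder(fid, site, pool):
    return FounderTruth(fid, {site: pool}, {site: pool})


class TestCross:
    def test_wt_parents_give_wt_offspring(self, locus600):
        wt = _pool([(None, 1.0)])
        kids = cross(_founder("a", "amp", wt), _founder("b", "amp", wt), 20, seed=1)
        assert all(k.alleles["amp"] == (None, None) for k in kids)

    def test_two_allele_parents_bounded_by_four(self, locus600):
        cfg = SimConfig(sv_max_del=200, sv_max_ins=200)
        pa = draw_editing_outcomes(cfg, 2, seed=6, locus=locus600)
        pb = draw_editing_outcomes(cfg, 2, seed=7, locus=locus600)
        kids = cross(_founder("a", "amp", pa), _founder("b", "amp", pb), 200, seed=2)
        seen = {sig for k in kids for sig in
                (("WT" if a is None else a.signature(locus600))
                 for a in k.alleles["amp"])}
        assert len(seen) <= 4

    def test_mosaic_parents_transmit_over_four(self, locus600):
        # 3+3 disjoint germline alleles at balanced frequencies, 200
        # offspring: the union bound on the multinomial probability that
        # any of the 6 alleles is missed is sum_i (1 - f_i)^200 < 1e-9
        from crisprlong.simulate import draw_events
        cfg = SimConfig(sv_max_del=200, sv_max_ins=200)
        events = iter(draw_events(cfg, 20, seed=8, locus=locus600))
        freqs = (0.4, 0.35, 0.25)
        sigs = set()
        def balanced():
            picked = []
            while len(picked) < 3:
                e = next(events)
                if e.signature(locus600) not in sigs:
                    sigs.add(e.signature(locus600))
                    picked.append(e)
            return _pool(list(zip(picked, freqs)))
        pa, pb = balanced(), balanced()
        miss = sum((1 - f) ** 200 for pool in (pa, pb) for _, f in pool.alleles)
        assert miss < 1e-9
        kids = cross(_founder("a", "amp", pa), _founder("b", "amp", pb), 200, seed=3)
        seen = {a.signature(locus600) for k in kids for a in k.alleles["amp"]}
        assert len(seen) >= 5


class TestEmitAmpliconReads:
    def test_error_free_wt_reads_equal_reference(self, locus600):
        cfg = SimConfig(error_rate=0.0)
        pool = _pool([(None, 1.0)])
        reads, truth = emit_amplicon_reads(pool, locus600, cfg, seed=1,
                                           depth=20)
        assert all(seq == locus600.amplicon for _, seq in reads)
        assert set(truth.allele_signature) == {WT_SIGNATURE}

    def test_planted_deletion_share_within_binomial_se(self):
        from crisprlong.events import CompositeEvent, EditEvent
        locus = make_locus(2000, 0.5, 1000, seed=21, name="big")
        allele = CompositeEvent((EditEvent(DELETION, 700, 1603),))  # 903 bp
        cfg = SimConfig(error_rate=0.0)
        pool = _pool([(None, 0.6), (allele, 0.4)])
        reads, truth = emit_amplicon_reads(pool, locus, cfg, seed=2, depth=2000)
        share = (truth.allele_signature != WT_SIGNATURE).mean()
        se = (0.4 * 0.6 / 2000) ** 0.5
        assert abs(share - 0.4) <= 3 * se
        # reads carrying the deletion are 903 bp shorter
        short = sum(len(s) == len(locus.amplicon) - 903 for _, s in reads)
        assert short == (truth.allele_signature != WT_SIGNATURE).sum()

    def test_forced_dropout_removes_repeat_allele(self, locus600):
        rep = at_repeat_allele(locus600, 32)
        other = _pool([(None, 0.5), (rep, 0.5)])
        cfg = SimConfig(error_rate=0.0, p_amplify_dropout=0.0)
        reads, truth = emit_amplicon_reads(other, locus600, cfg, seed=3,
                                           depth=400)
        assert set(truth.allele_signature) == {WT_SIGNATURE}
        assert len(reads) < 400  # dropped molecules reduce depth

    def test_event_outside_primer_span_rejected(self):
        from crisprlong.core import ReferenceLocus
        from crisprlong.events import CompositeEvent, EditEvent
        loc = make_locus(600, 0.5, 300, seed=30)
        loc = ReferenceLocus(loc.name, loc.sequence, 300, primer_span=(100, 500))
        bad = CompositeEvent((EditEvent(DELETION, 50, 120),))
        with pytest.raises(ValueError, match="not amplifiable"):
            emit_amplicon_reads(_pool([(bad, 1.0)]), loc, SimConfig(), seed=1,
                                depth=5)

    def test_truth_table_exhaustive(self, locus600):
        cfg = SimConfig(error_rate=0.005)
        pool = draw_editing_outcomes(cfg, 5, seed=10, locus=locus600,
                                     include_wt=0.2)
        reads, truth = emit_amplicon_reads(pool, locus600, cfg, seed=4,
                                           depth=300)
        assert len(reads) == len(truth)
        assert sorted(r for r, _ in reads) == sorted(truth.read_id)

    def test_bit_reproducible(self, locus600):
        cfg = SimConfig(error_rate=0.01)
        pool = draw_editing_outcomes(cfg, 4, seed=11, locus=locus600)
        r1, t1 = emit_amplicon_reads(pool, locus600, cfg, seed=5, depth=50)
        r2, t2 = emit_amplicon_reads(pool, locus600, cfg, seed=5, depth=50)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)


class TestEmitCleavageReads:
    def test_no_background_all_termini_at_cut(self, guide):
        loci, truth = plant_offtarget_sites([make_locus(600, 0.5, 300, seed=6)],
                                            guide, [0], seed=1)
        rec = emit_cleavage_reads(loci, truth, depth=100, background_fraction=0.0,
                                  seed=1, reads_per_site=30)
        assert set(rec.coordinate) == {300}
        assert set(rec.orientation) == {"+", "-"}

    def test_pileup_heights_at_three_sites(self, guide):
        loci = [make_locus(600, 0.5, p, seed=40 + i, name=f"m{i}")
                for i, p in enumerate((150, 300, 450))]
        loci, truth = plant_offtarget_sites(loci, guide, [0, 1, 2], seed=2)
        rec = emit_cleavage_reads(loci, truth, depth=500, background_fraction=1.0,
                                  seed=3, reads_per_site=20)
        counts = rec.groupby(["locus", "coordinate"]).size()
        tall = counts[counts >= 20]
        assert len(tall) == 3

    def test_uniform_background_has_no_tall_pileup(self):
        locus = make_locus(10_000, 0.5, 5000, seed=7, name="bg")
        rec = emit_cleavage_reads([locus], [], depth=500,
                                  background_fraction=1.0, seed=4)
        max_pile = rec.groupby("coordinate").size().max()
        assert max_pile < 8


class TestEmitDepthTrack:
    def test_flat_noiseless(self):
        prof = emit_depth_track(500_000, [], 30.0, 0.0, window=50_000, seed=1)
        assert np.allclose(prof.depths, 30.0)

    def test_half_ratio_segment_expectation(self):
        prof = emit_depth_track(1_000_000, [((200_000, 450_000), 0.5)],
                                30.0, 0.0, window=50_000, seed=2)
        assert np.allclose(prof.depths[4:9], 15.0)
        assert np.allclose(np.delete(prof.depths, range(4, 9)), 30.0)

    def test_noise_cv_recovered(self):
        prof = emit_depth_track(50_000_000, [], 100.0, 0.05, window=50_000,
                                seed=3)
        cv = prof.depths.std() / prof.depths.mean()
        assert 0.04 <= cv <= 0.06

    def test_window_larger_than_genome_rejected(self):
        with pytest.raises(ValueError, match="window"):
            emit_depth_track(10_000, [], 30.0, 0.0, window=50_000, seed=0)


class TestFounder:
    def test_pools_respect_efficiency_and_origin(self, locus600):
        site = SiteSim(locus600, efficiency=0.9, germline_efficiency=1.0,
                       n_germline_alleles=3)
        cfg = SimConfig(sv_max_del=200, sv_max_ins=200, sites=(site,))
        f = simulate_founder(cfg, seed=1, founder_id="F0_x")
        som = f.somatic_pools["amp"]
        germ = f.germline_pools["amp"]
        assert som.alleles[0][0] is None
        assert som.alleles[0][1] == pytest.approx(0.1)
        assert all(a is not None for a, _ in germ.alleles)
        assert len(germ.alleles) == 3

    def test_at_repeat_flagging(self, locus600):
        rep = at_repeat_allele(locus600, 32)
        assert longest_dinucleotide_run(rep.sub_events[0].seq) == 32
        assert longest_dinucleotide_run("A" * 70) == 0  # homopolymer excluded
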