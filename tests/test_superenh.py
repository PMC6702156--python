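import math

import numpy as np
import pytest

from corecirc import (
    FragmentTrack,
    GenomicInterval,
    Peak,
    TSSRecord,
    active_genes,
    assign_to_genes,
    merge_intervals,
    nucleosome_free_regions,
    region_density,
    score_and_rank,
    stitch_enhancers,
    super_cutoff,
)
from corecirc.superenh import StitchedRegion

from ._oracles import cutoff_oracle


def peak(start, end, chrom="chr1", signal=1.0):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2, signal)


def tss(gene_id, pos, symbol=None, chrom="chr1", is_tf=False):
    return TSSRecord(
        gene_id, symbol or gene_id, GenomicInterval(chrom, pos, pos + 1, "+"), is_tf
    )


def region(start, end, name, signal=0.0, chrom="chr1"):
    return StitchedRegion(
        interval=GenomicInterval(chrom, start, end),
        constituents=(),
        total_signal=signal,
        name=name,
    )


class TestActiveGenes:
    def test_distance_boundary_in_a_single_line(self):
        # peak ends at 5000; TSS at 5999 is 999 bp away -> active (any line
        # suffices); TSS at 6001 is 1001 bp away -> inactive
        sets = {"L1": [peak(4000, 5000)], "L2": [], "L3": [], "L4": []}
        genes = [tss("G1", 5999), tss("G2", 6001), tss("G3", 6000)]
        active = active_genes(genes, sets, window=1000)
        assert active == {"G1", "G3"}  # exactly 1000 bp counts as within

    def test_any_transcript_tss_qualifies(self):
        sets = {"L1": [peak(10_000, 10_500)]}
        genes = [tss("G1", 500_000), tss("G1", 10_600)]
        assert active_genes(genes, sets, window=1000) == {"G1"}


class TestStitchEnhancers:
    def test_promoter_peak_removed_entirely(self):
        sets = {"L1": [peak(9_900, 10_100)]}
        assert stitch_enhancers(sets, [tss("G1", 10_000)]) == []

    def test_peaks_within_stitch_distance_merge(self):
        sets = {"L1": [peak(10_000, 11_000), peak(12_000, 12_500)]}
        (r,) = stitch_enhancers(sets, [])
        assert (r.interval.start, r.interval.end) == (10_000, 12_500)
        assert len(r.constituents) == 2

    def test_gap_beyond_stitch_distance_stays_split(self):
        sets = {"L1": [peak(10_000, 11_000), peak(13_000, 13_500)]}
        rs = stitch_enhancers(sets, [])
        assert len(rs) == 2  # 2000 > 1638

    def test_partially_overlapping_tss_zone_peak_is_kept(self):
        # only peaks entirely inside the exclusion zone are dropped
        sets = {"L1": [peak(11_000, 14_000)]}
        (r,) = stitch_enhancers(sets, [tss("G1", 10_000)])
        assert (r.interval.start, r.interval.end) == (11_000, 14_000)

    def test_raising_stitch_never_increases_regions_or_loses_bases(self, rng):
        sets = {
            "L1": [
                peak(int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 60_000, 25), rng.integers(200, 2000, 25))
            ]
        }
        prev_n, prev_bases = None, None
        for stitch in (0, 500, 1638, 5000):
            rs = stitch_enhancers(sets, [], stitch=stitch)
            n = len(rs)
            bases = sum(len(r.interval) for r in rs)
            if prev_n is not None:
                assert n <= prev_n
                assert bases >= prev_bases
            prev_n, prev_bases = n, bases


class TestScoreAndRank:
    def test_signal_is_density_times_length(self, rng):
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 20_000, 500)
        ]
        track = FragmentTrack(frags, 1_000_000)
        regions = [region(1000, 3000, "a"), region(8000, 8500, "b")]
        ranked = score_and_rank(regions, track)
        for r in ranked:
            d = region_density(track, r.interval)
            assert r.density_signal == pytest.approx(d)
            assert r.total_signal == pytest.approx(d * len(r.interval))

    def test_control_subtraction_floors_at_zero(self):
        t = FragmentTrack([GenomicInterval("chr1", 100, 150)], 1000)
        ctrl = FragmentTrack(
            [GenomicInterval("chr1", 100, 150)] * 5, 1000, label="input"
        )
        (r,) = score_and_rank([region(0, 1000, "a")], t, control=ctrl)
        assert r.density_signal == 0.0
        assert r.total_signal == 0.0

    def test_tie_break_longer_region_then_coordinates(self):
        t = FragmentTrack([], 1000)
        regions = [region(0, 100, "short"), region(5000, 5300, "long"), region(200, 300, "short2")]
        ranked = score_and_rank(regions, t)  # all zero signal
        assert [r.name for r in ranked] == ["long", "short", "short2"]
        assert [r.rank for r in ranked] == [1, 2, 3]


class TestSuperCutoff:
    def make(self, signals):
        return [
            region(i * 1000, i * 1000 + 500, f"r{i}", signal=s)
            for i, s in enumerate(signals)
        ]

    def test_all_equal_signals_no_superenhancers(self):
        with pytest.warns(UserWarning):
            _, flagged = super_cutoff(self.make([5.0] * 6))
        assert not any(r.is_super for r in flagged)

    def test_two_outliers_flagged(self):
        cutoff, flagged = super_cutoff(self.make([1, 1, 1, 1, 1, 1, 1, 1, 10, 100]))
        supers = sorted(r.total_signal for r in flagged if r.is_super)
        assert supers == [10, 100]
        assert cutoff == 10

    def test_linear_signals_have_no_slope_above_one(self):
        # exactly linear: scaled slope == 1 everywhere, never exceeds it
        _, flagged = super_cutoff(self.make(list(range(1, 21))))
        assert not any(r.is_super for r in flagged)
        assert cutoff_oracle(range(1, 21)) == math.inf

    def test_matches_exhaustive_rank_scan_on_hockey_sticks(self, rng):
        for _ in range(100):
            n_body = int(rng.integers(10, 60))
            n_tail = int(rng.integers(1, 6))
            body = rng.lognormal(2.0, 0.5, n_body)
            tail = rng.lognormal(6.0, 0.3, n_tail)
            signals = np.concatenate([body, tail])
            cutoff, flagged = super_cutoff(self.make(signals))
            assert cutoff == cutoff_oracle(signals)
            expected = {r.name for r in flagged if r.total_signal >= cutoff}
            assert {r.name for r in flagged if r.is_super} == expected

    def test_super_set_is_prefix_of_ranking(self, rng):
        signals = np.concatenate([rng.lognormal(2, 1, 40), rng.lognormal(7, 0.5, 3)])
        _, flagged = super_cutoff(self.make(signals))
        supers = [r.total_signal for r in flagged if r.is_super]
        others = [r.total_signal for r in flagged if not r.is_super]
        if supers and others:
            assert min(supers) >= max(others)


class TestAssignToGenes:
    def test_overlapping_proximal_closest(self):
        se = region(100_000, 110_000, "se1")
        se = StitchedRegion(se.interval, (), 1.0, 1.0, 1, True, "se1")
        genes = [
            tss("IN", 105_000),
            tss("NEAR", 140_000),  # 30 kb -> proximal
            tss("FAR", 170_000),  # 60 kb -> not proximal, not closest
        ]
        got = {(a.gene_id, a.relation) for a in assign_to_genes([se], genes)}
        assert got == {("IN", "overlapping"), ("NEAR", "proximal")}

    def test_closest_only_when_nothing_in_window(self):
        se = region(100_000, 110_000, "se1")
        genes = [tss("A", 300_000), tss("B", 500_000)]
        got = assign_to_genes([se], genes)
        assert [(a.gene_id, a.relation) for a in got] == [("A", "closest")]

    def test_gene_on_other_chromosome_never_assigned(self):
        se = region(0, 1000, "se1")
        assert assign_to_genes([se], [tss("X", 500, chrom="chr9")]) == []


class TestNucleosomeFreeRegions:
    def setup_scene(self):
        se = StitchedRegion(
            GenomicInterval("chr1", 10_000, 20_000), (), 1.0, 1.0, 1, True, "se1"
        )
        from corecirc.superenh import GeneAssignment

        assign = [GeneAssignment("se1", "G1", "proximal", 100)]
        return se, assign

    def test_straddling_atac_peak_excluded(self):
        se, assign = self.setup_scene()
        atac = {"L1": [peak(19_500, 20_500)]}
        assert nucleosome_free_regions(atac, [se], {"G1"}, assign) == []

    def test_se_of_inactive_gene_excluded(self):
        se, assign = self.setup_scene()
        atac = {"L1": [peak(12_000, 12_700)]}
        assert nucleosome_free_regions(atac, [se], set(), assign) == []

    def test_overlapping_atac_peaks_merge_into_one_nfr(self):
        se, assign = self.setup_scene()
        atac = {"L1": [peak(12_000, 12_700)], "L2": [peak(12_500, 13_100)]}
        (nfr,) = nucleosome_free_regions(atac, [se], {"G1"}, assign)
        assert (nfr.interval.start, nfr.interval.end) == (12_000, 13_100)
        assert nfr.se_id == "se1"
        merged = merge_intervals([peak(12_000, 12_700).interval, peak(12_500, 13_100).interval], 0)
        assert nfr.interval == merged[0]
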