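"""Co-binding overlap, TSS windows, pileups and moving-average profiles."""

import numpy as np
import pytest

from chromdyn import (
    GeneRecord,
    GenomicInterval,
    SignalTrack,
    assign_loci_to_genes,
    mark_cobinding_presence,
    moving_average_profile,
    overlap_binding,
    pileup_profile,
)
from chromdyn.cobinding import smooth_indicator, tss_distance

from conftest import random_intervals, random_track


def gene(i, tss, chrom="chr1", fc=0.0):
    return GeneRecord(f"G{i:03d}", chrom, tss, "+", fc)


class TestOverlap:
    def test_self_overlap_is_total(self, rng):
        ivs = random_intervals(rng, 20)
        result = overlap_binding(ivs, ivs)
        assert result.fraction == 1.0
        assert result.n_a == result.n_a_overlapping_b

    def test_disjoint_sets_share_nothing(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300), GenomicInterval("chr2", 0, 100)]
        result = overlap_binding(a, b)
        assert result.fraction == 0.0
        assert result.shared == []

    def test_empty_a_set_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            overlap_binding([], [GenomicInterval("chr1", 0, 1)])

    def test_translation_invariance(self, rng):
        a = random_intervals(rng, 15)
        b = random_intervals(rng, 15)
        shift = 12_345
        a2 = [GenomicInterval(iv.chrom, iv.start + shift, iv.end + shift) for iv in a]
        b2 = [GenomicInterval(iv.chrom, iv.start + shift, iv.end + shift) for iv in b]
        r1, r2 = overlap_binding(a, b), overlap_binding(a2, b2)
        assert (r1.n_a, r1.n_b, r1.n_a_overlapping_b) == (
            r2.n_a, r2.n_b, r2.n_a_overlapping_b
        )

    def test_min_overlap_is_one_bp_by_default(self):
        a = [GenomicInterval("chr1", 0, 101)]
        b = [GenomicInterval("chr1", 100, 200)]
        assert overlap_binding(a, b).fraction == 1.0
        # book-ended only: zero shared bases
        assert overlap_binding([GenomicInterval("chr1", 0, 100)], b).fraction == 0.0


class TestGeneAssignment:
    def test_locus_containing_tss_has_distance_zero(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert tss_distance(iv, 150) == 0
        g2l, _ = assign_loci_to_genes([iv], [gene(0, 150)], window=0)
        assert g2l["G000"] == [0]

    def test_window_boundary_is_inclusive_then_exclusive(self):
        iv = GenomicInterval("chr1", 1000, 2000)  # last covered base 1999
        inside = gene(0, 1999 + 10_000)
        outside = gene(1, 1999 + 10_001)
        g2l, _ = assign_loci_to_genes([iv], [inside, outside], window=10_000)
        assert g2l["G000"] == [0]
        assert g2l["G001"] == []

    def test_assignment_monotone_in_window(self, rng):
        loci = random_intervals(rng, 50, contig_len=1_000_000, max_len=500)
        genes = [gene(i, int(t)) for i, t in
                 enumerate(rng.integers(0, 1_000_000, size=40))]
        previous: dict[str, set] = {g.gene_id: set() for g in genes}
        for window in (0, 1_000, 5_000, 10_000, 50_000):
            g2l, _ = assign_loci_to_genes(loci, genes, window)
            for g in genes:
                assert previous[g.gene_id] <= set(g2l[g.gene_id])
                previous[g.gene_id] = set(g2l[g.gene_id])

    def test_matches_brute_force_distances(self, rng):
        loci = random_intervals(rng, 80, contig_len=1_000_000, max_len=400)
        genes = [gene(i, int(t)) for i, t in
                 enumerate(rng.integers(0, 1_000_000, size=60))]
        g2l, l2g = assign_loci_to_genes(loci, genes, window=10_000)
        for g in genes:
            expected = [
                idx for idx, iv in enumerate(loci)
                if tss_distance(iv, g.tss) <= 10_000
            ]
            assert sorted(g2l[g.gene_id]) == expected
        for idx, gene_ids in l2g.items():
            for gid in gene_ids:
                assert idx in g2l[gid]


class TestPresenceMarking:
    def test_no_shared_loci_gives_all_zero(self):
        genes = [gene(i, 1_000 * i + 100) for i in range(5)]
        np.testing.assert_array_equal(
            mark_cobinding_presence(genes, []), np.zeros(5, dtype=int)
        )

    def test_locus_at_every_tss_gives_all_one(self):
        genes = [gene(i, 10_000 * i + 500) for i in range(5)]
        loci = [GenomicInterval("chr1", g.tss - 10, g.tss + 10) for g in genes]
        np.testing.assert_array_equal(
            mark_cobinding_presence(genes, loci), np.ones(5, dtype=int)
        )


class TestMovingAverage:
    def test_hand_computed_truncated_window_means(self):
        smoothed = smooth_indicator([1, 0, 1, 0, 1], 3)
        np.testing.assert_allclose(smoothed, [0.5, 2 / 3, 1 / 3, 2 / 3, 0.5])

    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_constant_indicator_smooths_to_constant(self, value):
        np.testing.assert_array_equal(
            smooth_indicator([value] * 7, 5), np.full(7, value)
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_indicator([1, 0], 2)

    def test_reversal_symmetry(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            window = 2 * int(rng.integers(0, 6)) + 1
            ind = (rng.random(n) < 0.4).astype(float)
            np.testing.assert_allclose(
                smooth_indicator(ind[::-1], window),
                smooth_indicator(ind, window)[::-1],
            )

    def test_profile_sorts_by_fold_change_with_id_tiebreak(self):
        genes = [
            GeneRecord("b", "chr1", 0, "+", 1.0),
            GeneRecord("a", "chr1", 100, "+", 1.0),
            GeneRecord("c", "chr1", 200, "+", 3.0),
        ]
        prof = moving_average_profile(genes, [0, 1, 1], window_genes=1)
        assert prof.gene_ids == ["c", "a", "b"]
        np.testing.assert_array_equal(prof.indicator, [1, 1, 0])
        np.testing.assert_array_equal(prof.smoothed, [1, 1, 0])

    def test_indicator_misalignment_rejected(self):
        with pytest.raises(ValueError):
            moving_average_profile([gene(0, 10)], [1, 0])


class TestPileup:
    def test_uniform_track_gives_flat_profile(self):
        track = SignalTrack.from_segments([("chr1", 0, 100_000, 2.5)])
        loci = [GenomicInterval("chr1", 40_000, 40_400),
                GenomicInterval("chr1", 60_000, 60_400)]
        prof = pileup_profile(loci, track, flank=2_000, bin_size=50)
        assert len(prof.values) == 80
        np.testing.assert_allclose(prof.values, 2.5)

    def test_zero_track_gives_flat_zero(self):
        prof = pileup_profile(
            [GenomicInterval("chr1", 5_000, 5_200)], SignalTrack(), 1_000, 100
        )
        np.testing.assert_array_equal(prof.values, np.zeros(20))

    def test_mass_conservation_over_bins(self, rng):
        track = random_track(rng, n_segments=25)
        loci = [GenomicInterval("chr1", int(s), int(s) + 200)
                for s in rng.integers(2_000, 7_000, size=6)]
        flank, bin_size = 1_000, 50
        prof = pileup_profile(loci, track, flank, bin_size)
        captured = sum(
            track.sum_over(iv.chrom, iv.center - flank, iv.center + flank)
            for iv in loci
        )
        assert prof.values.sum() * bin_size * prof.n_loci == pytest.approx(captured)

    def test_empty_locus_list_rejected(self, rng):
        with pytest.raises(ValueError):
            pileup_profile([], random_track(rng), 1_000, 50)

    def test_flank_must_be_multiple_of_bin(self, rng):
        with pytest.raises(ValueError):
            pileup_profile([GenomicInterval("chr1", 0, 10)], random_track(rng), 1_000, 300)
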