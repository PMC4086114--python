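import io

import numpy as np
import pytest

from rbpscan.regions import (
    ConservationTrack,
    GenomicInterval,
    RegionAnnotation,
    classify,
    conservation_filter,
    intronic_reference_mean,
    mean_conservation,
    splice_flank_intervals,
)
from rbpscan.synth import toy_conservation_track, toy_gene_model
from rbpscan.wr import BindingSite


def _iv(pos, chrom="chrT", width=7):
    return GenomicInterval(chrom, pos - width // 2, pos - width // 2 + width)


def _site(region_class, genomic_start=None, chrom=None, seq_id="s", kmer="ACGUACG"):
    return BindingSite(
        seq_id=seq_id, anchor_offset=0, motif_id="m", protein="P", kmer=kmer,
        match_score=0.9, wr_score=0.95, region_class=region_class,
        genomic_start=genomic_start, chrom=chrom,
    )


class TestClassify:
    def test_all_six_classes_match_hand_annotation(self, gene_model):
        for region, mid in gene_model.probe_points.items():
            assert classify(gene_model.annotation, _iv(mid)) == region

    def test_splice_flank_distance_thresholds(self, gene_model):
        # exon1 ends at 1950 (0-based exclusive); 40 nt into the intron
        assert classify(gene_model.annotation, _iv(1990)) == "splice_flank"
        # 400 nt from any exon edge, still intronic
        assert classify(gene_model.annotation, _iv(2350)) == "mid_intron_intergenic"

    def test_outside_any_gene_is_intergenic(self, gene_model):
        assert classify(gene_model.annotation, _iv(9000)) == "mid_intron_intergenic"

    def test_unknown_chrom_warns_and_defaults(self, gene_model):
        with pytest.warns(UserWarning, match="absent"):
            got = classify(gene_model.annotation, _iv(100, chrom="chrZ"))
        assert got == "mid_intron_intergenic"

    def test_deterministic_and_total(self, gene_model, rng):
        valid = set(
            "splice_flank internal_exon utr5_exon utr3_exon ncRNA "
            "mid_intron_intergenic".split()
        )
        for pos in rng.integers(10, 9990, size=200):
            c1 = classify(gene_model.annotation, _iv(int(pos)))
            c2 = classify(gene_model.annotation, _iv(int(pos)))
            assert c1 == c2 and c1 in valid

    def test_bed_round_trip(self, gene_model):
        ann = RegionAnnotation.from_bed(io.StringIO(gene_model.annotation_bed))
        for region, mid in gene_model.probe_points.items():
            assert classify(ann, _iv(mid)) == region


class TestMeanConservation:
    def test_constant_track(self):
        track = ConservationTrack([("chr1", 0, 1000, 0.7)])
        assert mean_conservation(track, GenomicInterval("chr1", 500, 507)) == pytest.approx(0.7)

    def test_half_zero_half_one(self):
        # environment of a 10-wide site centered so the 50-nt environment
        # spans 25 positions at 0 and 25 at 1
        track = ConservationTrack([("chr1", 0, 100, 0.0), ("chr1", 100, 200, 1.0)])
        site = GenomicInterval("chr1", 95, 105)
        assert mean_conservation(track, site) == pytest.approx(0.5)

    def test_sparse_track_matches_direct_sum(self, rng):
        ivs = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1, 10))
            width = int(rng.integers(1, 6))
            ivs.append(("chr1", pos, pos + width, float(rng.random())))
            pos += width
        track = ConservationTrack(ivs)
        site = GenomicInterval("chr1", 40, 47)
        env_start, env_end = 40 - 21, 40 - 21 + 50
        total, count = 0.0, 0
        for c, s, e, v in ivs:
            for p in range(s, e):
                if env_start <= p < env_end:
                    total += v
                    count += 1
        expected = total / count if count >= 25 else None
        got = mean_conservation(track, site)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_undercovered_environment_is_no_data(self):
        track = ConservationTrack([("chr1", 0, 20, 1.0)])
        assert mean_conservation(track, GenomicInterval("chr1", 10, 17)) is None


class TestIntronicReference:
    def test_constant_track_gives_constant(self, gene_model):
        track = ConservationTrack([("chrT", 0, 10_000, 0.42)])
        assert intronic_reference_mean(track, gene_model.annotation) == pytest.approx(0.42)

    def test_pooled_mean_of_two_levels(self):
        ann = RegionAnnotation.from_interval_lists(
            exons=[("c", 1000, 1200)], gene_bounds=[("c", 500, 2000)]
        )
        flanks = splice_flank_intervals(ann)
        assert flanks == [("c", 900, 1000), ("c", 1200, 1300)]
        track = ConservationTrack([("c", 900, 1000, 0.2), ("c", 1200, 1300, 0.8)])
        assert intronic_reference_mean(track, ann) == pytest.approx(0.5)

    def test_matches_brute_force_pooled_mean(self, gene_model):
        track, _ = toy_conservation_track(gene_model)
        flanks = splice_flank_intervals(gene_model.annotation)
        total, count = 0.0, 0
        for chrom, s, e in flanks:
            for p in range(s, e):
                c, t = track.coverage_sum(chrom, p, p + 1)
                count += c
                total += t
        assert intronic_reference_mean(track, gene_model.annotation) == pytest.approx(
            total / count
        )

    def test_uncovered_flanks_hard_error(self, gene_model):
        track = ConservationTrack([("chrT", 9000, 9100, 1.0)])
        with pytest.raises(ValueError, match="no splice-flank"):
            intronic_reference_mean(track, gene_model.annotation)


class TestConservationFilter:
    def _track(self):
        # [0,1000): conserved at 1.0; [1000,2000): zero
        return ConservationTrack([("chr1", 0, 1000, 1.0), ("chr1", 1000, 2000, 0.0)])

    def test_exonic_sites_exempt_even_over_zero_track(self):
        site = _site("internal_exon", genomic_start=1501, chrom="chr1")
        kept = conservation_filter([site], self._track(), reference=0.5)
        assert kept == [site]

    def test_intergenic_below_reference_removed_at_boundary_kept(self):
        low = _site("mid_intron_intergenic", genomic_start=1501, chrom="chr1")
        high = _site("mid_intron_intergenic", genomic_start=401, chrom="chr1")
        assert conservation_filter([low], self._track(), reference=0.5) == []
        # equal to the reference: strict "<" keeps the site
        kept = conservation_filter([high], self._track(), reference=1.0)
        assert len(kept) == 1 and kept[0].conservation_passed is True

    def test_no_data_sites_kept(self):
        off_track = _site("mid_intron_intergenic", genomic_start=5001, chrom="chr1")
        unanchored = _site("mid_intron_intergenic")
        kept = conservation_filter([off_track, unanchored], self._track(), 0.5)
        assert len(kept) == 2
        assert all(s.conservation_passed is None for s in kept)

    def test_disabled_filter_is_identity(self):
        sites = [_site("mid_intron_intergenic", genomic_start=1501, chrom="chr1")]
        assert conservation_filter(sites, self._track(), 0.5, enabled=False) == sites

    def test_raising_reference_never_keeps_more(self, rng):
        track = ConservationTrack(
            [("chr1", i * 100, (i + 1) * 100, float(v))
             for i, v in enumerate(rng.random(20))]
        )
        sites = [
            _site("mid_intron_intergenic", genomic_start=int(p), chrom="chr1")
            for p in rng.integers(50, 1950, size=30)
        ]
        sizes = [
            len(conservation_filter(sites, track, ref))
            for ref in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_membership_is_order_independent(self, rng):
        track = self._track()
        sites = [
            _site("mid_intron_intergenic", genomic_start=int(p), chrom="chr1",
                  seq_id=f"s{i}")
            for i, p in enumerate(rng.integers(50, 1950, size=20))
        ]
        kept_fwd = {s.seq_id for s in conservation_filter(sites, track, 0.5)}
        kept_rev = {s.seq_id for s in conservation_filter(sites[::-1], track, 0.5)}
        assert kept_fwd == kept_rev

    def test_mixed_fixture_matches_hand_filter(self):
        track = self._track()
        ref = 0.5
        sites, expected_kept = [], []
        for i, (pos, region) in enumerate([
            (200, "mid_intron_intergenic"),   # env mean 1.0 -> kept
            (1500, "mid_intron_intergenic"),  # env mean 0.0 -> removed
            (1500, "internal_exon"),          # exempt -> kept
            (990, "mid_intron_intergenic"),   # env straddles: mean ~0.66 -> kept
            (1010, "mid_intron_intergenic"),  # env mean ~0.26 -> removed
            (1500, "splice_flank"),           # exempt
            (1500, "utr3_exon"),              # exempt
            (300, "mid_intron_intergenic"),   # kept
            (1800, "mid_intron_intergenic"),  # removed
            (3000, "mid_intron_intergenic"),  # off-track no-data -> kept
        ]):
            s = _site(region, genomic_start=pos + 1, chrom="chr1", seq_id=f"s{i}")
            sites.append(s)
            iv = GenomicInterval("chr1", pos, pos + len(s.kmer))
            mean = mean_conservation(track, iv)
            if region != "mid_intron_intergenic" or mean is None or not mean < ref:
                expected_kept.append(f"s{i}")
        kept = [s.seq_id for s in conservation_filter(sites, track, ref)]
        assert kept == expected_kept
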