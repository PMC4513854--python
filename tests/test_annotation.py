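import math
from collections import Counter

import numpy as np
import pytest

from cobind.annotation import (
    FeatureCategory,
    FeatureDistribution,
    classify_location,
    classify_locations,
    enrichment_log2,
    random_control,
    repeat_overlap,
    tss_distances,
)
from cobind.formats import GeneModel, GenomicInterval, Tag
from cobind.peak_calling import Peak


def make_peak(chrom, summit, width=100, name="p"):
    start = max(0, summit - width // 2)
    return Peak(GenomicInterval(chrom, start, start + width), summit=summit,
                tag_count=10, fold_enrichment=5.0, p_value=1e-9, name=name)


def simple_gene(strand="+", tx_start=10_000, tx_end=16_000, chrom="chr1"):
    """Coding gene with 2 exons; CDS starts 200 bp into the first exon."""
    exons = [
        GenomicInterval(chrom, tx_start, tx_start + 500, strand),
        GenomicInterval(chrom, tx_end - 500, tx_end, strand),
    ]
    return GeneModel("g", chrom, strand, tx_start, tx_end,
                     tx_start + 200, tx_end - 200, exons)


class TestTssDistances:
    def test_plus_gene_upstream_is_negative(self):
        genes = [simple_gene("+")]
        dists, _ = tss_distances([make_peak("chr1", 9_950)], genes)
        assert dists.tolist() == [-50]

    def test_minus_gene_strand_symmetry(self):
        genes = [simple_gene("-", tx_start=4_001, tx_end=10_001)]  # TSS at 10,000
        dists, _ = tss_distances([make_peak("chr1", 10_050)], genes)
        assert dists.tolist() == [-50]

    def test_histogram_bins_aligned_to_zero(self):
        genes = [simple_gene("+", tx_start=10_000)]
        peaks = [make_peak("chr1", 10_000 + d) for d in (-10, -30, -30)]
        _, (edges, counts) = tss_distances(peaks, genes, bin_width=20)
        hist = dict(zip(edges[:-1].tolist(), counts.tolist()))
        assert hist[-40] == 2 and hist[-20] == 1

    def test_empty_peaks_empty_outputs(self):
        dists, (_, counts) = tss_distances([], [simple_gene()])
        assert dists.size == 0 and counts.sum() == 0


class TestClassifyLocation:
    def test_proximal_promoter(self):
        assert classify_location(make_peak("chr1", 9_500), [simple_gene("+")]) \
            == FeatureCategory.PROXIMAL_PROMOTER

    def test_distal_promoter(self):
        assert classify_location(make_peak("chr1", 8_000), [simple_gene("+")]) \
            == FeatureCategory.DISTAL_PROMOTER

    def test_utr5_before_cds_start(self):
        assert classify_location(make_peak("chr1", 10_100), [simple_gene("+")]) \
            == FeatureCategory.UTR5

    def test_utr3_after_cds_end(self):
        assert classify_location(make_peak("chr1", 15_900), [simple_gene("+")]) \
            == FeatureCategory.UTR3

    def test_exon_within_cds(self):
        assert classify_location(make_peak("chr1", 10_400), [simple_gene("+")]) \
            == FeatureCategory.EXON

    def test_intron_between_exons(self):
        assert classify_location(make_peak("chr1", 12_000), [simple_gene("+")]) \
            == FeatureCategory.INTRON

    def test_far_from_everything_is_distal_intergenic(self):
        assert classify_location(make_peak("chr1", 50_000), [simple_gene("+")]) \
            == FeatureCategory.DISTAL_INTERGENIC

    def test_minus_strand_promoter_is_downstream_in_genome_coords(self):
        gene = simple_gene("-", tx_start=4_001, tx_end=10_001)
        assert classify_location(make_peak("chr1", 10_500), [gene]) \
            == FeatureCategory.PROXIMAL_PROMOTER

    def test_downstream_windows_anchor_at_transcript_end(self):
        gene = simple_gene("+")
        assert classify_location(make_peak("chr1", 16_500), [gene]) \
            == FeatureCategory.PROXIMAL_DOWNSTREAM
        assert classify_location(make_peak("chr1", 18_000), [gene]) \
            == FeatureCategory.DISTAL_DOWNSTREAM

    def test_literal_tss_downstream_mode(self):
        gene = simple_gene("+")
        # 500 bp downstream of the TSS but outside the transcript cannot
        # happen for this gene, so use a peak past tx_end: under the literal
        # reading it is > 3 kb from the TSS, hence intergenic
        assert classify_location(make_peak("chr1", 16_500), [gene],
                                 downstream_of="tss") \
            == FeatureCategory.DISTAL_INTERGENIC

    def test_total_on_random_positions(self, rng):
        genes = [simple_gene("+"), simple_gene("-", 30_000, 35_000)]
        for pos in rng.integers(100, 60_000, 300):
            assert isinstance(classify_location(make_peak("chr1", int(pos)), genes),
                              FeatureCategory)


def test_feature_distribution_percentages_sum_to_100(rng):
    cats = [list(FeatureCategory)[i] for i in rng.integers(0, 9, 500)]
    dist = FeatureDistribution.from_categories(cats)
    assert sum(dist.counts.values()) == dist.total == 500
    assert math.isclose(sum(dist.percentages.values()), 100.0, abs_tol=0.01)


class TestRandomControl:
    def test_count_and_centres_from_input_tags(self, toy, toy_peaks):
        tags = toy["tags_input"]
        controls = random_control(tags, toy_peaks, 200, seed=1,
                                  chrom_lengths=toy["lengths"])
        assert len(controls) == 200
        positions = {(t.chrom, t.pos) for t in tags}
        for iv in controls:
            center = iv.start + iv.width // 2
            # centre is a sampled tag position (up to edge clipping)
            assert (iv.chrom, center) in positions or iv.start == 0 \
                or iv.end == toy["lengths"][iv.chrom]

    def test_sample_larger_than_tags_rejected(self, toy_peaks):
        with pytest.raises(ValueError):
            random_control([Tag("chr1", 5, "+")], toy_peaks, 2, seed=0)

    def test_modal_category_on_gene_sparse_genome(self, toy, toy_dataset, toy_peaks):
        """Uniform input on a mostly intergenic genome: the modal control
        category is distal_intergenic, in line with the genic fraction."""
        controls = random_control(toy["tags_input"], toy_peaks, 500, seed=1,
                                  chrom_lengths=toy["lengths"])
        cats = classify_locations(controls, toy_dataset.genes)
        modal = Counter(cats).most_common(1)[0][0]
        assert modal == FeatureCategory.DISTAL_INTERGENIC
        genic_bp = sum(g.tx_end - g.tx_start + 2 * 3_000 for g in toy_dataset.genes)
        total_bp = sum(toy["lengths"].values())
        assert genic_bp / total_bp < 0.5  # sanity: genome is gene-sparse


class TestEnrichmentLog2:
    @staticmethod
    def _dist(pcts):
        counts = {c: 0 for c in FeatureCategory}
        counts.update({c: int(round(p * 10)) for c, p in pcts.items()})
        return FeatureDistribution(counts, sum(counts.values()))

    def test_identical_distributions_all_zero(self):
        d = self._dist({FeatureCategory.EXON: 40, FeatureCategory.INTRON: 60})
        log2 = enrichment_log2(d, d)
        assert log2[FeatureCategory.EXON] == 0.0
        assert log2[FeatureCategory.INTRON] == 0.0

    def test_promoter_enrichment_ratio(self):
        """25% vs 2% in proximal promoters is a 3.64 log2 enrichment."""
        peaks = self._dist({FeatureCategory.PROXIMAL_PROMOTER: 25,
                            FeatureCategory.DISTAL_INTERGENIC: 75})
        ctrl = self._dist({FeatureCategory.PROXIMAL_PROMOTER: 2,
                           FeatureCategory.DISTAL_INTERGENIC: 98})
        log2 = enrichment_log2(peaks, ctrl)
        assert log2[FeatureCategory.PROXIMAL_PROMOTER] == pytest.approx(
            math.log2(12.5), abs=1e-9
        )

    def test_utr5_enrichment_ratio(self):
        """10% vs 0.2% in 5' UTRs is a 5.64 log2 enrichment."""
        peaks = self._dist({FeatureCategory.UTR5: 10,
                            FeatureCategory.DISTAL_INTERGENIC: 90})
        ctrl = self._dist({FeatureCategory.UTR5: 0.2,
                           FeatureCategory.DISTAL_INTERGENIC: 99.8})
        log2 = enrichment_log2(peaks, ctrl)
        assert log2[FeatureCategory.UTR5] == pytest.approx(math.log2(50), abs=1e-9)

    def test_sentinels(self):
        peaks = self._dist({FeatureCategory.EXON: 100})
        ctrl = self._dist({FeatureCategory.INTRON: 100})
        log2 = enrichment_log2(peaks, ctrl)
        assert log2[FeatureCategory.EXON] == float("inf")
        assert log2[FeatureCategory.INTRON] == float("-inf")
        assert math.isnan(log2[FeatureCategory.UTR3])


class TestRepeatOverlap:
    def test_overlap_by_one_bp_counts(self):
        peak = make_peak("chr1", 150, width=100)  # [100, 200)
        assert repeat_overlap([peak], [GenomicInterval("chr1", 150, 160)]) == (1, 1)

    def test_half_open_abutment_does_not_count(self):
        peak = make_peak("chr1", 150, width=100)
        assert repeat_overlap([peak], [GenomicInterval("chr1", 200, 210)]) == (0, 1)

    def test_control_hit_rate_matches_track_fraction(self, toy, toy_dataset):
        """Width-1 controls drawn from uniform input hit the repeat track
        at its covered fraction, within binomial tolerance."""
        donors = [GenomicInterval("chr1", 0, 1)]  # width-1 donor peaks
        controls = random_control(toy["tags_input"], donors, 1_000, seed=1,
                                  chrom_lengths=toy["lengths"])
        n_hit, n = repeat_overlap(controls, toy_dataset.repeats)
        covered = sum(r.width for r in toy_dataset.repeats)
        frac = covered / sum(toy["lengths"].values())
        sigma = np.sqrt(n * frac * (1 - frac))
        assert abs(n_hit - n * frac) < 4 * sigma
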