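"""Feature classification, genome composition, TSS profiles and
condition overlap."""

import numpy as np
import pytest

from trescan import (
    FeatureClass,
    GeneModel,
    GenomeLabeler,
    GenomicInterval,
    Peak,
    classify_peak,
    condition_overlap,
    feature_enrichment,
    genome_feature_fractions,
    tss_profile,
)


def _gene(gene_id, chrom, start, end, strand="+", cds=None, exons=None):
    cds_start, cds_end = cds if cds else (start, end)
    exon_ivs = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in (exons or [(start, end)])
    )
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exon_ivs,
    )


def oracle_base_class(pos, genes, promoter_bp, downstream_bp):
    """Independent per-base classifier: check spans per class in strict
    precedence order, first claim wins."""

    def in_any(spans):
        return any(s <= pos < e for s, e in spans)

    for cls in ["promoter", "five_utr", "three_utr", "exon", "intron", "downstream"]:
        for g in genes:
            iv = g.interval
            plus = iv.strand == "+"
            if cls == "promoter":
                spans = [(iv.start - promoter_bp, iv.start)] if plus else [(iv.end, iv.end + promoter_bp)]
            elif cls == "downstream":
                spans = [(iv.end, iv.end + downstream_bp)] if plus else [(iv.start - downstream_bp, iv.start)]
            elif cls == "intron":
                spans = [(iv.start, iv.end)]
            else:
                spans = []
                for ex in g.exons:
                    lo_utr = (ex.start, min(ex.end, g.cds_start))
                    hi_utr = (max(ex.start, g.cds_end), ex.end)
                    coding = (max(ex.start, g.cds_start), min(ex.end, g.cds_end))
                    five, three = (lo_utr, hi_utr) if plus else (hi_utr, lo_utr)
                    if cls == "five_utr" and five[0] < five[1]:
                        spans.append(five)
                    if cls == "three_utr" and three[0] < three[1]:
                        spans.append(three)
                    if cls == "exon" and coding[0] < coding[1]:
                        spans.append(coding)
            if in_any(spans):
                return cls
    return "intergenic"


class TestGenomeFractions:
    def test_toy_contig_arithmetic(self):
        gene = _gene("g", "c1", 4000, 5000)
        fr = genome_feature_fractions(
            [gene], {"c1": 10_000}, promoter_bp=1000, downstream_bp=1000
        )
        assert fr[FeatureClass.exon] == pytest.approx(0.10)
        assert fr[FeatureClass.promoter] == pytest.approx(0.10)
        assert fr[FeatureClass.downstream] == pytest.approx(0.10)
        assert fr[FeatureClass.intergenic] == pytest.approx(0.70)

    def test_no_genes_all_intergenic(self):
        fr = genome_feature_fractions([], {"c1": 500})
        assert fr[FeatureClass.intergenic] == 1.0

    def test_fractions_sum_to_one(self, default_bundle):
        fr = genome_feature_fractions(
            default_bundle.genes, {c: len(s) for c, s in default_bundle.genome.items()}
        )
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_gene_past_contig_end_raises(self):
        gene = _gene("g", "c1", 100, 900)
        with pytest.raises(Exception, match="contig"):
            genome_feature_fractions([gene], {"c1": 500})


class TestClassifyPeak:
    def _labeler(self, genes, lengths, **kw):
        return GenomeLabeler(genes, lengths, **kw)

    def test_upstream_midpoint_is_promoter(self):
        gene = _gene("g", "c1", 50_000, 60_000)
        lab = self._labeler([gene], {"c1": 100_000})
        peak = Peak(GenomicInterval("c1", 47_900, 48_100))  # midpoint 2 kb upstream
        assert classify_peak(peak, lab) == FeatureClass.promoter

    def test_deep_intron_midpoint(self):
        gene = _gene(
            "g",
            "c1",
            10_000,
            40_000,
            cds=(10_100, 39_900),
            exons=[(10_000, 10_500), (39_500, 40_000)],
        )
        lab = self._labeler([gene], {"c1": 100_000})
        peak = Peak(GenomicInterval("c1", 24_900, 25_100))
        assert classify_peak(peak, lab) == FeatureClass.intron

    def test_minus_strand_promoter_side(self):
        gene = _gene("g", "c1", 50_000, 60_000, strand="-")
        lab = self._labeler([gene], {"c1": 100_000})
        peak = Peak(GenomicInterval("c1", 61_900, 62_100))  # 2 kb past end = upstream
        assert classify_peak(peak, lab) == FeatureClass.promoter

    def test_random_peaks_match_per_base_oracle(self, default_bundle):
        lengths = {c: len(s) for c, s in default_bundle.genome.items()}
        lab = GenomeLabeler(default_bundle.genes, lengths)
        rng = np.random.default_rng(17)
        genes_by_chrom = {}
        for g in default_bundle.genes:
            genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
        for _ in range(1000):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, lengths[chrom] - 300))
            peak = Peak(GenomicInterval(chrom, s, s + 300))
            expected = oracle_base_class(
                peak.interval.midpoint, genes_by_chrom.get(chrom, []), 5000, 5000
            )
            assert str(classify_peak(peak, lab)) == expected


class TestFeatureEnrichment:
    def test_fold_is_share_ratio(self):
        # construct: gene exon occupies 2% of the genome; 10% of peaks on it
        gene = _gene("g", "c1", 40_000, 42_000)
        lengths = {"c1": 100_000}
        peaks = [Peak(GenomicInterval("c1", 40_900, 41_100))] + [
            Peak(GenomicInterval("c1", 70_000 + i * 1000, 70_200 + i * 1000))
            for i in range(9)
        ]
        dist = feature_enrichment(peaks, [gene], lengths, promoter_bp=1000, downstream_bp=1000)
        assert dist.peak_fraction[FeatureClass.exon] == pytest.approx(0.1)
        assert dist.genome_fraction[FeatureClass.exon] == pytest.approx(0.02)
        assert dist.fold[FeatureClass.exon] == pytest.approx(5.0)

    def test_peak_fractions_sum_to_one(self, default_bundle):
        lengths = {c: len(s) for c, s in default_bundle.genome.items()}
        dist = feature_enrichment(
            default_bundle.peak_sets["untreated"], default_bundle.genes, lengths
        )
        assert sum(dist.peak_fraction.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(dist.genome_fraction.values()) == pytest.approx(1.0, abs=1e-9)

    def test_folds_invariant_under_genome_duplication(self):
        gene1 = _gene("g1", "c1", 40_000, 42_000)
        gene2 = _gene("g2", "c2", 40_000, 42_000)
        peaks = [Peak(GenomicInterval("c1", 40_900, 41_100))]
        d1 = feature_enrichment(peaks, [gene1], {"c1": 100_000})
        d2 = feature_enrichment(peaks, [gene1, gene2], {"c1": 100_000, "c2": 100_000})
        for c in FeatureClass:
            if d1.peak_fraction[c] > 0:
                assert d1.fold[c] == pytest.approx(d2.fold[c])


class TestTssProfile:
    def test_peak_on_tss_lands_in_zero_bin(self):
        gene = _gene("g", "c1", 50_000, 60_000)
        peak = Peak(GenomicInterval("c1", 49_900, 50_100))  # midpoint = TSS
        prof = tss_profile([peak], [gene], W=10_000, bin_size=200)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        assert prof.counts.sum() == 1
        assert centers[prof.counts.argmax()] == pytest.approx(100)

    def test_minus_strand_orientation_correction(self):
        gene = _gene("g", "c1", 40_000, 50_000, strand="-")  # TSS at 50_000
        peak = Peak(GenomicInterval("c1", 50_200, 50_400))  # 300 bp 5' of TSS
        prof = tss_profile([peak], [gene], W=1000, bin_size=100)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        hit = centers[np.flatnonzero(prof.counts)[0]]
        assert hit == pytest.approx(-250)  # bin [-300, -200)

    def test_profile_centred_when_peaks_planted_on_tss(self):
        rng = np.random.default_rng(23)
        genes = [
            _gene(f"g{i}", "c1", 20_000 + i * 30_000, 25_000 + i * 30_000,
                  strand="+" if i % 2 == 0 else "-")
            for i in range(30)
        ]
        peaks = []
        for _ in range(2000):
            g = genes[int(rng.integers(0, len(genes)))]
            d = int(rng.normal(0, 500))
            mid = g.tss + (d if g.strand == "+" else -d)
            peaks.append(Peak(GenomicInterval("c1", mid - 100, mid + 100)))
        prof = tss_profile(peaks, genes, W=10_000, bin_size=200)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        mean_d = float((centers * prof.counts).sum() / prof.counts.sum())
        se = 500 / np.sqrt(prof.counts.sum())
        assert abs(mean_d) <= 3 * se + 100  # 100 = half bin width slack

    def test_w_must_be_multiple_of_bin(self):
        with pytest.raises(ValueError):
            tss_profile([], [], W=1000, bin_size=300)


class TestConditionOverlap:
    def _peaks(self, spans, chrom="c1"):
        return [Peak(GenomicInterval(chrom, s, e)) for s, e in spans]

    def test_identical_sets_fully_shared(self):
        a = self._peaks([(0, 100), (500, 700)])
        res = condition_overlap(a, list(a))
        assert res["fraction_shared"] == 1.0
        assert res["a_only"] == 0

    def test_disjoint_contigs_unshared(self):
        a = self._peaks([(0, 100)], chrom="c1")
        b = self._peaks([(0, 100)], chrom="c2")
        res = condition_overlap(a, b)
        assert res["fraction_shared"] == 0.0

    def test_reciprocal_fraction_tightening(self):
        # 10 bp overlap of a 100 bp and a 20 bp peak: fails 50% reciprocal
        a = self._peaks([(0, 100)])
        b = self._peaks([(90, 110)])
        assert condition_overlap(a, b)["fraction_shared"] == 1.0
        assert condition_overlap(a, b, min_overlap_frac=0.5)["fraction_shared"] == 0.0

    def test_planted_shared_fraction_recovered(self):
        rng = np.random.default_rng(29)
        n, frac = 500, 0.4
        n_shared = int(n * frac)
        starts = rng.choice(np.arange(0, 2_000_000, 1200), size=2 * n - n_shared, replace=False)
        shared = starts[:n_shared]
        a_only = starts[n_shared : n_shared + (n - n_shared)]
        b_only = starts[n_shared + (n - n_shared) :]
        a = self._peaks([(int(s), int(s) + 400) for s in np.concatenate([shared, a_only])])
        b = self._peaks([(int(s), int(s) + 400) for s in np.concatenate([shared, b_only])])
        res = condition_overlap(a, b)
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(res["fraction_shared"] - frac) <= 3 * se
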