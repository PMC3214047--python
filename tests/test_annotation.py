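"""Peak-to-gene assignment, TSS distances and location classification."""

import numpy as np
import pytest
from scipy import stats

import chiptile as ct
from chiptile.annotation import classify_location, targets_to_frame
from chiptile.io_formats import GeneModel, Peak
from chiptile.synthetic import ArrayDesignConfig

from conftest import brute_classify

DESIGN = ArrayDesignConfig()


def _gene(strand="+", tx_start=10_000, tx_end=13_000, chrom="chr1"):
    """Two-exon coding gene; first exon short so the intron starts inside the
    +750 bp downstream design window."""
    exons = [(tx_start, tx_start + 400), (tx_end - 800, tx_end)]
    cds = (tx_start + 200, tx_end - 200)
    return GeneModel("G1", "GeneA", chrom, strand, tx_start, tx_end,
                     exons=exons, cds_start=cds[0], cds_end=cds[1])


class TestAssignment:
    def test_peak_on_tss(self):
        gene = _gene()
        peak = Peak("chr1", 9_900, 10_100, 4, 5.0, fdr=0.0)
        targets = ct.assign_peaks_to_genes([peak], [gene], DESIGN)
        assert len(targets) == 1
        assert targets[0].tss_distance == 0

    def test_peak_outside_design_window_unassigned(self):
        gene = _gene()
        peak = Peak("chr1", 4_900, 5_100, 4, 5.0, fdr=0.0)  # 5 kb upstream
        assert ct.assign_peaks_to_genes([peak], [gene], DESIGN) == []

    def test_shared_peak_assigned_to_both_genes(self):
        a = _gene(strand="+", tx_start=10_000, tx_end=13_000)
        b = GeneModel("G2", "GeneB", "chr1", "-", 6_000, 9_000,
                      exons=[(6_000, 9_000)], cds_start=6_200, cds_end=8_800)
        # windows: a -> [6500, 10750); b (TSS 8999) -> [8250, 12500)
        peak = Peak("chr1", 9_400, 9_600, 4, 5.0, fdr=0.0)
        targets = ct.assign_peaks_to_genes([peak], [a, b], DESIGN)
        assert {t.gene.symbol for t in targets} == {"GeneA", "GeneB"}

    def test_best_scoring_peak_is_representative(self):
        gene = _gene()
        weak = Peak("chr1", 8_000, 8_400, 4, 2.0, fdr=0.0)
        strong = Peak("chr1", 9_800, 10_200, 6, 6.0, fdr=0.0)
        targets = ct.assign_peaks_to_genes([weak, strong], [gene], DESIGN)
        assert len(targets) == 1
        assert targets[0].peak is strong


class TestClassification:
    def test_proximal_promoter(self):
        gene = _gene()
        peak = Peak("chr1", 9_700, 9_900, 4, 5.0)  # midpoint 9800, 200 bp upstream
        d, cls, sub = classify_location(peak, gene, DESIGN)
        assert (d, cls, sub) == (-200, "proximal_promoter", None)

    def test_distal_promoter(self):
        gene = _gene()
        peak = Peak("chr1", 7_400, 7_600, 4, 5.0)  # 2500 bp upstream
        d, cls, sub = classify_location(peak, gene, DESIGN)
        assert (d, cls, sub) == (-2500, "distal_promoter", None)

    def test_first_intron(self):
        gene = _gene()  # intron spans [10400, 12200)
        peak = Peak("chr1", 10_450, 10_550, 4, 5.0)
        _, cls, sub = classify_location(peak, gene, DESIGN)
        assert (cls, sub) == ("intragenic", "intron")

    def test_utr_and_cds_subclasses(self):
        gene = _gene()  # + strand: 5'UTR [10000,10200), CDS [10200,12800)
        cases = [
            (10_050, "utr5"),
            (10_300, "coding_exon"),
            # 3'UTR is outside the +750 design window for this geometry, so
            # check it on a shorter gene
        ]
        for pos, expected in cases:
            peak = Peak("chr1", pos - 50, pos + 50, 4, 5.0)
            _, cls, sub = classify_location(peak, gene, DESIGN)
            assert (cls, sub) == ("intragenic", expected)

    def test_utr3_on_short_gene(self):
        g = GeneModel("G3", "GeneC", "chr1", "+", 10_000, 10_600,
                      exons=[(10_000, 10_600)], cds_start=10_100, cds_end=10_500)
        peak = Peak("chr1", 10_500, 10_600, 4, 5.0)
        _, cls, sub = classify_location(peak, g, DESIGN)
        assert (cls, sub) == ("intragenic", "utr3")

    def test_intragenic_takes_precedence_within_1kb(self):
        # midpoint 300 bp downstream of TSS but inside the transcript
        gene = _gene()
        peak = Peak("chr1", 10_250, 10_350, 4, 5.0)
        _, cls, _ = classify_location(peak, gene, DESIGN)
        assert cls == "intragenic"

    def test_midpoint_outside_window_is_error(self):
        gene = _gene()
        peak = Peak("chr1", 2_000, 2_200, 4, 5.0)
        with pytest.raises(ValueError, match="design window"):
            classify_location(peak, gene, DESIGN)

    def test_strand_equivariance(self):
        """Mirroring gene and peak about the TSS yields identical classes."""
        plus = _gene(strand="+", tx_start=10_000, tx_end=13_000)
        # reflected gene: same local structure read from the other end
        L = 100_000
        def refl(x):
            return L - x
        minus = GeneModel("G1m", "GeneAm", "chr1", "-",
                          refl(plus.tx_end), refl(plus.tx_start),
                          exons=sorted((refl(b), refl(a)) for a, b in plus.exons),
                          cds_start=refl(plus.cds_end), cds_end=refl(plus.cds_start))
        rng = np.random.default_rng(0)
        for _ in range(100):
            offset = int(rng.integers(-3400, 740))
            mid_plus = plus.tss + offset
            p_plus = Peak("chr1", mid_plus - 50, mid_plus + 50, 4, 5.0)
            mid_minus = minus.tss - offset
            p_minus = Peak("chr1", mid_minus - 50, mid_minus + 50, 4, 5.0)
            d1, c1, s1 = classify_location(p_plus, plus, DESIGN)
            d2, c2, s2 = classify_location(p_minus, minus, DESIGN)
            assert (d1, c1, s1) == (d2, c2, s2)

    def test_matches_per_base_brute_force(self):
        """Classification equals literal per-base membership on random pairs."""
        _, genes = ct.generate_genome(40, seed=31)
        rng = np.random.default_rng(32)
        n_checked = 0
        while n_checked < 300:
            gene = genes[int(rng.integers(0, len(genes)))]
            offset = int(rng.integers(-DESIGN.upstream_bp, DESIGN.downstream_bp))
            sign = 1 if gene.strand == "+" else -1
            mid = gene.tss + sign * offset
            half = int(rng.integers(30, 200))
            peak = Peak(gene.chrom, mid - half, mid + half, 4, 5.0)
            d, cls, sub = classify_location(peak, gene, DESIGN)
            b_cls, b_sub = brute_classify(peak, gene, DESIGN)
            assert (cls, sub) == (b_cls, b_sub)
            n_checked += 1


class TestDistributions:
    def test_histogram_single_bin(self):
        gene = _gene()
        peak = Peak("chr1", 9_900, 10_100, 4, 5.0)
        targets = ct.assign_peaks_to_genes([peak], [gene], DESIGN)
        hist = ct.tss_distance_histogram(targets, DESIGN, bin_bp=250)
        assert hist["count"].sum() == 1
        row = hist[hist["count"] == 1].iloc[0]
        assert row.bin_center - 125 <= 0 <= row.bin_center + 125

    def test_histogram_covers_design_window(self):
        gene = _gene()
        peak = Peak("chr1", 9_900, 10_100, 4, 5.0)
        targets = ct.assign_peaks_to_genes([peak], [gene], DESIGN)
        hist = ct.tss_distance_histogram(targets, DESIGN, bin_bp=250)
        assert len(hist) == (3500 + 750) // 250

    def test_uniform_offsets_give_flat_histogram(self):
        """Uniformly placed binding offsets produce a flat TSS-distance
        histogram (chi-square goodness of fit)."""
        gene = _gene()
        rng = np.random.default_rng(33)
        targets = []
        for _ in range(2000):
            offset = int(rng.integers(-3500, 750))
            t = ct.TargetGene(gene, Peak("chr1", 0, 10, 4, 5.0), offset,
                              "proximal_promoter", None)
            targets.append(t)
        hist = ct.tss_distance_histogram(targets, DESIGN, bin_bp=250)
        chi2, p = stats.chisquare(hist["count"])
        assert p > 0.01

    def test_bad_bin_width(self):
        gene = _gene()
        peak = Peak("chr1", 9_900, 10_100, 4, 5.0)
        targets = ct.assign_peaks_to_genes([peak], [gene], DESIGN)
        with pytest.raises(ValueError):
            ct.tss_distance_histogram(targets, DESIGN, bin_bp=0)

    def test_location_proportions(self):
        gene = _gene()
        mk = lambda cls, sub: ct.TargetGene(gene, Peak("chr1", 0, 10, 4, 5.0), 0, cls, sub)
        targets = [
            mk("proximal_promoter", None),
            mk("distal_promoter", None),
            mk("intragenic", "utr5"),
            mk("intragenic", "intron"),
        ]
        dist = ct.location_distribution(targets)
        assert dist.class_proportions["proximal_promoter"] == 0.25
        assert dist.class_proportions["intragenic"] == 0.5
        assert sum(dist.class_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(dist.subclass_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert dist.subclass_proportions["utr5"] == 0.5

    def test_all_utr5_planted(self):
        gene = _gene()
        mk = lambda: ct.TargetGene(gene, Peak("chr1", 0, 10, 4, 5.0), 50,
                                   "intragenic", "utr5")
        dist = ct.location_distribution([mk() for _ in range(10)])
        assert dist.subclass_proportions["utr5"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ct.location_distribution([])

    def test_classification_exhaustive_and_exclusive(self, recovery_study):
        targets = ct.assign_peaks_to_genes(
            recovery_study["peaks"], recovery_study["genes"], DESIGN)
        assert targets
        for t in targets:
            assert t.location_class in ct.annotation.LOCATION_CLASSES
            assert (t.intragenic_subclass is not None) == (t.location_class == "intragenic")
        frame = targets_to_frame(targets)
        assert len(frame) == len(targets)
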