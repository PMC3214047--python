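"""Peak-to-gene assignment, TSS-distance distributions and location classes.

A peak is assigned to every gene whose promoter design window it overlaps (the
array platform defines the searchable space).  Classification uses the peak
midpoint: inside the transcript body is intragenic — subdivided into exonic
5'UTR, coding exon, exonic 3'UTR or intron — taking precedence over promoter
classes; upstream of the TSS splits at ``proximal_bp`` into proximal vs distal
promoter; downstream of the transcript but still on the array is 'other'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak
from .synthetic import ArrayDesignConfig, design_window

LOCATION_CLASSES = ("proximal_promoter", "distal_promoter", "intragenic", "other")
INTRAGENIC_SUBCLASSES = ("utr5", "intron", "coding_exon", "utr3")


@dataclass
class TargetGene:
    """A gene with its best supporting peak and TSS-relative location."""

    gene: GeneModel
    peak: Peak
    tss_distance: int  # signed bp, negative = upstream in transcription orientation
    location_class: str
    intragenic_subclass: str | None = None


@dataclass
class LocationDistribution:
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    subclass_counts: dict[str, int]
    subclass_proportions: dict[str, float]


def classify_location(
    peak: Peak,
    gene: GeneModel,
    design: ArrayDesignConfig | None = None,
    proximal_bp: int = 1000,
) -> tuple[int, str, str | None]:
    """Classify a peak against a gene model at the peak midpoint.

    Returns (signed TSS distance, location class, intragenic subclass).
    Raises if the midpoint falls outside the gene's design window, which the
    assignment contract forbids.
    """
    design = design or ArrayDesignConfig()
    mid = peak.midpoint
    t = gene.tss
    sign = 1 if gene.strand == "+" else -1
    d = (mid - t) * sign
    if not (-design.upstream_bp <= d < design.downstream_bp):
        raise ValueError(
            f"peak midpoint {mid} of {peak.name} outside the design window of "
            f"{gene.gene_id} (distance {d:+.1f})"
        )
    tss_distance = int(round(d))

    if gene.tx_start <= mid < gene.tx_end:
        pos = int(math.floor(mid))
        in_exon = any(a <= pos < b for a, b in gene.exons)
        if not in_exon:
            return tss_distance, "intragenic", "intron"
        if not gene.is_coding:
            # non-coding transcript: exonic hits counted as 5'UTR-like material
            return tss_distance, "intragenic", "utr5"
        if gene.strand == "+":
            if pos < gene.cds_start:
                sub = "utr5"
            elif pos >= gene.cds_end:
                sub = "utr3"
            else:
                sub = "coding_exon"
        else:
            if pos >= gene.cds_end:
                sub = "utr5"
            elif pos < gene.cds_start:
                sub = "utr3"
            else:
                sub = "coding_exon"
        return tss_distance, "intragenic", sub

    if d < 0:
        cls = "proximal_promoter" if d >= -proximal_bp else "distal_promoter"
        return tss_distance, cls, None
    return tss_distance, "other", None


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    design: ArrayDesignConfig | None = None,
    proximal_bp: int = 1000,
) -> list[TargetGene]:
    """Assign each peak to every gene whose design window it overlaps.

    A gene with several peaks keeps the highest-scoring one as its
    representative; the result is deduplicated by symbol (best score wins).
    """
    design = design or ArrayDesignConfig()
    by_symbol: dict[str, TargetGene] = {}
    for gene in genes:
        win_lo, win_hi = design_window(gene, design)
        best: Peak | None = None
        for p in peaks:
            if p.chrom != gene.chrom or p.end <= win_lo or p.start >= win_hi:
                continue
            mid = p.midpoint
            # assignment is by window overlap; classification needs the
            # midpoint inside the window too
            if not (win_lo <= mid < win_hi):
                continue
            if best is None or p.score > best.score:
                best = p
        if best is None:
            continue
        d, cls, sub = classify_location(best, gene, design, proximal_bp)
        tg = TargetGene(gene, best, d, cls, sub)
        key = gene.symbol.casefold()
        if key not in by_symbol or tg.peak.score > by_symbol[key].peak.score:
            by_symbol[key] = tg
    out = list(by_symbol.values())
    out.sort(key=lambda t: (t.gene.chrom, t.gene.tx_start))
    return out


def tss_distance_histogram(
    targets: Sequence[TargetGene],
    design: ArrayDesignConfig | None = None,
    bin_bp: int = 250,
) -> pd.DataFrame:
    """Counts of signed TSS distances in ``bin_bp`` bins covering the design window."""
    if not targets:
        raise ValueError("no targets to histogram")
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    design = design or ArrayDesignConfig()
    edges = np.arange(-design.upstream_bp, design.downstream_bp + bin_bp, bin_bp)
    edges = edges[edges <= design.downstream_bp]
    if edges[-1] < design.downstream_bp:
        edges = np.append(edges, design.downstream_bp)
    dists = np.array([t.tss_distance for t in targets])
    counts, _ = np.histogram(dists, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame({"bin_center": centers, "count": counts})


def location_distribution(targets: Sequence[TargetGene]) -> LocationDistribution:
    """Exact counts and normalized proportions per class and intragenic subclass."""
    if not targets:
        raise ValueError("no classified targets")
    class_counts = {c: 0 for c in LOCATION_CLASSES}
    sub_counts = {c: 0 for c in INTRAGENIC_SUBCLASSES}
    for t in targets:
        class_counts[t.location_class] += 1
        if t.location_class == "intragenic":
            sub_counts[t.intragenic_subclass] += 1
    n = len(targets)
    class_props = {c: k / n for c, k in class_counts.items()}
    n_intra = sum(sub_counts.values())
    sub_props = {
        c: (k / n_intra if n_intra else 0.0) for c, k in sub_counts.items()
    }
    return LocationDistribution(class_counts, class_props, sub_counts, sub_props)


def targets_to_frame(targets: Sequence[TargetGene]) -> pd.DataFrame:
    """Tabular view used by the CLI and pipeline outputs."""
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene.gene_id,
                "symbol": t.gene.symbol,
                "chrom": t.gene.chrom,
                "strand": t.gene.strand,
                "peak_start": t.peak.start,
                "peak_end": t.peak.end,
                "peak_score": t.peak.score,
                "peak_fdr": t.peak.fdr,
                "tss_distance": t.tss_distance,
                "location_class": t.location_class,
                "intragenic_subclass": t.intragenic_subclass or "none",
            }
            for t in targets
        ]
    )
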