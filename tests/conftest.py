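"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by exhaustive enumeration (1 bp
window stepping, per-base interval membership) so the fast implementations are
checked against logic that shares no code with them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import chiptile as ct

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force sliding-window oracle

def brute_sliding_peaks(starts, ends, values, cutoff, window_bp, min_probes):
    """Enumerate every 1 bp-stepped window, collect qualifying supporting-probe
    sets, merge sets sharing a probe, and span the supporting probes.

    Returns a list of (start, end, n_probes, score) tuples sorted by start.
    Probes must belong to a single chromosome and be sorted by start.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    values = np.asarray(values, dtype=float)
    mids = (starts + ends) / 2.0
    above = np.where(values > cutoff)[0]
    if len(above) < min_probes:
        return []
    a_mids = mids[above]
    lo_s = int(math.floor(a_mids.min())) - window_bp
    hi_s = int(math.ceil(a_mids.max())) + 1
    all_s = np.arange(lo_s, hi_s + 1)
    lo_idx = np.searchsorted(a_mids, all_s, side="left")
    hi_idx = np.searchsorted(a_mids, all_s + window_bp, side="left")
    counts = hi_idx - lo_idx
    qualifying = counts >= min_probes

    # union-find over supporting probe index ranges
    parent = list(range(len(above)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members = set()
    for lo, hi in zip(lo_idx[qualifying], hi_idx[qualifying]):
        members.update(range(lo, hi))
        root = find(lo)
        for j in range(lo + 1, hi):
            parent[find(j)] = root
    clusters: dict[int, list[int]] = {}
    for i in sorted(members):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for idxs in clusters.values():
        probe_idx = above[idxs]
        out.append(
            (
                int(starts[probe_idx].min()),
                int(ends[probe_idx].max()),
                len(probe_idx),
                float(values[probe_idx].mean()),
            )
        )
    out.sort()
    return out


# ---------------------------------------------------------------------------
# brute-force location-classification oracle

def brute_classify(peak, gene, design, proximal_bp=1000):
    """Per-base membership at the peak midpoint: test the midpoint base against
    transcript, exon and CDS intervals literally."""
    mid = (peak.start + peak.end) / 2.0
    pos = int(math.floor(mid))
    sign = 1 if gene.strand == "+" else -1
    d = (mid - gene.tss) * sign
    assert -design.upstream_bp <= d < design.downstream_bp

    if gene.tx_start <= mid < gene.tx_end:
        in_exon = False
        for a, b in gene.exons:
            if a <= pos < b:
                in_exon = True
        if not in_exon:
            return "intragenic", "intron"
        if gene.cds_start is None:
            return "intragenic", "utr5"
        # walk the transcript in 5'->3' order to label the base
        if gene.strand == "+":
            before_cds = pos < gene.cds_start
            after_cds = pos >= gene.cds_end
        else:
            before_cds = pos >= gene.cds_end
            after_cds = pos < gene.cds_start
        if before_cds:
            return "intragenic", "utr5"
        if after_cds:
            return "intragenic", "utr3"
        return "intragenic", "coding_exon"
    if d < 0:
        return ("proximal_promoter" if d >= -proximal_bp else "distal_promoter"), None
    return "other", None


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def recovery_study():
    """500-gene array with 50 planted sites at enrichment 5 and noise 0.3."""
    genome, genes = ct.generate_genome(500, seed=11)
    design = ct.generate_array_design(genes)
    probes, truth = ct.simulate_chip_signals(
        design, genes, site_fraction=0.1, enrichment_log2=5.0, noise_sd=0.3, seed=12
    )
    peaks = ct.call_peaks(probes, ct.PeakCallingConfig(seed=13))
    return {
        "genome": genome,
        "genes": genes,
        "design": design,
        "probes": probes,
        "truth": truth,
        "peaks": peaks,
    }


@pytest.fixture(scope="session")
def small_genes():
    _, genes = ct.generate_genome(20, seed=21)
    return genes
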