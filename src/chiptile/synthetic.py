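"""Synthetic data with known truth: toy genomes, promoter tiling-array designs,
planted ChIP enrichment, motif-spiked sequences and knockdown expression.

Every generator is a pure function of its configuration and seed.  The truth
ledger (:class:`SyntheticTruth`) records planted binding sites, differentially
expressed genes and motif positions so downstream recovery can be asserted by
direct inspection.

Noise model: channel intensities are log-normal, so per-probe log2 ratios are
Gaussian.  Planted sites default to a 500 bp window centred on the TSS,
matching the observed concentration of real binding sites within ~1 kb of the
TSS; ``site_offset`` moves them to exercise distal/intragenic location classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, ProbeRecord
from .motifs import IUPAC, reverse_complement


@dataclass
class PlantedSite:
    chrom: str
    start: int
    end: int
    gene: str
    enrichment_log2: float


@dataclass
class SyntheticTruth:
    """Ledger of everything planted by the generators."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "de_genes": self.de_genes,
            "motif_positions": {
                k: [[o, s] for o, s in v] for k, v in self.motif_positions.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_sites=[PlantedSite(**s) for s in payload["planted_sites"]],
            de_genes=payload["de_genes"],
            motif_positions={
                k: [(int(o), s) for o, s in v]
                for k, v in payload["motif_positions"].items()
            },
        )


@dataclass
class ArrayDesignConfig:
    """Promoter tiling-array design: probes cover TSS - upstream_bp to
    TSS + downstream_bp in transcription orientation."""

    upstream_bp: int = 3500
    downstream_bp: int = 750
    probe_len: int = 60
    probe_spacing: int = 100

    def __post_init__(self) -> None:
        if min(self.upstream_bp, self.downstream_bp, self.probe_len) <= 0:
            raise ValueError("design dimensions must be positive")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")


# gene placement layout: per-gene slot leaves room for the design window on
# either side of the gene body
_MARGIN = 5000
_MAX_GENE_LEN = 5000
_GENE_SPACING = 8000


def generate_genome(
    n_genes: int, seed: int, chrom: str = "chr1", chrom_length: int | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-random genome with non-overlapping multi-exon coding genes.

    Genes alternate strand so both orientations are represented; each has >=2
    exons, a CDS and 5'/3' UTRs so every intragenic substructure class
    (5'UTR, intron, coding exon, 3'UTR) is realizable.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    slot = _MAX_GENE_LEN + _GENE_SPACING
    needed = 2 * _MARGIN + n_genes * slot
    if chrom_length is None:
        chrom_length = needed
    elif chrom_length < needed:
        raise ValueError(
            f"n_genes={n_genes} exceeds genome capacity for length {chrom_length} "
            f"(need >= {needed})"
        )
    codes = rng.integers(0, 4, chrom_length)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    genes = []
    for i in range(n_genes):
        g_start = _MARGIN + i * slot
        strand = "+" if i % 2 == 0 else "-"
        genes.append(_random_gene(rng, chrom, g_start, strand, i))
    return {chrom: seq}, genes


def _random_gene(rng, chrom: str, g_start: int, strand: str, index: int) -> GeneModel:
    n_exons = int(rng.integers(2, 5))
    exon_lens = rng.integers(250, 600, n_exons)
    intron_lens = rng.integers(200, 800, n_exons - 1)
    exons = []
    pos = g_start
    for j in range(n_exons):
        exons.append((pos, pos + int(exon_lens[j])))
        pos += int(exon_lens[j])
        if j < n_exons - 1:
            pos += int(intron_lens[j])
    tx_start, tx_end = exons[0][0], exons[-1][1]
    utr_a = int(rng.integers(50, 150))  # at the tx_start side
    utr_b = int(rng.integers(50, 150))  # at the tx_end side
    if strand == "+":
        cds_start, cds_end = tx_start + utr_a, tx_end - utr_b
    else:
        cds_start, cds_end = tx_start + utr_b, tx_end - utr_a
    return GeneModel(
        gene_id=f"G{index + 1:04d}",
        symbol=f"Gene{index + 1:04d}",
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def design_window(gene: GeneModel, cfg: ArrayDesignConfig) -> tuple[int, int]:
    """Genomic half-open interval tiled for ``gene`` (upstream in transcription
    orientation)."""
    t = gene.tss
    if gene.strand == "+":
        return t - cfg.upstream_bp, t + cfg.downstream_bp
    return t - cfg.downstream_bp + 1, t + cfg.upstream_bp + 1


def generate_array_design(
    genes: Sequence[GeneModel], cfg: ArrayDesignConfig | None = None
) -> list[ProbeRecord]:
    """Tile each gene's promoter window with probes at ``probe_spacing``.

    Probe ids encode the gene of origin.  Intensities are zero until a signal
    simulation fills them in.
    """
    cfg = cfg or ArrayDesignConfig()
    region = cfg.upstream_bp + cfg.downstream_bp
    probes = []
    seen: set[tuple[str, int, int]] = set()
    for gene in genes:
        t = gene.tss
        k = 0
        off = 0
        while off < region:
            if gene.strand == "+":
                start = t - cfg.upstream_bp + off
                end = start + cfg.probe_len
            else:
                end = t + cfg.upstream_bp - off + 1
                start = end - cfg.probe_len
            if start < 0:
                raise ValueError(
                    f"gene {gene.gene_id}: design window extends past chromosome start"
                )
            key = (gene.chrom, start, end)
            if key not in seen:
                seen.add(key)
                probes.append(
                    ProbeRecord(
                        probe_id=f"{gene.gene_id}_p{k:03d}",
                        chrom=gene.chrom,
                        start=start,
                        end=end,
                        chip=0.0,
                        input=0.0,
                    )
                )
            k += 1
            off += cfg.probe_spacing
    probes.sort(key=lambda p: (p.chrom, p.start, p.end))
    return probes


def simulate_chip_signals(
    design: Sequence[ProbeRecord],
    genes: Sequence[GeneModel],
    site_fraction: float,
    enrichment_log2: float,
    noise_sd: float,
    seed: int,
    site_window_bp: int = 500,
    min_probes: int = 4,
    site_offset: int = 0,
    baseline_log2: float = 10.0,
    site_genes: Sequence[int] | None = None,
) -> tuple[list[ProbeRecord], SyntheticTruth]:
    """Plant enriched sites near the TSS of a random fraction of genes.

    Both channels are independently log-normal around the baseline (so probe
    log2 ratios are N(0, sqrt(2) * noise_sd) off-site); the ChIP channel gains
    2**enrichment_log2 over planted windows.
    ``site_offset`` shifts the site centre downstream (transcription
    orientation) of the TSS.  ``site_genes`` (gene indices) overrides the
    random choice of planted genes; ``site_fraction`` is then ignored.
    """
    if not design:
        raise ValueError("design must be non-empty")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not 0.0 <= site_fraction <= 1.0:
        raise ValueError("site_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if site_genes is not None:
        chosen = sorted(int(i) for i in site_genes)
    else:
        n_sites = int(round(site_fraction * len(genes)))
        chosen = sorted(rng.choice(len(genes), size=n_sites, replace=False).tolist())

    mids = np.array([p.midpoint for p in design])
    chroms = np.array([p.chrom for p in design])
    planted = np.zeros(len(design), dtype=bool)
    truth = SyntheticTruth()
    for gi in chosen:
        gene = genes[gi]
        sign = 1 if gene.strand == "+" else -1
        centre = gene.tss + sign * site_offset
        lo = centre - site_window_bp // 2
        hi = lo + site_window_bp
        mask = (chroms == gene.chrom) & (mids >= lo) & (mids < hi)
        if mask.sum() < min_probes:
            raise ValueError(
                f"site at {gene.chrom}:{lo}-{hi} covers only {int(mask.sum())} probes "
                f"(need >= {min_probes}); use a larger window or denser spacing"
            )
        planted |= mask
        truth.planted_sites.append(
            PlantedSite(gene.chrom, int(lo), int(hi), gene.symbol, enrichment_log2)
        )

    n = len(design)
    input_vals = np.exp2(rng.normal(baseline_log2, noise_sd, n))
    chip_vals = np.exp2(
        rng.normal(baseline_log2, noise_sd, n) + enrichment_log2 * planted
    )
    out = [
        ProbeRecord(p.probe_id, p.chrom, p.start, p.end, float(c), float(v))
        for p, c, v in zip(design, chip_vals, input_vals)
    ]
    return out, truth


def simulate_expression(
    genes: Sequence[str],
    de_fraction: float,
    effect_log2: float,
    n_case: int,
    n_control: int,
    noise_sd: float,
    seed: int,
):
    """log2 expression matrix with a planted fraction of DE genes.

    Controls are N(mu_g, noise_sd) around a per-gene baseline; DE genes are
    shifted by +/-``effect_log2`` in the case group with a random sign recorded
    in the truth ledger.
    """
    from .io_formats import ExpressionTable
    import pandas as pd

    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_genes = len(genes)
    n_de = int(round(de_fraction * n_genes))
    chosen = sorted(rng.choice(n_genes, size=n_de, replace=False).tolist())
    signs = rng.choice([-1.0, 1.0], size=n_de)

    mu = rng.uniform(4.0, 12.0, n_genes)
    shift = np.zeros(n_genes)
    truth = SyntheticTruth()
    for gi, s in zip(chosen, signs):
        shift[gi] = s * effect_log2
        truth.de_genes[genes[gi]] = float(s * effect_log2)

    case = mu[:, None] + shift[:, None] + rng.normal(0, noise_sd, (n_genes, n_case))
    ctrl = mu[:, None] + rng.normal(0, noise_sd, (n_genes, n_control))
    samples = [f"case_{i + 1}" for i in range(n_case)] + [
        f"control_{i + 1}" for i in range(n_control)
    ]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=pd.Index(genes, name="symbol"), columns=samples
    )
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionTable(values, groups), truth


def embed_motifs(
    sequences: Mapping[str, str], consensus: str, fraction: float, seed: int
) -> tuple[dict[str, str], SyntheticTruth]:
    """Plant one concrete instance of an IUPAC consensus in a fraction of sequences.

    The instance is a uniform-random resolution of the consensus placed at a
    uniform random offset and strand; positions go into the truth ledger.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    consensus = consensus.upper()
    for ch in consensus:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
    k = len(consensus)
    ids = sorted(sequences)
    if ids and min(len(sequences[i]) for i in ids) < k:
        raise ValueError("consensus longer than the shortest sequence")
    rng = np.random.default_rng(seed)
    n_sel = int(round(fraction * len(ids)))
    chosen = sorted(rng.choice(len(ids), size=n_sel, replace=False).tolist())

    out = dict(sequences)
    truth = SyntheticTruth()
    for idx in chosen:
        name = ids[idx]
        seq = out[name]
        instance = "".join(
            IUPAC[ch][rng.integers(0, len(IUPAC[ch]))] for ch in consensus
        )
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        planted = instance if strand == "+" else reverse_complement(instance)
        offset = int(rng.integers(0, len(seq) - k + 1))
        out[name] = seq[:offset] + planted + seq[offset + k:]
        truth.motif_positions.setdefault(name, []).append((offset, strand))
    return out, truth
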