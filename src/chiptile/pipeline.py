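"""End-to-end orchestration of the ChIP-chip and integration analyses.

Stages communicate only through files under the configured output directory,
so any stage can be rerun standalone; a manifest records the configuration
snapshot, input digests, per-stage outputs and filter counts.  All randomness
is seeded from the configuration, and no output embeds timestamps or absolute
paths, so a rerun with the same configuration and seeds is byte-identical.

Direction semantics for the knockdown integration: a gene bound by the factor
whose expression *falls* when the factor is knocked down (case - control < 0)
is labelled 'activated'; bound and *up* in the knockdown is 'repressed'.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation as anno
from . import diffexpr, io_formats, motifs, sets
from .io_formats import GeneSet
from .peaks import PeakCallingConfig, call_peaks
from .synthetic import ArrayDesignConfig, design_window

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str
    genes: str
    genes_dialect: str = "gff3"
    chip_lines: dict[str, str] = field(default_factory=dict)
    control_line: str | None = None
    control_signals: str | None = None
    genome: str | None = None
    categories: str | None = None
    expression: str | None = None
    chip_targets: str | None = None
    cofactor_targets: str | None = None
    chip_peaks: str | None = None
    design: ArrayDesignConfig = field(default_factory=ArrayDesignConfig)
    peak_calling: PeakCallingConfig = field(default_factory=PeakCallingConfig)
    sam: diffexpr.SAMConfig = field(default_factory=diffexpr.SAMConfig)
    proximal_bp: int = 1000
    motif_k: int = 10
    gsea_n_perm: int = 1000
    gsea_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("design", ArrayDesignConfig),
            ("peak_calling", PeakCallingConfig),
            ("sam", diffexpr.SAMConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def snapshot(self) -> dict:
        """JSON-safe config snapshot; output_dir excluded so reruns into
        different directories stay comparable."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return d

    def input_paths(self) -> list[str]:
        paths = [self.genes, *self.chip_lines.values()]
        for p in (
            self.control_signals, self.genome, self.categories,
            self.expression, self.chip_targets, self.cofactor_targets,
            self.chip_peaks,
        ):
            if p:
                paths.append(p)
        return paths


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, cfg: PipelineConfig):
        self.data = {
            "config": cfg.snapshot(),
            "inputs": {p: _sha256(p) for p in sorted(set(cfg.input_paths()))},
            "stages": [],
        }

    def stage(self, name: str, outputs: list[str], counts: dict) -> None:
        logger.info("stage %s: %s", name, counts)
        self.data["stages"].append(
            {"name": name, "outputs": sorted(outputs), "counts": counts}
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _read_categories(path: str) -> dict[str, GeneSet]:
    """Two-column TSV (category, symbol) -> category gene sets."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out: dict[str, GeneSet] = {}
    for cat, grp in df.groupby(0):
        out[str(cat)] = GeneSet(str(cat), grp[1].tolist())
    return out


def _call_and_annotate(cfg: PipelineConfig, name: str, signals_path: str,
                       genes, out_dir: Path, mani: _Manifest):
    probes = io_formats.read_probe_signals(signals_path)
    pk_cfg = dataclasses.replace(cfg.peak_calling)
    peaks = call_peaks(probes, pk_cfg)
    peaks_path = out_dir / f"{name}.peaks.bed"
    io_formats.write_peaks(peaks, peaks_path)
    targets = anno.assign_peaks_to_genes(peaks, genes, cfg.design, cfg.proximal_bp)
    targets_path = out_dir / f"{name}.targets.tsv"
    anno.targets_to_frame(targets).to_csv(targets_path, sep="\t", index=False,
                                          float_format="%.6f")
    gene_set = GeneSet(name, [t.gene.symbol for t in targets])
    set_path = out_dir / f"{name}.targets.txt"
    io_formats.write_gene_set(gene_set, set_path)
    mani.stage(
        f"peaks:{name}",
        [str(p.relative_to(out_dir)) for p in (peaks_path, targets_path, set_path)],
        {"probes": len(probes), "peaks_fdr_pass": len(peaks), "target_genes": len(gene_set)},
    )
    return peaks, targets, gene_set


def _background_sequences(genes, target_set: GeneSet, genome, design_cfg,
                          cap: int = 200) -> dict[str, str]:
    """Promoter design-window sequences of non-target genes (motif background)."""
    out: dict[str, str] = {}
    for g in genes:
        if g.symbol in target_set:
            continue
        lo, hi = design_window(g, design_cfg)
        seq = genome.get(g.chrom, "")
        if 0 <= lo < hi <= len(seq):
            out[g.gene_id] = seq[lo:hi]
        if len(out) >= cap:
            break
    return out


def _discover_motifs(fg: dict[str, str], bg: dict[str, str], k: int,
                     out_prefix: Path) -> list[str]:
    scores = motifs.kmer_zscores(fg, bg, k=k)
    top = scores[:20]
    kmer_path = out_prefix.with_suffix(".kmers.tsv")
    with open(kmer_path, "w") as fh:
        fh.write("kmer\tfg_count\texpected\tz_score\n")
        for s in top:
            fh.write(f"{s.kmer}\t{s.fg_count}\t{s.expected:.6f}\t{s.z_score:.6f}\n")
    pwm = motifs.build_pwm(top[0].kmer, fg)
    pwm.z_score = top[0].z_score
    pwm_path = out_prefix.with_suffix(".pwm.tsv")
    with open(pwm_path, "w") as fh:
        fh.write("A\tC\tG\tT\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    return [str(kmer_path), str(pwm_path)]


def run_chip_analysis(cfg: PipelineConfig) -> dict:
    """Per-line peak calling, annotation, control subtraction, Venn
    intersection, TSS/location distributions, category enrichment and motif
    discovery on common-target peak sequences."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mani = _Manifest(cfg)
    genes = io_formats.read_gene_models(cfg.genes, cfg.genes_dialect)

    line_sets: dict[str, GeneSet] = {}
    line_targets: dict[str, list] = {}
    line_peaks: dict[str, list] = {}
    for name in sorted(cfg.chip_lines):
        peaks, targets, gene_set = _call_and_annotate(
            cfg, name, cfg.chip_lines[name], genes, out_dir, mani
        )
        line_peaks[name], line_targets[name], line_sets[name] = peaks, targets, gene_set

    if cfg.control_signals:
        ctrl_name = cfg.control_line or "control"
        _, _, ctrl_set = _call_and_annotate(
            cfg, ctrl_name, cfg.control_signals, genes, out_dir, mani
        )
        for name in list(line_sets):
            before = len(line_sets[name])
            line_sets[name] = sets.subtract_control(line_sets[name], ctrl_set)
            line_sets[name].name = name
            mani.stage(
                f"subtract_control:{name}", [],
                {"before": before, "after": len(line_sets[name])},
            )

    names = sorted(line_sets)
    if 2 <= len(names) <= 3:
        vr = sets.venn([line_sets[n] for n in names])
        venn_path = out_dir / "venn.json"
        with open(venn_path, "w") as fh:
            json.dump(
                {
                    "sets": names,
                    "regions": {"+".join(sorted(k)): v for k, v in vr.region_counts.items()},
                    "common": vr.common.symbols,
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        common = vr.common
        mani.stage("venn", ["venn.json"], {"common": len(common), "union": vr.union_size})
    else:
        common = line_sets[names[0]]
    common_path = out_dir / "common_targets.txt"
    io_formats.write_gene_set(common, common_path)

    all_targets = [
        t for n in names for t in line_targets[n] if t.gene.symbol in line_sets[n]
    ]
    if all_targets:
        hist = anno.tss_distance_histogram(all_targets, cfg.design)
        hist_path = out_dir / "tss_histogram.tsv"
        hist.to_csv(hist_path, sep="\t", index=False, float_format="%.1f")
        dist = anno.location_distribution(all_targets)
        loc_path = out_dir / "location_distribution.json"
        with open(loc_path, "w") as fh:
            json.dump(dataclasses.asdict(dist), fh, indent=1, sort_keys=True)
            fh.write("\n")
        mani.stage(
            "annotation_summary",
            ["tss_histogram.tsv", "location_distribution.json", "common_targets.txt"],
            {"targets": len(all_targets)},
        )

    if cfg.categories:
        universe = GeneSet("array", [g.symbol for g in genes])
        enr = sets.category_enrichment(common, _read_categories(cfg.categories), universe)
        enr_path = out_dir / "enrichment.tsv"
        with open(enr_path, "w") as fh:
            fh.write("category\tk\tK\tn\tN\tp_value\tq_value\n")
            for r in enr:
                fh.write(
                    f"{r.category}\t{r.overlap}\t{r.category_size}\t{r.query_size}\t"
                    f"{r.universe_size}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
                )
        mani.stage("enrichment", ["enrichment.tsv"], {"categories": len(enr)})

    if cfg.genome:
        genome = io_formats.read_fasta(cfg.genome)
        rep_peaks = []
        seen = set()
        for n in names:
            for t in line_targets[n]:
                key = t.gene.symbol.casefold()
                if t.gene.symbol in common and key not in seen:
                    seen.add(key)
                    rep_peaks.append(t.peak)
        if rep_peaks:
            fg = motifs.extract_peak_sequences(rep_peaks, genome)
            bg = _background_sequences(genes, common, genome, cfg.design)
            outputs = _discover_motifs(fg, bg, cfg.motif_k, out_dir / "common_motifs")
            mani.stage(
                "motifs",
                [os.path.basename(p) for p in outputs],
                {"foreground_peaks": len(fg), "background_windows": len(bg)},
            )

    mani.write(out_dir / "manifest.json")
    return mani.data


def run_integration(cfg: PipelineConfig) -> dict:
    """SAM differential expression, intersection with ChIP targets,
    co-binding partition, per-partition motif discovery, GSEA and
    activated/repressed labelling."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mani = _Manifest(cfg)
    if not cfg.expression or not cfg.chip_targets:
        raise ValueError("integration needs 'expression' and 'chip_targets' inputs")

    expr = io_formats.read_expression(cfg.expression)
    de = diffexpr.sam_significance(expr, cfg.sam)
    de_path = out_dir / "de_results.tsv"
    diffexpr.de_results_frame(de).to_csv(de_path, sep="\t", index=False,
                                         float_format="%.6f")
    sig = [r for r in de if r.direction != "ns"]
    de_set = GeneSet("de", [r.symbol for r in sig])
    mani.stage(
        "sam", ["de_results.tsv"],
        {
            "genes": len(de),
            "significant": len(sig),
            "up": sum(r.direction == "up" for r in sig),
            "down": sum(r.direction == "down" for r in sig),
        },
    )

    chip = io_formats.read_gene_set(cfg.chip_targets, "chip")
    bound_and_regulated = GeneSet(
        "bound_and_regulated", [r.symbol for r in sig if r.symbol in chip]
    )
    reg_path = out_dir / "regulation.tsv"
    with open(reg_path, "w") as fh:
        fh.write("symbol\tlog2_fc\tq_value\tregulation\n")
        for r in sig:
            if r.symbol not in chip:
                continue
            # knockdown lowers an activated target: down => activated
            label = "activated" if r.direction == "down" else "repressed"
            fh.write(f"{r.symbol}\t{r.log2_fold_change:.6f}\t{r.q_value:.6f}\t{label}\n")
    mani.stage(
        "integration", ["regulation.tsv"],
        {"chip_targets": len(chip), "bound_and_regulated": len(bound_and_regulated)},
    )

    partition_outputs = []
    partitions: dict[str, GeneSet] = {}
    if cfg.cofactor_targets:
        cofactor = io_formats.read_gene_set(cfg.cofactor_targets, "cofactor")
        both, only = sets.partition_by_cobinding(bound_and_regulated, cofactor)
        partitions = {"cobound": both, "primary_only": only}
        for pname, pset in partitions.items():
            p_path = out_dir / f"{pname}.txt"
            io_formats.write_gene_set(pset, p_path)
            partition_outputs.append(f"{pname}.txt")
        mani.stage(
            "partition", partition_outputs,
            {"cobound": len(both), "primary_only": len(only)},
        )

    if cfg.genome and cfg.chip_peaks and partitions:
        genome = io_formats.read_fasta(cfg.genome)
        genes = io_formats.read_gene_models(cfg.genes, cfg.genes_dialect)
        peaks = io_formats.read_peaks(cfg.chip_peaks)
        targets = anno.assign_peaks_to_genes(peaks, genes, cfg.design, cfg.proximal_bp)
        peak_by_symbol = {t.gene.symbol.casefold(): t.peak for t in targets}
        bg = _background_sequences(genes, chip, genome, cfg.design)
        for pname, pset in partitions.items():
            fg_peaks = [peak_by_symbol[k] for k in sorted(pset.keys) if k in peak_by_symbol]
            if len(fg_peaks) < 2:
                logger.info("partition %s: too few peaks for motif discovery", pname)
                continue
            fg = motifs.extract_peak_sequences(fg_peaks, genome)
            outputs = _discover_motifs(fg, bg, cfg.motif_k, out_dir / f"{pname}_motifs")
            mani.stage(
                f"motifs:{pname}", [os.path.basename(p) for p in outputs],
                {"foreground_peaks": len(fg)},
            )

    ranked = sorted(
        ((r.symbol, r.log2_fold_change) for r in de), key=lambda t: -t[1]
    )
    gr = diffexpr.gsea(ranked, chip, n_perm=cfg.gsea_n_perm, seed=cfg.gsea_seed)
    gsea_path = out_dir / "gsea.json"
    with open(gsea_path, "w") as fh:
        json.dump(
            {
                "es": round(gr.es, 6),
                "p_value": round(gr.p_value, 6),
                "n_hits": gr.n_hits,
                "leading_edge": gr.leading_edge,
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    mani.stage("gsea", ["gsea.json"], {"es": round(gr.es, 6), "p": round(gr.p_value, 6)})

    mani.write(out_dir / "manifest.json")
    return mani.data
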