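"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the I/O boundary only.  Gene symbols are matched
case-insensitively everywhere downstream, but the original case is preserved
for output.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "chip", "input"]
PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "n_probes", "fdr"]


class FormatError(ValueError):
    """Malformed or invariant-violating input file content."""


@dataclass
class ProbeRecord:
    """One two-channel tiling-array probe: raw ChIP and input intensities."""

    probe_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    chip: float
    input: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"probe {self.probe_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.chip < 0 or self.input < 0:
            raise FormatError(f"probe {self.probe_id}: negative intensity")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GeneModel:
    """TSS-anchored gene structure used for annotation and array design.

    ``cds_start``/``cds_end`` delimit the genomic CDS span (thickStart/thickEnd
    semantics); both endpoints must fall inside exons.  Absent for non-coding
    transcripts.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tx_end <= self.tx_start:
            raise FormatError(f"gene {self.gene_id}: empty transcript interval")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise FormatError(f"gene {self.gene_id}: empty exon ({a},{b})")
            if a < self.tx_start or b > self.tx_end:
                raise FormatError(
                    f"gene {self.gene_id}: exon ({a},{b}) outside transcript bounds"
                )
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 < b1:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise FormatError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if self.cds_end <= self.cds_start:
                raise FormatError(f"gene {self.gene_id}: empty CDS interval")
            for pos in (self.cds_start, self.cds_end - 1):
                if not any(a <= pos < b for a, b in exons):
                    raise FormatError(
                        f"gene {self.gene_id}: CDS endpoint {pos} outside exon union"
                    )

    @property
    def tss(self) -> int:
        """TSS position: tx_start on '+', tx_end - 1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass
class Peak:
    """A called enriched region spanning its supporting probes."""

    chrom: str
    start: int
    end: int
    n_probes: int
    score: float  # mean log2 fold enrichment of supporting probes
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError("peak with end <= start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GeneSet:
    """A named set of gene symbols, deduplicated case-insensitively.

    Original case of the first occurrence of each symbol is preserved.
    """

    def __init__(self, name: str, symbols: Iterable[str]):
        self.name = name
        self._by_key: dict[str, str] = {}
        for s in symbols:
            key = s.casefold()
            if key not in self._by_key:
                self._by_key[key] = s

    @property
    def symbols(self) -> list[str]:
        return sorted(self._by_key.values(), key=str.casefold)

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(self._by_key)

    def original(self, key: str) -> str:
        return self._by_key[key]

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._by_key

    def __iter__(self):
        return iter(self.symbols)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSet) and self.keys == other.keys

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"


class ExpressionTable:
    """genes x samples log2 expression matrix with a case/control label per sample."""

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str] | pd.Series):
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        if list(groups.index) != list(values.columns):
            groups = groups.reindex(values.columns)
        if groups.isna().any():
            raise FormatError("every sample needs a group label")
        bad = set(groups.unique()) - {"case", "control"}
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if values.isna().any().any():
            raise FormatError("expression table contains missing values")
        if values.index.duplicated().any():
            raise FormatError("duplicate gene symbols in expression table")
        for g in ("case", "control"):
            if (groups == g).sum() < 2:
                raise FormatError(f"need >=2 samples in group '{g}'")
        self.values = values.astype(float)
        self.groups = groups

    @property
    def symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_matrix(self, group: str) -> np.ndarray:
        return self.values.loc[:, self.groups == group].to_numpy()


# ---------------------------------------------------------------------------
# probe signal TSV

def read_probe_signals(path: str | os.PathLike) -> list[ProbeRecord]:
    """Read a probe-signal TSV, validate, and return records sorted by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            rec = ProbeRecord(
                probe_id=str(row.probe_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                chip=float(row.chip),
                input=float(row.input),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        key = (rec.chrom, rec.start, rec.end)
        if key in seen:
            raise FormatError(f"{path}: duplicate probe interval {key}")
        seen.add(key)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_probe_signals(records: Sequence[ProbeRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.probe_id, r.chrom, r.start, r.end, r.chip, r.input) for r in records],
        columns=PROBE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# gene models (GFF3 / BED12)

def read_gene_models(path: str | os.PathLike, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive) or BED12 (0-based half-open)."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'gff3' or 'bed12')")


def _read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        cds = [(c.start - 1, c.end) for c in db.children(g, featuretype="CDS")]
        cds_start = min(a for a, _ in cds) if cds else None
        cds_end = max(b for _, b in cds) if cds else None
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=g.attributes.get("Name", [g.id])[0],
                chrom=g.seqid,
                strand=g.strand,
                tx_start=g.start - 1,
                tx_end=g.end,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene + exon + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.symbol}"
            fh.write(
                f"{g.chrom}\tchiptile\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tchiptile\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            if g.is_coding:
                # one CDS feature per overlapping exon segment
                j = 0
                for (a, b) in g.exons:
                    lo, hi = max(a, g.cds_start), min(b, g.cds_end)
                    if lo < hi:
                        j += 1
                        fh.write(
                            f"{g.chrom}\tchiptile\tCDS\t{lo + 1}\t{hi}\t.\t{g.strand}\t0\t"
                            f"ID={g.gene_id}.cds{j};Parent={g.gene_id}\n"
                        )


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            coding = thick_end > thick_start
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


# ---------------------------------------------------------------------------
# peaks (BED6+2)

def write_peaks(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    """Write peaks as BED6+2: chrom start end name score strand n_probes fdr."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PEAK_COLUMNS) + "\n")
        for p in peaks:
            fdr = p.fdr if p.fdr is not None else float("nan")
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.6f}\t.\t"
                f"{p.n_probes}\t{fdr:.6f}\n"
            )


def read_peaks(path: str | os.PathLike) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise FormatError(f"{path}: line {lineno}: expected 8 fields")
            fdr = float(f[7])
            peaks.append(
                Peak(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    n_probes=int(f[6]), score=float(f[4]),
                    fdr=None if np.isnan(fdr) else fdr,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# gene sets / ortholog maps

def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """Plain text, one symbol per line; '#' lines ignored."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.append(s)
    return GeneSet(name or os.path.splitext(os.path.basename(path))[0], symbols)


def write_gene_set(gene_set: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in gene_set.symbols:
            fh.write(s + "\n")


def read_ortholog_table(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Two-column TSV (symbol_a, symbol_b); one-to-many rows allowed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    return [(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


# ---------------------------------------------------------------------------
# expression TSV

def read_expression(path: str | os.PathLike) -> ExpressionTable:
    """genes x samples TSV; second line '#group<TAB>case|control...' labels samples."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        if not group_line or group_line[0] != "#group":
            raise FormatError(f"{path}: second line must be the '#group' label row")
        body = fh.read()
    samples = header[1:]
    groups = dict(zip(samples, group_line[1:]))
    df = pd.read_csv(
        io.StringIO(body), sep="\t", header=None, names=header, index_col=0
    )
    df.index.name = header[0]
    return ExpressionTable(df, groups)


def write_expression(table: ExpressionTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\t" + "\t".join(table.samples) + "\n")
        fh.write("#group\t" + "\t".join(table.groups[s] for s in table.samples) + "\n")
        for sym, row in table.values.iterrows():
            fh.write(sym + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
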