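"""Gene-level set algebra: Venn decomposition, negative-control subtraction,
co-binding partition, overlap fractions, ortholog intersection and
hypergeometric category enrichment.

All operations match symbols case-insensitively (mouse/human conventions
differ by case) while preserving the original case for output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class VennResult:
    """Exclusive-region decomposition of 2 or 3 gene sets."""

    set_names: list[str]
    region_counts: dict[frozenset, int]  # key = subset of set_names, exclusive region
    common: GeneSet                      # symbols present in every input set

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *names: str) -> int:
        return self.region_counts[frozenset(names)]


@dataclass
class EnrichmentResult:
    category: str
    overlap: int       # k
    category_size: int  # K
    query_size: int    # n
    universe_size: int  # N
    p_value: float
    q_value: float


def venn(sets: Sequence[GeneSet]) -> VennResult:
    """Exact exclusive-region decomposition of 2 or 3 named gene sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn takes 2 or 3 gene sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("gene sets must have distinct names")
    keysets = {s.name: s.keys for s in sets}
    union: set[str] = set().union(*keysets.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for key in union:
        members = frozenset(n for n in names if key in keysets[n])
        counts[members] += 1
    common_keys = frozenset.intersection(*keysets.values())
    common = GeneSet("common", [sets[0].original(k) for k in sorted(common_keys)])
    return VennResult(names, counts, common)


def subtract_control(targets: GeneSet, control: GeneSet) -> GeneSet:
    """Remove putative false positives: symbols also found in the control set."""
    keep = [s for s in targets.symbols if s not in control]
    return GeneSet(f"{targets.name}_minus_{control.name}", keep)


def overlap_fraction(query: GeneSet, reference: GeneSet) -> float:
    """Percentage of the query found in the reference set."""
    if len(query) == 0:
        raise ValueError("empty query set")
    k = sum(1 for s in query.symbols if s in reference)
    return 100.0 * k / len(query)


def partition_by_cobinding(
    primary_targets: GeneSet, cofactor_targets: GeneSet
) -> tuple[GeneSet, GeneSet]:
    """Split primary targets into (also bound by cofactor, primary only)."""
    both = [s for s in primary_targets.symbols if s in cofactor_targets]
    only = [s for s in primary_targets.symbols if s not in cofactor_targets]
    return (
        GeneSet(f"{primary_targets.name}_and_{cofactor_targets.name}", both),
        GeneSet(f"{primary_targets.name}_only", only),
    )


def map_orthologs(
    set_a: GeneSet,
    set_b: GeneSet,
    ortholog_table: Sequence[tuple[str, str]] | None = None,
) -> GeneSet:
    """Genes of ``set_a`` with an ortholog (or case-insensitive namesake) in ``set_b``.

    With a table, every (a, b) pair is considered (one-to-many allowed);
    without one, case-insensitive symbol identity is the fallback.  The result
    is reported in ``set_a``'s namespace.
    """
    if ortholog_table is None:
        shared = [s for s in set_a.symbols if s in set_b]
    else:
        b_keys = set_b.keys
        mapped = {
            a.casefold()
            for a, b in ortholog_table
            if b.casefold() in b_keys and a.casefold() in set_a.keys
        }
        shared = [set_a.original(k) for k in sorted(mapped)]
    return GeneSet(f"{set_a.name}_shared_{set_b.name}", shared)


def category_enrichment(
    query: GeneSet,
    annotation: Mapping[str, GeneSet],
    universe: GeneSet,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per category, BH-adjusted across
    categories, sorted by p-value.

    Query symbols outside the universe are dropped with a warning; category
    sets are likewise restricted to the universe.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    uni = universe.keys
    q = query.keys & uni
    dropped = len(query) - len(q)
    if dropped:
        logger.warning(
            "%d of %d query symbols are outside the universe and were dropped",
            dropped, len(query),
        )
    N, n = len(uni), len(q)
    results = []
    for cat_name in sorted(annotation):
        cat = annotation[cat_name].keys & uni
        K = len(cat)
        k = len(q & cat)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        results.append(EnrichmentResult(cat_name, k, K, n, N, p, q_value=1.0))
    if results:
        _, q_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q_adj):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.category))
    return results
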