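"""Two-class permutation differential expression, regression validation and a
running-enrichment (GSEA-style) test.

The moderated statistic follows the SAM family: d = (mean_case - mean_control)
/ (se + s0), where se is the pooled two-sample standard error and s0 a small
positive fudge constant (here the 5th percentile of per-gene SEs) that damps
spuriously large statistics from genes with tiny variance.  Significance comes
from balanced label permutations: per gene, q = median over permutations of the
count of null |d*| at or above |d|, divided by the gene's rank, monotone-
adjusted and truncated to [0, 1].

The enrichment test is the classic unweighted Kolmogorov-Smirnov running sum
over a ranked gene list, with gene-set permutation for the p-value — the
knockdown design has too few replicates per arm for stable phenotype
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class SAMConfig:
    n_permutations: int = 200
    fdr_target: float = 0.01
    s0_percentile: float = 5.0
    s0_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class DEResult:
    symbol: str
    d_statistic: float
    log2_fold_change: float  # case - control (data already log2)
    q_value: float
    direction: str  # 'up' | 'down' | 'ns'


@dataclass
class GseaResult:
    es: float
    p_value: float
    leading_edge: list[str]
    n_hits: int


@dataclass
class RegressionResult:
    slope: float
    inv_slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# SAM-style statistic

def _d_and_fc(values: np.ndarray, case: np.ndarray, ctrl: np.ndarray, s0: float):
    """Vectorized d-statistic and fold change for a genes x samples matrix."""
    x1, x2 = values[:, case], values[:, ctrl]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    fc = m1 - m2
    return fc / (se + s0), fc, se


def _default_s0(se: np.ndarray, percentile: float) -> float:
    return float(np.percentile(se, percentile))


def sam_statistic(
    expr: ExpressionTable, s0: float | None = None, s0_percentile: float = 5.0
) -> pd.DataFrame:
    """Per-gene d-statistic and log2 fold change (case - control).

    When ``s0`` is None it is set to the ``s0_percentile``-th percentile of the
    per-gene pooled standard errors.
    """
    values = expr.values.to_numpy()
    case = (expr.groups == "case").to_numpy()
    ctrl = (expr.groups == "control").to_numpy()
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both groups need samples")
    if s0 is None:
        _, _, se = _d_and_fc(values, case, ctrl, 0.0)
        s0 = _default_s0(se, s0_percentile)
    d, fc, _ = _d_and_fc(values, case, ctrl, s0)
    return pd.DataFrame({"d": d, "log2_fc": fc}, index=expr.values.index)


def _label_permutations(
    n_samples: int, case_mask: np.ndarray, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct case-label assignments (which samples play 'case'), capped.

    All C(n, n_case) assignments are enumerated when feasible and subsampled
    otherwise; the observed assignment is included, which is mildly
    conservative.
    """
    n_case = int(case_mask.sum())
    combos = list(combinations(range(n_samples), n_case))
    if len(combos) > n_perm:
        idx = rng.choice(len(combos), size=n_perm, replace=False)
        combos = [combos[i] for i in sorted(idx.tolist())]
    if len(combos) < 10:
        logger.warning("only %d distinct label permutations available", len(combos))
    masks = []
    for combo in combos:
        m = np.zeros(n_samples, dtype=bool)
        m[list(combo)] = True
        masks.append(m)
    return masks


def sam_significance(expr: ExpressionTable, cfg: SAMConfig | None = None) -> list[DEResult]:
    """Permutation significance for the knockdown contrast.

    q_g = median over permutations of #{null |d*| >= |d_g|} divided by
    #{observed |d| >= |d_g|}, monotone-adjusted so q never decreases as |d|
    falls, truncated to [0, 1].  Genes with q below ``cfg.fdr_target`` are
    split into 'up'/'down' by fold-change sign.
    """
    cfg = cfg or SAMConfig()
    values = expr.values.to_numpy()
    case = (expr.groups == "case").to_numpy()
    ctrl = (expr.groups == "control").to_numpy()
    if cfg.s0_override is not None:
        s0 = cfg.s0_override
    else:
        _, _, se = _d_and_fc(values, case, ctrl, 0.0)
        s0 = _default_s0(se, cfg.s0_percentile)
    d_obs, fc, _ = _d_and_fc(values, case, ctrl, s0)
    abs_d = np.abs(d_obs)

    rng = np.random.default_rng(cfg.seed)
    masks = _label_permutations(values.shape[1], case, cfg.n_permutations, rng)
    # null |d| per permutation, each sorted for counting
    null_sorted = []
    for m in masks:
        d_null, _, _ = _d_and_fc(values, m, ~m, s0)
        null_sorted.append(np.sort(np.abs(d_null)))

    G = len(abs_d)
    counts = np.empty((len(null_sorted), G))
    for b, col in enumerate(null_sorted):
        counts[b] = G - np.searchsorted(col, abs_d, side="left")
    med_null = np.median(counts, axis=0)
    obs_sorted = np.sort(abs_d)
    rank = G - np.searchsorted(obs_sorted, abs_d, side="left")  # #{|d| >= |d_g|}
    raw_q = np.clip(med_null / rank, 0.0, 1.0)

    # monotone adjustment: most significant first, running minimum of the tail
    order = np.argsort(-abs_d, kind="stable")
    adj = np.minimum.accumulate(raw_q[order][::-1])[::-1]
    q = np.empty_like(raw_q)
    q[order] = adj

    results = []
    for sym, di, fci, qi in zip(expr.symbols, d_obs, fc, q):
        if qi < cfg.fdr_target:
            direction = "up" if fci >= 0 else "down"
        else:
            direction = "ns"
        results.append(DEResult(sym, float(di), float(fci), float(qi), direction))
    return results


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "symbol": r.symbol,
                "d": r.d_statistic,
                "log2_fc": r.log2_fold_change,
                "q_value": r.q_value,
                "direction": r.direction,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# cross-platform fold-change regression

def validate_regression(
    fc_platform_a: Mapping[str, float], fc_platform_b: Mapping[str, float]
) -> RegressionResult:
    """OLS of platform-b fold changes on platform-a over the shared genes."""
    a_keys = {k.casefold(): v for k, v in fc_platform_a.items()}
    b_keys = {k.casefold(): v for k, v in fc_platform_b.items()}
    shared = sorted(a_keys.keys() & b_keys.keys())
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes for regression")
    x = np.array([a_keys[k] for k in shared])
    y = np.array([b_keys[k] for k in shared])
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        inv_slope=float(1.0 / fit.slope) if fit.slope != 0 else float("inf"),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(shared),
    )


# ---------------------------------------------------------------------------
# GSEA-style running enrichment

def _es_from_hits(hit_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed extremum of the unweighted KS running sum and the full sum."""
    L = hit_mask.size
    nh = int(hit_mask.sum())
    if nh == L:
        return 1.0, np.ones(L)
    inc = np.where(hit_mask, 1.0 / nh, -1.0 / (L - nh))
    running = np.cumsum(inc)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea(
    ranked: Sequence[tuple[str, float]],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Running-sum enrichment of ``gene_set`` in a descending ranked list.

    Unweighted increments (+1/Nh at hits, -1/(L-Nh) at misses); ES is the
    signed extremum.  The p-value is the fraction of gene-set permutations
    (random same-size sets) whose |ES| reaches |ES_observed|, with +1
    smoothing.  ES depends only on hit positions, so it is invariant to any
    strictly monotone transformation of the ranking values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vals = [v for _, v in ranked]
    if any(vals[i] < vals[i + 1] for i in range(len(vals) - 1)):
        raise ValueError("ranked list must be sorted by descending value")
    genes = [g for g, _ in ranked]
    hit_mask = np.array([g in gene_set for g in genes])
    L, nh = hit_mask.size, int(hit_mask.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    es, running = _es_from_hits(hit_mask)

    if es >= 0:
        peak = int(np.argmax(np.abs(running)))
        leading = [g for g, h in zip(genes[: peak + 1], hit_mask[: peak + 1]) if h]
    else:
        trough = int(np.argmax(np.abs(running)))
        leading = [g for g, h in zip(genes[trough:], hit_mask[trough:]) if h]

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        null_mask = np.zeros(L, dtype=bool)
        null_mask[rng.choice(L, size=nh, replace=False)] = True
        es_null, _ = _es_from_hits(null_mask)
        if abs(es_null) >= abs(es):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return GseaResult(es=es, p_value=float(p), leading_edge=leading, n_hits=nh)
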