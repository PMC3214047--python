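"""Sliding-window ChIP-chip peak detection with randomization FDR.

The detection rule: per-probe log2 enrichment of ChIP over input, a global
cutoff of mean + 6 x sample SD of all probe log-ratios ("hypothetical
maximum"), and a 500 bp sliding window that qualifies wherever four or more
above-cutoff probe midpoints fall inside it.  Overlapping qualifying windows
that share a supporting probe merge into one peak spanning its supporting
probes; the peak score is the mean log2 ratio of those probes.

The false discovery rate is empirical: probe values are permuted across probe
positions (spatial clustering destroyed, value distribution — and hence the
cutoff — preserved) and detection is rerun; a peak scoring s gets
FDR = E[# null peaks >= s] / (# observed peaks >= s), monotone-adjusted so FDR
never increases with score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import Peak, ProbeRecord


@dataclass
class PeakCallingConfig:
    window_bp: int = 500
    min_probes: int = 4
    sd_multiplier: float = 6.0
    n_randomizations: int = 20
    fdr_threshold: float = 0.01
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.min_probes <= 0 or self.sd_multiplier <= 0:
            raise ValueError("window_bp, min_probes and sd_multiplier must be positive")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")


class SignalTrack:
    """Per-chromosome sorted probe intervals with one finite log2 ratio each."""

    def __init__(self, chroms: Sequence[str], starts, ends, values):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("signal track values must be finite")
        order = np.lexsort((starts, np.asarray(chroms)))
        self.chroms = np.asarray(chroms)[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.values = values[order]

    def __len__(self) -> int:
        return len(self.values)

    def per_chrom(self):
        """Yield (chrom, starts, ends, values) with arrays sorted by start."""
        for chrom in np.unique(self.chroms):
            m = self.chroms == chrom
            yield chrom, self.starts[m], self.ends[m], self.values[m]

    def with_values(self, values) -> "SignalTrack":
        t = SignalTrack.__new__(SignalTrack)
        t.chroms, t.starts, t.ends = self.chroms, self.starts, self.ends
        t.values = np.asarray(values, dtype=float)
        return t


def compute_enrichment(
    probes: Sequence[ProbeRecord], pseudocount: float = 1.0
) -> SignalTrack:
    """log2((chip + pseudocount) / (input + pseudocount)) per probe."""
    chip = np.array([p.chip for p in probes], dtype=float)
    inp = np.array([p.input for p in probes], dtype=float)
    if (chip < 0).any() or (inp < 0).any():
        raise ValueError("intensities must be non-negative")
    values = np.log2((chip + pseudocount) / (inp + pseudocount))
    return SignalTrack(
        [p.chrom for p in probes],
        [p.start for p in probes],
        [p.end for p in probes],
        values,
    )


def compute_cutoff(track: SignalTrack, sd_multiplier: float = 6.0) -> float:
    """Global cutoff: mean + sd_multiplier x sample SD over the whole track."""
    if len(track) < 2:
        raise ValueError("need >= 2 probes to compute a cutoff")
    v = track.values
    return float(v.mean() + sd_multiplier * v.std(ddof=1))


def _qualifying_ranges(mids: np.ndarray, window_bp: int, min_probes: int):
    """Maximal index ranges [lo, hi] of above-cutoff midpoints contained in some
    qualifying width-``window_bp`` window.

    Every window's probe content is a contiguous run of sorted midpoints, and
    every maximal run is realized by the integer-start window anchored at
    floor(m_lo); enumerating those anchors covers all qualifying windows.
    """
    ranges = []
    anchors = np.floor(mids).astype(np.int64)
    lo_idx = np.searchsorted(mids, anchors, side="left")
    hi_idx = np.searchsorted(mids, anchors + window_bp, side="left") - 1
    for lo, hi in zip(lo_idx.tolist(), hi_idx.tolist()):
        if hi - lo + 1 >= min_probes:
            ranges.append((lo, hi))
    return ranges


def _merge_index_ranges(ranges):
    """Union of index ranges that share at least one index."""
    merged = []
    for lo, hi in sorted(ranges):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def sliding_window_peaks(
    track: SignalTrack, cutoff: float, cfg: PeakCallingConfig
) -> list[Peak]:
    """Detect peaks: windows of ``window_bp`` holding >= ``min_probes``
    above-cutoff probe midpoints, merged where they share a supporting probe."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    peaks = []
    for chrom, starts, ends, values in track.per_chrom():
        above = values > cutoff
        if above.sum() < cfg.min_probes:
            continue
        mids = (starts[above] + ends[above]) / 2.0
        a_starts, a_ends, a_vals = starts[above], ends[above], values[above]
        ranges = _qualifying_ranges(mids, cfg.window_bp, cfg.min_probes)
        for lo, hi in _merge_index_ranges(ranges):
            peaks.append(
                Peak(
                    chrom=str(chrom),
                    start=int(a_starts[lo]),
                    end=int(a_ends[lo:hi + 1].max()),
                    n_probes=hi - lo + 1,
                    score=float(a_vals[lo:hi + 1].mean()),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def randomization_fdr(
    track: SignalTrack,
    peaks: list[Peak],
    cutoff: float,
    cfg: PeakCallingConfig,
) -> list[Peak]:
    """Attach an empirical FDR to each peak by value permutation.

    Each randomization permutes log2 ratios uniformly across all probe
    positions and reruns detection; FDR(s) = mean null count of peaks scoring
    >= s over the observed count, truncated to [0, 1] and monotone-adjusted
    (running minimum from worst to best score).
    """
    if cfg.n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if not peaks:
        return []
    rng = np.random.default_rng(cfg.seed)
    null_scores = []
    for _ in range(cfg.n_randomizations):
        permuted = track.with_values(rng.permutation(track.values))
        null_scores.extend(p.score for p in sliding_window_peaks(permuted, cutoff, cfg))
    null_scores = np.sort(np.asarray(null_scores, dtype=float))
    obs_scores = np.asarray([p.score for p in peaks], dtype=float)
    obs_sorted = np.sort(obs_scores)

    # counts of scores >= s
    null_ge = len(null_scores) - np.searchsorted(null_scores, obs_scores, side="left")
    obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, obs_scores, side="left")
    fdr = np.clip(null_ge / cfg.n_randomizations / obs_ge, 0.0, 1.0)

    # monotone adjustment: FDR non-increasing in score
    order = np.argsort(-obs_scores, kind="stable")
    adj = np.minimum.accumulate(fdr[order][::-1])[::-1]
    fdr_adj = np.empty_like(fdr)
    fdr_adj[order] = adj
    return [replace(p, fdr=float(f)) for p, f in zip(peaks, fdr_adj)]


def call_peaks(
    probes: Sequence[ProbeRecord], cfg: PeakCallingConfig | None = None
) -> list[Peak]:
    """Full detection: enrichment -> cutoff -> sliding window -> randomization
    FDR -> threshold at ``cfg.fdr_threshold``.  Output sorted by (chrom, start)."""
    cfg = cfg or PeakCallingConfig()
    track = compute_enrichment(probes, cfg.pseudocount)
    cutoff = compute_cutoff(track, cfg.sd_multiplier)
    candidates = sliding_window_peaks(track, cutoff, cfg)
    with_fdr = randomization_fdr(track, candidates, cutoff, cfg)
    kept = [p for p in with_fdr if p.fdr < cfg.fdr_threshold]
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept
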