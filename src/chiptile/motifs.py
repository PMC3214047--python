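"""k-mer overrepresentation motif discovery and IUPAC consensus scanning.

The discovery core ranks exact k-mers (forward and reverse-complement
occurrences collapsed onto a canonical strand) by a binomial z-score of their
foreground count against a per-position background frequency, then builds a
position weight matrix (PWM) from the mismatch neighbourhood of the top k-mer.
Degenerate consensus elements such as the interferon-stimulated response
element (ISRE, GAAANNGAAA) and the ETS-IRF composite element (EICE,
TTTCNNTTCC) are located by exact IUPAC scanning on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

# canonical consensus elements for IRF-family composite sites
ISRE_CONSENSUS = "TTTCNNTTTC"   # two tandem IRF half-sites (TTTC) spaced by 2 nt
EICE_CONSENSUS = "TTTCNNTTCC"   # ETS-IRF composite element
EICE_SITE = "GGAAGTGAAAC"       # concrete EICE instance (reverse strand GTTTCACTTCC)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerScore:
    kmer: str        # canonical form
    fg_count: int
    expected: float
    z_score: float


@dataclass
class PWM:
    """Column-stochastic base-frequency matrix: ``matrix[i]`` is the (A,C,G,T)
    distribution at motif position i and sums to 1."""

    width: int
    matrix: np.ndarray          # shape (width, 4)
    source_kmer: str
    z_score: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.width, 4):
            raise ValueError("PWM matrix must have shape (width, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# sequence encoding helpers

def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; any non-ACGT character becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of the canonical form of every valid k-window of ``seq``."""
    enc = _encode(seq)
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (windows < 4).all(axis=1)
    windows = windows[valid]
    if windows.size == 0:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows @ powers
    rc = (3 - windows[:, ::-1]) @ powers
    return np.minimum(fwd, rc)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _n_positions(sequences: Iterable[str], k: int) -> int:
    return sum(max(len(s) - k + 1, 0) for s in sequences)


# ---------------------------------------------------------------------------
# operations

def extract_peak_sequences(
    peaks: Sequence, genome: Mapping[str, str], flank_bp: int = 0
) -> dict[str, str]:
    """Uppercase sequence of each peak interval +/- ``flank_bp``; ids encode coordinates."""
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in genome:
            raise ValueError(f"peak {p.name}: chromosome {p.chrom!r} not in genome")
        chrom_seq = genome[p.chrom]
        lo, hi = p.start - flank_bp, p.end + flank_bp
        if lo < 0 or hi > len(chrom_seq):
            raise ValueError(
                f"peak {p.name}: interval [{lo},{hi}) out of bounds for "
                f"{p.chrom} (length {len(chrom_seq)})"
            )
        out[f"{p.chrom}:{lo}-{hi}"] = chrom_seq[lo:hi].upper()
    return out


def kmer_zscores(
    foreground: Mapping[str, str] | Sequence[str],
    background: Mapping[str, str] | Sequence[str],
    k: int = 10,
) -> list[KmerScore]:
    """Rank canonical k-mers by binomial z against the background frequency.

    Counts collapse a k-mer and its reverse complement; every k-window of every
    sequence contributes one canonical observation (overlaps counted).  The
    background per-position frequency is half-count smoothed,
    p = (count + 0.5) / (N_bg + 1), so the expectation is strictly positive
    and z-scores stay finite for k-mers unseen in a finite background.
    """
    fg_seqs = list(foreground.values()) if isinstance(foreground, Mapping) else list(foreground)
    bg_seqs = list(background.values()) if isinstance(background, Mapping) else list(background)
    if k < 4:
        raise ValueError("k must be >= 4")
    if fg_seqs and min(len(s) for s in fg_seqs) < k:
        raise ValueError("k longer than the shortest foreground sequence")
    n_bg = _n_positions(bg_seqs, k)
    if n_bg < 10 * k:
        raise ValueError("background too small (need total length >= 10k)")

    def _all_codes(seqs: list[str]) -> np.ndarray:
        parts = [_window_codes(s, k) for s in seqs]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    fg_all = _all_codes(fg_seqs)
    bg_all = _all_codes(bg_seqs)
    n_fg = _n_positions(fg_seqs, k)

    codes = np.concatenate([fg_all, bg_all])
    uniq, inverse = np.unique(codes, return_inverse=True)
    fg_counts = np.bincount(inverse[: len(fg_all)], minlength=len(uniq))
    bg_counts = np.bincount(inverse[len(fg_all):], minlength=len(uniq))
    p_bg = (bg_counts + 0.5) / (n_bg + 1)
    expected = n_fg * p_bg
    z = (fg_counts - expected) / np.sqrt(expected * (1.0 - p_bg))

    scores = [
        KmerScore(_decode(int(c), k), int(f), float(e), float(zz))
        for c, f, e, zz in zip(uniq, fg_counts, expected, z)
    ]
    scores.sort(key=lambda s: (-s.z_score, s.kmer))
    return scores


def _hamming_rows(windows: np.ndarray, target: np.ndarray) -> np.ndarray:
    return (windows != target).sum(axis=1)


def build_pwm(
    top_kmer: str,
    foreground: Mapping[str, str] | Sequence[str],
    max_mismatch: int = 1,
    pseudocount: float = 0.25,
) -> PWM:
    """PWM from all foreground occurrences of ``top_kmer`` within ``max_mismatch``.

    Occurrences on either strand are oriented to the k-mer's strand before
    stacking; counts are smoothed with ``pseudocount`` per base and
    position-normalized.
    """
    seqs = list(foreground.values()) if isinstance(foreground, Mapping) else list(foreground)
    k = len(top_kmer)
    target = _encode(top_kmer)
    if (target >= 4).any():
        raise ValueError("top_kmer must be plain ACGT")
    counts = np.zeros((k, 4), dtype=float)
    n_occ = 0
    for s in seqs:
        enc = _encode(s)
        if len(enc) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (windows < 4).all(axis=1)
        win = windows[valid]
        if win.size == 0:
            continue
        d_fwd = _hamming_rows(win, target)
        rc_win = 3 - win[:, ::-1]
        d_rc = _hamming_rows(rc_win, target)
        use_fwd = d_fwd <= max_mismatch
        use_rc = (d_rc <= max_mismatch) & ~use_fwd  # forward orientation wins ties
        for w in win[use_fwd]:
            counts[np.arange(k), w] += 1
            n_occ += 1
        for w in rc_win[use_rc]:
            counts[np.arange(k), w] += 1
            n_occ += 1
    if n_occ == 0:
        raise ValueError(
            f"no occurrence of {top_kmer!r} within {max_mismatch} mismatches"
        )
    counts += pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return PWM(width=k, matrix=matrix, source_kmer=top_kmer)


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")  # overlapping matches


def scan_consensus(
    sequences: Mapping[str, str], pattern: str
) -> dict[str, list[tuple[int, str]]]:
    """Exact IUPAC matching on both strands.

    Returns per-sequence lists of (offset, strand); offsets are 0-based on the
    forward strand, minus-strand hits come from matching the reverse complement
    of ``pattern``.  If the pattern is its own reverse complement both strands
    are reported.
    """
    if not pattern:
        raise ValueError("empty pattern")
    fwd = _iupac_regex(pattern)
    rc_pattern = reverse_complement(pattern.upper())
    rev = _iupac_regex(rc_pattern)
    same = rc_pattern == pattern.upper()
    hits: dict[str, list[tuple[int, str]]] = {}
    for name, seq in sequences.items():
        s = seq.upper()
        found = [(m.start(), "+") for m in fwd.finditer(s)]
        if not same:
            found += [(m.start(), "-") for m in rev.finditer(s)]
        else:
            found += [(off, "-") for off, _ in found]
        found.sort()
        hits[name] = found
    return hits
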