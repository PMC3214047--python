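# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design choices made where the problem was
genuinely open. Everything quantitative claimed here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Peak detection on promoter tiling arrays

The substrate is a two-colour promoter tiling array: for each gene, probes
(60 bp, 100 bp spacing by default) tile the window from 3.5 kb upstream to
0.75 kb downstream of the TSS in transcription orientation. Per-probe
enrichment is `log2((chip + c) / (input + c))` with pseudocount `c = 1.0`,
which guards zero intensities without materially shifting mid-range signals
(channel baselines are ~2^10).

**Cutoff.** The detection threshold is global over the analysed track (not
per chromosome): mean + `sd_multiplier` × sample SD of all probe log-ratios,
with `sd_multiplier = 6`. A 6-SD cutoff presumes the enriched fraction of
probes is small; when planted (or true) sites occupy more than a few percent
of probes they inflate the SD and the cutoff can exceed the enrichment
itself, so detection collapses on very small arrays with dense signal. This
is a property of the rule, not a bug; the synthetic study conditions keep the
enriched fraction near 1%.

**Window rule.** A window of `window_bp = 500` qualifies iff at least
`min_probes = 4` above-cutoff probe *midpoints* lie inside it. Qualifying
windows that share a supporting probe merge (transitively) into one peak
spanning the supporting probes; the score is the mean log2 ratio of those
probes (a region summary, deliberately not the max). The implementation
enumerates only windows anchored at `floor(midpoint)` of each above-cutoff
probe — every maximal window content occurs at such an anchor — and is tested
for exact equality against brute-force 1 bp window enumeration.

**Randomization FDR.** The null model permutes log2 ratios uniformly across
all probe positions, destroying spatial clustering while preserving the value
distribution (hence the cutoff is unchanged). With `n_randomizations = 20`,
a peak scoring *s* gets `FDR = mean_b(#null peaks ≥ s) / (#observed ≥ s)`,
truncated to [0, 1] and monotone-adjusted (running minimum from worst to best
score) so FDR never increases with score. Peaks are reported at
`fdr_threshold = 0.01` (strict inequality). The randomization scheme and the
per-peak (rather than per-threshold) FDR are our documented choices; both are
configurable.

## Annotation

A peak is assigned to every gene whose design window contains the peak
midpoint; a gene with several peaks keeps its highest-scoring one, and the
target list is deduplicated by symbol. Classification is at the peak
midpoint:

- inside the transcript body → intragenic, subdivided by the midpoint base:
  exonic 5′ of the CDS → 5′UTR, within the CDS span → coding exon, exonic 3′
  of the CDS → 3′UTR, otherwise intron. Intragenic takes precedence over the
  promoter classes even within 1 kb of the TSS.
- upstream of the TSS → proximal promoter within `proximal_bp = 1000`,
  distal promoter beyond it (the 1 kb boundary is a package default — the
  natural cut given how concentrated binding is within ±1 kb — and is
  configurable).
- downstream of the transcript but still on the array → other.

CDS coordinates follow thickStart/thickEnd semantics: they delimit the
genomic CDS span and both endpoints must fall inside exons. Non-coding
transcripts have no CDS; their exonic midpoints are binned as 5′UTR-like
untranslated material, a documented approximation (the synthetic generator
only emits coding genes). A midpoint can sit at a half-integer position
(even-length peak); interval membership uses the exact midpoint, the stored
TSS distance rounds to the nearest integer.

## Synthetic data and its truth ledger

Generators are pure functions of (configuration, seed) and record everything
they plant, so recovery is assertable by inspection.

- **Genome/genes:** uniform-random sequence; non-overlapping genes in fixed
  slots (8 kb spacing, so neighbouring design windows rarely interact),
  alternating strand, 2–4 exons, CDS plus 5′/3′ UTRs — every intragenic
  subclass is realizable.
- **ChIP signals:** both channels independently log-normal around a 2^10
  baseline with `noise_sd` (default usage 0.3) on the log2 scale, so
  off-site log-ratios are N(0, √2·noise_sd). Planted genes get a 500 bp
  window centred on the TSS (offsettable to exercise distal/intragenic
  classes) where the ChIP channel gains `2^enrichment_log2` (default usage
  5). A planted window must cover ≥ 4 probes or generation fails loudly.
- **Expression:** per-gene baselines uniform on log2 [4, 12], Gaussian noise
  (`noise_sd = 0.5` in the study conditions); a `de_fraction` of genes is
  shifted ±`effect_log2` in the case group with random sign. The knockdown
  design defaults to 6 vs 6 replicates, matching the larger of the two
  replicate counts the source design used; tests exercise 5 vs 5 as well.
- **Motifs:** one concrete IUPAC resolution of the consensus per selected
  sequence (not Poisson-many), at a uniform offset and strand — this makes
  recovery tests exact. The default planted element is the EICE instance
  `GGAAGTGAAAC`.

What the generator deliberately omits: dye bias, spatial artifacts, probe GC
effects, replicate correlation, heavy-tailed expression noise. Passing tests
therefore demonstrate correctness of the *procedures* under a clean
two-channel noise model, not robustness to real-array artifacts.

## SAM-style differential expression

`d = (mean_case − mean_control) / (se + s0)` with the pooled two-sample
standard error. The fudge constant `s0` is the 5th percentile of per-gene
pooled SEs — a simpler, monotone alternative to the coefficient-of-variation
search in the original SAM, overridable with a fixed value. The null comes
from distinct case/control label assignments (full enumeration when ≤
`n_permutations = 200`, otherwise a seeded subsample; the observed assignment
is included, which is mildly conservative). Per gene,
`q = median_b(#null |d*| ≥ |d|) / #observed |d| ≥ |d|`, truncated to [0, 1]
and monotone-adjusted (suffix minimum in order of decreasing |d|).
Significance at `q < 0.01`, split into up/down by fold-change sign. On null
tables the significant fraction stays within the binomial envelope of 1%;
at 10% planted effects of 2.0 log2 units (5v5, noise 0.5) recall exceeds
0.8 — both measured by the acceptance suite.

Cross-platform validation is ordinary least squares of one platform's
log2 fold changes on the other's over shared genes (case-insensitive symbol
match, ≥ 3 genes), reporting slope, 1/slope, intercept, r² and the two-sided
p for slope ≠ 0.

## GSEA-style running enrichment

Classic unweighted Kolmogorov–Smirnov running sum over a descending ranked
list: +1/Nh at set members, −1/(L−Nh) elsewhere; ES is the signed extremum,
so it depends only on hit positions and is invariant to monotone
transformations of the ranking values. The p-value uses *gene-set
permutation* (random same-size sets, `+1` smoothing): with 5–6 replicates
per arm, phenotype permutation would rest on too few distinct label
assignments to be stable. Leading edge: members at or before the extremum
(after it for negative ES).

## Motif discovery

k-mers (default `k = 10`, the ISRE/EICE core length; sensible range 6–12)
are counted over every window of every sequence with forward and
reverse-complement forms collapsed to the lexicographically smaller
canonical form; overlapping occurrences count (documented; negligible for
non-periodic motifs). Against a user-supplied background (in the pipeline:
promoter design windows of non-target genes), the score is a binomial z,

    z = (n_fg − E) / sqrt(E (1 − p)),   E = N_fg_positions · p,

with the background per-position frequency half-count smoothed,
`p = (count_bg + 0.5) / (N_bg + 1)`. The smoothing is essential at k = 10:
a finite background (~10^5–10^6 windows) leaves most of the ~5·10^5
canonical 10-mers unseen, and an unsmoothed frequency of zero would make
every foreground-only k-mer infinitely significant. Exact k-mers with
degeneracy deferred to PWM construction replace enumeration of degenerate
motifs: the core stays oracle-checkable while producing the same scientific
output, a ranked matrix.

The PWM stacks all foreground occurrences within `max_mismatch = 1` of the
top k-mer (reverse-strand occurrences oriented to the k-mer), adds 0.25 per
base and position-normalizes. Consensus scanning is exact IUPAC matching on
both strands with overlapping hits, offsets 0-based on the forward strand;
a palindromic pattern reports both strands at the same offset.

## Pipeline semantics

Stages communicate only through files; the manifest records a config
snapshot (output directory excluded), SHA-256 digests of all inputs, and
per-stage output lists and filter counts (probes → peaks → targets → after
control subtraction), so the analysis flow numbers are inspectable. No
output embeds timestamps or absolute output paths: a rerun with the same
configuration and seeds is byte-identical, and the acceptance suite asserts
it.

Direction convention for the knockdown integration: a bound gene whose
expression *falls* on knockdown (case − control < 0) is labelled
**activated** by the factor; bound and up is **repressed**.

## Problem sizes

The packaged study conditions are sized for a single CPU: 500-gene arrays
(21,500 probes) for recovery, ~2,000-probe null arrays across 20 seeds for
FDR calibration, 400-gene three-line designs for the Venn flow, 1,000-gene
expression tables with 200 permutations, 500 spiked sequences against a
500 kb background for motif recovery. These sizes give stable pass/fail
behaviour for the stated thresholds while keeping a full run in minutes.

## Known limitations

- No between-array normalization (quantile/loess) or replicate-combining
  model; inputs are assumed normalized.
- The mean+6SD cutoff degrades gracefully only while enriched probes are a
  small fraction of the track (see above).
- Nearest-gene assignment outside the design window is out of scope: the
  array platform defines the searchable space.
- The proximal/distal split at 1 kb is a convention; published proportions
  obtained with other boundaries will not be reproduced numerically.
- Ortholog mapping without a table falls back to case-insensitive symbol
  identity, which misses renamed orthologs.
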