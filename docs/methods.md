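# Methods

This note documents the models and procedures crescan implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter
when comparing results across tools.

## Motif model and scanning

A PWM is parsed from TRANSFAC flat-file count records (`AC`/`ID`/`DE`
header lines, numbered `pos A C G T [consensus]` rows, `//`
terminator). Frequencies are plain row-normalized counts — no
pseudocounts. Because matches are scored with a min–max-normalized
similarity rather than log-odds, zero frequencies are harmless: they
simply pin the per-position minimum at zero.

The matrix similarity score (MSS) weights each position by its
information content `I(i) = Σ_b f(i,b)·ln(4·f(i,b))` (0 for a uniform
row, ln 4 for a certain one; `0·ln 0 := 0`) and min–max-normalizes the
weighted frequency sum over the window, so MSS ∈ [0, 1] with the
consensus at exactly 1. This is the scoring convention associated with
TRANSFAC matrix libraries and the 0.85/0.99 threshold style. The
*core* is the 5 consecutive positions of maximal summed information
(leftmost on ties; matrices shorter than 5 positions use the whole
matrix and are flagged), and the core score is the MSS restricted to
those positions. Degenerate cases: a zero-information matrix scores 1
on any window (Max = Min); windows containing any non-ACGT character
score 0, which deliberately refuses to fabricate matches inside masked
or ambiguous sequence.

Scanning evaluates every window start on both strands — a minus-strand
hit means the matrix matches the reverse complement of the window and
is reported at the window's start offset in gene orientation. A
sequence of length *n* yields exactly `2·(n−L+1)` candidate windows.
Overlapping hits, and opposite-strand hits at the same offset, are
counted as distinct sites; no collapsing rule is applied at the hit
level. The scanner is vectorized (stride-tricks window view + fancy
indexing), which is what keeps the 100-replicate benchmark experiment
in the acceptance suite around a minute on one CPU.

Sequence logos for matched site sets are built *a posteriori* from the
actual window contents (minus-strand windows reverse-complemented
first), yielding an L×4 count matrix; `plotting.plot_logo` renders it
as stacked information-scaled bars. A dedicated glyph-stretching logo
renderer was considered out of scope; the count matrix itself is the
tested artifact.

## Promoter frames and deduplication

All coordinates are 0-based half-open. TSS-relative position 0 is the
TSS base itself; upstream is negative. The proximal window defaults to
(−600, +100) and deep upstream regions to (−20000, +100). For a
minus-strand gene the genomic slice `[tss−end+1, tss−start+1)` is
reverse-complemented so every promoter is stored in gene orientation.
Slices running off a contig are clipped and flagged `truncated`;
truncated promoters are retained and scanned over their available
sequence, since the per-promoter count statistic tolerates unequal
lengths. Whether the background should exclude truncated or very short
promoters is a judgment call; the default here is to include them.

Deduplication keeps one record per gene (leftmost genomic start) and
then resolves genomically overlapping windows between distinct genes
with a left-to-right sweep — the survivor of any conflict is the
leftmost-starting window, ties broken by gene id. The sweep guarantees
a pairwise non-overlapping result (asserted against a quadratic oracle
in the tests). The survivor rule itself is a convention: any
deterministic one-per-conflict rule would do, and none is canonical.

## Enrichment statistics

Foreground = the regulated gene set (selected as |log₂FC| > 1 and
adjusted p < 0.01 by default, direction-restricted when asked);
background = a uniform random sample (default n = 1000, seeded) from
the deduplicated promoter universe minus the foreground.

The Mann–Whitney–Wilcoxon test is two-sided; direction is read off the
d/b ratio, and the pass criteria impose direction anyway through
`log₂(d/b) ≥ 1`. Per-promoter site counts are heavily tied, so the
normal approximation with tie-corrected variance (and continuity
correction) is the default; exact enumeration is used automatically
only when both sets have ≤8 genes and the pooled counts are tie-free,
and can be forced via `method=`. When the background mean b is 0 the
enrichment is undefined (NaN, never passes); a diagnostic ratio with b
floored at one site over the whole background is reported separately
rather than silently inflating the headline statistic.

BH adjustment runs over all matrices tested in the run, including
matrices with zero hits. Redundancy collapsing keeps, within each
matrix group, the result with the smallest adjusted p (ties: raw p,
then matrix id). The default grouping — shared factor-name prefix of
the matrix id — is a heuristic stand-in for what is inherently an
editorial grouping; callers can pass an explicit mapping.

Positional profiles use the distance of a hit's start upstream of the
TSS, `max(0, −offset)`; hits at or downstream of the TSS count at
distance 0 and therefore appear in every cumulative bin. Curves are
cumulative fractions of genes with ≥1 site within each 200-bp bin
boundary up to 20 kb, so they are nondecreasing and bounded by [0, 1]
by construction; the foreground-minus-background difference is the
reported enrichment curve.

Cooperativity relates per-gene site counts to induction strength:
class medians of log₂FC for genes with 0, 1 or >1 sites, plus a
two-sided Spearman rank correlation between raw count and log₂FC
(rank-based, consistent with the rest of the nonparametric stack).
Degenerate inputs — constant counts or constant fold changes — are
reported as ρ = 0, p = 1 rather than NaN, so "no detectable
association" is the stated conclusion. "Per gene normalized"
time-course values are row-mean-centered log₂ values (z-scoring is
available behind a flag); the time-course heat map in `plotting` is a
thin rendering (Euclidean-distance hierarchical clustering for row
order), not a tested statistical claim.

## nCounter processing

Background threshold: per sample, mean + 2·SD of the negative-control
counts, with the sample (n−1) SD, requiring ≥2 negatives. Corrected
counts are clamped at zero — counts are physical. Reference selection
uses the coefficient of variation of log₂(count+1) across samples and
takes the k = 7 smallest (deterministic tie-break by gene id);
geNorm-style pairwise stability was deliberately left out of scope.
Note that per-sample scale variation is common-mode noise this metric
cannot remove, so at small sample counts it compresses the contrast
between genuinely stable and noisy candidates — the reference-selection
benchmark in the tests therefore uses 8 replicates per condition.

Normalization rescales each sample by `mean(g)/g_s`, where `g_s` is
the geometric mean of the reference genes in sample s. Anchoring on
the mean of the per-sample geometric means keeps values on the
original count scale; any positive anchor yields identical
between-sample ratios, which is the quantity all downstream calls use.
Consequently, rescaling one sample's raw counts by c > 0 (negatives
included — the clamp commutes with positive scaling) changes the
normalized matrix by exactly one global factor and leaves every
expression ratio invariant. Repression is called per gene on condition
means over replicates: `(mean_mock − mean_treated)/mean_mock > 0.20`,
undefined (with a warning) when the mock mean is 0. The same
>20%-reduction rule doubles as the dependence criterion in the Fisher
analyses; no claim is made that it uniquely reproduces any particular
published split. Fisher's exact test is two-sided by the
minimum-likelihood convention (sum of all hypergeometric outcomes no
more probable than the observed table) — the convention that
reproduces the published p = 0.0019 for the 11/19-vs-2/21 table — and
is cross-checked in the tests against an independent enumeration over
the hypergeometric mass function.

## Synthetic data: what it emulates and what it does not

The generator produces (a) i.i.d.-base genomes at a controlled GC
content with non-overlapping, both-strand gene layouts; (b) promoters
with Poisson(λ)-distributed planted motif instances sampled from the
PWM's frequency rows, at uniform or TSS-proximal exponential
positions, never overwriting one another; (c) DE tables with
designated up/down truth sets (log₂FC ~ Normal(±effect, SD), effect
1.5, SD 0.3 by default); and (d) nCounter runs built as Poisson
background plus per-sample-scaled log-normal signal with planted 40%
repression in a designated gene class. Everything is deterministic
given a seed, and manifests record every planted instance.

Default study conditions: λ = 2.0 sites/promoter in 60 regulated genes
versus λ = 0.5 in 1000 background promoters, window (−600, +100),
GC 0.5. The standard planted matrix is a fixed, sharp 12-position
ISRE-like matrix (dominant base 97% per position). Because planted
instances are *sampled* from the matrix, a predictable fraction falls
below the 0.85/0.99 thresholds; this thinning applies equally to
foreground and background, so the measured log₂(d/b) stays centered on
the planted density contrast (log₂ 4 = 2) while absolute densities sit
below the planted λ.

What passing tests on this generator do **not** show: real promoters
are not i.i.d. sequence (GC heterogeneity, CpG islands, repeats all
modulate spurious hit rates), real motif occurrences are not Poisson
or independent of position and of each other, microarray effect sizes
are not Gaussian with uniform p-values, and real nCounter noise has
probe-specific components. The pipeline's statistics are defined
relative to whichever scanner and background set are plugged in;
absolute hit counts and percentages on real data will differ with the
matrix library, annotation build and scoring program used.

## Numerical conventions and problem sizes

Tie-breaks are deterministic everywhere (leftmost core, leftmost
surviving promoter, lexicographic gene/matrix ids) so reruns are
byte-identical. Information values within 1e-15 of zero are clamped to
zero to make "uniform row → exactly 0" hold in floating point. The
test and acceptance workloads use 100 sequence-level replicates for
the planted-motif experiment, 500 null simulations for the
Mann–Whitney calibration, 1000 random PWM/window pairs for the scoring
oracle and 200 random 2×2 tables for the Fisher oracle — sizes chosen
so the full suite runs in about two minutes on one CPU while keeping
Monte-Carlo bands (3 binomial SDs) tight enough to be meaningful.

## Known limitations

- The MSS/MATCH scoring convention is the de-facto standard for
  TRANSFAC-style matrices, but other scanners (log-odds with
  background models, p-value-calibrated thresholds) will produce
  different absolute hit counts; only the relative enrichment
  machinery is scanner-agnostic.
- The background gene sample is uniform; GC- or length-matched
  background resampling is not implemented.
- Redundancy grouping by id prefix is a heuristic; curated groups
  should be supplied for real matrix libraries.
- Reference-gene stability by CV of log counts is simple and
  transparent but suboptimal when per-sample scale variation dominates
  (see above); with many candidates and few samples, prefer more
  replicates or a pairwise-stability method.
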