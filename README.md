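# crescan

Promoter cis-regulatory element analysis for interferon-style
transcriptional responses: TRANSFAC-format position-weight-matrix (PWM)
scanning of promoter sequences, per-promoter site-count enrichment
statistics, positional profiling of binding sites upstream of the
transcription start site (TSS), induction-strength/cooperativity
analyses, and NanoString-nCounter-style digital count normalization
with Fisher-exact dependence testing.

It is written for regulatory genomicists who have (a) a set of
co-regulated genes from a differential-expression experiment and want
to know which transcription-factor binding motifs are over-represented
in their promoters, and/or (b) multiplexed digital count data
(nCounter-like) to normalize and test. Every stage can also be driven
by the built-in synthetic-data module, which plants motifs and effects
with known ground truth, so the whole pipeline is verifiable end to
end without any external downloads.

## The statistics at the core

**Motif scanning.** A match of a PWM of length *L* to a sequence
window *s* is scored with the matrix similarity score

```
MSS = (Current − Min) / (Max − Min)
Current = Σᵢ I(i) · f(i, sᵢ)
Min/Max = Σᵢ I(i) · min_b / max_b f(i, b)
I(i)    = Σ_b f(i, b) · ln(4 f(i, b))
```

where `f(i, b)` is the frequency of base *b* at position *i* and
`I(i)` the position's information weight. A consensus window scores
exactly 1. The *core score* is the same statistic restricted to the 5
consecutive positions of maximal summed information. Both strands of
each promoter (default window −600 to +100 around the TSS) are
scanned; a window is a hit when MSS ≥ 0.85 **and** core score ≥ 0.99.

**Enrichment.** For each matrix, sites per promoter are counted in a
regulated gene set (*foreground*) and a random background set. The two
count distributions are compared with a two-sided
Mann–Whitney–Wilcoxon test; p-values are Benjamini–Hochberg adjusted
across matrices. The reported effect is `log₂(d/b)`, the log-ratio of
mean sites per promoter in foreground (d) versus background (b). A
matrix *passes* when `log₂(d/b) ≥ 1` (≥2-fold), adjusted `p < 0.005`,
and sites occur in ≥5 foreground promoters covering ≥25% of the set.
Highly redundant matrices are collapsed to the group member with the
smallest adjusted p.

**Positional profiles.** Over 20 kb upstream regions, the cumulative
fraction of genes with ≥1 site within each 200-bp distance bin of the
TSS is computed for foreground and background, and their difference
highlights where the signal concentrates.

**nCounter normalization.** Per sample, the mean + 2 SD of the
negative-control counts is subtracted from every gene (clamped at 0);
samples are then rescaled so the geometric mean of the 7 most stable
reference genes (smallest CV of log₂ counts) is equal everywhere.
Genes whose treated mean drops >20% below the mock mean are called
repressed, and 2×2 gene-class × call tables are tested with the
two-sided (minimum-likelihood) Fisher exact test.

## Worked example

`examples/02_motif_enrichment.py` plants an ISRE-like matrix at 2.0
sites/promoter in 60 "regulated" promoters versus 0.5 in 1000
background promoters, scans, and runs the full statistics stack:

```
matrix                 : V$ISRE_01
mean sites/promoter (d): 1.700 in the regulated set
mean sites/promoter (b): 0.410 in the background
log2(d/b) enrichment   : 2.05  (2.0 = 4-fold)
promoters with sites   : 46/60 (77%)
MWW p (BH-adjusted)    : 4.23e-18
passes all criteria    : True
```

The measured densities are below the planted rates because sampled
(non-consensus) instances occasionally fall under the match
thresholds, but the thinning hits both sets equally, so the measured
`log₂(d/b)` of 2.05 recovers the planted 4-fold density contrast. See
`examples/` for scanning, positional profiling, nCounter normalization
and cooperativity walk-throughs; each prints the numbers it computes
and a line on how to read them.

A thin CLI wraps the same library calls:

```bash
crescan simulate --outdir sim --seed 1      # synthetic input bundle
crescan enrich --genome sim/genome.fa --tss sim/tss.bed \
    --matrices sim/matrices.transfac --de-table sim/de_table.tsv \
    --outdir out --seed 1
crescan ncounter --counts sim/ncounter_counts.tsv \
    --roles sim/ncounter_roles.tsv --meta sim/ncounter_meta.tsv --outdir nc
```

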