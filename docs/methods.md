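# Methods

This note documents the models and procedures implemented in `beecage`,
the defaults they use, the numerical choices made where a convention was
genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and input conventions

All internal coordinates are 0-based half-open, the BED/SAM convention;
GFF3 (1-based closed) is converted on read and the two conversions are
mutually inverse. A gene's `cds_end` stores the genomic bound of the
stop codon at its 3′ end — an exclusive upper bound on `+` genes and an
inclusive lower bound on `−` genes — and is derived from CDS features
when present. Strand-aware "upstream" always means the gene's 5′
direction: the previous gene by start coordinate on `+`, the next one
on `−`.

Pairs are matched by QNAME over primary SAM records. The inner distance
is the gap between mates in genome coordinates (downstream mate start −
upstream mate end); it is negative for overlapping mates, which
therefore always pass an upper-bound filter. The pair's MAPQ is the
minimum over mapped mates.

## Tag filtering

Five exclusion rules run in a fixed order — MAPQ < 20, mate unmapped,
mates on different scaffolds, mates not in opposite-strand (FR)
orientation, inner distance above the supplied bound — and each removed
pair is attributed to the first rule it fails, so the report counts plus
the retained count partition any input exactly (fuzz-tested). The
orientation rule removes same-strand pairs; the protocol this follows
describes the excluded class as mates on "alternate" strands, but
opposite-strand FR is the only geometry a proper pair can have, so the
literal reading would discard every valid pair. `orientation_literal`
inverts the rule for anyone who wants the literal behavior. The
inner-distance bound is conventionally mean + sd estimated from the
mapped pairs themselves (`estimate_inner_distance`, sample moments with
n−1).

## Gene association and count matrices

The association window of gene *g* is `[5′start − 2000, end)` in genome
coordinates (mirrored on `−`), truncated at the same-strand upstream
gene's boundary and the scaffold origin. A tag associates with *g* when
its mate-1 *span* intersects the window (not merely the 5′ end), so one
tag crossing a boundary legitimately counts for two adjacent genes.
After truncation the windows of same-strand genes never overlap, which
makes the region index a simple sorted scan.

Two expression filters are exposed, matching their two uses: `presence`
(non-zero in ≥ 2 samples of at least one group; the expression-matrix
filter) and `cpm` (≥ 1 count per million in ≥ 2 samples, boundary
inclusive; the differential-expression filter). `rescale_to_min`
multiplies each sample by (minimum library / its library), producing
real-valued counts whose library sizes are exactly equal.

TMM normalization follows the original trimmed-mean-of-M-values
estimator: reference sample = the one whose 75th-percentile count
fraction is closest to the mean of those fractions; per sample, log2
count-fraction ratios (M) trimmed 30% per tail and average log2
abundances (A) trimmed 5% per tail; the factor is 2 to the
precision-weighted trimmed mean of M with delta-method binomial weights;
factors are rescaled to geometric mean 1 (asserted to 1e-12). The
implementation is checked against an independent reference
implementation (edgeR's `calcNormFactors`) on a frozen 200-gene matrix
and agrees within 2%.

## Paraclu TSS clustering

Tag 5′ positions (mate-1 5′ ends) are clustered per sample, scaffold and
strand with the Paraclu density recursion. For penalty *d* (tags/bp) the
score of a segment is `Σ weights − d·span`. Every segment that is a
maximal-scoring segment for some *d ≥ 0* is emitted, with
`max_density` = the penalty at which it splits (the minimum "detachment
density" over its proper prefixes and suffixes — flank weight divided by
the span the flank vacates, measured to the first retained position) and
`min_density` = the penalty at which its last enclosing segment split.
Single positions have `max_density = ∞`.

Two deliberate conventions: spans are half-open (a singleton spans 1 bp)
so densities stay finite and in tags/bp, unlike the original tool's
last-minus-first spans; and segments whose density interval is empty are
not reported, with their children attached to the nearest reported
ancestor (weight is conserved down the hierarchy, which is asserted).

Correctness is established against a brute-force oracle that computes,
for every one of the O(n²) site segments, its split density by direct
enumeration and its detachment density as the maximum split density over
all proper supersegments — with no shared code with the recursion. The
suites compare the full cluster sets (spans, tag sums, both densities)
on hundreds of random instances with up to 20 weighted positions;
continuous weights are used because tied decompositions (e.g. runs of
identical adjacent weights) make the cluster set non-unique on a
measure-zero set of inputs.

Cluster filters: span ≤ 50 bp, rescaled tag sum ≥ 5, stability
`max_density / min_density ≥ 2` (an infinite ratio passes — the
"baseline density" is the cluster's `min_density`), then removal of any
kept cluster strictly contained in another kept cluster. The 50 bp
boundary is kept inclusive (span ≤ 50): the removal sentence ("more
than 50 bp … removed") is treated as operative over the looser
"less than 50 bp" phrasing of the goal.

## Common TSSs, differential usage, promoters

Filtered clusters are assigned to the gene whose association window
contains their strand-aware 5′ start (windows are disjoint per strand,
so assignment is unique). Per gene and group, clusters from all the
group's samples form connected components under ≥ 1 bp span overlap
(transitively closed — the weakest defensible cross-sample identity
rule). A component is *common* when every sample of the group
contributes to it; among common components the one with the greatest
summed tag count wins, ties breaking to the 5′-most; the TSS is the
5′-most boundary of the merged span (genomic minimum on `+`, maximum −
1 on `−`).

Differential TSS usage compares the two groups' common TSSs for genes
with at least two distinct cluster components across all samples; a
call is positive when the distance is strictly greater than 100 bp.
The strict inequality follows the defining phrasing of the rule
(">100 bp"); since "at least 100 bp" also appears in the source
protocol's summary, `inclusive=True` (CLI `--min-dist-inclusive`)
switches to ≥.

Promoters cover `[−2000, +200]` bp around the TSS in the direction of
transcription, truncated so they do not overlap the same-strand
upstream gene, do not pass the gene's own stop-codon boundary, and stay
within the scaffold; empty intervals after truncation are omitted with
a warning. Genome-wide background sets use the annotated gene 5′ start
as the TSS proxy, since most genes lack a common CAGE TSS in any one
group. G/C content is (G+C)/(A+C+G+T) with N excluded from the
denominator and all-N sequences flagged undefined.

## Differential expression

Counts are negative-binomial with variance `μ + φμ²` (edgeR-style
dispersion φ; the biological coefficient of variation is √φ). The
common φ maximizes the conditional log-likelihood given per-group
totals, summed over genes, on counts scaled (mean-preserving) to the
geometric-mean effective library size; the search is bounded on
log φ ∈ [1e-4, 10]. Tagwise dispersions maximize each gene's own
conditional likelihood plus `prior_df` (default 10, the long-standing
default of the package this mirrors) times the average per-gene common
likelihood — a shrinkage whose limits are exact: infinite prior returns
the common value, zero prior the per-gene MLE. Tagwise optimization is
on a log grid (201 points) that always contains the common estimate.

The exact test conditions on the gene's total: with equal libraries and
r_g = n_g/φ the group-A total is distributed over splits of the total
by a ratio of gamma terms, and the two-sided p doubles the smaller tail
(each tail includes the observed point), capped at 1. Library
equalization before testing is mean-preserving count scaling to the
geometric-mean effective size, with rounding — a deliberate
approximation of the quantile-adjusted pseudo-counts used by the
original implementation; its adequacy is established by simulation
(empirical type-I error within [0.03, 0.07] at α = 0.05 over 20 × 2,000
null genes, and exact agreement with the binomial closed form in the
φ → 0 single-sample limit). log2 fold changes use CPM with a 0.5
pseudo-count so zero counts stay finite. BH FDR control and the
hypergeometric set-overlap test (with Bonferroni for multiple study
comparisons) use scipy's implementations behind the module's surface.

The gland-contamination screen (`hpg_screen`) intersects DEGs with
genes strongly upregulated in the hypopharyngeal gland (log2 FC > 3, or
the top 1/5/10/20% by fold change); since gland development tracks the
nursing state, genes in the nurse-gland top 10% are excluded from the
forager-side comparison.

## Descriptive statistics

CV² is (sd/mean)² within a group with sample sd; the within-group
variance of Z-scored expression standardizes each gene across all
samples first. Z-scoring and CV² use sample (n−1) sd — the source
protocol does not state which; the choice is exposed only through the
documented convention. The rank-sum test enumerates exactly when the
pooled size is ≤ 20 with no ties, otherwise uses the tie-corrected
normal approximation with continuity correction. Ward clustering runs
the Lance–Williams recurrence on the provided distances (Euclidean for
gene profiles, 1 − Pearson for samples; constant rows under the Pearson
metric are an error rather than silently dropped). The CPCC is the
Pearson correlation of condensed observed distances against cophenetic
distances; it is exactly 1 on ultrametric inputs. k-means is Lloyd's
algorithm with k-means++ seeding, best of 10 restarts, deterministic
under a fixed seed, with the within-cluster sum of squares asserted
non-increasing at every iteration. BCV selects the top-n (default 500)
genes by within-group variance of log2 CPM and reports √φ of the common
dispersion fit on that subset; note the selection step biases the
estimate slightly upward for strongly dispersed data.

## Motif enrichment

The per-sequence score is the natural log of the average likelihood
ratio of a PWM over every window on both strands (windows containing N
contribute LR = 1); the set score is the mean over sequences. PWMs are
row-normalized counts with a 0.01 pseudocount per cell, which keeps
reverse-strand windows away from zero likelihoods. Significance is
empirical: each of `n_draws` (default 1,000) draws samples a
length-matched (± 10%) background set — the opposing group's promoters,
all promoters, or uniform random genomic segments — and
`p = (1 + #{draws ≥ observed}) / (n_draws + 1)`, which is exactly
super-uniform under exchangeability. A motif is reported enriched when
score > 6 and p < 0.05; the threshold mirrors the protocol's
configuration but the score is not the cited tool's raw score, whose
internal formula is not reproduced — rankings and calibration, not raw
score values, are the supported interface.

## The synthetic-data generator

`simulate_truth`/`simulate_tags` emulate the study design: 2 scaffolds ×
60 non-overlapping genes (2.5–3.5 kb, gaps 0.8–1.5 kb, uniform ACGT
sequence), two groups of 8 samples, 5×10⁴ tag pairs per sample with
per-sample library sizes spread by a factor of 2, NB counts with
φ = 0.1, mate-1 5′ ends normal around the group TSS (sd 5 bp), mate 2
downstream at a truncated-normal inner distance (mean 588 bp, sd
767 bp, floor −50 bp — the values estimated by the study's mapping
step). 15% of genes are differentially expressed with |log2 FC| ≥ 2 and
20% carry a group-B TSS shifted 150–400 bp downstream; a shifted gene
counts as ground-truth alternative only when its offset exceeds 100 bp,
so sub-threshold shifts exercise the caller's specificity. The five
filter-violation classes are injected mutually exclusively per pair and
recorded in a ledger, making the filter report exactly decomposable.
The DEG/alt-TSS fractions are generator defaults chosen for measurement
resolution at 120 genes, not study estimates.

What the generator does **not** model: sequencing errors, rRNA or
barcode artifacts, multi-mapping, splicing (mate 2 is placed at the
genomic inner distance), overlapping genes, biased base composition,
and broad/multi-modal promoter architectures. Passing truth-recovery
tests therefore demonstrates the pipeline's correctness under the
stated model — peaked TSSs, NB counts — not performance on real
libraries with those complications.

## Problem sizes used by the test and acceptance runs

Integration tests run one full synthetic study at the design conditions
above (≈ 8×10⁵ pairs); calibration and recovery suites use 2,000-gene
matrices over 20 seeds; the Paraclu oracle suite enumerates 500 random
instances of up to 20 positions; motif spike-in recovery uses 100 seeds
of 50 spiked 300-bp promoters against 20 decoy PWMs, and the null
calibration 400 replicates. `scripts/acceptance.py` re-runs the
pipeline at depth 2×10⁴ over 60 genes; these sizes are the package's
own validation choices and all scale up through `SimConfig`.
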