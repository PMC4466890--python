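# beecage

A tested, reusable implementation of a CAGE-based brain promoterome
analysis for the honey bee (*Apis mellifera*): from mapped paired-end CAGE
tag pairs to gene expression matrices, differentially expressed genes,
transcription start site (TSS) clusters, per-group consensus TSSs,
differential TSS usage calls, reconstructed promoters, and enrichment
statistics. A synthetic-data generator reproduces the study design — two
behavioral groups (nurses and foragers) of eight individually sequenced
brains — so every stage can be validated against known truth without any
sequencing data.

**Who it is for.** Researchers analyzing CAGEscan/nanoCAGE libraries in
non-model genomes who need the complete tag-to-promoter pipeline, and
anyone who wants a transparent, testable reference for its statistical
core.

## The methods at the core

- **Tag filtering.** A pair is dropped when MAPQ < 20, a mate is unmapped,
  mates map to different scaffolds, mates are not in opposite-strand
  orientation, or the inner distance exceeds mean + sd of the estimated
  inner-distance distribution.
- **Gene association.** A tag joins gene *g* when its mate-1 span
  intersects `[TSS_g − 2000, end_g)`, truncated at the end of the
  same-strand upstream gene.
- **TSS clustering (Paraclu).** For a density penalty *d* per bp, the
  score of a segment of weighted tag 5′ positions is
  `S(d) = Σ w − d·span`; every segment that is maximal for some *d ≥ 0*
  is a cluster, carrying the density interval `[min_density,
  max_density)` over which it is maximal. Clusters longer than 50 bp,
  with fewer than 5 rescaled tags, or with stability
  `max_density / min_density < 2` are removed; nested survivors collapse
  to the outermost. A group's **common TSS** for a gene is the
  cross-sample cluster component with the greatest total tag count that
  is present in *every* sample of the group; two groups use
  **alternative TSSs** when their common TSSs lie more than 100 bp apart.
- **Differential expression.** Counts are modeled negative-binomial with
  variance `μ + φμ²`. Libraries are normalized by trimmed mean of
  M-values (TMM); φ is estimated by conditional maximum likelihood with
  empirical-Bayes tagwise shrinkage; the two-group exact test conditions
  on each gene's total count and doubles the smaller tail;
  Benjamini–Hochberg controls the FDR at 0.05.
- **Promoters and enrichment.** Promoters are `[−2000, +200]` bp around
  the TSS, truncated at the upstream gene and the stop codon.
  Over-representation of GO terms uses Fisher's exact test with BH
  correction; motif enrichment scores promoter sets by the log average
  PWM likelihood ratio over all windows (both strands) with empirical
  randomization p-values against three backgrounds (opposing promoters,
  all promoters, random genome).

## Worked example

```python
from beecage import synthetic_data as sd, tag_pipeline as tp, diffexp, tss_analysis as ta

cfg = sd.SimConfig(depth=20_000, genes_per_scaffold=30)
truth = sd.simulate_truth(cfg, seed=1)
tags = sd.simulate_tags(truth, seed=2)

pairs = [p for ps in tags.pairs_by_sample.values() for p in ps]
mean, sd_ = tp.estimate_inner_distance(pairs)
kept, report = tp.filter_pairs(pairs, inner_max=mean + sd_)
print(f"inner distance: mean {mean:.0f} bp, sd {sd_:.0f} bp")
print(f"retained {report.retained} of {report.total} pairs")

matrix = tp.build_count_matrix(tp.associate_tags(kept, truth.annotation), truth.groups())
de = diffexp.de_pipeline(matrix)
print(f"{int(de.significant.sum())} of {len(de)} genes differentially expressed (FDR < 0.05)")

by_sample = {}
for p in kept:
    by_sample.setdefault(p.sample_id, []).append(p)
tss = ta.tss_pipeline(by_sample, truth.annotation, truth.groups())
n_alt = sum(c.is_alternative for c in tss["alt_calls"])
print(f"{n_alt} genes with alternative TSS usage (>100 bp apart)")

res = diffexp.overlap_test_counts(646, 1058, 96, 12453)
print(f"alt-TSS x DEG overlap: p = {res.p_value:.2e}")
```

prints

```
inner distance: mean 676 bp, sd 638 bp
retained 279005 of 337235 pairs
11 of 60 genes differentially expressed (FDR < 0.05)
17 genes with alternative TSS usage (>100 bp apart)
alt-TSS x DEG overlap: p = 2.93e-08
```

The simulation planted 11 differentially expressed and 17
alternative-TSS genes among 60 — the pipeline recovers all of them with
no false calls. The final line is the hypergeometric overlap of the
published study's printed gene counts (646 alternative-TSS genes and
1,058 DEGs sharing 96, among 12,453 expressed genes): alternative TSS
usage is significantly more prevalent among DEGs than genome-wide.

A `beecage` console command exposes the same pipeline as subcommands
(`simulate`, `filter`, `counts`, `de`, `tss`, `stats`, `overlap`,
`enrich go`, `enrich motif`); run `beecage --help`.

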