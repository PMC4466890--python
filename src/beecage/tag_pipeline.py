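"""From mapped tag pairs to raw and normalized count matrices.

Filtering follows the CAGEscan quality rules: drop a pair if its mapping
quality is below 20, a mate is unmapped, the mates map to different
scaffolds, the mates are not in the expected opposite-strand orientation,
or the inner distance exceeds a supplied bound (conventionally the sample
mean plus one standard deviation of the inner-distance distribution).
Attribution in the report is first-failing-rule in that fixed order, so the
per-rule counts plus the retained count always partition the input.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_core import BeeCageError, GeneModel, GenomeAnnotation, MappedPair

FILTER_RULES = (
    "low_mapq",
    "mate_unmapped",
    "different_scaffold",
    "same_orientation",
    "inner_distance_excess",
)


@dataclass
class FilterReport:
    """Per-rule removal counts; ``retained + sum(counts) == input size``."""

    low_mapq: int = 0
    mate_unmapped: int = 0
    different_scaffold: int = 0
    same_orientation: int = 0
    inner_distance_excess: int = 0
    retained: int = 0

    def rule_counts(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in FILTER_RULES}

    @property
    def total(self) -> int:
        return self.retained + sum(self.rule_counts().values())


def estimate_inner_distance(pairs) -> tuple[float, float]:
    """Sample mean and sd (n-1) of inner distance over eligible pairs.

    Eligible pairs have both mates mapped on one scaffold.  Fewer than two
    eligible pairs is an error.
    """
    dists = [p.inner_distance for p in pairs if p.inner_distance is not None]
    if len(dists) < 2:
        raise BeeCageError("need >= 2 pairs with both mates mapped on one scaffold")
    arr = np.asarray(dists, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def filter_pairs(
    pairs,
    mapq_min: int = 20,
    inner_max: float | None = None,
    orientation_literal: bool = False,
) -> tuple[list[MappedPair], FilterReport]:
    """Apply the five exclusion rules in fixed order; return survivors.

    ``inner_max`` is typically mean + sd from :func:`estimate_inner_distance`
    (``None`` disables the inner-distance rule).  By default mates must be in
    opposite-strand (FR) orientation; ``orientation_literal`` inverts the
    rule and removes opposite-strand pairs instead.
    """
    report = FilterReport()
    kept: list[MappedPair] = []
    for p in pairs:
        if p.mapq < mapq_min:
            report.low_mapq += 1
            continue
        if p.mate1_unmapped or p.mate2_unmapped:
            report.mate_unmapped += 1
            continue
        if p.scaffold_1 != p.scaffold_2:
            report.different_scaffold += 1
            continue
        same = p.strand_1 == p.strand_2
        if (same and not orientation_literal) or (not same and orientation_literal):
            report.same_orientation += 1
            continue
        if inner_max is not None and p.inner_distance is not None and p.inner_distance > inner_max:
            report.inner_distance_excess += 1
            continue
        report.retained += 1
        kept.append(p)
    return kept, report


def association_region(gene: GeneModel, annotation: GenomeAnnotation) -> tuple[int, int]:
    """The window a tag must intersect to be credited to ``gene``.

    2000 bp upstream of the gene's 5' start through the gene end, truncated
    at the end of the same-strand upstream gene (strand-aware) and at the
    scaffold origin.
    """
    up = annotation.upstream_of(gene)
    if gene.strand == "+":
        start = max(0, gene.start - 2000)
        if up is not None:
            start = max(start, up.end)
        return start, gene.end
    end = gene.end + 2000
    if up is not None:
        end = min(end, up.start)
    return gene.start, end


class _RegionIndex:
    """Sorted association regions per (scaffold, strand) for span queries."""

    def __init__(self, annotation: GenomeAnnotation):
        self._idx: dict[tuple[str, str], tuple[list[int], list[int], list[str]]] = {}
        for key in {(g.scaffold, g.strand) for g in annotation}:
            genes = annotation.genes_on(*key)
            regions = sorted(
                (association_region(g, annotation), g.gene_id) for g in genes
            )
            starts = [r[0][0] for r in regions]
            ends = [r[0][1] for r in regions]
            ids = [r[1] for r in regions]
            self._idx[key] = (starts, ends, ids)

    def overlapping(self, scaffold: str, strand: str, span_start: int, span_end: int):
        entry = self._idx.get((scaffold, strand))
        if entry is None:
            return
        starts, ends, ids = entry
        i = bisect_right(starts, span_end - 1) - 1
        # walk left while regions can still reach into the span; regions of
        # successive same-strand genes are non-overlapping after truncation,
        # so this terminates after at most a couple of steps
        while i >= 0 and ends[i] > span_start:
            yield ids[i]
            i -= 1


def associate_tags(
    retained_pairs,
    annotation: GenomeAnnotation,
) -> dict[str, dict[str, np.ndarray]]:
    """Map pairs to genes by mate-1 span intersection with association regions.

    Returns sample_id -> gene_id -> sorted array of mate-1 5' positions (one
    entry per associated pair).  Association is strand-matched (mate-1 strand
    must equal the gene strand); a tag spanning two adjacent genes' regions
    is credited to both.
    """
    index = _RegionIndex(annotation)
    out: dict[str, dict[str, list[int]]] = {}
    for p in retained_pairs:
        if p.mate1_unmapped:
            continue
        per_sample = out.setdefault(p.sample_id, {})
        for gid in index.overlapping(p.scaffold_1, p.strand_1, p.mate1_start, p.mate1_end):
            per_sample.setdefault(gid, []).append(p.five_prime_pos)
    return {
        sid: {gid: np.array(sorted(v), dtype=int) for gid, v in genes.items()}
        for sid, genes in out.items()
    }


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x samples counts with group labels and library sizes."""

    counts: pd.DataFrame
    groups: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise BeeCageError("duplicate sample ids")
        if not self.counts.columns.equals(self.library_sizes.index):
            raise BeeCageError("library_sizes index must match sample columns")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise BeeCageError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.columns]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, groups: pd.Series) -> "CountMatrix":
        return cls(counts, groups, counts.sum(axis=0))

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.groups, self.library_sizes)


def build_count_matrix(
    associations: dict[str, dict[str, np.ndarray]],
    groups: pd.Series,
    annotation: GenomeAnnotation | None = None,
    keep_zeros: bool = False,
) -> CountMatrix:
    """Tabulate per-gene tag counts into a genes x samples matrix.

    A pair associated with two genes contributes one count to each.  Genes
    with no tags in any sample appear as zero rows only when ``keep_zeros``
    is set and an annotation is supplied.
    """
    samples = list(groups.index)
    if len(samples) != len(set(samples)):
        raise BeeCageError("duplicate sample ids")
    if keep_zeros and annotation is not None:
        gene_ids = [g.gene_id for g in annotation]
    else:
        seen = set()
        for per_sample in associations.values():
            seen.update(per_sample)
        gene_ids = sorted(seen)
    counts = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    for sid in samples:
        for gid, positions in associations.get(sid, {}).items():
            counts.loc[gid, sid] = len(positions)
    return CountMatrix.from_counts(counts, groups)


def rescale_to_min(matrix: CountMatrix) -> CountMatrix:
    """Scale every sample to the minimum library size (real-valued counts)."""
    libs = matrix.library_sizes.astype(float)
    if (libs <= 0).any():
        raise BeeCageError("zero library size")
    scaled = matrix.counts * (libs.min() / libs)
    return CountMatrix(scaled, matrix.groups, scaled.sum(axis=0))


def filter_expressed(matrix: CountMatrix, mode: str = "presence") -> CountMatrix:
    """Drop weakly expressed genes.

    ``presence``: keep genes non-zero in at least two samples of at least
    one group.  ``cpm``: keep genes with at least 1 tag per million library
    reads in at least two samples (any group), boundary inclusive.
    """
    if mode == "presence":
        keep = pd.Series(False, index=matrix.counts.index)
        for group in matrix.groups.unique():
            cols = matrix.groups.index[matrix.groups == group]
            if len(cols) < 2:
                raise BeeCageError(f"group {group!r} has fewer than 2 samples")
            keep |= (matrix.counts[cols] > 0).sum(axis=1) >= 2
    elif mode == "cpm":
        cpm = matrix.counts * 1e6 / matrix.library_sizes
        keep = (cpm >= 1.0).sum(axis=1) >= 2
    else:
        raise BeeCageError(f"unknown filter mode {mode!r}")
    return CountMatrix(matrix.counts.loc[keep], matrix.groups, matrix.library_sizes)


def tmm_factors(matrix: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  Per sample, log2 count-fraction
    ratios (M) are trimmed 30% per tail and mean log2 abundances (A) 5% per
    tail, then combined with asymptotic delta-method binomial precision
    weights; factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        return pd.Series(1.0, index=matrix.counts.columns)
    if ref_sample is None:
        f75 = np.array(
            [np.quantile(counts[:, j], 0.75) / libs[j] for j in range(counts.shape[1])]
        )
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = matrix.counts.columns.get_loc(ref_sample)

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        factors[j] = _tmm_pair(counts[:, j], counts[:, ref], libs[j], libs[ref])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    use = (obs > 0) & (ref > 0)
    obs, ref = obs[use], ref[use]
    if obs.size == 0:
        import logging

        logging.getLogger("beecage").warning("no usable genes for TMM; factor set to 1")
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    r_l = rankdata(log_r)
    r_s = rankdata(abs_e)
    keep = (r_l >= lo_l) & (r_l <= hi_l) & (r_s >= lo_s) & (r_s <= hi_s)
    if not keep.any():
        import logging

        logging.getLogger("beecage").warning("TMM trimming removed all genes; factor set to 1")
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)
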