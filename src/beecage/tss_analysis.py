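"""Density clustering of tag 5' ends, common TSS calls, differential TSS
usage and promoter reconstruction.

The clustering is the Paraclu density recursion: for a penalty d per base,
the score of a segment of weighted tag positions is (total weight) - d *
(span).  Every segment that is maximal for some d >= 0 is a cluster,
annotated with the density interval over which it is maximal:
``min_density`` (where it detaches from its parent) and ``max_density``
(where it splits into children; infinite for single positions).  Spans are
half-open, so a singleton has span 1 — a deliberate departure from the
original tool's last-minus-first convention that keeps densities finite
and in tags/bp.

The stability ratio max_density/min_density is the usual Paraclu filter
("maximum density / baseline density"); clusters are additionally capped at
50 bp span and 5 rescaled tags, and nested survivors are collapsed to the
outermost, mirroring the promoterome protocol this package implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf

import numpy as np
import pandas as pd

from .io_core import BeeCageError, GeneModel, GenomeAnnotation
from .tag_pipeline import association_region

log = logging.getLogger("beecage")


@dataclass
class TagCluster:
    """A Paraclu cluster of tag 5' positions on one scaffold and strand."""

    scaffold: str | None
    strand: str | None
    start: int
    end: int
    tag_sum: float
    min_density: float
    max_density: float
    sample_id: str | None = None
    parent: "TagCluster | None" = None
    children: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise BeeCageError("cluster span must be >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        return self.tag_sum / self.span

    @property
    def stability(self) -> float:
        if self.min_density == 0:
            return inf
        return self.max_density / self.min_density

    def five_prime_start(self) -> int:
        """Strand-aware starting position (genomic min on +, max-1 on -)."""
        return self.start if self.strand != "-" else self.end - 1


def paraclu(
    positions,
    weights,
    scaffold: str | None = None,
    strand: str | None = None,
    sample_id: str | None = None,
) -> list[TagCluster]:
    """Cluster weighted tag positions on one scaffold+strand.

    ``positions`` must be strictly increasing with positive weights.
    Returns the nested cluster hierarchy as a flat list (root first,
    pre-order); degenerate nodes whose density interval is empty are not
    reported, their children attach to the nearest reported ancestor.
    """
    pos = np.asarray(positions, dtype=int)
    w = np.asarray(weights, dtype=float)
    if pos.size == 0:
        return []
    if pos.size != w.size:
        raise BeeCageError("positions and weights must have equal length")
    if np.any(np.diff(pos) <= 0):
        raise BeeCageError("positions must be strictly increasing")
    if np.any(w <= 0):
        raise BeeCageError("weights must be positive")
    cum = np.concatenate([[0.0], np.cumsum(w)])

    def wsum(i: int, j: int) -> float:
        return cum[j + 1] - cum[i]

    out: list[TagCluster] = []
    # explicit stack (pre-order) so long position runs cannot overflow the
    # interpreter recursion limit
    stack: list[tuple[int, int, float, TagCluster | None]] = []

    def step(i: int, j: int, min_den: float, parent: TagCluster | None) -> None:
        total = wsum(i, j)
        if i == j:
            max_den = inf
            k = None
        else:
            # weakest prefix or suffix detachment density over all internal
            # boundaries: flank weight over the span it vacates (up to the
            # first retained position), the original Paraclu criterion
            ks = np.arange(i, j)
            pre = (cum[ks + 1] - cum[i]) / (pos[ks + 1] - pos[i])
            suf = (cum[j + 1] - cum[ks + 1]) / (pos[j] - pos[ks])
            dens = np.minimum(pre, suf)
            kk = int(np.argmin(dens))
            max_den = float(dens[kk])
            k = ks[kk]
        node = None
        if max_den > min_den:
            node = TagCluster(
                scaffold,
                strand,
                int(pos[i]),
                int(pos[j]) + 1,
                total,
                min_den,
                max_den,
                sample_id,
                parent,
            )
            if parent is not None:
                parent.children.append(node)
            out.append(node)
        if k is not None:
            child_min = max(min_den, max_den)
            anchor = node if node is not None else parent
            stack.append((k + 1, j, child_min, anchor))
            stack.append((i, k, child_min, anchor))

    stack.append((0, pos.size - 1, 0.0, None))
    while stack:
        step(*stack.pop())
    return out


def paraclu_all_segments(positions, weights) -> list[tuple[int, int, float, float, float]]:
    """Brute-force oracle: density intervals for every contiguous segment.

    Independent of the recursion: for each of the O(n^2) site segments S,
    ``max_density(S)`` is the minimum detachment density over its proper
    prefixes and suffixes — flank weight over the span the flank vacates,
    i.e. up to the first retained position (the penalty at which S splits) —
    and ``min_density(S)`` is the maximum of ``max_density`` over all proper
    supersegments (the penalty at which every enclosing segment has already
    split).  Returns (first_site, last_site, tag_sum, min_density,
    max_density) for segments with a non-empty interval.
    """
    pos = np.asarray(positions, dtype=int)
    w = np.asarray(weights, dtype=float)
    n = pos.size
    cum = np.concatenate([[0.0], np.cumsum(w)])
    bmax = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                bmax[i, j] = inf
                continue
            best = inf
            for k in range(i, j):
                pre = (cum[k + 1] - cum[i]) / (pos[k + 1] - pos[i])
                suf = (cum[j + 1] - cum[k + 1]) / (pos[j] - pos[k])
                best = min(best, min(pre, suf))
            bmax[i, j] = best
    out = []
    for i in range(n):
        for j in range(i, n):
            mind = 0.0
            for a in range(0, i + 1):
                for b in range(j, n):
                    if (a, b) != (i, j):
                        mind = max(mind, bmax[a, b])
            if bmax[i, j] > mind:
                out.append((int(pos[i]), int(pos[j]), float(cum[j + 1] - cum[i]), mind, float(bmax[i, j])))
    return out


def filter_clusters(
    hierarchy: list[TagCluster],
    max_span: int = 50,
    min_tags: float = 5.0,
    min_stability: float = 2.0,
) -> list[TagCluster]:
    """Apply the promoterome cluster filters to a Paraclu hierarchy.

    Keeps clusters with span <= ``max_span`` bp, at least ``min_tags``
    (rescaled) tags and a max/baseline density ratio of at least
    ``min_stability`` (an infinite ratio passes); then drops any kept
    cluster strictly contained in another kept cluster, so only the
    outermost survivors remain.
    """
    kept = [
        c
        for c in hierarchy
        if c.span <= max_span and c.tag_sum >= min_tags and c.stability >= min_stability
    ]
    out = []
    for c in kept:
        contained = any(
            o is not c and o.start <= c.start and c.end <= o.end and (o.start, o.end) != (c.start, c.end)
            for o in kept
        )
        if not contained:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# per-sample clustering over a whole tag set
# ---------------------------------------------------------------------------


def cluster_sample(
    five_prime_by_loc: dict[tuple[str, str], np.ndarray],
    weight: float,
    sample_id: str,
    max_span: int = 50,
    min_tags: float = 5.0,
    min_stability: float = 2.0,
) -> list[TagCluster]:
    """Paraclu + filters over one sample's tag 5' ends.

    ``five_prime_by_loc`` maps (scaffold, strand) to arrays of 5' positions;
    ``weight`` is the per-tag rescaled weight (min library / this library).
    """
    clusters: list[TagCluster] = []
    for (scaffold, strand), raw in five_prime_by_loc.items():
        pos, counts = np.unique(np.asarray(raw, dtype=int), return_counts=True)
        if pos.size == 0:
            continue
        hierarchy = paraclu(pos, counts * weight, scaffold, strand, sample_id)
        clusters.extend(filter_clusters(hierarchy, max_span, min_tags, min_stability))
    return clusters


@dataclass(frozen=True)
class CommonTSS:
    """Per-gene, per-group consensus start site."""

    gene_id: str
    group: str
    tss_pos: int
    merged_span: tuple[int, int]
    tag_total: float
    n_samples_supporting: int


@dataclass(frozen=True)
class AltTSSCall:
    """A comparison of two groups' common TSSs for one gene."""

    gene_id: str
    tss_group_a: int
    tss_group_b: int
    distance: int
    is_alternative: bool


def assign_clusters_to_genes(
    clusters: list[TagCluster], annotation: GenomeAnnotation
) -> dict[str, list[TagCluster]]:
    """Assign clusters to genes: the cluster's 5' start must fall inside the
    gene's tag-association region (strand-matched)."""
    by_gene: dict[str, list[TagCluster]] = {}
    regions: dict[str, tuple[int, int]] = {}
    for g in annotation:
        regions[g.gene_id] = association_region(g, annotation)
    genes_by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in annotation:
        genes_by_loc.setdefault((g.scaffold, g.strand), []).append(g)
    for c in clusters:
        for g in genes_by_loc.get((c.scaffold, c.strand), []):
            lo, hi = regions[g.gene_id]
            if lo <= c.five_prime_start() < hi:
                by_gene.setdefault(g.gene_id, []).append(c)
    return by_gene


def _components(clusters: list[TagCluster]) -> list[list[TagCluster]]:
    """Connected components under >= 1 bp span overlap (transitive)."""
    comps: list[list[TagCluster]] = []
    cur: list[TagCluster] = []
    cur_end = -1
    for c in sorted(clusters, key=lambda c: (c.start, c.end)):
        if cur and c.start < cur_end:
            cur.append(c)
            cur_end = max(cur_end, c.end)
        else:
            if cur:
                comps.append(cur)
            cur = [c]
            cur_end = c.end
    if cur:
        comps.append(cur)
    return comps


def common_tss(
    per_sample_clusters: dict[str, list[TagCluster]],
    group_samples: dict[str, list[str]],
    annotation: GenomeAnnotation,
) -> dict[str, dict[str, CommonTSS]]:
    """Per group and gene, the consensus TSS supported by every sample.

    Clusters from all samples of a group assigned to a gene are merged into
    connected components by span overlap; a component is *common* when every
    sample of the group contributes at least one cluster.  Among common
    components the one with the greatest summed tag count wins (ties break
    to the 5'-most component on the gene strand); the TSS is the 5'-most
    boundary of its merged span.
    """
    all_clusters = [c for cs in per_sample_clusters.values() for c in cs]
    by_gene = assign_clusters_to_genes(all_clusters, annotation)
    result: dict[str, dict[str, CommonTSS]] = {g: {} for g in group_samples}
    for gene_id, clusters in by_gene.items():
        gene = annotation.get(gene_id)
        for group, samples in group_samples.items():
            sample_set = set(samples)
            group_clusters = [c for c in clusters if c.sample_id in sample_set]
            best: tuple | None = None
            for comp in _components(group_clusters):
                support = {c.sample_id for c in comp}
                if support != sample_set:
                    continue
                total = sum(c.tag_sum for c in comp)
                lo = min(c.start for c in comp)
                hi = max(c.end for c in comp)
                tss = lo if gene.strand == "+" else hi - 1
                # prefer greater tag total; tie-break 5'-most on the strand
                five_key = tss if gene.strand == "+" else -tss
                cand = (-total, five_key, tss, lo, hi, len(support))
                if best is None or cand < best:
                    best = cand
            if best is not None:
                neg_total, _fk, tss, lo, hi, nsup = best
                result[group][gene_id] = CommonTSS(
                    gene_id, group, tss, (lo, hi), -neg_total, nsup
                )
    return result


def multi_cluster_genes(
    per_sample_clusters: dict[str, list[TagCluster]], annotation: GenomeAnnotation
) -> set[str]:
    """Genes with >= 2 distinct cluster components over all samples."""
    all_clusters = [c for cs in per_sample_clusters.values() for c in cs]
    by_gene = assign_clusters_to_genes(all_clusters, annotation)
    return {g for g, cs in by_gene.items() if len(_components(cs)) >= 2}


def alternative_tss(
    common_a: dict[str, CommonTSS],
    common_b: dict[str, CommonTSS],
    min_dist: int = 100,
    eligible_genes: set[str] | None = None,
    inclusive: bool = False,
) -> list[AltTSSCall]:
    """Differential TSS usage: groups' common TSSs more than 100 bp apart.

    Only genes present in both groups' maps (and, when given, in
    ``eligible_genes`` — conventionally genes with multiple clusters across
    samples) are compared.  The distance rule is strict (> ``min_dist``)
    unless ``inclusive`` is set.
    """
    calls = []
    for gene_id in sorted(set(common_a) & set(common_b)):
        if eligible_genes is not None and gene_id not in eligible_genes:
            continue
        ta, tb = common_a[gene_id].tss_pos, common_b[gene_id].tss_pos
        dist = abs(ta - tb)
        is_alt = dist >= min_dist if inclusive else dist > min_dist
        calls.append(AltTSSCall(gene_id, ta, tb, dist, is_alt))
    return calls


def tss_pipeline(
    pairs_by_sample: dict[str, list],
    annotation: GenomeAnnotation,
    groups: pd.Series,
    max_span: int = 50,
    min_tags: float = 5.0,
    min_stability: float = 2.0,
    min_dist: int = 100,
    inclusive: bool = False,
) -> dict:
    """Retained pairs -> per-sample clusters -> common TSSs -> alt calls.

    Tag weights are rescaled to the minimum per-sample retained-pair count
    before clustering, so the 5-tag cluster floor refers to rescaled tags.
    Returns a dict with 'clusters' (per sample), 'common' (per group),
    'alt_calls' and 'multi_cluster_genes'.
    """
    libs = {sid: len(pairs) for sid, pairs in pairs_by_sample.items()}
    min_lib = min(v for v in libs.values() if v > 0)
    per_sample: dict[str, list[TagCluster]] = {}
    for sid, pairs in pairs_by_sample.items():
        by_loc: dict[tuple[str, str], list[int]] = {}
        for p in pairs:
            if p.mate1_unmapped:
                continue
            by_loc.setdefault((p.scaffold_1, p.strand_1), []).append(p.five_prime_pos)
        weight = min_lib / libs[sid] if libs[sid] else 1.0
        per_sample[sid] = cluster_sample(
            {k: np.array(v) for k, v in by_loc.items()},
            weight,
            sid,
            max_span,
            min_tags,
            min_stability,
        )
    group_samples = {g: list(groups.index[groups == g]) for g in groups.unique()}
    common = common_tss(per_sample, group_samples, annotation)
    multi = multi_cluster_genes(per_sample, annotation)
    labels = list(groups.unique())
    alt_calls: list[AltTSSCall] = []
    if len(labels) == 2:
        alt_calls = alternative_tss(
            common[labels[0]], common[labels[1]], min_dist, multi, inclusive
        )
    return {
        "clusters": per_sample,
        "common": common,
        "alt_calls": alt_calls,
        "multi_cluster_genes": multi,
    }


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def extract_promoters(
    annotation: GenomeAnnotation,
    tss_map: dict[str, int] | None = None,
    up: int = 2000,
    down: int = 200,
    scaffold_lengths: dict[str, int] | None = None,
) -> dict[str, tuple[str, int, int]]:
    """Reconstruct promoter intervals around TSSs.

    The promoter covers [-``up``, +``down``] bp around the TSS in the
    direction of transcription, truncated so it does not overlap the
    same-strand upstream gene, does not pass the gene's stop-codon boundary
    (``cds_end``), and stays within scaffold bounds.  Without ``tss_map``
    the annotated gene 5' start is used (the genome-wide background set).
    Genes whose promoter is empty after truncation are omitted with a
    warning.
    """
    out: dict[str, tuple[str, int, int]] = {}
    for gene in annotation:
        if tss_map is not None:
            if gene.gene_id not in tss_map:
                continue
            tss = tss_map[gene.gene_id]
        else:
            tss = gene.tss_annotated
        up_gene = annotation.upstream_of(gene)
        if gene.strand == "+":
            start, end = tss - up, tss + down
            if up_gene is not None:
                start = max(start, up_gene.end)
            if gene.cds_end is not None:
                end = min(end, gene.cds_end)
        else:
            start, end = tss + 1 - down, tss + 1 + up
            if up_gene is not None:
                end = min(end, up_gene.start)
            if gene.cds_end is not None:
                start = max(start, gene.cds_end)
        start = max(start, 0)
        if scaffold_lengths is not None:
            end = min(end, scaffold_lengths[gene.scaffold])
        if end <= start:
            log.warning("promoter of %s empty after truncation; omitted", gene.gene_id)
            continue
        out[gene.gene_id] = (gene.scaffold, start, end)
    return out


def promoter_sequences(
    promoters: dict[str, tuple[str, int, int]], genome: dict[str, str]
) -> dict[str, str]:
    """Extract promoter sequences (forward strand) from the genome."""
    return {g: genome[scf][s:e] for g, (scf, s, e) in promoters.items()}


def gc_fraction(sequences) -> list[float]:
    """(G+C)/(A+C+G+T) per sequence; N excluded; NaN for all-N sequences."""
    out = []
    for seq in sequences:
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise BeeCageError(f"non-DNA letters {sorted(bad)}")
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            out.append(float("nan"))
        else:
            out.append((seq.count("G") + seq.count("C")) / acgt)
    return out
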