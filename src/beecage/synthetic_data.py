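"""Synthetic CAGE data with known truth.

Emulates the study design every downstream stage is tested against: two
behavioral groups (nurse/forager) of 8 brain samples each, per-gene
negative-binomial tag-pair counts (variance mu + phi mu^2), peaked 5'-end
distributions around group-specific TSSs, CAGEscan paired-mate geometry with
a truncated-normal inner distance (defaults mean 588 bp, sd 767 bp), and
configurable fractions of differentially expressed and alternative-TSS
genes.  Every stochastic choice is recorded in a truth ledger so recall and
false-call rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .io_core import (
    BASES,
    BeeCageError,
    GeneModel,
    GenomeAnnotation,
    MappedPair,
    PWM,
    write_fasta,
    write_gene_models,
)

VIOLATION_CLASSES = (
    "low_mapq",
    "mate_unmapped",
    "different_scaffold",
    "same_orientation",
    "inner_distance_excess",
)

GROUPS = ("nurse", "forager")


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Lengths are bp, depths are tag pairs per sample.  ``depth_spread`` is the
    max/min ratio of per-sample library sizes so normalization is exercised
    non-trivially.  ``violation_rates`` are per-pair probabilities of the
    five mutually exclusive filter-violation classes.
    """

    n_scaffolds: int = 2
    genes_per_scaffold: int = 60
    gene_length: tuple[int, int] = (2500, 3500)
    intergenic_gap: tuple[int, int] = (800, 1500)
    scaffold_length: int | None = None
    n_samples_per_group: int = 8
    fraction_deg: float = 0.15
    min_abs_log2fc: float = 2.0
    fraction_alt_tss: float = 0.2
    alt_tss_offset: tuple[float, float] = (150.0, 400.0)
    tss_peak_width: float = 5.0
    inner_distance_mean: float = 588.0
    inner_distance_sd: float = 767.0
    inner_distance_min: float = -50.0
    read_length: int = 79
    depth: int = 50_000
    depth_spread: float = 2.0
    dispersion: float = 0.1
    violation_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_deg", "fraction_alt_tss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BeeCageError(f"{name} must be in [0, 1]")
        if self.depth < 1:
            raise BeeCageError("depth must be >= 1")
        bad = set(self.violation_rates) - set(VIOLATION_CLASSES)
        if bad:
            raise BeeCageError(f"unknown violation classes: {sorted(bad)}")
        for v in self.violation_rates.values():
            if not 0.0 <= v <= 1.0:
                raise BeeCageError("violation rates must be in [0, 1]")
        if sum(self.violation_rates.values()) > 1.0:
            raise BeeCageError("violation rates sum above 1")


@dataclass
class TruthSet:
    """Ground truth: annotation + genome + per-gene and per-sample tables.

    ``genes`` is indexed by gene_id with columns baseline_mean, dispersion,
    group_log2fc, tss_nurse, tss_forager, is_deg, is_alt_tss; ``samples`` is
    indexed by sample_id with columns group, target_depth.
    """

    config: SimConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    genes: pd.DataFrame
    samples: pd.DataFrame

    def groups(self) -> pd.Series:
        return self.samples["group"]

    def to_dir(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "annotation": out / "genes.gff3",
            "genes": out / "truth_genes.tsv",
            "samples": out / "truth_samples.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gene_models(self.annotation, paths["annotation"])
        self.genes.to_csv(paths["genes"], sep="\t")
        self.samples.to_csv(paths["samples"], sep="\t")
        return paths


def simulate_truth(config: SimConfig, seed: int | None = None) -> TruthSet:
    """Lay out a toy genome, gene models and per-gene truth.

    Genes are placed sequentially with random intergenic gaps, so they never
    overlap (an explicit ``scaffold_length`` that cannot hold the requested
    genes is an error).  DEG and alternative-TSS flags are independent
    Bernoulli draws at the configured fractions; alternative TSSs are offset
    downstream by a draw from ``alt_tss_offset`` (support > 100 bp).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    pad = int(
        2 * config.read_length
        + config.inner_distance_mean
        + 3 * config.inner_distance_sd
        + 100
    )
    for si in range(config.n_scaffolds):
        scaffold = f"scf{si + 1}"
        pos = 2500
        for gi in range(config.genes_per_scaffold):
            length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{si + 1:02d}{gi + 1:03d}"
            start, end = pos, pos + length
            cds_end = end if strand == "+" else start
            genes.append(GeneModel(gid, scaffold, strand, start, end, cds_end))
            pos = end + int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        total = pos + pad
        if config.scaffold_length is not None:
            if config.scaffold_length < total:
                raise BeeCageError(
                    f"cannot place {config.genes_per_scaffold} genes in "
                    f"{config.scaffold_length} bp without overlap"
                )
            total = config.scaffold_length
        genome[scaffold] = "".join(
            np.array(list(BASES))[rng.integers(0, 4, size=total)]
        )
    annotation = GenomeAnnotation(genes)

    n_genes = len(genes)
    weights = rng.lognormal(0.0, 1.0, size=n_genes)
    weights /= weights.sum()
    is_deg = rng.random(n_genes) < config.fraction_deg
    lfc_mag = rng.uniform(config.min_abs_log2fc, config.min_abs_log2fc + 1.5, size=n_genes)
    lfc_sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    log2fc = np.where(is_deg, lfc_mag * lfc_sign, 0.0)
    shifted = rng.random(n_genes) < config.fraction_alt_tss
    offsets = rng.uniform(config.alt_tss_offset[0], config.alt_tss_offset[1], size=n_genes)

    tss_a = np.empty(n_genes, dtype=int)
    tss_b = np.empty(n_genes, dtype=int)
    off_int = np.zeros(n_genes, dtype=int)
    for i, g in enumerate(genes):
        tss_a[i] = g.tss_annotated
        if shifted[i]:
            off_int[i] = int(round(offsets[i]))
            tss_b[i] = tss_a[i] + off_int[i] if g.strand == "+" else tss_a[i] - off_int[i]
        else:
            tss_b[i] = tss_a[i]
    # ground truth under the >100 bp differential-usage rule: a shifted TSS
    # closer than that is a true negative for the caller
    is_alt = shifted & (off_int > 100)

    gene_table = pd.DataFrame(
        {
            "scaffold": [g.scaffold for g in genes],
            "strand": [g.strand for g in genes],
            "baseline_mean": weights * config.depth,
            "dispersion": config.dispersion,
            "group_log2fc": log2fc,
            "tss_nurse": tss_a,
            "tss_forager": tss_b,
            "is_deg": is_deg,
            "is_alt_tss": is_alt,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )

    n = config.n_samples_per_group
    sids = [f"N{i + 1:02d}" for i in range(n)] + [f"F{i + 1:02d}" for i in range(n)]
    grp = ["nurse"] * n + ["forager"] * n
    half = np.sqrt(config.depth_spread)
    factors = np.exp(rng.uniform(np.log(1 / half), np.log(half), size=2 * n))
    samples = pd.DataFrame(
        {"group": grp, "target_depth": np.rint(config.depth * factors).astype(int)},
        index=pd.Index(sids, name="sample_id"),
    )
    return TruthSet(config, annotation, genome, gene_table, samples)


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size: int | None = None):
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    if phi <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), size=size)


@dataclass
class SimulatedTags:
    """Generated pairs plus a per-pair truth ledger.

    ``ledger`` has one row per pair: qname, sample_id, gene_id, class
    ('clean' or a violation class).
    """

    pairs_by_sample: dict[str, list[MappedPair]]
    ledger: pd.DataFrame
    sam_paths: dict[str, Path] | None = None


def _association_span(gene: GeneModel, annotation: GenomeAnnotation) -> tuple[int, int]:
    # local copy of the tag-association window (see tag_pipeline) used to
    # keep simulated 5' ends inside the region a tag can be credited to
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


def simulate_tags(
    truth: TruthSet, seed: int | None = None, out_dir: str | Path | None = None
) -> SimulatedTags:
    """Draw tag pairs per gene x sample and optionally write per-sample SAM.

    Pair counts are NB(mean = depth_s * baseline_g * 2^(+-lfc/2 by group),
    phi); clean mate-1 5' ends are discretized normals around the group TSS
    clipped to the gene's association region; mate 2 sits downstream at a
    truncated-normal inner distance.  Violation pairs are injected at the
    configured per-class rates (mutually exclusive per pair) and recorded in
    the ledger.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    classes = ("clean",) + VIOLATION_CLASSES
    probs = np.array(
        [1.0 - sum(cfg.violation_rates.values())]
        + [cfg.violation_rates.get(c, 0.0) for c in VIOLATION_CLASSES]
    )
    scaffolds = sorted(truth.genome)
    scaff_len = {s: len(seq) for s, seq in truth.genome.items()}
    rl = cfg.read_length
    inner_excess_base = cfg.inner_distance_mean + cfg.inner_distance_sd + 2000.0

    pairs_by_sample: dict[str, list[MappedPair]] = {}
    led_rows: list[tuple[str, str, str, str]] = []
    gene_models = {g.gene_id: g for g in truth.annotation}
    spans = {gid: _association_span(g, truth.annotation) for gid, g in gene_models.items()}

    for sid, srow in truth.samples.iterrows():
        group = srow["group"]
        depth_factor = srow["target_depth"] / cfg.depth
        pairs: list[MappedPair] = []
        serial = 0
        for gid, grow in truth.genes.iterrows():
            gene = gene_models[gid]
            shift = grow["group_log2fc"] / 2.0
            mu = (
                depth_factor
                * grow["baseline_mean"]
                * 2.0 ** (shift if group == "forager" else -shift)
            )
            n = int(_nb_draw(rng, mu, grow["dispersion"]))
            if n == 0:
                continue
            tss = grow["tss_forager"] if group == "forager" else grow["tss_nurse"]
            lo, hi = spans[gid]
            p5 = np.rint(rng.normal(tss, cfg.tss_peak_width, size=n)).astype(int)
            p5 = np.clip(p5, lo, hi - 1)
            inner = rng.normal(cfg.inner_distance_mean, cfg.inner_distance_sd, size=n)
            inner = np.maximum(inner, cfg.inner_distance_min).astype(int)
            which = rng.choice(len(classes), size=n, p=probs)
            L = scaff_len[gene.scaffold]
            for k in range(n):
                serial += 1
                qname = f"{sid}:{gid}:{serial}"
                cls = classes[which[k]]
                d = int(inner[k])
                if cls == "inner_distance_excess":
                    d = int(inner_excess_base + abs(rng.normal(0.0, 500.0)))
                if gene.strand == "+":
                    m1s = int(np.clip(p5[k], 0, L - rl))
                    m1e = m1s + rl
                    m2s = int(np.clip(m1e + d, 0, L - rl))
                    m2e = m2s + rl
                    st1, st2 = "+", "-"
                else:
                    m1e = int(np.clip(p5[k] + 1, rl, L))
                    m1s = m1e - rl
                    m2e = int(np.clip(m1s - d, rl, L))
                    m2s = m2e - rl
                    st1, st2 = "-", "+"
                scf1 = scf2 = gene.scaffold
                mapq = 60
                m1_un = m2_un = False
                if cls == "low_mapq":
                    mapq = 10
                elif cls == "mate_unmapped":
                    m2_un = True
                elif cls == "different_scaffold":
                    others = [s for s in scaffolds if s != gene.scaffold] or [gene.scaffold]
                    scf2 = others[int(rng.integers(len(others)))]
                    m2s = int(np.clip(m2s, 0, scaff_len[scf2] - rl))
                    m2e = m2s + rl
                elif cls == "same_orientation":
                    st2 = st1
                pairs.append(
                    MappedPair(
                        sample_id=sid,
                        qname=qname,
                        scaffold_1=scf1,
                        scaffold_2=None if m2_un else scf2,
                        strand_1=st1,
                        strand_2=None if m2_un else st2,
                        mate1_start=m1s,
                        mate1_end=m1e,
                        mate2_start=None if m2_un else m2s,
                        mate2_end=None if m2_un else m2e,
                        mapq=mapq,
                        mate1_unmapped=m1_un,
                        mate2_unmapped=m2_un,
                    )
                )
                led_rows.append((qname, sid, gid, cls))
        pairs_by_sample[sid] = pairs

    ledger = pd.DataFrame(led_rows, columns=["qname", "sample_id", "gene_id", "class"])
    sam_paths = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sam_paths = {}
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": s, "LN": scaff_len[s]} for s in scaffolds],
        }
        for sid, pairs in pairs_by_sample.items():
            path = out / f"{sid}.sam"
            write_pairs_sam(pairs, path, header)
            sam_paths[sid] = path
        ledger.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    return SimulatedTags(pairs_by_sample, ledger, sam_paths)


def write_pairs_sam(pairs: list[MappedPair], path: str | Path, header: dict) -> None:
    """Serialize pairs as a minimal valid SAM file (two records per pair)."""
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for p in pairs:
            for mate in (1, 2):
                rec = pysam.AlignedSegment(af.header)
                rec.query_name = p.qname
                rec.is_paired = True
                rec.is_read1 = mate == 1
                rec.is_read2 = mate == 2
                scf = p.scaffold_1 if mate == 1 else p.scaffold_2
                strand = p.strand_1 if mate == 1 else p.strand_2
                start = p.mate1_start if mate == 1 else p.mate2_start
                end = p.mate1_end if mate == 1 else p.mate2_end
                unmapped = p.mate1_unmapped if mate == 1 else p.mate2_unmapped
                if unmapped:
                    rec.is_unmapped = True
                    rec.mapping_quality = 0
                else:
                    rec.reference_id = tid[scf]
                    rec.reference_start = start
                    rec.mapping_quality = p.mapq
                    rec.is_reverse = strand == "-"
                    rec.cigarstring = f"{end - start}M"
                    rec.query_sequence = "N" * (end - start)
                o_scf = p.scaffold_2 if mate == 1 else p.scaffold_1
                o_un = p.mate2_unmapped if mate == 1 else p.mate1_unmapped
                if o_un:
                    rec.mate_is_unmapped = True
                else:
                    rec.next_reference_id = tid[o_scf]
                    rec.next_reference_start = p.mate2_start if mate == 1 else p.mate1_start
                    rec.mate_is_reverse = (p.strand_2 if mate == 1 else p.strand_1) == "-"
                af.write(rec)


def spike_motifs(
    genome: dict[str, str],
    promoter_intervals: list[tuple[str, int, int]],
    pwm: PWM,
    per_promoter_rate: float,
    seed: int | None = None,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Write the PWM consensus into promoters at the given per-promoter rate.

    Returns the modified genome and an insertion ledger of (scaffold,
    offset) pairs, one per modified promoter.  Promoters shorter than the
    consensus are skipped with a warning.
    """
    import logging

    log = logging.getLogger("beecage")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    L = len(consensus)
    seqs = {k: list(v) for k, v in genome.items()}
    ledger: list[tuple[str, int]] = []
    for scaffold, start, end in promoter_intervals:
        if not (0 <= start <= end <= len(genome[scaffold])):
            raise BeeCageError(f"promoter ({scaffold},{start},{end}) outside genome bounds")
        if rng.random() >= per_promoter_rate:
            continue
        if end - start < L:
            log.warning("promoter %s:%d-%d shorter than consensus; skipped", scaffold, start, end)
            continue
        off = start + int(rng.integers(0, end - start - L + 1))
        seqs[scaffold][off : off + L] = consensus
        ledger.append((scaffold, off))
    return {k: "".join(v) for k, v in seqs.items()}, ledger
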