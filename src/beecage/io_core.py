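"""Readers/writers for the formats the pipeline touches, plus the shared
coordinate convention.

Every coordinate handled inside this package is 0-based, half-open
(``[start, end)``), the convention of BED and SAM arithmetic.  GFF3 input
(1-based, closed) is converted on read; BED passes through unchanged.
Conversions are mutually inverse on valid inputs.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("beecage")

STRANDS = ("+", "-")

BASES = "ACGT"


class BeeCageError(ValueError):
    """Raised for malformed inputs or contract violations."""


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the CLI."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``cds_end`` is the genomic bound of the stop codon at the gene's 3' end:
    an exclusive upper bound for ``+`` genes and an inclusive lower bound for
    ``-`` genes (promoters are clipped so they never extend past it in the
    direction of transcription).
    """

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise BeeCageError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise BeeCageError(f"{self.gene_id}: need 0 <= start < end")
        if self.cds_end is not None and not (self.start <= self.cds_end <= self.end):
            raise BeeCageError(f"{self.gene_id}: cds_end outside gene span")

    @property
    def tss_annotated(self) -> int:
        """The gene's annotated 5' start (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeAnnotation:
    """Ordered gene models with a strand-aware upstream-neighbor index.

    Genes are kept sorted by start within each (scaffold, strand).  The
    upstream neighbor of a gene is the nearest same-strand gene in the gene's
    5' direction: the previous gene (by start) on ``+``, the next one on
    ``-``.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise BeeCageError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
        self._by_loc: dict[tuple[str, str], list[GeneModel]] = {}
        for g in self._genes:
            self._by_loc.setdefault((g.scaffold, g.strand), []).append(g)
        self._upstream: dict[str, GeneModel | None] = {}
        for key, gs in self._by_loc.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(gs):
                if g.strand == "+":
                    self._upstream[g.gene_id] = gs[i - 1] if i > 0 else None
                else:
                    self._upstream[g.gene_id] = gs[i + 1] if i + 1 < len(gs) else None

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, scaffold: str, strand: str) -> list[GeneModel]:
        return self._by_loc.get((scaffold, strand), [])

    def upstream_of(self, gene: GeneModel | str) -> GeneModel | None:
        gid = gene if isinstance(gene, str) else gene.gene_id
        return self._upstream[gid]


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def _parse_gff3_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise BeeCageError(f"bad GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gene_models(source: str | Path | IO[str]) -> GenomeAnnotation:
    """Read gene (and optional CDS) features from GFF3 into an annotation.

    GFF3 coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention.  CDS children (``Parent=`` the gene id) define
    ``cds_end``: max CDS end for ``+`` genes, min CDS start for ``-`` genes.
    Malformed lines raise with their line number; duplicate gene ids are
    rejected.
    """
    genes: list[tuple[str, str, str, int, int]] = []
    cds: dict[str, list[tuple[int, int]]] = {}
    fh = _open_text(source)
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise BeeCageError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        scaffold, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise BeeCageError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise BeeCageError(f"GFF3 line {lineno}: end < start")
        if ftype == "gene":
            att = _parse_gff3_attributes(attrs)
            if "ID" not in att:
                raise BeeCageError(f"GFF3 line {lineno}: gene without ID")
            genes.append((att["ID"], scaffold, strand, start1 - 1, end1))
        elif ftype == "CDS":
            att = _parse_gff3_attributes(attrs)
            parent = att.get("Parent", att.get("ID"))
            if parent is not None:
                cds.setdefault(parent, []).append((start1 - 1, end1))
    models = []
    for gid, scaffold, strand, start, end in genes:
        cds_end: int | None = None
        if gid in cds:
            if strand == "+":
                cds_end = max(e for _s, e in cds[gid])
            else:
                cds_end = min(s for s, _e in cds[gid])
        models.append(GeneModel(gid, scaffold, strand, start, end, cds_end))
    return GenomeAnnotation(models)


def write_gene_models(annotation: GenomeAnnotation, dest: str | Path | IO[str]) -> None:
    """Write an annotation back to GFF3 (gene + CDS features)."""
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    fh.write("##gff-version 3\n")
    for g in sorted(annotation, key=lambda g: (g.scaffold, g.start, g.gene_id)):
        fh.write(
            f"{g.scaffold}\tbeecage\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        if g.cds_end is not None:
            s, e = (g.start, g.cds_end) if g.strand == "+" else (g.cds_end, g.end)
            if e > s:
                fh.write(
                    f"{g.scaffold}\tbeecage\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )
    if isinstance(dest, (str, Path)):
        fh.close()


# ---------------------------------------------------------------------------
# mapped pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MappedPair:
    """One CAGE tag pair: mate 1 carries the transcript 5' end.

    Coordinates are 0-based half-open.  ``inner_distance`` is the gap between
    the mates in genome coordinates (downstream mate start minus upstream
    mate end) and may be negative for overlapping mates; it is ``None``
    unless both mates map to one scaffold.  ``mapq`` is the minimum mapping
    quality over the mapped mates (0 if neither maps).
    """

    sample_id: str
    qname: str
    scaffold_1: str | None
    scaffold_2: str | None
    strand_1: str | None
    strand_2: str | None
    mate1_start: int | None
    mate1_end: int | None
    mate2_start: int | None
    mate2_end: int | None
    mapq: int
    mate1_unmapped: bool = False
    mate2_unmapped: bool = False

    @property
    def both_mapped(self) -> bool:
        return not (self.mate1_unmapped or self.mate2_unmapped)

    @property
    def inner_distance(self) -> int | None:
        if not self.both_mapped or self.scaffold_1 != self.scaffold_2:
            return None
        if self.mate1_start <= self.mate2_start:
            up_end, down_start = self.mate1_end, self.mate2_start
        else:
            up_end, down_start = self.mate2_end, self.mate1_start
        return down_start - up_end

    @property
    def five_prime_pos(self) -> int | None:
        """5' end of mate 1 on its strand (the CAGE TSS signal)."""
        if self.mate1_unmapped:
            return None
        return self.mate1_start if self.strand_1 == "+" else self.mate1_end - 1


def read_alignments(
    source: str | Path | IO[str], sample_id: str | None = None
) -> Iterator[MappedPair]:
    """Stream mate-matched pairs out of a SAM file.

    Mates are matched by QNAME over primary records; a QNAME with anything
    other than exactly two primary records is an error.  Unmapped mates are
    flagged, not dropped — filtering is a later pipeline stage.
    """
    if isinstance(source, (str, Path)):
        af = pysam.AlignmentFile(str(source), "r", check_sq=False)
    else:
        af = pysam.AlignmentFile(source, "r", check_sq=False)
    if not af.header.to_dict():
        raise BeeCageError("SAM input has no header")
    pending: dict[str, pysam.AlignedSegment] = {}
    sid = sample_id if sample_id is not None else "sample"

    def _mk(rec1: pysam.AlignedSegment, rec2: pysam.AlignedSegment) -> MappedPair:
        if rec1.is_read2 and rec2.is_read1:
            rec1, rec2 = rec2, rec1
        if not (rec1.is_read1 and rec2.is_read2):
            raise BeeCageError(f"QNAME {rec1.query_name!r}: mates not flagged read1/read2")

        def _coords(r: pysam.AlignedSegment):
            if r.is_unmapped:
                return None, None, None, None, True
            return (
                r.reference_name,
                "-" if r.is_reverse else "+",
                r.reference_start,
                r.reference_end,
                False,
            )

        s1, st1, a1, b1, u1 = _coords(rec1)
        s2, st2, a2, b2, u2 = _coords(rec2)
        mapqs = [r.mapping_quality for r in (rec1, rec2) if not r.is_unmapped]
        return MappedPair(
            sample_id=sid,
            qname=rec1.query_name,
            scaffold_1=s1,
            scaffold_2=s2,
            strand_1=st1,
            strand_2=st2,
            mate1_start=a1,
            mate1_end=b1,
            mate2_start=a2,
            mate2_end=b2,
            mapq=min(mapqs) if mapqs else 0,
            mate1_unmapped=u1,
            mate2_unmapped=u2,
        )

    for rec in af:
        if rec.is_secondary or rec.is_supplementary:
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
        else:
            yield _mk(mate, rec)
    if pending:
        bad = next(iter(pending))
        raise BeeCageError(f"QNAME {bad!r} does not have exactly 2 primary records")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple],
    dest: str | Path | IO[str],
) -> None:
    """Write BED6 records, deterministically sorted by (chrom, start, end, name).

    Intervals are (chrom, start, end, name, score, strand) tuples already in
    0-based half-open coordinates (BED-native, emitted unchanged).
    """
    rows = []
    for iv in intervals:
        chrom, start, end, name, score, strand = iv
        if start < 0 or end < 0:
            raise BeeCageError(f"negative BED coordinate in {iv!r}")
        rows.append((str(chrom), int(start), int(end), str(name), score, str(strand)))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    for chrom, start, end, name, score, strand in rows:
        fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
    if isinstance(dest, (str, Path)):
        fh.close()


def read_bed(source: str | Path | IO[str]) -> list[tuple]:
    """Read BED6 back into (chrom, start, end, name, score, strand) tuples."""
    fh = _open_text(source)
    out = []
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        chrom, start, end, name, score, strand = line.split("\t")
        out.append((chrom, int(start), int(end), name, score, strand))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a genome FASTA into a scaffold -> sequence dict (uppercased)."""
    fh = _open_text(source)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], dest: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(dest), "fasta")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over (A, C, G, T).

    ``matrix`` holds row-normalized probabilities, one row per motif
    position; rows sum to 1 within 1e-9.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise BeeCageError(f"{self.motif_id}: matrix must be L x 4 with L >= 1")
        if np.any(m < 0):
            raise BeeCageError(f"{self.motif_id}: negative matrix entries")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise BeeCageError(f"{self.motif_id}: rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def pwm_from_counts(motif_id: str, counts: np.ndarray, pseudocount: float = 0.01) -> PWM:
    """Row-normalize a count matrix: (c + p) / (sum(c) + 4 p) per position."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise BeeCageError(f"{motif_id}: negative counts")
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PWM(motif_id, probs, pseudocount)


def read_pwms(source: str | Path | IO[str], pseudocount: float = 0.01) -> list[PWM]:
    """Parse JASPAR-style count blocks: ``>id`` then 4 rows labeled A/C/G/T.

    Counts plus ``pseudocount`` are converted to row-normalized
    probabilities.  Unequal row lengths and negative counts are errors.
    """
    fh = _open_text(source)
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal motif_id, rows
        if motif_id is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise BeeCageError(f"{motif_id}: missing rows for {sorted(missing)}")
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise BeeCageError(f"{motif_id}: unequal row lengths")
        counts = np.array([rows[b] for b in BASES], dtype=float).T
        pwms.append(pwm_from_counts(motif_id, counts, pseudocount))
        motif_id, rows = None, {}

    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            motif_id = line[1:].split()[0]
            continue
        if motif_id is None:
            raise BeeCageError("PWM rows before any >id header")
        base, rest = line[0].upper(), line[1:]
        if base not in BASES:
            raise BeeCageError(f"{motif_id}: unexpected row label {line[0]!r}")
        vals = [float(v) for v in rest.replace("[", " ").replace("]", " ").split()]
        rows[base] = vals
    _flush()
    return pwms


def write_pwms(pwms: Sequence[PWM], dest: str | Path | IO[str]) -> None:
    """Write PWMs as JASPAR-style probability blocks (re-readable)."""
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    for pwm in pwms:
        fh.write(f">{pwm.motif_id}\n")
        for bi, base in enumerate(BASES):
            vals = " ".join(f"{v:.6f}" for v in pwm.matrix[:, bi])
            fh.write(f"{base} {vals}\n")
    if isinstance(dest, (str, Path)):
        fh.close()
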