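"""GO term over-representation and promoter motif enrichment.

GO enrichment is the standard one-sided Fisher/hypergeometric test per term
with BH correction.  Motif enrichment scores a promoter set against a PWM
with the log of the average likelihood ratio over all windows on both
strands, and calibrates it with an empirical randomization: draws of
length-matched background sequence sets give the null distribution of the
set score, and the p-value is the (add-one) fraction of draws at or above
the observed score.  Three background strategies mirror the promoterome
protocol: the opposing group's promoters, all annotated promoters, or
random genomic segments.  The score is a stated approximation of the
Clover statistic this protocol used — thresholds (score > 6, p < 0.05) are
kept as configuration, the raw-score formula is not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_core import BASES, BeeCageError, PWM
from .diffexp import bh_fdr

BACKGROUND_KINDS = ("opposing_promoters", "all_promoters", "random_genome")


@dataclass(frozen=True)
class EnrichedTerm:
    term_id: str
    k: int  # query genes carrying the term
    K: int  # background genes carrying the term
    n: int  # query size
    N: int  # background size
    p: float
    q: float


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    score: float
    p_empirical: float
    background_kind: str
    enriched: bool


def go_enrichment(
    query_genes,
    background_genes,
    gene2term: pd.DataFrame,
) -> list[EnrichedTerm]:
    """Per-term right-tail hypergeometric enrichment with BH correction.

    ``gene2term`` needs columns gene_id, term_id (many-to-many); the query
    must be a subset of the background; terms absent from the background
    are skipped.  Results are sorted by p.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query <= background:
        raise BeeCageError("query genes must be a subset of the background")
    for col in ("gene_id", "term_id"):
        if col not in gene2term.columns:
            raise BeeCageError(f"gene2term missing column {col!r}")
    sub = gene2term[gene2term["gene_id"].isin(background)]
    N, n = len(background), len(query)
    rows = []
    for term_id, genes in sub.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    out = [
        EnrichedTerm(term_id, k, K, n, N, p, float(q))
        for (term_id, k, K, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda t: (t.p, t.term_id))
    return out


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise BeeCageError(f"non-DNA letter {exc.args[0]!r} in sequence") from exc


def _window_log_lrs(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log likelihood ratios of every window on one strand.

    ``logodds`` is L x 5 (log(P_pwm/bg) per base, 0 in the N column so any
    window containing N scores LR = 1 only if fully N; windows with any N
    are instead forced to LR = 1 below).
    """
    L = logodds.shape[0]
    if codes.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = logodds[np.arange(L)[None, :], win].sum(axis=1)
    has_n = (win == 4).any(axis=1)
    scores[has_n] = 0.0
    return scores


def _logodds(pwm: PWM, bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement L x 5 log-odds tables."""
    fwd = np.zeros((len(pwm), 5))
    fwd[:, :4] = np.log(pwm.matrix) - np.log(bg)[None, :]
    # reverse complement: reverse positions, swap A<->T and C<->G
    rc = np.zeros_like(fwd)
    rc[:, :4] = fwd[::-1, [3, 2, 1, 0]]
    return fwd, rc


def pwm_scan_score(
    sequence: str, pwm: PWM, bg_freqs=(0.25, 0.25, 0.25, 0.25)
) -> float:
    """Log of the average likelihood ratio over all windows, both strands.

    Windows containing N contribute LR = 1.  Sequences shorter than the
    motif are an error (the set-level scorer excludes them with a warning).
    """
    bg = np.asarray(bg_freqs, dtype=float)
    if np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise BeeCageError("background frequencies must be positive and sum to 1")
    codes = _encode(sequence)
    if codes.size < len(pwm):
        raise BeeCageError("sequence shorter than the motif")
    fwd, rc = _logodds(pwm, bg)
    lrs = np.concatenate([_window_log_lrs(codes, fwd), _window_log_lrs(codes, rc)])
    # log-mean-exp for numerical safety on sharp matrices
    m = lrs.max()
    return float(m + np.log(np.exp(lrs - m).mean()))


def _set_score(seqs: list[np.ndarray], fwd: np.ndarray, rc: np.ndarray) -> float:
    scores = []
    for codes in seqs:
        if codes.size < fwd.shape[0]:
            continue
        lrs = np.concatenate([_window_log_lrs(codes, fwd), _window_log_lrs(codes, rc)])
        m = lrs.max()
        scores.append(m + np.log(np.exp(lrs - m).mean()))
    if not scores:
        raise BeeCageError("no target sequence is as long as the motif")
    return float(np.mean(scores))


def _draw_background(
    rng: np.random.Generator,
    target_lengths: list[int],
    background_seqs: list[np.ndarray] | None,
    genome_codes: list[np.ndarray] | None,
    length_tol: float,
) -> list[np.ndarray]:
    import logging

    out = []
    if genome_codes is not None:
        weights = np.array([c.size for c in genome_codes], dtype=float)
        weights /= weights.sum()
        for L in target_lengths:
            ci = rng.choice(len(genome_codes), p=weights)
            codes = genome_codes[ci]
            start = int(rng.integers(0, max(1, codes.size - L + 1)))
            out.append(codes[start : start + L])
        return out
    lengths = np.array([c.size for c in background_seqs])
    warned = False
    for L in target_lengths:
        ok = np.where(np.abs(lengths - L) <= length_tol * L)[0]
        if ok.size == 0:
            ok = np.arange(len(background_seqs))
            if not warned:
                logging.getLogger("beecage").warning(
                    "no length-matched background for length %d; sampling freely", L
                )
                warned = True
        out.append(background_seqs[int(rng.choice(ok))])
    return out


def motif_enrichment(
    target_seqs: list[str],
    background,
    pwms: list[PWM],
    n_draws: int = 1000,
    seed: int | None = None,
    background_kind: str = "all_promoters",
    bg_freqs=(0.25, 0.25, 0.25, 0.25),
    score_min: float = 6.0,
    alpha: float = 0.05,
    length_tol: float = 0.10,
) -> list[MotifEnrichment]:
    """Empirical motif enrichment of a promoter set against a background.

    ``background`` is a list of sequences (promoter backgrounds) or a
    scaffold -> sequence dict (``background_kind='random_genome'``; draws
    are uniform genomic segments).  Each of ``n_draws`` draws samples
    len(targets) background sequences length-matched within ±``length_tol``
    (with replacement); p_empirical = (1 + #{draw score >= observed}) /
    (n_draws + 1).  A motif is reported enriched when its observed score
    exceeds ``score_min`` and p_empirical < ``alpha``.
    """
    if n_draws < 1:
        raise BeeCageError("n_draws must be >= 1")
    if background_kind not in BACKGROUND_KINDS:
        raise BeeCageError(f"unknown background kind {background_kind!r}")
    if not target_seqs:
        raise BeeCageError("empty target set")
    rng = np.random.default_rng(seed)
    bg = np.asarray(bg_freqs, dtype=float)
    targets = [_encode(s) for s in target_seqs]
    target_lengths = [t.size for t in targets]
    genome_codes = None
    background_codes = None
    if background_kind == "random_genome":
        if not isinstance(background, dict):
            raise BeeCageError("random_genome background needs a scaffold->sequence dict")
        genome_codes = [_encode(s) for s in background.values()]
    else:
        background_codes = [_encode(s) for s in background]
        if not background_codes:
            raise BeeCageError("empty background set")

    draws = [
        _draw_background(rng, target_lengths, background_codes, genome_codes, length_tol)
        for _ in range(n_draws)
    ]
    out = []
    for pwm in pwms:
        fwd, rc = _logodds(pwm, bg)
        obs = _set_score(targets, fwd, rc)
        exceed = sum(1 for d in draws if _set_score(d, fwd, rc) >= obs)
        p_emp = (1 + exceed) / (n_draws + 1)
        out.append(
            MotifEnrichment(
                pwm.motif_id, obs, p_emp, background_kind,
                bool(obs > score_min and p_emp < alpha),
            )
        )
    return out


def compare_gc_bias(target_promoter_seqs, other_promoter_seqs) -> tuple[float, float]:
    """G/C-content difference between two promoter sets with a rank-sum test.

    Returns (mean GC of targets - mean GC of others, two-sided Wilcoxon p).
    """
    from .descriptive_stats import wilcoxon_rank_sum
    from .tss_analysis import gc_fraction

    gc_a = [g for g in gc_fraction(target_promoter_seqs) if not np.isnan(g)]
    gc_b = [g for g in gc_fraction(other_promoter_seqs) if not np.isnan(g)]
    if not gc_a or not gc_b:
        raise BeeCageError("empty promoter set")
    delta = float(np.mean(gc_a) - np.mean(gc_b))
    p = wilcoxon_rank_sum(gc_a, gc_b)
    return delta, p
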