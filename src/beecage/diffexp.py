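"""Negative-binomial exact-test differential expression.

Counts are modeled NB with variance mu + phi mu^2.  A common dispersion is
estimated by conditional maximum likelihood on counts scaled to a common
effective library size; per-gene (tagwise) dispersions shrink each gene's
own conditional likelihood toward the common one with a prior weight.  The
two-group test conditions on the gene's total count: under equal effective
libraries the group-A total given the overall total has a closed
conditional distribution, and the two-sided p-value doubles the smaller
tail (capped at 1).  Library equalization is mean-preserving count scaling
to the geometric-mean effective size — a deliberate, simulation-calibrated
approximation of the quantile adjustment used by the edgeR implementation
this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control, hypergeom, spearmanr

from .io_core import BeeCageError
from .tag_pipeline import CountMatrix, tmm_factors

PHI_MIN, PHI_MAX = 1e-4, 10.0


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_cpm: float
    log2fc: float
    p_value: float
    q_value: float
    dispersion: float


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric right-tail overlap of two gene sets in a universe."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p_value: float
    p_bonferroni: float


# ---------------------------------------------------------------------------
# dispersion estimation (conditional likelihood given per-group totals)
# ---------------------------------------------------------------------------


def _equalized_counts(matrix: CountMatrix, effective_lib_sizes: pd.Series | None) -> np.ndarray:
    counts = matrix.counts.to_numpy(dtype=float)
    if effective_lib_sizes is None:
        libs = matrix.library_sizes.to_numpy(dtype=float)
        factors = tmm_factors(matrix).to_numpy()
        eff = libs * factors
    else:
        eff = effective_lib_sizes.loc[matrix.counts.columns].to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    return counts * (common / eff)


def _group_cols(matrix: CountMatrix) -> list[np.ndarray]:
    cols = []
    for group in matrix.groups.unique():
        idx = np.where((matrix.groups == group).to_numpy())[0]
        cols.append(idx)
    return cols


def _cond_loglik_per_gene(y: np.ndarray, group_cols: list[np.ndarray], phi: float) -> np.ndarray:
    """Conditional NB log-likelihood per gene, summed over groups.

    For one group of n samples with counts y_i and total z, conditioning on
    z removes the mean: l(phi) = sum_i lgamma(y_i + r) + lgamma(n r)
    - lgamma(z + n r) - n lgamma(r), with r = 1/phi (phi-free terms
    dropped).
    """
    r = 1.0 / phi
    total = np.zeros(y.shape[0])
    for idx in group_cols:
        sub = y[:, idx]
        n = len(idx)
        z = sub.sum(axis=1)
        total += (
            gammaln(sub + r).sum(axis=1)
            + gammaln(n * r)
            - gammaln(z + n * r)
            - n * gammaln(r)
        )
    return total


def estimate_common_dispersion(
    matrix: CountMatrix,
    effective_lib_sizes: pd.Series | None = None,
) -> float:
    """Common dispersion maximizing the summed conditional log-likelihood.

    Counts are scaled to a common effective library size first; the search
    is over log phi in [1e-4, 10].  At least two samples per group; all-zero
    matrices are an error.
    """
    y = _equalized_counts(matrix, effective_lib_sizes)
    if not (y.sum(axis=1) > 0).any():
        raise BeeCageError("all genes have zero counts")
    groups = _group_cols(matrix)
    for idx in groups:
        if len(idx) < 2:
            raise BeeCageError("each group needs >= 2 samples")

    def neg(logphi: float) -> float:
        return -float(_cond_loglik_per_gene(y, groups, np.exp(logphi)).sum())

    res = minimize_scalar(
        neg, bounds=(np.log(PHI_MIN), np.log(PHI_MAX)), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def estimate_tagwise_dispersion(
    matrix: CountMatrix,
    phi_common: float,
    prior_df: float = 10.0,
    effective_lib_sizes: pd.Series | None = None,
    grid_size: int = 201,
) -> pd.Series:
    """Per-gene dispersions shrunk toward the common value.

    Maximizes, per gene, its own conditional log-likelihood plus
    ``prior_df`` times the average per-gene common log-likelihood — an
    empirical-Bayes compromise: prior_df -> infinity returns the common
    dispersion for every gene, prior_df = 0 the per-gene conditional MLE.
    Optimized on a log-spaced grid that always contains ``phi_common``.
    """
    y = _equalized_counts(matrix, effective_lib_sizes)
    groups = _group_cols(matrix)
    n_genes = y.shape[0]
    grid = np.unique(
        np.concatenate([np.geomspace(PHI_MIN, PHI_MAX, grid_size), [phi_common]])
    )
    per_gene = np.empty((n_genes, grid.size))
    common = np.empty(grid.size)
    for gi, phi in enumerate(grid):
        ll = _cond_loglik_per_gene(y, groups, phi)
        per_gene[:, gi] = ll
        common[gi] = ll.mean()
    objective = per_gene + prior_df * common[None, :]
    best = grid[objective.argmax(axis=1)]
    return pd.Series(best, index=matrix.counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# the exact test
# ---------------------------------------------------------------------------


def exact_test_nb(
    counts_a,
    counts_b,
    phi: float,
    effective_lib_sizes=None,
) -> float:
    """Two-sided conditional NB test for a two-group count difference.

    With equal libraries the group-A total a given the grand total t has
    P(a | t) proportional to C(a + r1) * C(t - a + r2) gamma terms with
    r_g = n_g / phi; the p-value doubles the smaller tail (each including
    the observed point), capped at 1.  When effective library sizes are
    given, counts are first scaled (mean-preserving) to their geometric
    mean and rounded.
    """
    if phi < 0:
        raise BeeCageError("dispersion must be >= 0")
    a_arr = np.asarray(counts_a, dtype=float)
    b_arr = np.asarray(counts_b, dtype=float)
    if effective_lib_sizes is not None:
        eff = np.asarray(effective_lib_sizes, dtype=float)
        common = np.exp(np.mean(np.log(eff)))
        scaled = np.concatenate([a_arr, b_arr]) * (common / eff)
        a_arr = scaled[: a_arr.size]
        b_arr = scaled[a_arr.size :]
    a = int(round(a_arr.sum()))
    b = int(round(b_arr.sum()))
    t = a + b
    if t == 0:
        return 1.0
    phi = max(phi, 1e-12)
    r1 = a_arr.size / phi
    r2 = b_arr.size / phi
    k = np.arange(t + 1)
    logw = (
        gammaln(k + r1)
        - gammaln(k + 1)
        + gammaln(t - k + r2)
        - gammaln(t - k + 1)
    )
    logw -= logsumexp(logw)
    lo = logsumexp(logw[: a + 1])
    hi = logsumexp(logw[a:])
    p = 2.0 * np.exp(min(lo, hi))
    return float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise BeeCageError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return false_discovery_control(p, method="bh")


def de_pipeline(
    matrix: CountMatrix,
    fdr: float = 0.05,
    prior_df: float = 10.0,
    cpm_filter: bool = True,
) -> pd.DataFrame:
    """CPM filter -> TMM -> common+tagwise dispersion -> exact test -> BH.

    Returns a per-gene frame (mean_cpm, log2fc, p_value, q_value,
    dispersion, significant).  log2fc is group B vs group A in the order
    the group labels first appear, computed on CPM with a 0.5 pseudo-count.
    """
    from .tag_pipeline import filter_expressed

    work = filter_expressed(matrix, mode="cpm") if cpm_filter else matrix
    factors = tmm_factors(work)
    eff = work.library_sizes * factors
    phi_common = estimate_common_dispersion(work, effective_lib_sizes=eff)
    phi_gene = estimate_tagwise_dispersion(
        work, phi_common, prior_df=prior_df, effective_lib_sizes=eff
    )
    labels = list(work.groups.unique())
    if len(labels) != 2:
        raise BeeCageError("exactly two groups required")
    cols_a = work.groups.index[work.groups == labels[0]]
    cols_b = work.groups.index[work.groups == labels[1]]
    cpm = work.counts * 1e6 / eff
    mean_cpm = cpm.mean(axis=1)
    log2fc = np.log2(cpm[cols_b].mean(axis=1) + 0.5) - np.log2(cpm[cols_a].mean(axis=1) + 0.5)
    eff_a = eff.loc[cols_a]
    eff_b = eff.loc[cols_b]
    eff_all = pd.concat([eff_a, eff_b])
    pvals = np.empty(work.counts.shape[0])
    for i, (gid, row) in enumerate(work.counts.iterrows()):
        pvals[i] = exact_test_nb(
            row[cols_a].to_numpy(),
            row[cols_b].to_numpy(),
            phi_gene.loc[gid],
            effective_lib_sizes=eff_all.to_numpy(),
        )
    qvals = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "mean_cpm": mean_cpm,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "dispersion": phi_gene,
            "significant": qvals < fdr,
        },
        index=work.counts.index,
    )


# ---------------------------------------------------------------------------
# set overlap, HPG screen, cross-study concordance
# ---------------------------------------------------------------------------


def overlap_test_counts(
    n_a: int, n_b: int, n_overlap: int, n_universe: int, m_tests: int = 1
) -> OverlapResult:
    """Right-tail hypergeometric P(X >= k) with Bonferroni adjustment."""
    if n_overlap > min(n_a, n_b):
        raise BeeCageError("overlap larger than the smaller set")
    if max(n_a, n_b) > n_universe:
        raise BeeCageError("set larger than the universe")
    p = float(hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
    return OverlapResult(n_a, n_b, n_overlap, n_universe, p, min(1.0, m_tests * p))


def overlap_test(set_a, set_b, universe, m_tests: int = 1) -> OverlapResult:
    """Hypergeometric overlap of two gene sets within a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise BeeCageError("sets must be subsets of the universe")
    return overlap_test_counts(len(set_a), len(set_b), len(set_a & set_b), len(universe), m_tests)


def hpg_screen(
    de_up: dict[str, set],
    hpg_table: pd.DataFrame,
    lfc_min: float = 3.0,
    top_fractions: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20),
    contaminating_group: str = "nurse",
) -> dict:
    """Screen DEGs against glandular (HPG) contamination.

    ``de_up`` maps group label -> genes upregulated in that group;
    ``hpg_table`` needs columns gene_id, group, log2fc (gland vs brain).
    Returns, per group, the DEGs intersecting (a) genes with gland log2fc >
    ``lfc_min`` and (b) the top fractions of gland-upregulated genes by
    fold change.  For groups other than ``contaminating_group``, genes that
    are also in the contaminating group's top 10% are excluded first (the
    gland develops with the contaminating state, so contamination would
    masquerade as that group's upregulation).
    """
    for col in ("gene_id", "group", "log2fc"):
        if col not in hpg_table.columns:
            raise BeeCageError(f"hpg_table missing column {col!r}")
    by_group = {g: sub.sort_values("log2fc", ascending=False) for g, sub in hpg_table.groupby("group")}
    contam_top10: set = set()
    if contaminating_group in by_group:
        sub = by_group[contaminating_group]
        up = sub[sub["log2fc"] > 0]
        contam_top10 = set(up.head(max(1, int(np.ceil(0.10 * len(up)))))["gene_id"]) if len(up) else set()
    out: dict = {}
    for group, degs in de_up.items():
        if group not in by_group:
            out[group] = {"strong": set(), "top": {f: set() for f in top_fractions}}
            continue
        sub = by_group[group]
        degs_eff = set(degs)
        if group != contaminating_group:
            degs_eff -= contam_top10
        strong = set(sub[sub["log2fc"] > lfc_min]["gene_id"]) & degs_eff
        up = sub[sub["log2fc"] > 0]
        top = {}
        for frac in top_fractions:
            k = max(1, int(np.ceil(frac * len(up)))) if len(up) else 0
            top[frac] = set(up.head(k)["gene_id"]) & degs_eff
        out[group] = {"strong": strong, "top": top}
    return out


def spearman_log2fc(results_a: pd.Series, results_b: pd.Series) -> float:
    """Spearman rank correlation of log2 fold changes over shared genes."""
    shared = results_a.index.intersection(results_b.index)
    if len(shared) < 3:
        raise BeeCageError("need >= 3 shared genes")
    rho, _p = spearmanr(results_a.loc[shared], results_b.loc[shared])
    return float(rho)
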