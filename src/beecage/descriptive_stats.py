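"""Expression variability, clustering and dendrogram validation.

Variability is summarized three ways: per-gene CV^2 within a group, the
within-group variance of row-standardized (Z-scored) expression, and the
biological coefficient of variation sqrt(phi) over the most variable genes.
Sample/gene clustering is Ward's minimum-variance linkage; its fidelity to
the observed distances is the cophenetic correlation coefficient (CPCC) —
the Pearson correlation between observed pairwise distances and the merge
heights joining each pair in the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io_core import BeeCageError
from .tag_pipeline import CountMatrix


def _group_counts(matrix: CountMatrix, group: str) -> pd.DataFrame:
    cols = matrix.groups.index[matrix.groups == group]
    if len(cols) < 2:
        raise BeeCageError(f"group {group!r} needs >= 2 samples")
    return matrix.counts[cols]


def cv2_per_gene(matrix: CountMatrix, group: str) -> pd.Series:
    """Squared coefficient of variation (sd/mean)^2 within a group.

    Sample sd (n-1); genes with zero group mean are returned as NaN rather
    than computed.
    """
    sub = _group_counts(matrix, group)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    out = (sd / mean) ** 2
    out[mean == 0] = np.nan
    return out.rename("cv2")


def zscore_variance(matrix: CountMatrix, group: str) -> pd.Series:
    """Within-group variance of row-standardized expression.

    Each gene is Z-scored across ALL samples (mean 0, sample sd 1), then
    the variance is taken over the group's columns only.  Genes constant
    across all samples are NaN.
    """
    sub_cols = matrix.groups.index[matrix.groups == group]
    if len(sub_cols) < 2:
        raise BeeCageError(f"group {group!r} needs >= 2 samples")
    mean = matrix.counts.mean(axis=1)
    sd = matrix.counts.std(axis=1, ddof=1)
    z = matrix.counts.sub(mean, axis=0).div(sd, axis=0)
    out = z[sub_cols].var(axis=1, ddof=1)
    out[sd == 0] = np.nan
    return out.rename("zvar")


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled size is <= 20 with no ties, otherwise
    the tie-corrected normal approximation with continuity correction
    (``mode`` forces 'exact' or 'approx').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BeeCageError("empty input")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise BeeCageError(f"unknown mode {mode!r}")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# hierarchical clustering + CPCC
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """A merge tree (scipy linkage matrix) over labeled items."""

    linkage: np.ndarray
    labels: list[str]


def _distances(data: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return pdist(data, metric="euclidean")
    if metric == "pearson":
        sd = data.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise BeeCageError("constant row: Pearson distance undefined")
        corr = np.corrcoef(data)
        return squareform(1.0 - corr, checks=False)
    raise BeeCageError(f"unknown metric {metric!r}")


def ward_cluster(matrix: pd.DataFrame, axis: str = "rows", metric: str = "euclidean") -> Dendrogram:
    """Ward (inner squared distance, minimum variance) linkage.

    ``axis='rows'`` clusters gene profiles, ``axis='columns'`` sample
    profiles.  ``metric`` is 'euclidean' or 'pearson' (distance = 1 - r);
    the Lance-Williams recurrence runs on the provided distances either
    way, the MATLAB-style 'ward' convention.
    """
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index)
    if axis in ("columns", "cols", "samples"):
        data = data.T
        labels = list(matrix.columns)
    elif axis not in ("rows", "genes"):
        raise BeeCageError(f"unknown axis {axis!r}")
    if data.shape[0] < 2:
        raise BeeCageError("need >= 2 items to cluster")
    Z = linkage(_distances(data, metric), method="ward")
    return Dendrogram(Z, [str(l) for l in labels])


def cophenetic_distances(dendrogram: Dendrogram) -> np.ndarray:
    """Condensed cophenetic distances: the merge height joining each pair."""
    return cophenet(dendrogram.linkage)


def cophenetic_cpcc(dendrogram: Dendrogram, observed_distances) -> float:
    """Cophenetic correlation coefficient.

    Pearson correlation between the condensed observed distances x_ij and
    the cophenetic distances d_ij (merge height of the lowest cluster
    containing both i and j): sum (x - xbar)(d - dbar) over the root of the
    two sums of squares.
    """
    x = np.asarray(observed_distances, dtype=float)
    if x.ndim == 2:
        x = squareform(x, checks=False)
    d = cophenetic_distances(dendrogram)
    if x.size != d.size:
        raise BeeCageError("distance matrix does not match the dendrogram items")
    if len(dendrogram.labels) < 3:
        raise BeeCageError("CPCC needs >= 3 items")
    xc = x - x.mean()
    dc = d - d.mean()
    return float((xc * dc).sum() / np.sqrt((xc**2).sum() * (dc**2).sum()))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def _kmeanspp_init(data: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = data.shape[0]
    centers = np.empty((k, data.shape[1]))
    centers[0] = data[rng.integers(n)]
    d2 = ((data - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[c] = data[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((data - centers[c]) ** 2).sum(axis=1))
    return centers


def kmeans(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts.

    Returns (labels, within-cluster sum of squares).  Deterministic for a
    fixed seed; the within-cluster SS is asserted non-increasing across
    Lloyd iterations.
    """
    data = np.asarray(matrix, dtype=float)
    n = data.shape[0]
    if k > n:
        raise BeeCageError("k must not exceed the number of items")
    rng = np.random.default_rng(seed)
    best_labels, best_ss = None, np.inf
    for _init in range(n_init):
        centers = _kmeanspp_init(data, k, rng)
        prev_ss = np.inf
        for _it in range(max_iter):
            d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            ss = float(d2[np.arange(n), labels].sum())
            assert ss <= prev_ss + 1e-9, "Lloyd iteration increased within-cluster SS"
            for c in range(k):
                members = data[labels == c]
                if len(members):
                    centers[c] = members.mean(axis=0)
                else:  # re-seed empty cluster at the worst-fit point
                    centers[c] = data[d2[np.arange(n), labels].argmax()]
            if prev_ss - ss < 1e-12:
                break
            prev_ss = ss
        if ss < best_ss:
            best_ss, best_labels = ss, labels.copy()
    return best_labels, best_ss


def bcv_top_genes(matrix: CountMatrix, group: str, top_n: int = 500) -> float:
    """Biological coefficient of variation over the most variable genes.

    Selects ``top_n`` genes by within-group variance of log2 CPM, estimates
    the common NB dispersion on that subset restricted to the group, and
    returns sqrt(phi).  Fewer genes than ``top_n`` uses all with a warning.
    """
    import logging

    from .diffexp import estimate_common_dispersion

    sub = _group_counts(matrix, group)
    libs = matrix.library_sizes.loc[sub.columns]
    logcpm = np.log2(sub * 1e6 / libs + 0.5)
    n = min(top_n, sub.shape[0])
    if n < top_n:
        logging.getLogger("beecage").warning(
            "only %d genes available for BCV (requested %d)", sub.shape[0], top_n
        )
    top = logcpm.var(axis=1, ddof=1).nlargest(n).index
    group_matrix = CountMatrix(
        sub.loc[top],
        matrix.groups.loc[sub.columns],
        libs,
    )
    phi = estimate_common_dispersion(group_matrix, effective_lib_sizes=libs)
    return float(np.sqrt(phi))
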