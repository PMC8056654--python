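"""Weighted co-expression network core, implemented from scratch.

Soft-threshold adjacency (unsigned, |cor|^beta), scale-free topology fit,
classic topological overlap, average-linkage clustering with a static
quantile height cut, SVD module eigengenes with deterministic sign
orientation, iterative eigengene-dissimilarity merging, and module
membership (kME).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyMatrix",
    "ModuleSet",
    "soft_adjacency",
    "scale_free_fit",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_membership",
    "select_core_genes",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric genes x genes weights in [0,1]; zero diagonal."""

    values: np.ndarray
    genes: pd.Index
    beta: float

    def connectivity(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned) plus derived summaries."""

    labels: pd.Series  # gene -> module id
    linkage: np.ndarray | None = None
    eigengenes: pd.DataFrame | None = None  # modules x profiles
    membership: pd.DataFrame | None = None  # genes x modules

    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids()}


def _row_correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows correlate 0 (warned)."""
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d constant-variance gene(s); their correlations are set to 0", flat.sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(flat, 1.0, sd * X.shape[1])
    Z = Xc / denom[:, None]
    corr = Z @ (Xc / np.where(flat, 1.0, sd)[:, None]).T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def soft_adjacency(matrix: pd.DataFrame, beta: float = 5.0) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency ``a_ij = |pearson(g_i, g_j)|^beta``."""
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    if matrix.shape[1] < 3:
        raise InsufficientDataError("need >= 3 profiles for co-expression")
    corr = _row_correlation(matrix.to_numpy(dtype=float))
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    adj = (adj + adj.T) / 2.0  # enforce exact symmetry against float noise
    return AdjacencyMatrix(adj, matrix.index, float(beta))


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of binned connectivity frequency on connectivity."""
    k = adjacency.connectivity()
    if np.allclose(k, k[0]):
        raise DegenerateInputError("all connectivities identical; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    total = k.size
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.sum() / total))
    if len(xs) < 2:
        raise InsufficientDataError("fewer than 2 occupied connectivity bins")
    slope, intercept, r, _, _ = stats.linregress(xs, ys)
    return float(r ** 2)


def topological_overlap(adjacency: AdjacencyMatrix) -> np.ndarray:
    """Classic unsigned TOM: shared-neighbor credit normalized by the smaller hub.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``, unit
    diagonal; the clustering dissimilarity is ``1 - TOM``.
    """
    A = adjacency.values
    k = adjacency.connectivity()
    shared = A @ A  # diagonal of A is 0, so u != i; the u = j term is a_ij * a_jj = 0
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return tom


def detect_modules(
    dissimilarity: np.ndarray,
    genes: pd.Index,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> ModuleSet:
    """Average-linkage clustering with a static cut at a merge-height quantile.

    Branches below the cut smaller than ``min_module_size`` are labelled 0
    (unassigned); surviving modules are numbered by decreasing size (ties by
    first gene position).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ParameterError("dissimilarity must be square and symmetric")
    n = D.shape[0]
    if n != len(genes):
        raise ParameterError("gene index length does not match the matrix")
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all unassigned", n)
        return ModuleSet(pd.Series(0, index=genes), linkage=None)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    return ModuleSet(pd.Series(labels, index=genes), linkage=Z)


def _relabel_by_size(raw: np.ndarray, min_module_size: int) -> np.ndarray:
    """0 for undersized branches; otherwise 1..M by decreasing size."""
    out = np.zeros(raw.size, dtype=int)
    clusters = []
    for c in np.unique(raw):
        members = np.where(raw == c)[0]
        if members.size >= min_module_size:
            clusters.append((members.size, members[0], c, members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new_id, (_, _, _, members) in enumerate(clusters, start=1):
        out[members] = new_id
    return out


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=1, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(X, dtype=float)
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return Z, ok


def module_eigengenes(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First right singular vector of each module's standardized submatrix.

    Eigengenes have unit norm and are sign-oriented so their correlation
    with the module's mean (standardized) profile is non-negative, which
    makes module membership reproducible.  Zero-variance genes are dropped
    from their module with a warning.
    """
    labels = labels.loc[matrix.index]
    mes = {}
    for module in sorted(m for m in labels.unique() if m != 0):
        sub = matrix.loc[labels[labels == module].index].to_numpy(dtype=float)
        Z, ok = _standardize_rows(sub)
        if not ok.all():
            logger.warning("module %s: dropped %d zero-variance gene(s)", module, (~ok).sum())
            Z = Z[ok]
        if Z.shape[0] < 2:
            raise InsufficientDataError(f"module {module} has fewer than 2 usable genes")
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        me = vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(me, mean_profile - mean_profile.mean()) < 0:
            me = -me
        mes[module] = me
    return pd.DataFrame(mes, index=matrix.columns).T


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return np.nan
    return float(np.dot(u - u.mean(), v - v.mean()) / (u.size * su * sv))


def merge_modules(
    matrix: pd.DataFrame,
    labels: pd.Series,
    dissim_threshold: float = 0.3,
) -> ModuleSet:
    """Iteratively merge the closest eigengene pair while below the threshold.

    Closeness is ``1 - pearson(ME_a, ME_b)``; eigengenes are recomputed
    after every merge, and final labels are renumbered by decreasing size.
    """
    labels = labels.copy()
    while True:
        ids = sorted(m for m in labels.unique() if m != 0)
        if len(ids) < 2:
            break
        mes = module_eigengenes(matrix, labels)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = 1.0 - _pearson(mes.loc[a].to_numpy(), mes.loc[b].to_numpy())
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best is None or best[0] >= dissim_threshold:
            break
        _, a, b = best
        labels[labels == b] = a
        logger.debug("merged module %s into %s (dissim %.4f)", b, a, best[0])

    relabeled = _relabel_by_size(labels.to_numpy(), min_module_size=1)
    # preserve 0 labels
    relabeled[labels.to_numpy() == 0] = 0
    out = pd.Series(relabeled, index=labels.index)
    mes = module_eigengenes(matrix, out) if (out != 0).any() else None
    return ModuleSet(out, eigengenes=mes)


def module_membership(matrix: pd.DataFrame, module_set: ModuleSet) -> pd.DataFrame:
    """kME: pearson correlation of each gene's profile with each module eigengene.

    Zero-variance genes get NaN membership (excluded, with a warning).
    """
    if module_set.eigengenes is None:
        raise ParameterError("module_set has no eigengenes; compute them first")
    X = matrix.to_numpy(dtype=float)
    Z, ok = _standardize_rows(X)
    if not ok.all():
        logger.warning("module_membership: %d zero-variance gene(s) -> NaN", (~ok).sum())
    n = X.shape[1]
    mm = {}
    for module in module_set.eigengenes.index:
        me = module_set.eigengenes.loc[module].to_numpy()
        me_z = (me - me.mean()) / me.std(ddof=1)
        vals = (Z @ me_z) / (n - 1)
        vals[~ok] = np.nan
        mm[module] = np.clip(vals, -1.0, 1.0)
    out = pd.DataFrame(mm, index=matrix.index)
    module_set.membership = out
    return out


def select_core_genes(membership: pd.DataFrame, module: int, mm_min: float = 0.95) -> list[str]:
    """Genes whose membership in ``module`` strictly exceeds ``mm_min``.

    Sorted by descending membership, ties by gene id.
    """
    if module not in membership.columns:
        raise ParameterError(f"module {module} not in membership matrix")
    col = membership[module].dropna()
    sel = col[col > mm_min]
    order = sorted(sel.index, key=lambda g: (-sel[g], g))
    return list(order)
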