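"""Group-contrast statistics for gene panels.

Permutation test of drug-group expression differences (left tail, shared
label permutations across genes), univariate logistic risk with rank AUC,
panel selection, and the significance--strength correlation.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    GroupingError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "permutation_test",
    "logistic_fit",
    "rank_auc",
    "gene_risk",
    "select_panel",
    "significance_strength_correlation",
]

_TIE_ATOL = 1e-12


def permutation_test(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided (left-tail) permutation test of per-gene group differences.

    Observed ``d = mean(A) - mean(B)`` per gene.  The null relabels the
    pooled drugs into sizes ``(|A|, |B|)``; one relabeling per iteration is
    shared by all genes, preserving the inter-gene correlation of the null.
    When ``C(|A|+|B|, |A|)`` <= ``n_perm`` the full enumeration replaces
    sampling.

    The p-value counts ties into the tail with the finite-sample +1
    correction: ``p = (#{d* <= d} + 1) / (m + 1)``, which is never 0 and is
    valid under the null; ``frac_less`` additionally reports the raw
    proportion strictly below the observed difference.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise GroupingError(f"groups overlap: {sorted(set_a & set_b)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise GroupingError("each group needs >= 2 members")
    missing = (set_a | set_b) - set(matrix.columns)
    if missing:
        raise GroupingError(f"group members absent from matrix columns: {sorted(missing)}")

    cols = list(group_a) + list(group_b)
    X = matrix[cols].to_numpy(dtype=float)
    n_a, n_b = len(group_a), len(group_b)
    n = n_a + n_b
    obs = X[:, :n_a].mean(axis=1) - X[:, n_a:].mean(axis=1)
    totals = X.sum(axis=1)

    n_exact = comb(n, n_a)
    exact = n_exact <= n_perm
    if exact:
        sel = np.zeros((n, n_exact), dtype=float)
        for j, idx in enumerate(combinations(range(n), n_a)):
            sel[list(idx), j] = 1.0
        m = n_exact
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n, n_perm), dtype=float)
        for j in range(n_perm):
            sel[rng.permutation(n)[:n_a], j] = 1.0
        m = n_perm

    sums_a = X @ sel  # genes x m
    null_d = sums_a / n_a - (totals[:, None] - sums_a) / n_b
    le = (null_d <= obs[:, None] + _TIE_ATOL).sum(axis=1)
    lt = (null_d < obs[:, None] - _TIE_ATOL).sum(axis=1)

    return pd.DataFrame(
        {
            "gene": matrix.index,
            "obs_diff": obs,
            "perm_p": (le + 1) / (m + 1),
            "frac_less": lt / m,
            "n_null": m,
            "exact": exact,
        }
    ).set_index("gene", drop=False).rename_axis(None)


def logistic_fit(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Univariate logistic regression by IRLS.

    Returns ``(beta0, beta1, converged)``.  Callers should screen for
    separation first; a diverging fit is reported as non-converged.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta[0], beta[1], False
        if not np.all(np.isfinite(new)) or np.abs(new).max() > 1e3:
            return new[0], new[1], False
        if np.abs(new - beta).max() < tol:
            return new[0], new[1], True
        beta = new
    return beta[0], beta[1], False


def rank_auc(x: np.ndarray, y: np.ndarray) -> float:
    """AUC as the midrank Mann--Whitney statistic of ``x`` against binary ``y``."""
    ranks = stats.rankdata(x)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC needs both classes present")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def gene_risk(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene univariate logistic odds ratio and rank AUC.

    ``labels`` maps profile id -> {0, 1}.  OR is per one unit of the gene's
    value.  Perfect separation (or a non-converging fit) flags the record
    and reports the +inf odds-ratio sentinel rather than a penalized fit.
    """
    labels = labels.loc[matrix.columns]
    y = labels.to_numpy(dtype=float)
    classes = set(np.unique(y))
    if not classes == {0.0, 1.0}:
        raise DegenerateInputError(f"labels must contain both classes 0 and 1, got {sorted(classes)}")
    rows = []
    for gene in matrix.index:
        x = matrix.loc[gene].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ParameterError(f"gene {gene}: non-finite expression values")
        auc = rank_auc(x, y)
        separated = x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()
        if separated:
            beta0, beta1, converged = np.nan, np.inf, False
            flagged = True
            or_ = np.inf
        else:
            beta0, beta1, converged = logistic_fit(x, y)
            flagged = not converged
            or_ = np.inf if flagged else float(np.exp(beta1))
        rows.append(dict(gene=gene, beta=beta1, odds_ratio=or_, auc=auc, flagged=flagged))
    return pd.DataFrame(rows).set_index("gene", drop=False).rename_axis(None)


def select_panel(records: pd.DataFrame, or_min: float = 6.0, auc_min: float = 0.7) -> list[str]:
    """Genes with ``OR > or_min`` AND ``AUC > auc_min``, by descending OR."""
    sel = records[(records["odds_ratio"] > or_min) & (records["auc"] > auc_min)]
    sel = sel.sort_values(["odds_ratio", "gene"], ascending=[False, True], kind="stable")
    return list(sel["gene"])


def significance_strength_correlation(
    perm: pd.DataFrame, risk: pd.DataFrame
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of -log10 permutation p vs odds ratio.

    Computed over shared genes; records with non-finite OR are dropped with
    a warning (the +inf separation sentinel carries no magnitude).
    """
    shared = perm.index.intersection(risk.index)
    sig = -np.log10(perm.loc[shared, "perm_p"].to_numpy(dtype=float))
    or_ = risk.loc[shared, "odds_ratio"].to_numpy(dtype=float)
    finite = np.isfinite(or_) & np.isfinite(sig)
    if (~finite).any():
        logger.warning("correlation: dropped %d gene(s) with non-finite values", (~finite).sum())
    sig, or_ = sig[finite], or_[finite]
    if sig.size < 3:
        raise InsufficientDataError("need >= 3 shared genes with finite values")
    if np.std(sig) == 0 or np.std(or_) == 0:
        raise DegenerateInputError("correlation undefined: one of the vectors is constant")
    r, p = stats.pearsonr(sig, or_)
    return float(r), float(p)
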