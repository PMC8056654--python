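"""Structural and physicochemical diversity of a drug set.

Pairwise Tanimoto similarity on binary fingerprints, and per-property
coefficient of variation on a numeric property table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["tanimoto_matrix", "property_cv"]

_MEAN_TOL = 1e-12


def tanimoto_matrix(fingerprints: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise Tanimoto ``|A&B| / |A|B|`` plus the mean over distinct pairs.

    ``fingerprints`` is a drugs x bits 0/1 frame.  The diagonal is 1; a pair
    of two all-zero vectors is undefined (NaN, excluded from the average
    with a warning).
    """
    if fingerprints.shape[0] < 2:
        raise InsufficientDataError("need >= 2 fingerprints")
    B = fingerprints.to_numpy(dtype=bool)
    zero = ~B.any(axis=1)
    if zero.any():
        logger.warning("tanimoto_matrix: %d all-zero fingerprint(s)", int(zero.sum()))
    inter = (B.astype(np.int64) @ B.astype(np.int64).T).astype(float)
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(union > 0, inter / np.maximum(union, 1e-300), np.nan)
    np.fill_diagonal(T, 1.0)
    n = T.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = T[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise DegenerateInputError("no defined fingerprint pair")
    avg = float(vals[finite].mean())
    return pd.DataFrame(T, index=fingerprints.index, columns=fingerprints.index), avg


def property_cv(table: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-property coefficient of variation (sample sd / |mean|) + average.

    Properties whose absolute mean is below tolerance are excluded from the
    average with a warning (their CV would be numerically meaningless).
    """
    if table.shape[0] < 2:
        raise InsufficientDataError("need >= 2 drugs")
    numeric = table.astype(float)
    means = numeric.mean(axis=0)
    sds = numeric.std(axis=0, ddof=1)
    cvs = {}
    excluded = []
    for prop in numeric.columns:
        if abs(means[prop]) <= _MEAN_TOL:
            excluded.append(prop)
            continue
        cvs[prop] = float(sds[prop] / abs(means[prop]))
    if excluded:
        logger.warning("property_cv: excluded near-zero-mean propert(ies) %s", excluded)
    if not cvs:
        raise DegenerateInputError("all properties excluded (near-zero means)")
    series = pd.Series(cvs)
    return series, float(series.mean())
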