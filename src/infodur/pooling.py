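"""Adaptive partial pooling of in-context and across-context estimates.

The closed-form hierarchical shrinkage estimator combines the in-context
estimate ``alpha_local`` (precision ``n_cx / var_within``) with the
across-context word average ``alpha_global`` (precision ``1 / var_between``):

    pooled = w * alpha_local + (1 - w) * alpha_global,
    w = (n_cx / var_within) / (n_cx / var_within + 1 / var_between)

The local estimate dominates when the context is frequent and words vary
little within it; the global average dominates when the context is rare or
words vary little overall.  This is the combiner only — full hierarchical
model fitting lives in :mod:`infodur.models`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corpus import BigramStats
from .io import CONTEXT_COL, WORD_COL

log = logging.getLogger("infodur")


def partial_pool(alpha_local, alpha_global, n_cx, var_within, var_between):
    """Precision-weighted combination of local and global estimates.

    All arguments may be scalars or broadcastable arrays.

    Parameters
    ----------
    alpha_local
        Estimate from the current context.
    alpha_global
        Across-context word average.
    n_cx
        Context frequency (number of observations backing the local
        estimate); ``n_cx = 0`` returns the global estimate.
    var_within
        Variance of the characteristic across words within the context,
        >= 0.  Zero with ``n_cx > 0`` means infinite local precision and
        returns the local estimate (logged).
    var_between
        Variance of word averages across words, > 0.

    Returns
    -------
    float or numpy.ndarray
        The pooled estimate, always inside ``[min, max]`` of the two inputs.
    """
    alpha_local = np.asarray(alpha_local, dtype=float)
    alpha_global = np.asarray(alpha_global, dtype=float)
    n_cx = np.asarray(n_cx, dtype=float)
    var_within = np.asarray(var_within, dtype=float)
    var_between = np.asarray(var_between, dtype=float)

    if np.any(var_between <= 0):
        raise ValueError("var_between must be > 0")
    if np.any(var_within < 0):
        raise ValueError("var_within must be >= 0")
    if np.any(n_cx < 0):
        raise ValueError("n_cx must be >= 0")

    degenerate = (var_within == 0) & (n_cx > 0)
    if np.any(degenerate):
        log.info(
            "partial_pool: %d case(s) with var_within=0 and n_cx>0; "
            "returning the local estimate (infinite local precision)",
            int(np.count_nonzero(degenerate)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_local = np.where(var_within > 0, n_cx / np.where(var_within > 0, var_within, 1.0), np.inf)
        prec_local = np.where(n_cx == 0, 0.0, prec_local)
        w = prec_local / (prec_local + 1.0 / var_between)
    w = np.where(np.isinf(prec_local), 1.0, w)
    pooled = w * alpha_local + (1.0 - w) * alpha_global
    if pooled.ndim == 0:
        return float(pooled)
    return pooled


def pool_predictability(stats: BigramStats) -> pd.DataFrame:
    """Shrunken predictability for every observed (context, word) pair.

    Applies :func:`partial_pool` on the log-probability scale with
    ``alpha_local`` the pair's predictability, ``alpha_global`` the word's
    token-weighted mean predictability (= minus its informativity),
    ``var_within`` the variance of predictability across word types within
    the pair's context, and ``var_between`` the variance of the word
    averages across word types.

    Returns the ``stats.pairs`` table with ``alpha_global``, ``var_within``
    and ``pooled_predictability`` columns added.
    """
    pairs = stats.pairs.copy()
    word_mean = stats.words.set_index(WORD_COL)["informativity"].mul(-1.0)
    pairs["alpha_global"] = pairs[WORD_COL].map(word_mean).astype(float)

    var_within = pairs.groupby(CONTEXT_COL, sort=False)["predictability"].transform(
        lambda s: float(np.var(s.to_numpy()))
    )
    pairs["var_within"] = var_within
    var_between = float(np.var(word_mean.to_numpy()))
    if var_between <= 0:
        raise ValueError(
            "variance of word-average predictability is zero; "
            "partial pooling is undefined on this corpus"
        )
    pairs["pooled_predictability"] = partial_pool(
        pairs["predictability"].to_numpy(),
        pairs["alpha_global"].to_numpy(),
        pairs["n_cx"].to_numpy(),
        pairs["var_within"].to_numpy(),
        var_between,
    )
    return pairs
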