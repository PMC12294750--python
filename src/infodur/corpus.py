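"""Bigram information statistics: conditional probabilities, predictability,
informativity and context frequency.

Definitions (all logs natural unless a base-2 flag is passed):

* conditional probability ``p(w|cx) = n(w, cx) / n_cx`` — unsmoothed
  maximum-likelihood relative frequency.  No add-k, no back-off: the whole
  point of the downstream diagnostic is the raw estimator's sampling noise,
  so smoothing here would contaminate it.
* predictability ``log p(w|cx)`` ≤ 0 — forward bigram surprisal with the
  sign flipped.
* informativity ``I(w) = -(1/n_w) Σ_tokens log p(w|cx)`` ≥ 0 — the
  token-weighted mean surprisal of the word over its occurrences.  With
  token weighting, a word seen in exactly one context type has
  ``I(w) = -predictability`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTEXT_COL, WORD_COL

_LOG_BASES = {"e": 1.0, "2": float(np.log(2.0))}


@dataclass
class BigramStats:
    """Frequency and information statistics of a token table.

    Attributes
    ----------
    pairs : pandas.DataFrame
        One row per observed (context, word) pair: ``context``, ``word``,
        ``count`` n(w,cx), ``n_cx``, ``p`` = p(w|cx), ``predictability``.
    words : pandas.DataFrame
        One row per word type: ``word``, ``n_w``, ``informativity``.
    contexts : pandas.DataFrame
        One row per context type: ``context``, ``n_cx``.
    log_base : str
        "e" (nats) or "2" (bits).
    """

    pairs: pd.DataFrame
    words: pd.DataFrame
    contexts: pd.DataFrame
    log_base: str = "e"

    @property
    def n_tokens(self) -> int:
        return int(self.pairs["count"].sum())

    def validate(self) -> None:
        """Check the defining identities (normalization, marginals, signs)."""
        g = self.pairs.groupby("context", sort=False)
        psums = g["p"].sum()
        if not np.allclose(psums.to_numpy(), 1.0, atol=1e-12, rtol=0):
            raise AssertionError("conditional probabilities do not normalize per context")
        ncx = g["count"].sum()
        ref = self.contexts.set_index("context")["n_cx"]
        if not ncx.sort_index().equals(ref.sort_index().astype(ncx.dtype)):
            raise AssertionError("context marginals inconsistent with pair counts")
        nw = self.pairs.groupby("word", sort=False)["count"].sum()
        refw = self.words.set_index("word")["n_w"]
        if not nw.sort_index().equals(refw.sort_index().astype(nw.dtype)):
            raise AssertionError("word marginals inconsistent with pair counts")
        if (self.pairs["predictability"] > 1e-12).any():
            raise AssertionError("positive predictability")
        if (self.words["informativity"] < -1e-12).any():
            raise AssertionError("negative informativity")


def compute_bigram_stats(tokens: pd.DataFrame, log_base: str = "e") -> BigramStats:
    """Estimate :class:`BigramStats` from a token table by relative frequency.

    Parameters
    ----------
    tokens : pandas.DataFrame
        Token table with ``word`` and ``context`` columns (one row per token).
    log_base : {"e", "2"}
        Base of the logs in predictability/informativity.

    Raises
    ------
    ValueError
        If the table is empty.
    """
    if len(tokens) == 0:
        raise ValueError("cannot estimate bigram statistics from an empty token table")
    if log_base not in _LOG_BASES:
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    scale = _LOG_BASES[log_base]

    counts = (
        tokens.groupby([CONTEXT_COL, WORD_COL], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    n_cx = counts.groupby(CONTEXT_COL, sort=False)["count"].transform("sum")
    counts["n_cx"] = n_cx
    counts["p"] = counts["count"] / counts["n_cx"]
    counts["predictability"] = np.log(counts["p"].to_numpy()) / scale
    # guard against -0.0 for p == 1 pairs
    counts.loc[counts["p"] == 1.0, "predictability"] = 0.0

    n_w = counts.groupby(WORD_COL, sort=False)["count"].transform("sum")
    surprisal_mass = -counts["predictability"] * counts["count"]
    words = pd.DataFrame(
        {
            WORD_COL: counts[WORD_COL],
            "n_w": n_w,
            "_mass": surprisal_mass,
        }
    )
    words = words.groupby(WORD_COL, sort=True).agg(n_w=("n_w", "first"), _mass=("_mass", "sum"))
    words["informativity"] = words["_mass"] / words["n_w"]
    words = words.drop(columns="_mass").reset_index()

    contexts = (
        counts.groupby(CONTEXT_COL, sort=True)["count"].sum().rename("n_cx").reset_index()
    )
    return BigramStats(pairs=counts, words=words, contexts=contexts, log_base=log_base)


def attach_predictors(tokens: pd.DataFrame, stats: BigramStats) -> pd.DataFrame:
    """Attach per-token regressors from ``stats`` to a token table.

    Adds ``predictability`` (of the token's pair), ``informativity`` (of the
    token's word) and ``context_freq`` (n_cx of its context).

    Raises
    ------
    KeyError
        If a token's (context, word) pair was never observed in ``stats``.
    """
    pair_cols = stats.pairs[[CONTEXT_COL, WORD_COL, "predictability", "n_cx"]]
    merged = tokens.merge(pair_cols, on=[CONTEXT_COL, WORD_COL], how="left")
    missing = merged["predictability"].isna()
    if missing.any():
        i = int(np.flatnonzero(missing.to_numpy())[0])
        pair = (merged[CONTEXT_COL].iloc[i], merged[WORD_COL].iloc[i])
        raise KeyError(f"(context, word) pair {pair} not present in BigramStats")
    merged = merged.merge(stats.words[[WORD_COL, "informativity"]], on=WORD_COL, how="left")
    merged = merged.rename(columns={"n_cx": "context_freq"})
    merged.index = tokens.index
    merged.index.name = tokens.index.name
    return merged
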