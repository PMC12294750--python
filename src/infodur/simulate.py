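"""Parametric-bootstrap null simulator.

The diagnostic's engine: generate many datasets in which log durations are
driven by *true* predictability only (the generating model has no
informativity effect and no interactions), while the analysis model sees
predictability and informativity *re-estimated from each resampled sample*.
Any informativity effect the analysis then finds is, by construction, an
artifact of sampling noise in the conditional-probability estimates.

One replicate:

1. For every observed (context, word) pair, draw a count
   ``k ~ Binomial(n_cx, p(w|cx))`` — each token of the context is a biased
   coin toss.  Context frequencies are held at their observed values.
   Draws are independent across pairs, so within a context the sample
   probabilities ``k / n_cx`` need not sum to one (a multinomial variant is
   available behind ``scheme="multinomial"``).
2. Pairs with ``k >= 1`` contribute ``k`` tokens; sample predictability is
   ``log(k / n_cx)`` and sample informativity is recomputed from the
   replicate's own tokens.
3. Each token's log duration is drawn from
   ``Normal(b0 + b_pred * pred_true + b_info * info_true + word_effect,
   sigma_resid)`` — always from the TRUE (source-corpus) statistics, never
   the sample estimates.
4. The analysis model is refit and its coefficient table recorded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import BigramStats, compute_bigram_stats
from .io import CONTEXT_COL, WORD_COL, derive_seed
from .models import DurationModel, ModelSpec

log = logging.getLogger("infodur")


@dataclass
class GeneratingModel:
    """Ground truth of the simulation.

    Parameters
    ----------
    b0 : float
        Intercept, log seconds.
    b_pred : float
        True predictability coefficient (per nat).
    sigma_resid : float
        Residual SD of log duration (0 only in degenerate noiseless checks).
    b_info : float
        True informativity coefficient; 0 defines the null regime.
    word_effects : dict or None
        Word random intercepts (log seconds).  ``None`` with
        ``sigma_word > 0`` means "draw once per corpus/experiment".
    sigma_word : float
        SD for drawing word effects when no map is given.
    """

    b0: float
    b_pred: float
    sigma_resid: float
    b_info: float = 0.0
    word_effects: dict[str, float] | None = None
    sigma_word: float = 0.0

    def __post_init__(self) -> None:
        # 0 is allowed for the degenerate noiseless case (exact-recovery checks)
        if self.sigma_resid < 0:
            raise ValueError("sigma_resid must be >= 0")
        if self.sigma_word < 0:
            raise ValueError("sigma_word must be >= 0")

    def materialize_word_effects(self, words, rng: np.random.Generator) -> "GeneratingModel":
        """Return a copy whose ``word_effects`` is an explicit map for ``words``."""
        if self.word_effects is not None:
            return self
        if self.sigma_word > 0:
            draws = rng.normal(0.0, self.sigma_word, size=len(words))
        else:
            draws = np.zeros(len(words))
        return replace(self, word_effects=dict(zip(list(words), draws.tolist())))


def calibrate_generating_model(data: pd.DataFrame, use_random_intercept: bool = False) -> GeneratingModel:
    """Calibrate the generating model from real (or synthetic) data.

    Fits ``duration_log ~ predictability`` — deliberately *without*
    informativity, so the predictability coefficient absorbs the full
    bivariate relationship — optionally with a per-word random intercept.
    The generating model takes that fit's intercept and slope, its predicted
    word effects (mixed fits), and the SD of its residuals as the noise SD.
    """
    spec = ModelSpec(
        fixed_terms=["predictability"],
        random_intercept=use_random_intercept,
        estimator="mixed" if use_random_intercept else "ols",
    )
    res = DurationModel(data, spec).fit()
    if not res.converged:
        raise RuntimeError("calibration fit did not converge")
    word_effects = None
    sigma_word = 0.0
    if use_random_intercept and res.random_effects is not None:
        word_effects = {w: float(v) for w, v in res.random_effects.iloc[:, 0].items()}
        sigma_word = float(np.sqrt(max(res.var_word, 0.0)))
    return GeneratingModel(
        b0=float(res.params["Intercept"]),
        b_pred=float(res.params["predictability"]),
        sigma_resid=res.sigma_resid,
        b_info=0.0,
        word_effects=word_effects,
        sigma_word=sigma_word,
    )


def resample_pair_counts(stats: BigramStats, rng: np.random.Generator,
                         scheme: str = "binomial") -> pd.DataFrame:
    """Draw resampled counts ``k(w, cx)`` for every observed pair.

    ``scheme="binomial"`` draws each pair independently,
    ``k ~ Binomial(n_cx, p(w|cx))``; ``scheme="multinomial"`` draws each
    context's vector jointly so counts sum to ``n_cx``.
    """
    pairs = stats.pairs.copy()
    if scheme == "binomial":
        pairs["k"] = rng.binomial(pairs["n_cx"].to_numpy(), pairs["p"].to_numpy())
    elif scheme == "multinomial":
        k = np.empty(len(pairs), dtype=np.int64)
        for _, idx in pairs.groupby(CONTEXT_COL, sort=False).indices.items():
            p = pairs["p"].to_numpy()[idx]
            n = int(pairs["n_cx"].to_numpy()[idx][0])
            k[idx] = rng.multinomial(n, p / p.sum())
        pairs["k"] = k
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    return pairs


def _expand_tokens(pairs_k: pd.DataFrame, stats: BigramStats) -> pd.DataFrame:
    """Token-level replicate table from pair counts (pairs with k=0 drop out)."""
    keep = pairs_k[pairs_k["k"] > 0]
    reps = keep["k"].to_numpy()
    idx = np.repeat(np.arange(len(keep)), reps)
    rep = pd.DataFrame(
        {
            WORD_COL: keep[WORD_COL].to_numpy()[idx],
            CONTEXT_COL: keep[CONTEXT_COL].to_numpy()[idx],
            "k": reps[idx],
            "context_freq": keep["n_cx"].to_numpy()[idx],
            "pred_true": keep["predictability"].to_numpy()[idx],
        }
    )
    info = stats.words.set_index(WORD_COL)["informativity"]
    rep["info_true"] = rep[WORD_COL].map(info).to_numpy()
    return rep


def estimate_sample_predictors(replicate: pd.DataFrame) -> pd.DataFrame:
    """Re-estimate predictability and informativity from the replicate itself.

    Requires columns ``word``, ``k`` (the replicate count of the token's
    pair) and ``context_freq`` (the number of binomial trials).  Adds
    ``sample_predictability = log(k / context_freq)`` and
    ``sample_informativity`` = token-weighted mean sample surprisal of each
    word over the replicate's tokens.  Words with zero tokens are simply
    absent from the replicate (their informativity is undefined).
    """
    rep = replicate.copy()
    rep["sample_predictability"] = np.log(rep["k"].to_numpy() / rep["context_freq"].to_numpy())
    rep.loc[rep["k"] == rep["context_freq"], "sample_predictability"] = 0.0
    rep["sample_informativity"] = rep.groupby(WORD_COL, sort=False)[
        "sample_predictability"
    ].transform("mean").mul(-1.0)
    return rep


def simulate_durations(replicate: pd.DataFrame, gen: GeneratingModel,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw simulated log durations from the generating model.

    The mean uses the TRUE statistics carried by the replicate
    (``pred_true``, ``info_true``), never the sample re-estimates.
    """
    rep = replicate.copy()
    if gen.word_effects is not None:
        eff = rep[WORD_COL].map(gen.word_effects)
        if eff.isna().any():
            missing = rep.loc[eff.isna(), WORD_COL].iloc[0]
            raise KeyError(f"no stored word effect for word {missing!r}")
        eff = eff.to_numpy(dtype=float)
    else:
        eff = 0.0
    mu = (
        gen.b0
        + gen.b_pred * rep["pred_true"].to_numpy()
        + gen.b_info * rep["info_true"].to_numpy()
        + eff
    )
    rep["duration_log"] = mu + rng.normal(0.0, gen.sigma_resid, size=len(rep))
    return rep


class NullSimSummary:
    """Per-replicate coefficient tables from a null experiment.

    Attributes
    ----------
    results : pandas.DataFrame
        Long table with columns ``replicate``, ``term``, ``estimate``,
        ``se``, ``p``, ``converged``.
    meta : dict
        Provenance: generating model, analysis spec, n_reps, master_seed,
        predictor source, resampling scheme, convergence-failure count.
    """

    def __init__(self, results: pd.DataFrame, meta: dict):
        self.results = results
        self.meta = meta

    @property
    def n_reps(self) -> int:
        return int(self.meta["n_reps"])

    @property
    def n_failed(self) -> int:
        return int(self.meta["n_failed"])

    def converged_mask(self) -> pd.Series:
        per_rep = self.results.groupby("replicate")["converged"].first()
        return per_rep

    def term_frame(self, term: str) -> pd.DataFrame:
        """Converged replicates' rows for one term."""
        sub = self.results[(self.results["term"] == term) & self.results["converged"]]
        if sub.empty and term not in set(self.results["term"]):
            raise KeyError(f"term {term!r} not present in the analysis model")
        return sub

    def estimates(self, term: str) -> np.ndarray:
        return self.term_frame(term)["estimate"].to_numpy()

    def pvalues(self, term: str) -> np.ndarray:
        return self.term_frame(term)["p"].to_numpy()

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)

    def meta_json(self) -> str:
        def default(o):
            if isinstance(o, GeneratingModel):
                d = o.__dict__.copy()
                if d.get("word_effects") is not None:
                    d["word_effects"] = f"<map of {len(d['word_effects'])} words>"
                return d
            if isinstance(o, ModelSpec):
                return o.__dict__
            return str(o)

        return json.dumps(self.meta, default=default, indent=2)


def run_null_experiment(
    tokens: pd.DataFrame,
    gen: GeneratingModel,
    analysis_spec: ModelSpec,
    n_reps: int,
    master_seed: int,
    predictor_source: str = "sample",
    scheme: str = "binomial",
    freeze_informativity: bool = False,
    stats: BigramStats | None = None,
) -> NullSimSummary:
    """Run the full null experiment.

    Parameters
    ----------
    tokens : pandas.DataFrame
        Source token table (``word``, ``context``); its bigram statistics
        define both the resampling probabilities and the TRUE predictors.
    gen : GeneratingModel
        Ground truth for duration generation (``b_info=0`` for the null).
    analysis_spec : ModelSpec
        The model fit to every replicate (terms named ``predictability``,
        ``informativity``, ``context_freq`` and their interactions).
    n_reps, master_seed
        Replicate count and the root seed; replicate ``i`` uses
        :func:`infodur.derive_seed` ``(master_seed, i)``, so reruns are
        bit-identical.
    predictor_source : {"sample", "true"}
        Whether the analysis sees sample-re-estimated predictors (the
        realistic, noisy case) or the generating truth (the calibration
        benchmark).
    freeze_informativity : bool
        With ``predictor_source="sample"``, keep informativity frozen at its
        source-corpus value while predictability is re-estimated.

    Returns
    -------
    NullSimSummary
        Every converged replicate's coefficient table; replicates whose fit
        fails (rank deficiency or non-convergence) are flagged, counted and
        excluded from diagnostics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if predictor_source not in ("sample", "true"):
        raise ValueError(f"predictor_source must be 'sample' or 'true', got {predictor_source!r}")
    if stats is None:
        stats = compute_bigram_stats(tokens)

    gen = gen.materialize_word_effects(
        stats.words[WORD_COL].tolist(),
        np.random.default_rng(derive_seed(master_seed, n_reps)),  # off-replicate stream
    ) if (gen.word_effects is None and gen.sigma_word > 0) else gen

    rows: list[dict] = []
    n_failed = 0
    n_dropped_words = 0
    for i in range(n_reps):
        rng = np.random.default_rng(derive_seed(master_seed, i))
        pairs_k = resample_pair_counts(stats, rng, scheme=scheme)
        rep = _expand_tokens(pairs_k, stats)
        n_dropped_words += stats.words.shape[0] - rep[WORD_COL].nunique()
        if predictor_source == "sample":
            rep = estimate_sample_predictors(rep)
            rep["predictability"] = rep["sample_predictability"]
            rep["informativity"] = (
                rep["info_true"] if freeze_informativity else rep["sample_informativity"]
            )
        else:
            rep["predictability"] = rep["pred_true"]
            rep["informativity"] = rep["info_true"]
        rep = simulate_durations(rep, gen, rng)

        try:
            res = DurationModel(rep, analysis_spec).fit()
            ok = res.converged
        except ValueError as exc:  # rank-deficient replicate design
            log.debug("replicate %d fit failed: %s", i, exc)
            ok = False
            res = None
        if not ok:
            n_failed += 1
        for term in analysis_spec.term_names:
            rows.append(
                {
                    "replicate": i,
                    "term": term,
                    "estimate": float(res.params[term]) if ok else np.nan,
                    "se": float(res.bse[term]) if ok else np.nan,
                    "p": float(res.pvalues[term]) if ok else np.nan,
                    "converged": ok,
                }
            )
    if n_failed == n_reps:
        raise RuntimeError("all replicates failed to converge")

    meta = {
        "gen": gen,
        "analysis_spec": analysis_spec,
        "n_reps": n_reps,
        "master_seed": master_seed,
        "predictor_source": predictor_source,
        "scheme": scheme,
        "freeze_informativity": freeze_informativity,
        "n_failed": n_failed,
        "mean_words_absent_per_replicate": n_dropped_words / n_reps,
    }
    return NullSimSummary(pd.DataFrame(rows), meta)
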