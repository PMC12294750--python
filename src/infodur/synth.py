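"""Synthetic Zipfian bigram corpora with known ground truth.

Natural corpora have two distributional properties the diagnostic's
behaviour hinges on: context (preceding-word) frequencies are approximately
Zipfian with exponent near 1 — so a large share of contexts occur exactly
once — and within each context the conditional word distribution is itself
highly skewed and context-specific.  The generator reproduces exactly these
two properties and nothing else (no real lexicon, no phonetics):

* context marginal: ``p(cx) ∝ rank^-zipf_exponent`` over the context
  inventory;
* per-context conditionals: Zipf-shaped with exponent
  ``conditional_sharpness`` over a context-specific random permutation of
  the word inventory (a symmetric-Dirichlet alternative is available);
* tokens drawn i.i.d. from the joint, durations generated exactly as the
  null simulator does, from TRUE conditional probabilities:
  ``Normal(b0 + b_pred*pred + b_info*info + word_effect, sigma_resid)``.

The latent truth (conditional probabilities, per-word informativity, word
effects) is returned alongside the observable token table so every other
module is testable against known ground truth with no external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXT_COL, WORD_COL, derive_seed
from .simulate import GeneratingModel

log = logging.getLogger("infodur")


def _default_gen() -> GeneratingModel:
    # magnitudes in the range observed for log-second word durations:
    # intercept ~ -2 (≈0.1 s words), predictability slope -0.08 per nat,
    # word SD 0.15, residual SD 0.35
    return GeneratingModel(b0=-2.0, b_pred=-0.08, sigma_resid=0.35,
                           b_info=0.0, sigma_word=0.15)


@dataclass
class SynthConfig:
    """Configuration of the synthetic corpus.

    Defaults give a small conversational-corpus-like sample: 2,000 tokens
    over 500 context types and a word inventory (2,000 types) large relative
    to the sample, which reproduces the distributional regime of real
    word-duration datasets — over half the observed word types and roughly
    40% of contexts occur exactly once, and estimated predictability and
    informativity correlate around -0.9 — the regime where
    conditional-probability estimates are noisiest.
    """

    n_context_types: int = 500
    n_word_types: int = 2000
    zipf_exponent: float = 1.0
    n_tokens: int = 2000
    conditional_sharpness: float = 1.5
    conditional_family: str = "zipf"  # or "dirichlet"
    gen: GeneratingModel = field(default_factory=_default_gen)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_context_types", "n_word_types", "n_tokens"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.zipf_exponent <= 0 or self.conditional_sharpness <= 0:
            raise ValueError("zipf_exponent and conditional_sharpness must be > 0")
        if self.conditional_family not in ("zipf", "dirichlet"):
            raise ValueError(f"unknown conditional_family {self.conditional_family!r}")
        if self.n_tokens < self.n_context_types:
            log.warning("n_tokens < n_context_types: many contexts will be unobserved")


@dataclass
class SynthTruth:
    """Latent ground truth behind a generated corpus."""

    cond_probs: pd.DataFrame        # contexts x words, true p(w|cx)
    context_probs: pd.Series        # true p(cx)
    word_probs: pd.Series           # true marginal p(w)
    informativity: pd.Series        # true I(w) from latent probabilities
    word_effects: pd.Series         # the drawn random intercepts
    pred_true: pd.Series            # per generated token, log p(w|cx)
    gen: GeneratingModel


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** s
    return w / w.sum()


def generate_corpus(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Generate a token table with durations plus its latent truth.

    Returns
    -------
    tokens : pandas.DataFrame
        Columns ``word``, ``context``, ``duration_log``; index ``token_id``.
    truth : SynthTruth
    """
    rng = np.random.default_rng(derive_seed(config.seed, 0))
    n_cx, n_w = config.n_context_types, config.n_word_types
    contexts = np.array([f"c{i:04d}" for i in range(n_cx)])
    words = np.array([f"w{i:04d}" for i in range(n_w)])

    p_cx = _zipf_weights(n_cx, config.zipf_exponent)

    cond = np.empty((n_cx, n_w))
    if config.conditional_family == "zipf":
        base = _zipf_weights(n_w, config.conditional_sharpness)
        for c in range(n_cx):
            perm = rng.permutation(n_w)
            cond[c, perm] = base
    else:
        cond[:] = rng.dirichlet(np.full(n_w, config.conditional_sharpness), size=n_cx)

    p_w = p_cx @ cond  # true marginal over words
    # true informativity: expected surprisal of w over its context distribution,
    # I(w) = -sum_cx P(cx|w) log p(w|cx) with P(cx|w) = p(cx) p(w|cx) / p(w)
    logc = np.log(cond)
    informativity = -np.einsum("c,cw,cw->w", p_cx, cond, logc) / p_w

    gen = config.gen.materialize_word_effects(words.tolist(), rng)
    effects = np.array([gen.word_effects[w] for w in words])

    ci = rng.choice(n_cx, size=config.n_tokens, p=p_cx)
    wi = np.empty(config.n_tokens, dtype=np.int64)
    for c in np.unique(ci):
        mask = ci == c
        wi[mask] = rng.choice(n_w, size=int(mask.sum()), p=cond[c])

    pred_true = logc[ci, wi]
    mu = gen.b0 + gen.b_pred * pred_true + gen.b_info * informativity[wi] + effects[wi]
    duration_log = mu + rng.normal(0.0, gen.sigma_resid, size=config.n_tokens)

    tokens = pd.DataFrame(
        {WORD_COL: words[wi], CONTEXT_COL: contexts[ci], "duration_log": duration_log}
    )
    tokens.index.name = "token_id"

    truth = SynthTruth(
        cond_probs=pd.DataFrame(cond, index=contexts, columns=words),
        context_probs=pd.Series(p_cx, index=contexts, name="p_cx"),
        word_probs=pd.Series(p_w, index=words, name="p_w"),
        informativity=pd.Series(informativity, index=words, name="informativity_true"),
        word_effects=pd.Series(effects, index=words, name="word_effect"),
        pred_true=pd.Series(pred_true, index=tokens.index, name="pred_true"),
        gen=gen,
    )
    return tokens, truth


def write_truth_sidecar(truth: SynthTruth, path) -> None:
    """Write the per-word latent truth as CSV (kept separate from tokens)."""
    df = pd.DataFrame(
        {
            "word": truth.informativity.index,
            "p_w": truth.word_probs.to_numpy(),
            "informativity_true": truth.informativity.to_numpy(),
            "word_effect": truth.word_effects.to_numpy(),
        }
    )
    df.to_csv(path, index=False)
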