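# Methods

This note documents the statistical machinery implemented in `infodur`:
the information statistics, the regression models, the null-simulation
procedure, the synthetic-corpus generator, and the numerical and design
choices behind them.

## Information statistics (`infodur.corpus`)

Given a token table (one row per word token with its preceding-word
context), conditional probabilities are unsmoothed maximum-likelihood
relative frequencies, p̂(w|cx) = n(w,cx)/n_cx. No add-k and no back-off:
the diagnostic's subject matter is the sampling noise of exactly this raw
estimator, and smoothing would partially pool by stealth and contaminate
it.

- Predictability of a token: log p̂(w|cx) ≤ 0 (natural log by default; a
  base-2 flag rescales every coefficient by 1/ln 2 and changes nothing
  else).
- Informativity of a word: the token-weighted mean surprisal over the
  word's occurrences, I(w) = −(1/n_w) Σ_tokens log p̂(w|cx). Token
  weighting (rather than weighting context types equally) is chosen
  because it makes the single-context identity exact: a word observed in
  only one context type has I(w) = −predictability, the boundary case that
  drives the collinearity between the two predictors. The averaging scheme
  is a genuine degree of freedom in the literature's verbal definitions;
  the type-weighted alternative would differ only for words with skewed
  context distributions.

## Partial pooling (`infodur.pooling`)

The closed-form shrinkage combiner weighs the in-context estimate by its
precision n_cx/σ²_cx against the across-context word average with
precision 1/σ²_w. It is provided both as a scalar/vector function and as a
per-pair "shrunken predictability" table where σ²_cx is the variance of
predictability across word types within the context and σ²_w the variance
of word-average predictability across word types. Degenerate cases follow
the precision logic: n_cx = 0 returns the across-context average; σ²_cx = 0
with n_cx > 0 means infinite local precision and returns the local
estimate (logged, since for singleton contexts this is an artifact of a
one-point variance). Pooling operates on whatever scale it is given (here
log probability); the module does not decide that question.

## Duration models (`infodur.models`)

The analysis models are Gaussian linear models of log duration (log
seconds) with fixed effects drawn from {predictability, informativity,
context frequency, the two interactions with context frequency} and,
optionally, a per-word random intercept (and a random predictability
slope, only identifiable when some word recurs). OLS fits use statsmodels
OLS; mixed fits use statsmodels MixedLM with REML by default (matching the
mixed-modeling convention in this literature). Predictors enter raw:
uncentered, unscaled, context frequency in counts, since the downstream
diagnostics compare coefficients across refits of identically-constructed
designs.

Numerical choices:

- Rank-deficient designs raise with the offending terms named (QR
  diagnostic). Inside simulation loops this surfaces as a counted,
  excluded replicate rather than an exception — replicates in which, e.g.,
  every surviving word is a singleton make informativity exactly collinear
  with predictability.
- Mixed-model degrees of freedom use the residual-df approximation,
  recorded as `df_method="residual"` in every result. At the sample sizes
  the package targets (thousands of tokens) t-test p-values are
  insensitive to the df approximation; a Satterthwaite-style correction
  would matter only for small-group designs outside this package's scope.
- Non-convergence never silently returns estimates: the results object
  carries `converged=False` with NaN estimates, and downstream summaries
  exclude and count such replicates.
- A boundary variance estimate (word variance → 0, singular random-effect
  covariance) degenerates the predicted word effects to zero, with a
  logged warning, rather than failing the fit.
- R² family: adjusted R² from the fixed-effects fitted values; for mixed
  models, marginal R² = var(Xβ̂)/(var(Xβ̂)+σ̂²_word+σ̂²_resid) and conditional
  R² adds the random-intercept variance to the numerator (for random
  slopes the random variance is the observation-averaged zᵢ'Ĝzᵢ).
- The mixed path is validated against lme4 (REML, same fixture) in the
  test suite to 4 decimals on coefficients and variance components; lme4
  serves only as an independent oracle, never as the implementation.

## The null simulator (`infodur.simulate`)

The generating model is the simulation's ground truth: duration_log ~
Normal(b0 + b_pred·pred_true + b_info·info_true + u_word, sigma_resid),
with b_info = 0 defining the null regime and no interaction terms ever
generated (the true predictability effect is constant across contexts, so
any interaction the analysis finds is itself diagnostic). Calibration fits
duration ~ predictability — deliberately omitting informativity so the
predictability coefficient absorbs the full bivariate relationship — and
takes the residual SD of that fit as the noise SD; a mixed calibration
additionally yields predicted per-word intercepts, which are reused
deterministically across replicates (word effects are stable word
properties, not fresh noise).

One replicate:

1. For every observed (context, word) pair, k ~ Binomial(n_cx, p̂(w|cx)),
   independently across pairs — each token of the context is a biased coin
   toss. Context frequencies are held at their observed values. Because
   draws are independent, sample probabilities within a context need not
   sum to 1; k/n_cx uses the number of trials as denominator. A
   multinomial per-context variant (counts sum to n_cx) is available
   behind `scheme="multinomial"`.
2. Pairs with k ≥ 1 contribute k tokens; words with no surviving tokens
   drop out of the replicate (their informativity is undefined), and the
   average number of dropped words is reported in the summary metadata.
3. Sample predictability is log(k/n_cx); sample informativity is
   recomputed from the replicate's own tokens. A flag
   (`freeze_informativity`) instead keeps informativity at its
   source-corpus value while predictability is re-estimated — a
   substantially more liberal variant (the false-alarm rates it produces
   are an order of magnitude higher, because the stable informativity
   column is then a clean proxy for the part of true predictability that
   sampling noise removed from the estimated column). Recomputation is the
   primary setting as the stricter and more internally consistent reading
   of "estimate everything from the sample".
4. Durations are drawn from the generating model using TRUE (source)
   statistics — never the sample re-estimates — and the analysis model is
   refit on the replicate.

Per-replicate seeds derive from the master seed via SeedSequence spawn
keys, so experiments are bit-identical under rerun and replicates are
pairable across experiment arms: two sweeps run with the same master seed
share their resampling and noise streams (common random numbers), which is
how the test suite sharpens ordering comparisons between effect sizes.

"Significant in the expected direction" is operationalised as two-sided
p < α AND the coefficient sign matching the expected direction, making the
nominal directional rate α/2 (2.5% at the usual α).

## Diagnostics (`infodur.diagnostics`)

All rates are over converged replicates, with the failure count carried in
metadata. The mean spurious effect defaults to the mean over all converged
replicates, with the significant-only variant reported alongside (the two
coincide when the false-alarm rate saturates). Monte-Carlo p-values are
plain exceedance fractions with the "< 1/n" convention at zero
exceedances; the conservative (k+1)/(n+1) estimator is available by flag.
Conditional probabilities on empty conditioning sets are returned as
undefined (None), never 0.

## Synthetic corpora (`infodur.synth`)

The generator reproduces the two distributional properties the diagnostic's
behaviour hinges on, and nothing else:

- Context (preceding-word) frequencies follow a Zipf marginal with
  exponent ~1, so a large share of context types occur once or a handful
  of times — the regime where conditional-probability estimates are
  noisiest.
- Per-context conditional word distributions are themselves Zipf-shaped
  (exponent `conditional_sharpness`) over a context-specific random
  permutation of the word inventory, giving context-dependent
  predictability; a symmetric-Dirichlet alternative is available.

Defaults — 2,000 tokens, 500 context types, 2,000 word types, context
exponent 1.0, conditional sharpness 1.5, b0 = −2 log-seconds,
b_pred = −0.08 per nat, word-intercept SD 0.15, residual SD 0.35 — were
chosen so the observable corpus matches the distributional fingerprint of
real conversational duration datasets: r(predictability, informativity)
≈ −0.9, over half the observed word types singletons, roughly 40% of
contexts observed once, durations centred near 0.15 s. Tokens are i.i.d.
draws from the joint; durations are generated exactly as in the null
simulator from TRUE conditional probabilities, and the latent truth
(conditional probabilities, true informativity
I(w) = −Σ_cx P(cx|w) log p(w|cx), word effects) is returned in a separate
structure so observable and truth data cannot be confused.

What the generator does **not** emulate: a real lexicon or phonetics,
speech-rate and prosodic covariates, utterance structure (tokens are
exchangeable), and — importantly — the asymmetry of real duration studies
in which bigram statistics come from a far larger corpus than the analysed
tokens, so that analysed tokens are often low-probability continuations of
very frequent contexts. That asymmetry substantially amplifies the
noise-driven informativity artifact in real datasets; on the self-contained
synthetic corpus the artifact is present and directionally identical
(directional false-alarm rates above nominal, positive mean spurious
coefficient growing with |b_pred|, spurious main effects co-occurring with
negative context-frequency interactions) but much smaller in magnitude.
Passing tests therefore demonstrate the mechanism and the machinery, not
the effect sizes to be expected on any particular real dataset — for
those, run the pipeline on the dataset itself.

## Problem sizes

The shipped experiments use the 2,000-token default corpus with 1,000
replicates for the calibration benchmark (true predictors; the
informativity test then holds its nominal level exactly, since the
analysis regressors are the generating ones and the t-test is exact under
Gaussian noise) and 400-replicate paired sweeps for the sample-predictor
false-alarm analyses. A 50,000-token corpus is used for parameter
recovery. These sizes put Monte-Carlo error well inside the decision
margins of every check while keeping any single experiment in the
tens-of-seconds range.

## Known limitations

- Satterthwaite df are not implemented (see above); `df_method` records
  the approximation used.
- The mixed random-slope model is fit but its R² partition treats the
  random variance via the observation-averaged quadratic form, which is
  one of several conventions.
- Informativity is token-weighted; a type-weighted variant is not
  implemented.
- The simulator treats corpus probabilities as the probabilities driving
  behaviour; mismatch between corpus and speaker experience (a real
  concern for rare words) is out of scope and would add noise the
  diagnostic does not model.
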