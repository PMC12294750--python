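"""Decision quantities computed from null-simulation summaries.

Everything here reduces a :class:`~infodur.simulate.NullSimSummary` — the
per-replicate coefficient tables of a null experiment — to the numbers one
actually decides with: directional false-alarm rates, mean spurious
coefficients, Monte-Carlo p-values for an observed coefficient, and
co-occurrence probabilities between a spurious main effect and its
context-frequency interaction.

All rates are computed over *converged* replicates only; the convergence
failure count travels in the summary's metadata.  "Significant in the
expected direction" means two-sided p < alpha AND the coefficient's sign
matches the expected sign, so the nominal directional rate is alpha/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec
from .simulate import GeneratingModel, NullSimSummary, run_null_experiment
from .io import derive_seed


@dataclass
class FalseAlarmResult:
    rate: float          # P(p < alpha and sign as expected)
    sign_prop: float     # P(sign as expected), unconditional on significance
    n_converged: int
    n_significant: int   # directional count behind `rate`


def _term_arrays(summary: NullSimSummary, term: str) -> tuple[np.ndarray, np.ndarray]:
    sub = summary.term_frame(term)
    if len(sub) == 0:
        raise ValueError("zero converged replicates")
    return sub["estimate"].to_numpy(), sub["p"].to_numpy()


def false_alarm_rate(summary: NullSimSummary, term: str, expected_sign: int,
                     alpha: float = 0.05) -> FalseAlarmResult:
    """Directional false-alarm rate of ``term`` across converged replicates.

    A false alarm is a replicate with two-sided ``p < alpha`` whose
    coefficient sign equals ``expected_sign`` (+1 or -1).  Also reports the
    unconditional proportion of replicates with the expected sign.
    """
    if expected_sign not in (1, -1):
        raise ValueError("expected_sign must be +1 or -1")
    est, p = _term_arrays(summary, term)
    hit = (p < alpha) & (np.sign(est) == expected_sign)
    return FalseAlarmResult(
        rate=float(hit.mean()),
        sign_prop=float((np.sign(est) == expected_sign).mean()),
        n_converged=len(est),
        n_significant=int(hit.sum()),
    )


def spurious_effect_mean(summary: NullSimSummary, term: str,
                         significant_only: bool = False, alpha: float = 0.05,
                         expected_sign: int | None = None) -> float:
    """Mean coefficient of ``term`` over converged replicates.

    By default the mean runs over ALL converged replicates; with
    ``significant_only`` it is restricted to directional false alarms
    (requires ``expected_sign``).
    """
    est, p = _term_arrays(summary, term)
    if significant_only:
        if expected_sign is None:
            raise ValueError("significant_only requires expected_sign")
        mask = (p < alpha) & (np.sign(est) == expected_sign)
        if not mask.any():
            return float("nan")
        est = est[mask]
    return float(est.mean())


def mc_pvalue(summary: NullSimSummary, term: str, observed: float,
              direction: str = ">=", conservative: bool = False) -> float | str:
    """Monte-Carlo p-value of an observed coefficient against the null draws.

    The fraction of converged null estimates at least as extreme as
    ``observed`` in the stated direction (``">="`` or ``"<="``).  With zero
    exceedances the bound string ``"< 1/n"`` is returned; ``conservative``
    switches to the (k+1)/(n+1) estimator, which never returns a bound.
    """
    if not np.isfinite(observed):
        raise ValueError("observed coefficient must be finite")
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    est, _ = _term_arrays(summary, term)
    k = int((est >= observed).sum() if direction == ">=" else (est <= observed).sum())
    n = len(est)
    if conservative:
        return float((k + 1) / (n + 1))
    if k == 0:
        return f"< {1.0 / n:g}"
    return float(k / n)


@dataclass
class DirectionConditionals:
    p_fa_main: float                    # P(directional false alarm on main term)
    p_inter_dir_given_fa: float | None  # P(interaction in expected dir | FA on main)
    p_main_dir_given_fa_inter: float | None  # P(main in expected dir | FA on interaction)
    n_fa_main: int
    n_fa_inter: int


def direction_conditionals(summary: NullSimSummary, main_term: str, interaction_term: str,
                           alpha: float = 0.05, main_sign: int = 1,
                           interaction_sign: int = -1) -> DirectionConditionals:
    """Co-occurrence of a spurious main effect with its interaction.

    Returns the directional false-alarm probability of ``main_term``, the
    probability the interaction has its expected sign *given* a main-term
    false alarm, and the probability the main term has its expected sign
    given a directional false alarm on the interaction.  Conditioning events
    with zero members yield ``None`` (undefined), never 0.
    """
    main = summary.term_frame(main_term).set_index("replicate")
    inter = summary.term_frame(interaction_term).set_index("replicate")
    common = main.index.intersection(inter.index)
    main, inter = main.loc[common], inter.loc[common]
    if len(common) == 0:
        raise ValueError("zero converged replicates")

    fa_main = (main["p"] < alpha) & (np.sign(main["estimate"]) == main_sign)
    fa_inter = (inter["p"] < alpha) & (np.sign(inter["estimate"]) == interaction_sign)

    p_fa_main = float(fa_main.mean())
    if fa_main.any():
        p_inter_dir = float((np.sign(inter.loc[fa_main, "estimate"]) == interaction_sign).mean())
    else:
        p_inter_dir = None
    if fa_inter.any():
        p_main_dir = float((np.sign(main.loc[fa_inter, "estimate"]) == main_sign).mean())
    else:
        p_main_dir = None
    return DirectionConditionals(
        p_fa_main=p_fa_main,
        p_inter_dir_given_fa=p_inter_dir,
        p_main_dir_given_fa_inter=p_main_dir,
        n_fa_main=int(fa_main.sum()),
        n_fa_inter=int(fa_inter.sum()),
    )


def sweep_table(
    tokens: pd.DataFrame,
    base_gen: GeneratingModel,
    grid: Sequence[tuple[float, float]],
    analysis_specs: dict[str, ModelSpec] | Iterable[tuple[str, ModelSpec]],
    n_reps: int,
    master_seed: int,
    predictor_source: str = "sample",
    alpha: float = 0.05,
    expected_sign: int = 1,
    term: str = "informativity",
) -> pd.DataFrame:
    """Grid of null experiments over generating settings × analysis models.

    Parameters
    ----------
    grid : sequence of (b_pred, b_info)
        Generating coefficients; other generating-model fields come from
        ``base_gen`` (typically a calibration fit).
    analysis_specs : mapping label -> ModelSpec

    Returns
    -------
    pandas.DataFrame
        One row per cell with the directional false-alarm rate, mean
        spurious effect (over all converged replicates and over the
        significant ones), sign proportion and failure count.  Fully
        reproducible from ``master_seed`` (each cell gets a derived seed).
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    specs = dict(analysis_specs)
    rows = []
    cell = 0
    for b_pred, b_info in grid:
        gen = GeneratingModel(
            b0=base_gen.b0,
            b_pred=b_pred,
            sigma_resid=base_gen.sigma_resid,
            b_info=b_info,
            word_effects=base_gen.word_effects,
            sigma_word=base_gen.sigma_word,
        )
        for label, spec in specs.items():
            summary = run_null_experiment(
                tokens, gen, spec, n_reps,
                master_seed=derive_seed(master_seed, cell),
                predictor_source=predictor_source,
            )
            fa = false_alarm_rate(summary, term, expected_sign, alpha)
            rows.append(
                {
                    "b_pred": b_pred,
                    "b_info": b_info,
                    "model": label,
                    "fa_rate": fa.rate,
                    "sign_prop": fa.sign_prop,
                    "mean_effect": spurious_effect_mean(summary, term),
                    "mean_effect_significant": spurious_effect_mean(
                        summary, term, significant_only=True,
                        alpha=alpha, expected_sign=expected_sign,
                    ),
                    "n_converged": fa.n_converged,
                    "n_failed": summary.n_failed,
                }
            )
            cell += 1
    return pd.DataFrame(rows)


def plot_null_distribution(summary: NullSimSummary, term: str,
                           observed: float | None = None, ax=None):
    """Histogram of a term's null coefficients, with the observed value marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    est = summary.estimates(term)
    ax.hist(est, bins=40, color="0.7", edgecolor="0.4")
    if observed is not None:
        ax.axvline(observed, color="k", linestyle="--", label=f"observed = {observed:g}")
        ax.legend()
    ax.set_xlabel(f"{term} coefficient under the null")
    ax.set_ylabel("replicates")
    return ax
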