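"""Duration regression models.

The analysis models are linear regressions of log word duration on
information-theoretic predictors:

    duration_log ~ predictability + informativity
                   [ + context_freq + interactions ] [ + (1|word) ]

fit either by ordinary least squares or as a Gaussian mixed model with a
random intercept (optionally a random predictability slope) per word type.
The statsmodels-style surface is :class:`DurationModel` (construct from a
DataFrame or an lme4-flavoured formula) whose :meth:`DurationModel.fit`
returns a :class:`DurationResults` with the coefficient table, variance
components, the R-squared family and a ``summary()``.

Degrees of freedom for mixed-model t tests use the residual-df
approximation, recorded in ``df_method``; at the sample sizes this package
targets (thousands of tokens) the df choice does not move p-values.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger("infodur")

INTERCEPT = "Intercept"


@dataclass
class ModelSpec:
    """Specification of a duration regression.

    Parameters
    ----------
    fixed_terms : list of str
        Ordered fixed-effect terms.  ``"Intercept"`` is implicit and always
        included first; interactions are written ``"a:b"`` and require both
        parents.
    random_intercept : bool
        Include a per-word random intercept (mixed model).
    random_slope : str or None
        Column name getting a per-word random slope (mixed model); requires
        at least one word with two or more tokens.
    estimator : {"ols", "mixed"}
    reml : bool
        REML (default, matching the lme4 default) vs. ML for mixed fits.
    group : str
        Grouping column for random effects.
    """

    fixed_terms: list[str] = field(default_factory=lambda: ["predictability", "informativity"])
    random_intercept: bool = False
    random_slope: str | None = None
    estimator: str = "ols"
    reml: bool = True
    group: str = "word"

    def __post_init__(self) -> None:
        self.fixed_terms = [t for t in self.fixed_terms if t != INTERCEPT]
        if self.estimator not in ("ols", "mixed"):
            raise ValueError(f"estimator must be 'ols' or 'mixed', got {self.estimator!r}")
        if self.estimator == "ols" and (self.random_intercept or self.random_slope):
            raise ValueError("random terms require estimator='mixed'")
        if self.random_slope and not self.random_intercept:
            raise ValueError("a random slope requires the random intercept")
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(f"interaction {t!r} requires both parents as main effects")

    @property
    def term_names(self) -> list[str]:
        return [INTERCEPT] + list(self.fixed_terms)


_RANDOM_RE = re.compile(r"\(\s*([^|]+?)\s*\|\s*(\w+)\s*\)")


def parse_formula(formula: str) -> tuple[str, ModelSpec]:
    """Parse an lme4-flavoured formula into (response, :class:`ModelSpec`).

    Supports ``+``, ``:``, ``*`` (with one level of parentheses on the left
    factor) and random terms ``(1|word)`` / ``(1 + predictability|word)``.
    """
    if "~" not in formula:
        raise ValueError(f"formula needs '~': {formula!r}")
    lhs, rhs = (s.strip() for s in formula.split("~", 1))

    random_intercept = False
    random_slope: str | None = None
    group = "word"

    def grab_random(m: re.Match) -> str:
        nonlocal random_intercept, random_slope, group
        inner, group = m.group(1), m.group(2)
        parts = [p.strip() for p in inner.split("+")]
        for p in parts:
            if p in ("1", ""):
                random_intercept = True
            elif p == "0":
                pass
            else:
                random_intercept = True
                random_slope = p
        return ""

    rhs = _RANDOM_RE.sub(grab_random, rhs)

    terms: list[str] = []

    def add(t: str) -> None:
        if t and t != "1" and t not in terms:
            terms.append(t)

    for chunk in (c.strip() for c in _split_top(rhs)):
        if not chunk:
            continue
        if "*" in chunk:
            left, right = (s.strip() for s in chunk.split("*", 1))
            lefts = [s.strip() for s in left.strip("() ").split("+")]
            rights = [s.strip() for s in right.strip("() ").split("+")]
            for a in lefts:
                add(a)
            for b in rights:
                add(b)
            for a in lefts:
                for b in rights:
                    add(f"{a}:{b}")
        else:
            add(chunk)

    estimator = "mixed" if random_intercept else "ols"
    spec = ModelSpec(
        fixed_terms=terms,
        random_intercept=random_intercept,
        random_slope=random_slope,
        estimator=estimator,
        group=group,
    )
    return lhs, spec


def _split_top(expr: str) -> list[str]:
    """Split on '+' outside parentheses."""
    out, depth, cur = [], 0, []
    for ch in expr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "+" and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def _design_matrix(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X[INTERCEPT] = 1.0
    for term in spec.fixed_terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
        else:
            if term not in data.columns:
                raise KeyError(f"model term {term!r} not found in data")
            X[term] = data[term].to_numpy(dtype=float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite values in the design matrix")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pinpoint offending columns via the R diagonal of a pivoted QR
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(f"rank-deficient design; collinear term(s): {bad or list(X.columns)}")


class DurationModel:
    """Linear (mixed) model of log word duration.

    Parameters
    ----------
    data : pandas.DataFrame
        Token table carrying the response and every regressor named in the
        spec (typically the output of :func:`infodur.attach_predictors`).
    spec : ModelSpec
    response : str
        Response column, default ``duration_log``.

    Examples
    --------
    >>> model = DurationModel.from_formula(
    ...     "duration_log ~ predictability + informativity + (1|word)", data)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, response: str = "duration_log"):
        if response not in data.columns:
            raise KeyError(f"response column {response!r} not in data")
        n_min = len(spec.fixed_terms) + 3  # p fixed terms + intercept + 2
        if len(data) < n_min:
            raise ValueError(f"need at least {n_min} rows for {len(spec.fixed_terms) + 1} fixed terms")
        if spec.random_slope is not None:
            sizes = data.groupby(spec.group).size()
            if sizes.max() < 2:
                raise ValueError(
                    "random slope requested but every group has a single "
                    "observation; the slope variance is unidentifiable"
                )
        self.data = data
        self.spec = spec
        self.response = response
        self.endog = data[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("non-finite response values")
        self.exog = _design_matrix(data, spec)
        _check_rank(self.exog)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "DurationModel":
        response, spec = parse_formula(formula)
        return cls(data, spec, response=response)

    def fit(self, reml: bool | None = None, fix_var_word: float | None = None) -> "DurationResults":
        """Fit the model.

        Parameters
        ----------
        reml : bool, optional
            Override the spec's REML flag (mixed fits only).
        fix_var_word : float, optional
            Only ``0.0`` is supported: constrain the word-intercept variance
            to zero, which degenerates the mixed model to OLS (useful as a
            consistency check).
        """
        spec = self.spec
        if fix_var_word is not None:
            if fix_var_word != 0.0:
                raise NotImplementedError("only fix_var_word=0.0 is supported")
            return self._fit_ols(forced_mixed_zero=spec.estimator == "mixed")
        if spec.estimator == "ols":
            return self._fit_ols()
        return self._fit_mixed(reml=spec.reml if reml is None else reml)

    # -- estimators ---------------------------------------------------------

    def _fit_ols(self, forced_mixed_zero: bool = False) -> "DurationResults":
        res = sm.OLS(self.endog, self.exog).fit()
        n, p = self.exog.shape
        df_resid = float(n - p)
        params = pd.Series(res.params, index=self.exog.columns)
        bse = pd.Series(res.bse, index=self.exog.columns)
        tvals = params / bse
        pvals = pd.Series(2 * sps.t.sf(np.abs(tvals), df_resid), index=self.exog.columns)
        var_resid = float(res.ssr / df_resid)
        fitted = res.fittedvalues
        return DurationResults(
            model=self,
            params=params,
            bse=bse,
            tvalues=tvals,
            df=pd.Series(df_resid, index=self.exog.columns),
            pvalues=pvals,
            var_word=0.0,
            var_resid=var_resid,
            resid=self.endog - fitted,
            fitted_fixed=np.asarray(fitted, dtype=float),
            random_effects=None,
            converged=True,
            df_method="residual",
            estimator="mixed(var_word=0)" if forced_mixed_zero else "ols",
        )

    def _fit_mixed(self, reml: bool) -> "DurationResults":
        groups = self.data[self.spec.group].to_numpy()
        if self.spec.random_slope is not None:
            exog_re = pd.DataFrame(
                {
                    INTERCEPT: np.ones(len(self.data)),
                    self.spec.random_slope: self.data[self.spec.random_slope].to_numpy(float),
                },
                index=self.data.index,
            )
        else:
            exog_re = pd.DataFrame({INTERCEPT: np.ones(len(self.data))}, index=self.data.index)

        model = sm.MixedLM(self.endog, self.exog, groups=groups, exog_re=exog_re)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                try:
                    res = model.fit(reml=reml)
                except (np.linalg.LinAlgError, ValueError):
                    res = model.fit(reml=reml, method="powell")
                converged = bool(getattr(res, "converged", True))
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("mixed fit failed: %s", exc)
                return self._failed_result(str(exc))
        if not converged:
            log.warning("mixed fit did not converge")

        k = self.exog.shape[1]
        params = pd.Series(np.asarray(res.params)[:k], index=self.exog.columns)
        bse = pd.Series(np.asarray(res.bse)[:k], index=self.exog.columns)
        tvals = params / bse
        n = len(self.endog)
        df_resid = float(n - k)
        pvals = pd.Series(2 * sps.t.sf(np.abs(tvals), df_resid), index=self.exog.columns)

        var_word = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
        fitted_fixed = self.exog.to_numpy() @ params.to_numpy()

        try:
            re_dict = res.random_effects
        except (np.linalg.LinAlgError, ValueError):
            # variance component on the boundary (cov_re singular): the BLUPs
            # degenerate to zero
            log.warning("singular random-effect covariance; predicted effects set to 0")
            zeros = np.zeros(exog_re.shape[1])
            re_dict = {g: pd.Series(zeros, index=exog_re.columns) for g in pd.unique(groups)}
        ranef = pd.DataFrame(re_dict).T
        ranef.index.name = self.spec.group
        # conditional residuals: y - X b - Z u
        zu = np.zeros(n)
        re_cols = list(exog_re.columns)
        re_map = {g: np.asarray(v, dtype=float) for g, v in re_dict.items()}
        zmat = exog_re.to_numpy()
        for i, g in enumerate(groups):
            zu[i] = zmat[i] @ re_map[g]
        resid = self.endog - fitted_fixed - zu

        return DurationResults(
            model=self,
            params=params,
            bse=bse,
            tvalues=tvals,
            df=pd.Series(df_resid, index=self.exog.columns),
            pvalues=pvals,
            var_word=var_word,
            var_resid=var_resid,
            resid=resid,
            fitted_fixed=fitted_fixed,
            random_effects=ranef,
            converged=converged,
            df_method="residual",
            estimator="mixed",
            cov_re=np.asarray(res.cov_re, dtype=float),
            exog_re=exog_re.to_numpy(),
        )

    def _failed_result(self, message: str) -> "DurationResults":
        cols = self.exog.columns
        nan = pd.Series(np.nan, index=cols)
        return DurationResults(
            model=self,
            params=nan,
            bse=nan.copy(),
            tvalues=nan.copy(),
            df=nan.copy(),
            pvalues=nan.copy(),
            var_word=np.nan,
            var_resid=np.nan,
            resid=np.full(len(self.endog), np.nan),
            fitted_fixed=np.full(len(self.endog), np.nan),
            random_effects=None,
            converged=False,
            df_method="residual",
            estimator="mixed",
            failure=message,
        )


class DurationResults:
    """Fit results: coefficient table, variance components, R² family.

    Attributes
    ----------
    params, bse, tvalues, df, pvalues : pandas.Series indexed by term.
    var_word : float
        Word random-intercept variance (0 for OLS).
    var_resid : float
        Residual variance.
    converged : bool
        False flags a failed mixed optimisation; estimates are NaN and the
        result must be excluded downstream.
    r2, r2_adjusted, r2_marginal, r2_conditional : float
        Marginal/conditional R² follow the variance-partition definition for
        mixed models (fixed vs. fixed+random over total); for OLS they equal
        the plain R².
    """

    def __init__(self, model, params, bse, tvalues, df, pvalues, var_word, var_resid,
                 resid, fitted_fixed, random_effects, converged, df_method, estimator,
                 failure: str | None = None, cov_re=None, exog_re=None):
        self.model = model
        self.params = params
        self.bse = bse
        self.tvalues = tvalues
        self.df = df
        self.pvalues = pvalues
        self.var_word = var_word
        self.var_resid = var_resid
        self.resid = resid
        self.fitted_fixed = fitted_fixed
        self.random_effects = random_effects
        self.converged = converged
        self.df_method = df_method
        self.estimator = estimator
        self.failure = failure
        self._cov_re = cov_re
        self._exog_re = exog_re
        self.nobs = len(model.endog)
        self._compute_r2()

    # -- fit statistics -----------------------------------------------------

    def _compute_r2(self) -> None:
        if not self.converged:
            self.r2 = self.r2_adjusted = np.nan
            self.r2_marginal = self.r2_conditional = np.nan
            return
        y = self.model.endog
        n = self.nobs
        p = len(self.params) - 1  # predictors excluding intercept
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum((y - self.fitted_fixed) ** 2))
        self.r2 = 1.0 - sse / sst if sst > 0 else 1.0
        if n - p - 1 <= 0:
            raise ValueError("adjusted R^2 undefined: n <= p + 1")
        self.r2_adjusted = 1.0 - (1.0 - self.r2) * (n - 1) / (n - p - 1)
        if sse == 0.0:
            self.r2 = self.r2_adjusted = 1.0

        var_fixed = float(np.var(self.fitted_fixed))
        var_random = self.var_word if np.isfinite(self.var_word) else 0.0
        if self._cov_re is not None and self._exog_re is not None and self._cov_re.shape[0] > 1:
            # average Z_i' G Z_i over observations (random slope contribution)
            var_random = float(np.mean(np.einsum("ij,jk,ik->i", self._exog_re, self._cov_re, self._exog_re)))
        total = var_fixed + var_random + self.var_resid
        if self.estimator.startswith("mixed"):
            self.r2_marginal = var_fixed / total
            self.r2_conditional = (var_fixed + var_random) / total
        else:
            self.r2_marginal = self.r2
            self.r2_conditional = self.r2

    def fit_stats(self) -> tuple[float, float, float]:
        """(adjusted R², marginal R², conditional R²)."""
        if not self.converged:
            raise ValueError("fit did not converge; statistics unavailable")
        return self.r2_adjusted, self.r2_marginal, self.r2_conditional

    @property
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
            }
        )

    @property
    def sigma_resid(self) -> float:
        """Empirical SD of the (conditional) residuals."""
        return float(np.std(self.resid))

    def summary(self) -> str:
        lines = [
            f"Duration model ({self.estimator}, df method: {self.df_method})",
            f"n = {self.nobs}, converged = {self.converged}",
            "",
            self.coef_table.to_string(float_format=lambda v: f"{v: .5g}"),
            "",
            f"var(word) = {self.var_word:.5g}   var(resid) = {self.var_resid:.5g}",
            f"R2 = {self.r2:.4f}  adj. R2 = {self.r2_adjusted:.4f}  "
            f"marginal R2 = {self.r2_marginal:.4f}  conditional R2 = {self.r2_conditional:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "converged": self.converged,
            "df_method": self.df_method,
            "n": int(self.nobs),
            "coefficients": {
                t: {
                    "estimate": float(self.params[t]),
                    "se": float(self.bse[t]),
                    "t": float(self.tvalues[t]),
                    "df": float(self.df[t]),
                    "p": float(self.pvalues[t]),
                }
                for t in self.params.index
            },
            "var_word": float(self.var_word),
            "var_resid": float(self.var_resid),
            "r2_adjusted": float(self.r2_adjusted),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
        }


def fit_duration_model(data: pd.DataFrame, spec: ModelSpec,
                       response: str = "duration_log") -> DurationResults:
    """Functional wrapper: build a :class:`DurationModel` and fit it."""
    return DurationModel(data, spec, response=response).fit()


def compare_nested(full: DurationResults, reduced: DurationResults) -> float:
    """Adjusted-R² drop from removing terms, in percentage points.

    ``full`` and ``reduced`` must be fits of nested specs on the same rows.
    Returns ``100 * (adjR²_full − adjR²_reduced)``.
    """
    if full.nobs != reduced.nobs:
        raise ValueError("nested comparison requires the same data rows")
    full_terms = set(full.params.index)
    red_terms = set(reduced.params.index)
    if not red_terms < full_terms:
        raise ValueError("reduced model terms must be a strict subset of the full model's")
    return 100.0 * (full.r2_adjusted - reduced.r2_adjusted)
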