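"""Correlation screening and stepwise OLS prediction equations for SID.

Digestibility assays are slow and expensive; the practical goal of this
module is an equation that predicts the standardized ileal digestibility
of a nutrient from routinely assayed composition variables (fiber
fractions, glucosinolates, processing temperature, ...).  The workflow is

1. :func:`pearson_matrix` — Pearson r with two-sided p-values over all
   candidate variables and responses;
2. :func:`stepwise_select` — classical forward/backward stepwise OLS with
   entry/removal thresholds (defaults 0.05 / 0.10);
3. :func:`predict_from_model` — apply a fitted equation to a new
   composition.

Reported metrics follow the feed-evaluation literature: R-squared,
adjusted R-squared, the residual standard error ``sqrt(SSE / (n - p - 1))``
(often printed as "RSD" in digestibility papers) and the overall F-test
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionModel",
    "pearson_matrix",
    "ols_fit",
    "wls_fit",
    "stepwise_select",
    "predict_from_model",
    "StepwiseLinearRegression",
]


@dataclass
class RegressionModel:
    """A fitted linear prediction equation with its reporting metrics.

    ``rsd`` is the residual standard error in response units,
    ``p_value`` the p-value of the regression F-test (NaN for an
    intercept-only model).
    """

    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    rsd: float
    p_value: float
    n: int
    stderrs: dict[str, float] = field(default_factory=dict)

    def conf_int(self, predictor: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for one coefficient."""
        df = self.n - len(self.predictors) - 1
        half = stats.t.ppf(0.5 + level / 2.0, df) * self.stderrs[predictor]
        coef = self.coefficients[predictor]
        return coef - half, coef + half

    def predict(self, composition: Mapping[str, float]) -> float:
        return predict_from_model(self, composition)

    def equation(self, decimals: int = 3) -> str:
        """Human-readable equation, e.g. ``SID_Lys = 100.107 - 1.229*NDF``."""
        parts = [f"{self.intercept:.{decimals}f}"]
        for name in self.predictors:
            coef = self.coefficients[name]
            sign = "-" if coef < 0 else "+"
            parts.append(f" {sign} {abs(coef):.{decimals}f}*{name}")
        return f"{self.response} = " + "".join(parts)


def pearson_matrix(variables: pd.DataFrame | Mapping[str, Sequence[float]]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Returns ``(r, p)`` as symmetric DataFrames; the diagonal of ``r`` is
    exactly 1 with p = 0.  A zero-variance variable yields NaN in every
    off-diagonal cell involving it (flagged, not raised).  Requires at
    least 3 observations.
    """
    df = pd.DataFrame(variables)
    if len(df) < 3:
        raise ValueError("need at least 3 observations per pair")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    sds = df.std(ddof=1)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if sds[a] == 0 or sds[b] == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def _as_xy(x, y) -> tuple[pd.DataFrame, np.ndarray]:
    x = pd.DataFrame(x)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same number of rows")
    return x, y


def ols_fit(x, y, response: str = "y") -> RegressionModel:
    """Ordinary least squares of ``y`` on the columns of ``x``.

    ``x`` may be empty (intercept-only model).  Raises on rank-deficient
    design matrices, naming the collinear columns.
    """
    x, y = _as_xy(x, y)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient predictor matrix; collinear columns among: "
            + ", ".join(map(str, x.columns))
        )
    fit = sm.OLS(y, design).fit()
    sse = float(fit.ssr)
    rsd = np.sqrt(sse / (n - p - 1))
    return RegressionModel(
        response=response,
        predictors=tuple(map(str, x.columns)),
        intercept=float(fit.params[0]),
        coefficients={str(c): float(b)
                      for c, b in zip(x.columns, fit.params[1:])},
        r2=float(fit.rsquared) if p else 0.0,
        adj_r2=float(fit.rsquared_adj) if p else 0.0,
        rsd=float(rsd),
        p_value=float(fit.f_pvalue) if p else float("nan"),
        n=n,
        stderrs={str(c): float(se)
                 for c, se in zip(x.columns, fit.bse[1:])},
    )


def wls_fit(x, y, weights, response: str = "y") -> RegressionModel:
    """Weighted least squares with the same reporting surface as
    :func:`ols_fit`.

    ``weights`` are inverse-variance weights.  ``r2`` / ``rsd`` are
    reported on the weighted scale.
    """
    x, y = _as_xy(x, y)
    w = np.asarray(weights, dtype=float)
    if w.shape != y.shape or (w <= 0).any():
        raise ValueError("weights must be positive and match y in length")
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    fit = sm.WLS(y, design, weights=w).fit()
    rsd = np.sqrt(float(fit.ssr) / (n - p - 1))
    return RegressionModel(
        response=response,
        predictors=tuple(map(str, x.columns)),
        intercept=float(fit.params[0]),
        coefficients={str(c): float(b)
                      for c, b in zip(x.columns, fit.params[1:])},
        r2=float(fit.rsquared) if p else 0.0,
        adj_r2=float(fit.rsquared_adj) if p else 0.0,
        rsd=float(rsd),
        p_value=float(fit.f_pvalue) if p else float("nan"),
        n=n,
        stderrs={str(c): float(se)
                 for c, se in zip(x.columns, fit.bse[1:])},
    )


def _coef_pvalues(x: pd.DataFrame, y: np.ndarray) -> pd.Series:
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return pd.Series(fit.pvalues[1:], index=x.columns)


def stepwise_select(candidates, y, p_enter: float = 0.05,
                    p_remove: float = 0.10, response: str = "y"
                    ) -> RegressionModel:
    """Forward/backward stepwise OLS on partial-F p-values.

    At each step the excluded candidate with the smallest partial-F
    p-value (equivalently, the two-sided t-test of its coefficient in the
    augmented model) enters if that p-value is <= ``p_enter``; then any
    included predictor whose p-value has risen to >= ``p_remove`` leaves.
    Ties are broken by candidate input order, so the procedure is
    deterministic.  Returns the final fitted model, which may be
    intercept-only when nothing qualifies.
    """
    if p_remove < p_enter:
        raise ValueError(
            f"p_remove ({p_remove}) must be >= p_enter ({p_enter}) "
            "to avoid entry/removal cycling"
        )
    x, y = _as_xy(candidates, y)
    included: list[str] = []
    while True:
        changed = False
        excluded = [c for c in x.columns if c not in included]
        if excluded and len(y) > len(included) + 2:
            best_p, best_col = None, None
            for col in excluded:
                trial = x[included + [col]]
                design = sm.add_constant(trial.to_numpy(dtype=float),
                                         has_constant="add")
                if np.linalg.matrix_rank(design) < design.shape[1]:
                    continue
                pvals = _coef_pvalues(trial, y)
                pv = float(pvals[col])
                if best_p is None or pv < best_p:
                    best_p, best_col = pv, col
            if best_p is not None and best_p <= p_enter:
                included.append(best_col)
                changed = True
        if included:
            pvals = _coef_pvalues(x[included], y)
            worst = pvals.idxmax()
            if float(pvals[worst]) >= p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            break
    return ols_fit(x[included], y, response=response)


def predict_from_model(model: RegressionModel,
                       composition: Mapping[str, float]) -> float:
    """Evaluate a fitted equation at a new composition.

    Every model predictor must be present in ``composition``.
    """
    value = model.intercept
    for name in model.predictors:
        if name not in composition:
            raise KeyError(f"composition is missing predictor {name!r}")
        value += model.coefficients[name] * composition[name]
    return float(value)


class StepwiseLinearRegression:
    """Estimator-style wrapper around :func:`stepwise_select`.

    Follows the scikit-learn protocol (``fit`` / ``predict`` /
    ``get_params`` / ``set_params``; fitted attributes carry a trailing
    underscore) so it can sit in sklearn pipelines and model selection.
    ``X`` passed to :meth:`fit` should be a DataFrame so the selected
    predictors keep their names.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def get_params(self, deep: bool = True) -> dict:
        return {"p_enter": self.p_enter, "p_remove": self.p_remove}

    def set_params(self, **params) -> "StepwiseLinearRegression":
        for key, value in params.items():
            if key not in ("p_enter", "p_remove"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "StepwiseLinearRegression":
        X = pd.DataFrame(X)
        self.model_ = stepwise_select(X, y, p_enter=self.p_enter,
                                      p_remove=self.p_remove)
        self.selected_ = list(self.model_.predictors)
        self.intercept_ = self.model_.intercept
        self.coef_ = np.array(
            [self.model_.coefficients[c] for c in self.selected_]
        )
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        out = np.full(len(X), self.intercept_, dtype=float)
        for name, coef in zip(self.selected_, self.coef_):
            out += coef * X[name].to_numpy(dtype=float)
        return out

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        sst = ((y - y.mean()) ** 2).sum()
        return 1.0 - ((y - pred) ** 2).sum() / sst
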