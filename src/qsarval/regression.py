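"""Least-squares activity models: MLR, stepwise selection, quadratic design.

The linear model is Log10IC50 = b0 + Σ bi·xi fitted by ordinary least squares
(via statsmodels); the "non-linear" variant is the same OLS machinery on a
design augmented with squared descriptor columns, with exactly-collinear
squares pruned automatically (an integer descriptor taking only two values
makes its square an affine function of itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FittedLinearModel",
    "PolynomialSpec",
    "RankDeficientError",
    "UndefinedMetricError",
    "fit_ols",
    "stepwise_select",
    "coefficient_table",
    "anova",
    "fit_metrics",
    "build_poly_design",
    "predict",
    "adjusted_r2",
]


class RankDeficientError(ValueError):
    """The design matrix is not of full column rank."""


class UndefinedMetricError(ValueError):
    """A requested statistic is undefined for the given data."""


def _as_frame(X, names=None) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if names is not None:
        X.columns = list(names)
    X.columns = [str(c) for c in X.columns]
    return X.astype(float)


def _dependent_columns(D: pd.DataFrame) -> list[str]:
    """Columns whose removal does not reduce the design rank (the culprits)."""
    full_rank = np.linalg.matrix_rank(D.to_numpy())
    return [
        c
        for c in D.columns
        if np.linalg.matrix_rank(D.drop(columns=c).to_numpy()) == full_rank
    ]


@dataclass
class FittedLinearModel:
    """An OLS fit with intercept: coefficients plus everything validation needs.

    ``term_names`` lists the intercept first; ``hat_diagonal`` is the diagonal
    of X(XᵀX)⁻¹Xᵀ for the fitted design; ``sigma`` is the residual standard
    error sqrt(SSE/(n−K)) with K = p + 1 parameters.
    """

    term_names: list[str]
    coefficients: np.ndarray
    residuals: np.ndarray
    hat_diagonal: np.ndarray
    n: int
    K: int
    sigma: float
    y: np.ndarray = field(repr=False)
    design: pd.DataFrame = field(repr=False)   # n × K, intercept column first
    _sm_results: object = field(default=None, repr=False, compare=False)

    @property
    def fitted(self) -> np.ndarray:
        return self.y - self.residuals

    @property
    def feature_names(self) -> list[str]:
        return self.term_names[1:]

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    def to_json_dict(self) -> dict:
        return {
            "term_names": self.term_names,
            "coefficients": [float(c) for c in self.coefficients],
            "n": self.n,
            "K": self.K,
            "sigma": float(self.sigma),
        }


def fit_ols(X, y, names: list[str] | None = None) -> FittedLinearModel:
    """Fit y on X by ordinary least squares with an intercept.

    ``X`` is the descriptor/design matrix *without* the intercept column
    (DataFrame or array); ``y`` the activity vector.  Raises
    :class:`RankDeficientError` naming the dependent column(s) if the
    intercept-augmented design is rank deficient.
    """
    X = _as_frame(X, names)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    K = p + 1
    if n <= K:
        raise ValueError(f"need n > K: n={n}, K={K}")
    D = sm.add_constant(X, prepend=True, has_constant="raise")
    if np.linalg.matrix_rank(D.to_numpy()) < K:
        raise RankDeficientError(
            f"rank-deficient design; dependent column(s): {_dependent_columns(D)}"
        )
    res = sm.OLS(y, D).fit()
    hat = res.get_influence().hat_matrix_diag
    return FittedLinearModel(
        term_names=["intercept"] + list(X.columns),
        coefficients=np.asarray(res.params, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        hat_diagonal=np.asarray(hat, dtype=float),
        n=n,
        K=K,
        sigma=float(np.sqrt(res.ssr / (n - K))),
        y=y,
        design=D,
        _sm_results=res,
    )


def predict(model: FittedLinearModel, X) -> np.ndarray:
    """Predicted activities b0 + X·b for rows matching the model's terms."""
    X = _as_frame(X)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"design rows missing model term(s): {missing}")
    Xm = X[model.feature_names].to_numpy(dtype=float)
    return model.coefficients[0] + Xm @ model.coefficients[1:]


def coefficient_table(model: FittedLinearModel) -> pd.DataFrame:
    """Per-term estimate, SE, t, two-sided p and 95% CI (Student t, n−K df)."""
    res = model._sm_results
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "std_error": res.bse,
            "t": res.tvalues,
            "p_value": res.pvalues,
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
        }
    )
    table.index = pd.Index(model.term_names, name="term")
    return table


def anova(model: FittedLinearModel) -> pd.DataFrame:
    """Overall regression ANOVA: SS decomposition, mean squares, F and p."""
    res = model._sm_results
    p = model.K - 1
    ss_model, ss_error = float(res.ess), float(res.ssr)
    df_model, df_error = p, model.n - model.K
    ms_model = ss_model / df_model if df_model else np.nan
    ms_error = ss_error / df_error
    return pd.DataFrame(
        {
            "df": [df_model, df_error, model.n - 1],
            "sum_sq": [ss_model, ss_error, ss_model + ss_error],
            "mean_sq": [ms_model, ms_error, np.nan],
            "F": [float(res.fvalue) if df_model else np.nan, np.nan, np.nan],
            "p_value": [float(res.f_pvalue) if df_model else np.nan, np.nan, np.nan],
        },
        index=pd.Index(["model", "error", "total"], name="source"),
    )


def fit_metrics(model: FittedLinearModel) -> dict[str, float]:
    """R, R², adjusted R² and RMSE of a fitted model.

    RMSE uses the residual-degrees-of-freedom denominator sqrt(SSE/(n−K)),
    i.e. the square root of the ANOVA error mean square.
    """
    y = model.y
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise UndefinedMetricError("zero-variance response: R² undefined")
    sse = float((model.residuals**2).sum())
    r2 = 1.0 - sse / sst
    return {
        "R": float(np.sqrt(max(r2, 0.0))),
        "R2": r2,
        "R2_adj": adjusted_r2(r2, model.n, model.K - 1),
        "RMSE": float(np.sqrt(sse / (model.n - model.K))),
    }


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """((n−1)·R² − p) / (n − p − 1)."""
    return ((n - 1) * r2 - p) / (n - p - 1)


def stepwise_select(
    X,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    names: list[str] | None = None,
) -> list[str]:
    """Forward-backward stepwise selection by partial-F p-values.

    Terms enter when their partial p-value given the current set is the
    smallest and ≤ ``p_enter``; after every entry, retained terms with
    p > ``p_remove`` are dropped (worst first).  Deterministic: ties resolve
    by column order.  Returns the selected names in column order; empty if
    nothing passes (intercept-only model, with a warning).
    """
    if p_enter > p_remove:
        raise ValueError("need p_enter <= p_remove")
    X = _as_frame(X, names)
    y = np.asarray(y, dtype=float).ravel()
    selected: list[str] = []
    candidates = list(X.columns)

    def partial_p(term: str, current: list[str]) -> float:
        cols = current + [term]
        D = sm.add_constant(X[cols], prepend=True)
        if np.linalg.matrix_rank(D.to_numpy()) < len(cols) + 1:
            return np.inf  # adds nothing new
        res = sm.OLS(y, D).fit()
        return float(res.pvalues.iloc[-1])

    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            pvals = [(partial_p(c, selected), candidates.index(c), c) for c in remaining]
            best_p, _, best = min(pvals)
            if best_p <= p_enter:
                selected.append(best)
                changed = True
        # backward sweep
        while len(selected) > 0:
            D = sm.add_constant(X[selected], prepend=True)
            res = sm.OLS(y, D).fit()
            pv = res.pvalues.iloc[1:]
            worst = pv.idxmax()
            if float(pv.max()) > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        warnings.warn("no term passed p_enter; intercept-only model", stacklevel=2)
    return [c for c in X.columns if c in selected]


@dataclass(frozen=True)
class PolynomialSpec:
    """Which terms enter the quadratic design: all linear, a subset squared."""

    linear_terms: tuple[str, ...]
    squared_terms: tuple[str, ...]

    def __post_init__(self):
        extra = set(self.squared_terms) - set(self.linear_terms)
        if extra:
            raise ValueError(f"squared terms not among linear terms: {sorted(extra)}")


def build_poly_design(
    X, spec: PolynomialSpec | None = None, tol: float = 1e-10
) -> tuple[pd.DataFrame, PolynomialSpec]:
    """Append squared descriptor columns to the design.

    In auto mode (``spec=None``) each candidate square is kept only if it is
    not numerically a linear combination of the columns already in the design
    (intercept included): the candidate is projected onto their span and
    dropped when the relative residual norm falls below ``tol**0.5``.  A
    descriptor taking exactly two distinct values (e.g. an HBD count of 1 or
    2) always has its square pruned, since x² is then affine in x.
    """
    X = _as_frame(X)
    squared: list[str] = []
    D = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if spec is not None:
        squared = list(spec.squared_terms)
    else:
        for c in X.columns:
            cand = (X[c].to_numpy(dtype=float)) ** 2
            proj, *_ = np.linalg.lstsq(D, cand, rcond=None)
            resid = cand - D @ proj
            scale = np.linalg.norm(cand)
            if scale > 0 and np.linalg.norm(resid) / scale > np.sqrt(tol):
                squared.append(c)
                D = np.column_stack([D, cand])
    out = X.copy()
    for c in squared:
        out[f"{c}^2"] = X[c] ** 2
    return out, PolynomialSpec(tuple(X.columns), tuple(squared))
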