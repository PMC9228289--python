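"""Model validation statistics: LOO Q², external R², Y-randomization, cR²p,
and the Golbraikh–Tropsha acceptance report.

These are the statistics that decide whether a QSAR model is trusted:
internal predictivity (leave-one-out Q²cv), external predictivity on held-out
molecules, a permutation null for chance correlation (Y-randomization with
the cR²p summary), and a battery of threshold criteria combining them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import (
    FittedLinearModel,
    UndefinedMetricError,
    fit_metrics,
    fit_ols,
    predict,
)

__all__ = [
    "CrossValResult",
    "RandomizationResult",
    "GTReport",
    "q2_loo",
    "loo_predictions",
    "r2_test",
    "r2_external",
    "y_randomization",
    "crp2",
    "golbraikh_tropsha",
    "GT_THRESHOLDS",
]


@dataclass
class CrossValResult:
    """Per-molecule leave-one-out predictions and the Q²cv summary.

    Q²cv = 1 − Σ(ŷ₍₋ᵢ₎ − yᵢ)² / Σ(yᵢ − ȳ)², with ȳ the mean of *all* n
    observed training activities.
    """

    y_obs: np.ndarray
    y_pred: np.ndarray
    y_mean: float
    q2: float

    def to_frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame({"observed": self.y_obs, "predicted_cv": self.y_pred})
        if ids is not None:
            frame.index = pd.Index(ids, name="id")
        return frame


def loo_predictions(X, y, method: str = "shortcut") -> np.ndarray:
    """Leave-one-out predictions for an OLS fit of y on X (with intercept).

    ``method="shortcut"`` uses the exact hat-matrix identity
    ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ); ``method="refit"`` refits the model n times
    dropping one row each time.  The two agree to numerical precision and the
    refit route serves as the brute-force cross-check of the shortcut.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if method == "shortcut":
        model = fit_ols(X, y)
        return y - model.residuals / (1.0 - model.hat_diagonal)
    if method == "refit":
        preds = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            try:
                sub = fit_ols(X.iloc[keep], y[keep])
            except ValueError as exc:
                raise ValueError(f"LOO refit failed leaving out row {i}: {exc}") from exc
            preds[i] = predict(sub, X.iloc[[i]])[0]
        return preds
    raise ValueError(f"unknown method {method!r}")


def q2_loo(X, y, method: str = "shortcut") -> CrossValResult:
    """Leave-one-out cross-validated Q² of the OLS model of y on X."""
    y = np.asarray(y, dtype=float).ravel()
    preds = loo_predictions(X, y, method=method)
    y_mean = float(y.mean())
    sst = float(((y - y_mean) ** 2).sum())
    if sst == 0.0:
        raise UndefinedMetricError("zero-variance response: Q² undefined")
    press = float(((preds - y) ** 2).sum())
    return CrossValResult(y_obs=y, y_pred=preds, y_mean=y_mean, q2=1.0 - press / sst)


def r2_test(
    model: FittedLinearModel, X_test, y_test, y_train_mean: float
) -> float:
    """Predictive R² on a test set with the training mean in the denominator:
    R²test = 1 − Σ(ŷ − y)² / Σ(y − ȳ_train)².

    This is the strict predictive form; it can be strongly negative even when
    predictions track observations well, because the denominator centres on
    the training mean.  See :func:`r2_external` for the correlation form.
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) == 0:
        raise ValueError("empty test set")
    denom = float(((y_test - y_train_mean) ** 2).sum())
    if denom == 0.0:
        raise UndefinedMetricError("test activities all equal the training mean")
    preds = predict(model, X_test)
    return 1.0 - float(((preds - y_test) ** 2).sum()) / denom


def r2_external(y_obs, y_pred) -> float:
    """Squared Pearson correlation between observed and predicted activities.

    The external-validation statistic read off an observed-vs-predicted
    scatter; on the bundled GlyT1 test set it is the quantity quoted as
    R²ext.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.std() == 0 or y_pred.std() == 0:
        raise UndefinedMetricError("constant vector: correlation undefined")
    return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)


@dataclass
class RandomizationResult:
    """Per-permutation (R, R², Q²) triples and their summaries.

    ``crp2`` combines the original model's R and R² with the mean
    per-permutation R: cR²p = R·sqrt(R² − (mean R_rand)²).
    """

    runs: pd.DataFrame            # columns R, R2, Q2, one row per permutation
    seed: int
    original: dict[str, float]    # R, R2, Q2 of the unpermuted model
    crp2: float = field(init=False)

    def __post_init__(self):
        self.crp2 = crp2(
            self.original["R"], self.original["R2"], self.avg_R
        )

    @property
    def avg_R(self) -> float:
        return float(self.runs["R"].mean())

    @property
    def avg_R2(self) -> float:
        return float(self.runs["R2"].mean())

    @property
    def avg_Q2(self) -> float:
        return float(self.runs["Q2"].mean())

    def to_frame(self) -> pd.DataFrame:
        """Per-run table with the original model as the first row."""
        head = pd.DataFrame(
            [self.original], index=pd.Index(["original"], name="model")
        )[["R", "R2", "Q2"]]
        body = self.runs.copy()
        body.index = pd.Index(
            [f"random_{i + 1}" for i in range(len(body))], name="model"
        )
        return pd.concat([head, body])


def y_randomization(
    X, y, n_runs: int = 100, seed: int = 0
) -> RandomizationResult:
    """Chance-correlation null via response permutation.

    The activity vector is permuted uniformly at random ``n_runs`` times
    (without replacement — the descriptor matrix is untouched); the same OLS
    design is refitted each time and its R, R² and leave-one-out Q² recorded.
    A real structure–activity relationship should beat every permuted refit
    by a wide margin.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    def stats_for(y_perm: np.ndarray) -> dict[str, float]:
        model = fit_ols(X, y_perm)
        m = fit_metrics(model)
        q2 = q2_loo(X, y_perm).q2
        return {"R": m["R"], "R2": m["R2"], "Q2": q2}

    original = stats_for(y)
    rows = [stats_for(y[rng.permutation(len(y))]) for _ in range(n_runs)]
    return RandomizationResult(
        runs=pd.DataFrame(rows), seed=seed, original=original
    )


def crp2(R: float, R2: float, avg_R_rand: float) -> float:
    """Corrected randomization criterion cR²p = R·sqrt(R² − (avg R_rand)²)."""
    radicand = R2 - avg_R_rand**2
    if -1e-12 < radicand < 0:  # exact-zero case up to rounding
        radicand = 0.0
    if radicand < 0:
        raise UndefinedMetricError(
            f"R² = {R2:.4f} below squared average randomized R "
            f"({avg_R_rand:.4f}²): model no better than chance"
        )
    return float(R * np.sqrt(radicand))


#: (threshold, comparison) per criterion; comparisons are strict.
GT_THRESHOLDS: dict[str, tuple[float | str, str]] = {
    "R2": (0.6, ">"),
    "R2_adj": (0.6, ">"),
    "R2_test": (0.6, ">"),
    "Q2_cv": (0.5, ">"),
    "avg_R2_rand": ("R2", "<"),
    "avg_Q2_rand": ("Q2_cv", "<"),
    "cR2p": (0.5, ">"),
}


@dataclass
class GTReport:
    """Golbraikh–Tropsha criteria: one pass/fail row per statistic."""

    rows: pd.DataFrame  # columns: value, threshold, comparison, passed

    @property
    def passed(self) -> bool:
        return bool(self.rows["passed"].all())

    def to_json_dict(self) -> dict:
        return {
            "criteria": {
                name: {
                    "value": float(r["value"]),
                    "threshold": float(r["threshold"]),
                    "comparison": r["comparison"],
                    "passed": bool(r["passed"]),
                }
                for name, r in self.rows.iterrows()
            },
            "passed": self.passed,
        }


def golbraikh_tropsha(values: dict[str, float]) -> GTReport:
    """Evaluate the Golbraikh–Tropsha acceptance battery.

    ``values`` must supply all seven statistics named in
    :data:`GT_THRESHOLDS`.  Fixed thresholds are strict (a value exactly at
    the threshold fails); the randomization averages are compared against the
    model's own R² and Q²cv.
    """
    missing = [k for k in GT_THRESHOLDS if k not in values]
    if missing:
        raise KeyError(f"missing statistic(s): {missing}")
    records = []
    for name, (threshold, op) in GT_THRESHOLDS.items():
        thr = float(values[threshold]) if isinstance(threshold, str) else threshold
        v = float(values[name])
        ok = v > thr if op == ">" else v < thr
        records.append(
            {"value": v, "threshold": thr, "comparison": op, "passed": ok}
        )
    rows = pd.DataFrame(records, index=pd.Index(GT_THRESHOLDS, name="criterion"))
    return GTReport(rows=rows)
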