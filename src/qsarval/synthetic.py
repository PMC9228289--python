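"""Synthetic molecule tables with the statistical structure the pipeline assumes.

Descriptors are drawn uniformly within the ranges the bundled GlyT1 table
spans (counts as integers), and the activity is a known linear — optionally
quadratic — function of them plus Gaussian noise, so every stage of the
pipeline can be exercised against a known ground truth.  A pure-noise null
variant provides the negative control for the chance-correlation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DESCRIPTOR_NAMES, INTEGER_DESCRIPTORS, MoleculeRecord, QsarDataset

__all__ = ["SyntheticSpec", "generate_linear_dataset", "generate_null_dataset"]

#: Descriptor ranges read off the extremes of the bundled GlyT1 table.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ae": (38.0, 54.0),
    "gamma": (38.0, 58.0),
    "te": (5.0, 60.0),
    "hbd": (1, 2),
    "se": (2.2, 5.2),
    "td": (10, 14),
}

#: Default true coefficients: the six-descriptor GlyT1 activity model.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -10.408,
    "ae": -0.279,
    "gamma": 0.070,
    "te": 0.156,
    "hbd": 1.830,
    "se": 1.716,
    "td": 1.030,
}


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    ``beta`` maps ``intercept`` and descriptor names to true linear
    coefficients; ``beta_sq`` optionally maps descriptor names to quadratic
    coefficients.  ``sigma`` is the noise SD on the activity scale (the
    default 0.66 matches the residual scale of the reference fit).
    ``n_outliers`` appends that many points at 1.5× the descriptor ranges to
    exercise leverage classification.
    """

    n: int = 35
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    beta_sq: dict[str, float] | None = None
    sigma: float = 0.66
    seed: int = 0
    test_fraction: float = 0.0
    n_outliers: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if not hi > lo:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")


def _draw_descriptors(
    rng: np.random.Generator, n: int, ranges: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    cols = {}
    for name in DESCRIPTOR_NAMES:
        lo, hi = ranges[name]
        if name in INTEGER_DESCRIPTORS:
            cols[name] = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols)


def _to_dataset(X: pd.DataFrame, y: np.ndarray, subset: list[str]) -> QsarDataset:
    records = [
        MoleculeRecord(
            id=i + 1,
            descriptors={n: float(X.iloc[i][n]) for n in DESCRIPTOR_NAMES},
            activity=float(y[i]),
            subset=subset[i],
        )
        for i in range(len(X))
    ]
    return QsarDataset(records)


def generate_linear_dataset(
    spec: SyntheticSpec | None = None, **kwargs
) -> tuple[QsarDataset, dict]:
    """Generate a dataset whose activity is a known (linear or quadratic)
    function of the descriptors plus Gaussian noise.

    Returns the dataset and the ground-truth parameters
    ``{"beta": ..., "beta_sq": ..., "sigma": ...}``.  Reproducible under a
    fixed ``spec.seed``.
    """
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    X = _draw_descriptors(rng, spec.n, spec.ranges)
    if spec.n_outliers:
        far = {}
        for name in DESCRIPTOR_NAMES:
            lo, hi = spec.ranges[name]
            v = lo + 1.5 * (hi - lo)
            far[name] = round(v) if name in INTEGER_DESCRIPTORS else v
        X = pd.concat(
            [X, pd.DataFrame([far] * spec.n_outliers)], ignore_index=True
        )
    y = np.full(len(X), spec.beta.get("intercept", 0.0))
    for name in DESCRIPTOR_NAMES:
        y += spec.beta.get(name, 0.0) * X[name].to_numpy()
        if spec.beta_sq:
            y += spec.beta_sq.get(name, 0.0) * X[name].to_numpy() ** 2
    y += rng.normal(0.0, spec.sigma, size=len(X))
    subset = ["train"] * len(X)
    if spec.test_fraction > 0:
        n_test = int(round(spec.test_fraction * len(X)))
        for i in rng.choice(len(X), size=n_test, replace=False):
            subset[i] = "test"
    truth = {"beta": dict(spec.beta), "beta_sq": dict(spec.beta_sq or {}),
             "sigma": spec.sigma, "seed": spec.seed}
    return _to_dataset(X, y, subset), truth


def generate_null_dataset(n: int = 35, seed: int = 0) -> QsarDataset:
    """Descriptors as usual, activity i.i.d. standard normal (no signal).

    The negative control: any apparent fit quality on this data is chance
    correlation, so validation statistics should reject it.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    X = _draw_descriptors(rng, n, DEFAULT_RANGES)
    y = rng.standard_normal(n)
    return _to_dataset(X, y, ["train"] * n)
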