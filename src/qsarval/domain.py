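"""Leverage-based applicability domain and Williams classification.

A prediction is only trusted for molecules structurally similar to the
training set.  Similarity is measured by leverage h(x) = xᵀ(XᵀX)⁻¹x (x
including the intercept entry); molecules with h above the warning leverage
h* = 3K/n are structural (leverage) outliers, and molecules whose
standardized residual exceeds ±3 are response outliers.  Plotting leverage
against standardized residual gives the Williams diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import QsarDataset, split
from .regression import FittedLinearModel, RankDeficientError, fit_ols, predict

__all__ = [
    "DomainResult",
    "leverages",
    "h_star",
    "williams_classify",
    "williams_analysis",
]

CLASS_IN = "in_domain"
CLASS_LEVERAGE = "leverage_outlier"
CLASS_RESPONSE = "response_outlier"
CLASS_BOTH = "both"


@dataclass
class DomainResult:
    """Per-molecule leverage, standardized residual and domain class."""

    ids: list
    leverage: np.ndarray
    std_residual: np.ndarray
    classification: list[str]
    h_star: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "classification": self.classification,
            },
            index=pd.Index(self.ids, name="id"),
        )

    @property
    def outlier_ids(self) -> list:
        return [
            i
            for i, c in zip(self.ids, self.classification)
            if c != CLASS_IN
        ]


def _design(X) -> np.ndarray:
    X = pd.DataFrame(X).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def leverages(X_train, X_query=None) -> np.ndarray:
    """Leverage of each query row in the hat-matrix basis of ``X_train``.

    Both matrices are descriptor matrices without the intercept column (it is
    added internally).  With ``X_query=None`` the training rows themselves
    are scored, i.e. the hat-matrix diagonal is returned.
    """
    D = _design(X_train)
    M = D.T @ D
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise RankDeficientError("training design is rank deficient")
    Minv = np.linalg.inv(M)
    Q = D if X_query is None else _design(X_query)
    if Q.shape[1] != D.shape[1]:
        raise ValueError("query columns do not match training columns")
    return np.einsum("ij,jk,ik->i", Q, Minv, Q)


def h_star(K: int, n: int) -> float:
    """Warning leverage h* = 3K/n (K parameters incl. intercept, n samples)."""
    if not n > K > 0:
        raise ValueError(f"need n > K > 0, got K={K}, n={n}")
    return 3.0 * K / n


def williams_classify(
    ids,
    leverage,
    std_residual,
    h_star_value: float,
    resid_limit: float = 3.0,
) -> DomainResult:
    """Classify molecules by leverage and standardized residual.

    ``leverage_outlier`` iff h > h*; ``response_outlier`` iff
    \\|standardized residual\\| > ``resid_limit``; ``both`` when the two
    co-occur; otherwise ``in_domain``.
    """
    leverage = np.asarray(leverage, dtype=float)
    std_residual = np.asarray(std_residual, dtype=float)
    if not (len(ids) == len(leverage) == len(std_residual)):
        raise ValueError("ids, leverage and std_residual must align")
    classes = []
    for h, r in zip(leverage, std_residual):
        lev = h > h_star_value
        resp = abs(r) > resid_limit
        classes.append(
            CLASS_BOTH if lev and resp
            else CLASS_LEVERAGE if lev
            else CLASS_RESPONSE if resp
            else CLASS_IN
        )
    return DomainResult(
        ids=list(ids),
        leverage=leverage,
        std_residual=std_residual,
        classification=classes,
        h_star=h_star_value,
    )


def williams_analysis(
    dataset: QsarDataset,
    model: FittedLinearModel | None = None,
    resid_limit: float = 3.0,
) -> DomainResult:
    """Full applicability-domain analysis of a flagged dataset.

    The model (fitted on the training partition; refitted here if not
    supplied) provides the residual scale: standardized residuals are raw
    residuals divided by the training RMSE, for training and test molecules
    alike.  The hat-matrix basis pools the training molecules with the
    non-outlier test molecules — the in-domain candidate set a published
    Williams diagram plots as members — while molecules flagged as outliers
    in the dataset are scored as external queries against that basis.  The
    warning leverage uses the training count: h* = 3K/n_train.
    """
    train, test = split(dataset, drop_outliers=True)
    flagged = [r for r in dataset.records if r.outlier]
    if model is None:
        model = fit_ols(train.X, train.y)
    hs = h_star(model.K, len(train))

    member_records = train.records + test.records
    member_X = pd.concat([train.X, test.X])
    h_members = leverages(member_X)

    def std_resid(rec) -> float:
        # expand squared terms if the residual scale comes from a quadratic fit
        values = {}
        for term in model.feature_names:
            base = term[:-2] if term.endswith("^2") else term
            v = rec.descriptors[base]
            values[term] = v * v if term.endswith("^2") else v
        row = pd.DataFrame([values])
        return float((rec.activity - predict(model, row)[0]) / model.sigma)

    ids = [r.id for r in member_records]
    resids = [std_resid(r) for r in member_records]
    h_all = list(h_members)
    if flagged:
        flagged_X = pd.DataFrame(
            [[r.descriptors[n] for n in dataset.descriptor_names] for r in flagged],
            columns=list(dataset.descriptor_names),
        )
        h_all += list(leverages(member_X, flagged_X))
        ids += [r.id for r in flagged]
        resids += [std_resid(r) for r in flagged]
    return williams_classify(ids, h_all, resids, hs, resid_limit=resid_limit)
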