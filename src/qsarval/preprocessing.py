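"""Descriptor-pool reduction and correlation-matrix PCA.

Large descriptor pools are pruned by pairwise Pearson correlation before any
regression (highly collinear descriptors carry no independent information and
destabilise least squares), and projected onto principal components of the
correlation matrix for visual screening of poorly-explained molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaResult", "correlation_filter", "pca_correlation"]


@dataclass
class PcaResult:
    """Correlation-matrix PCA: scores, loadings and eigenvalues.

    Scores are the standardized data projected on the loadings; eigenvalues
    are sorted descending and sum to the number of variables.
    """

    scores: pd.DataFrame       # n × m, columns PC1..PCm
    loadings: pd.DataFrame     # p × m, rows = variable names
    eigenvalues: np.ndarray    # length m, descending

    def score_distances(self, n_components: int = 2) -> pd.Series:
        """Mahalanobis distance of each molecule in the leading score plane.

        Used to rank how poorly the retained components explain a molecule;
        large distances single out candidate outliers.
        """
        S = self.scores.iloc[:, :n_components].to_numpy()
        cov = np.cov(S, rowvar=False)
        delta = S - S.mean(axis=0)
        d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(np.atleast_2d(cov)), delta)
        return pd.Series(np.sqrt(d2), index=self.scores.index, name="mahalanobis")


def correlation_filter(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedily drop descriptors until no retained pair has |r| > threshold.

    At each step the most-correlated pair is found and one member dropped:
    the one with the larger mean absolute correlation against all remaining
    columns (ties broken by column order), which keeps the more independent
    representative.  Constant columns are removed first with a warning, since
    their correlation is undefined.  Deterministic, and idempotent on its own
    output.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    X = pd.DataFrame(X)
    if len(X) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    keep = list(X.columns)
    constant = [c for c in keep if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant column(s) {constant}: correlation undefined",
            stacklevel=2,
        )
        keep = [c for c in keep if c not in constant]
    while len(keep) > 1:
        corr = X[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(int(np.argmax(corr.values)), corr.shape)
        if corr.values[i, j] <= threshold:
            break
        a, b = corr.columns[i], corr.columns[j]
        mean_a = corr[a].drop(index=[a, b]).mean() if len(keep) > 2 else 0.0
        mean_b = corr[b].drop(index=[a, b]).mean() if len(keep) > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: drop the later column in the original order
            drop = max(a, b, key=keep.index)
        keep.remove(drop)
    return keep


def pca_correlation(X: pd.DataFrame) -> PcaResult:
    """Principal component analysis of the correlation matrix.

    Columns are standardized (mean 0, SD 1, population denominator) and the
    eigendecomposition of their correlation matrix taken; the sign of each
    loading vector is fixed so its largest-magnitude entry is positive, which
    makes score plots reproducible across runs and platforms.
    """
    X = pd.DataFrame(X)
    if len(X) < 2:
        raise ValueError("need at least 2 rows for PCA")
    variances = X.std(axis=0, ddof=0)
    if (variances == 0).any():
        bad = list(variances.index[variances == 0])
        raise ValueError(f"constant column(s) {bad} cannot be standardized")
    Z = (X - X.mean(axis=0)) / variances
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(R))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    for k in range(eigvecs.shape[1]):  # sign convention
        if eigvecs[np.argmax(np.abs(eigvecs[:, k])), k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comp_names = [f"PC{k + 1}" for k in range(eigvecs.shape[1])]
    loadings = pd.DataFrame(eigvecs, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvecs, index=X.index, columns=comp_names
    )
    return PcaResult(scores=scores, loadings=loadings, eigenvalues=eigvals)
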