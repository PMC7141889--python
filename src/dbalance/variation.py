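"""Pairwise log-ratio variation and differential proportionality.

The variation matrix T holds, for every feature pair (j, j*), the variance
across samples of log(x_j / x_j*).  T is zero exactly for proportional pairs
and is invariant to per-sample rescaling, which makes it the natural
dissimilarity for compositional data.

The differential proportionality statistic theta splits that variance by a
binary grouping: theta = (N1*T1 + N2*T2) / ((N1+N2)*T) is the within-group
share of a pair's log-ratio sum of squares.  theta near 0 means the pair's
log ratio shifts its mean strongly between groups (a discriminative pair);
theta = 1 means the grouping explains nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import CompositionTable

__all__ = ["VariationMatrix", "ThetaMatrix", "variation_matrix", "theta_matrix"]


@dataclass
class VariationMatrix:
    """Symmetric D x D matrix of pairwise log-ratio variances (zero diagonal)."""

    values: np.ndarray
    feature_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass
class ThetaMatrix:
    """Symmetric D x D matrix of differential proportionality in [0, 1].

    The diagonal (and any pair whose total log-ratio variance is zero) is set
    to 1: such pairs carry no discriminative information and should merge
    last when clustered.
    """

    values: np.ndarray
    feature_ids: list[str]
    group_sizes: tuple[int, int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def _logratio_variance(logx: np.ndarray) -> np.ndarray:
    """Pairwise var(log x_j - log x_j*) via the covariance identity.

    var(a - b) = var(a) + var(b) - 2 cov(a, b); O(N*D^2) instead of looping
    over pairs.  Population convention (ddof=0).
    """
    n = logx.shape[0]
    centered = logx - logx.mean(axis=0)
    cov = centered.T @ centered / n
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum(t, 0.0)  # clip negative round-off
    np.fill_diagonal(t, 0.0)
    return 0.5 * (t + t.T)


def variation_matrix(table: CompositionTable) -> VariationMatrix:
    """Compute the log-ratio variance matrix T over all feature pairs."""
    if np.any(table.values <= 0):
        raise ValueError("variation matrix requires strictly positive entries")
    if table.n_samples < 2:
        raise ValueError("variation matrix needs at least 2 samples")
    t = _logratio_variance(np.log(table.values))
    return VariationMatrix(t, list(table.feature_ids))


def theta_matrix(
    table: CompositionTable, labels: np.ndarray | None = None
) -> ThetaMatrix:
    """Compute differential proportionality theta for a binary grouping.

    With population variances, theta equals the within-group sum of squares
    of each pair's log ratio divided by its total sum of squares, so
    theta in [0, 1] and 1 - theta is the between-group share.
    """
    if labels is None:
        labels = table.labels
    if labels is None:
        raise ValueError("theta requires binary group labels")
    labels = np.asarray(labels)
    if np.any(table.values <= 0):
        raise ValueError("theta requires strictly positive entries")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    masks = [labels == g for g in groups]
    sizes = [int(m.sum()) for m in masks]
    if min(sizes) < 2:
        raise ValueError("each group needs at least 2 samples")

    logx = np.log(table.values)
    t_all = _logratio_variance(logx)
    n = table.n_samples
    within_ss = np.zeros_like(t_all)
    for m, sz in zip(masks, sizes):
        within_ss += sz * _logratio_variance(logx[m])
    total_ss = n * t_all
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(total_ss > 0, within_ss / total_ss, 1.0)
    theta = np.clip(theta, 0.0, 1.0)
    np.fill_diagonal(theta, 1.0)
    theta = 0.5 * (theta + theta.T)
    return ThetaMatrix(theta, list(table.feature_ids), (sizes[0], sizes[1]))
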