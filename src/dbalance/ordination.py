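"""Per-balance variance bookkeeping and the discriminant projection.

Because a full SBP is an orthonormal basis, the Aitchison total variance of
a composition table splits exactly into per-balance variances, and each of
those splits exactly (one-way ANOVA, population convention) into a
between-group and a within-group part.  Ranking distal discriminative
balances by variance and projecting onto the top few gives a discriminant
ordination whose axes are simple, interpretable log ratios.

Note the caveat: the basis vectors are orthonormal in composition space,
but balance coordinates viewed as variables across samples are generally
correlated, so the projection axes are interpretable rather than
statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .balances import BalanceCoordinates

__all__ = ["VarianceDecomposition", "decompose_variance", "top_k_projection"]


@dataclass
class VarianceDecomposition:
    """Per-balance total / between-group / within-group variance table."""

    table: pd.DataFrame  # balance_id, parts?, total, between, within, pct_total, pct_between

    @property
    def balance_ids(self) -> list[str]:
        return list(self.table["balance_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def decompose_variance(
    balances: BalanceCoordinates, labels: np.ndarray
) -> VarianceDecomposition:
    """One-way variance decomposition of every balance by a binary grouping.

    With population variances, between = sum_g n_g (mean_g - mean)^2 / N and
    within = sum_g n_g var_g / N, so between + within = total exactly.
    Fractions are taken against the grand totals over all supplied balances.
    """
    labels = np.asarray(labels)
    x = balances.values
    n = x.shape[0]
    if n < 2:
        raise ValueError("variance decomposition needs at least 2 samples")
    if len(labels) != n:
        raise ValueError("labels must match the number of samples")
    total = x.var(axis=0, ddof=0)
    grand_mean = x.mean(axis=0)
    between = np.zeros_like(total)
    within = np.zeros_like(total)
    for g in np.unique(labels):
        mask = labels == g
        ng = int(mask.sum())
        between += ng * (x[mask].mean(axis=0) - grand_mean) ** 2 / n
        within += ng * x[mask].var(axis=0, ddof=0) / n
    grand_total = total.sum()
    grand_between = between.sum()
    df = pd.DataFrame(
        {
            "balance_id": balances.balance_ids,
            "total": total,
            "between": between,
            "within": within,
            "pct_total": 100 * total / grand_total if grand_total > 0 else 0.0,
            "pct_between": 100 * between / grand_between if grand_between > 0 else 0.0,
        }
    )
    return VarianceDecomposition(df)


def top_k_projection(
    balances: BalanceCoordinates,
    decomposition: VarianceDecomposition,
    k: int = 3,
    criterion: str = "total",
) -> tuple[BalanceCoordinates, pd.DataFrame]:
    """Project samples onto the k balances maximizing the chosen variance.

    criterion "total" selects the most variable balances; "between" selects
    the ones with the most between-group variance.  Returns the N x k
    coordinates plus the rows of the decomposition table for the selection
    (in nonincreasing criterion order; ties broken by balance index).
    """
    if criterion not in ("total", "between"):
        raise ValueError("criterion must be 'total' or 'between'")
    df = decomposition.table
    if k > len(df):
        raise ValueError(f"k={k} exceeds the {len(df)} available balances")
    if list(df["balance_id"]) != list(balances.balance_ids):
        raise ValueError("decomposition does not match the balance coordinates")
    order = np.lexsort((np.arange(len(df)), -df[criterion].to_numpy()))[:k]
    chosen = df.iloc[order].reset_index(drop=True)
    coords = BalanceCoordinates(
        balances.values[:, order],
        list(balances.sample_ids),
        list(chosen["balance_id"]),
    )
    return coords, chosen
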