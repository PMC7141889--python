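"""Isometric log-ratio balance coordinates from a serial binary partition.

Each SBP column z contrasts a numerator block C+ (d+ parts) against a
denominator block C- (d- parts); its balance coordinate for sample i is

    b_iz = sqrt(d+ d- / (d+ + d-)) * log( gmean(x_i, C+) / gmean(x_i, C-) )

These are log contrasts with coefficients +sqrt(d-/(d+(d+ + d-))) on C+ and
-sqrt(d+/(d-(d+ + d-))) on C-, which makes the D-1 rows of a full SBP an
orthonormal basis of the CLR hyperplane: distances and total variance are
preserved (an isometry), and every coordinate is invariant to per-sample
rescaling.  The contrast matrix derived from a training set is a frozen
"balance rule" that applies unchanged to held-out samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import CompositionTable
from .sbp import SBPMatrix, SBPMatrixSubset

logger = logging.getLogger(__name__)

__all__ = ["ContrastMatrix", "BalanceCoordinates", "contrast_matrix", "compute_balances"]


@dataclass
class ContrastMatrix:
    """Z x D real log-contrast coefficients derived from an SBP.

    Every row sums to zero; for a full SBP the rows are orthonormal.
    """

    coefficients: np.ndarray
    feature_ids: list[str]
    balance_ids: list[str]
    n_plus: np.ndarray
    n_minus: np.ndarray


@dataclass
class BalanceCoordinates:
    """N x Z balance values; Z <= D-1."""

    values: np.ndarray
    sample_ids: list[str]
    balance_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.balance_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="sample_id")


def contrast_matrix(sbp: SBPMatrix | SBPMatrixSubset) -> ContrastMatrix:
    """Turn SBP signs into normalized log-contrast coefficients."""
    signs = sbp.signs
    d_plus = (signs == 1).sum(axis=0).astype(float)
    d_minus = (signs == -1).sum(axis=0).astype(float)
    tot = d_plus + d_minus
    plus_coef = np.sqrt(d_minus / (d_plus * tot))
    minus_coef = -np.sqrt(d_plus / (d_minus * tot))
    coef = np.where(signs.T == 1, plus_coef[:, None], 0.0)
    coef = np.where(signs.T == -1, minus_coef[:, None], coef)
    return ContrastMatrix(
        coef,
        list(sbp.feature_ids),
        list(sbp.balance_ids),
        d_plus.astype(int),
        d_minus.astype(int),
    )


def compute_balances(
    table: CompositionTable, sbp: SBPMatrix | SBPMatrixSubset
) -> BalanceCoordinates:
    """Evaluate balance coordinates for every sample of a table.

    The table must cover the SBP's features (extra features are ignored with
    a warning); this is what lets a training-derived balance rule run on a
    validation table.  Values are computed as contrast coefficients times
    log-abundances, which is numerically safer than products of large
    geometric means and provably identical.
    """
    missing = [f for f in sbp.feature_ids if f not in table.feature_ids]
    if missing:
        raise ValueError(f"table lacks features required by the SBP: {missing[:5]}")
    if set(table.feature_ids) != set(sbp.feature_ids):
        extra = len(table.feature_ids) - len(sbp.feature_ids)
        logger.warning("ignoring %d table features absent from the SBP", extra)
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    cols = [pos[f] for f in sbp.feature_ids]
    x = table.values[:, cols]
    if np.any(x <= 0):
        raise ValueError("balances require strictly positive abundances")
    contrasts = contrast_matrix(sbp)
    values = np.log(x) @ contrasts.coefficients.T
    return BalanceCoordinates(values, list(table.sample_ids), list(sbp.balance_ids))
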