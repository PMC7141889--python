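"""Compositional abundance tables: loading, filtering, zero replacement, and
log-ratio transformations.

A composition carries only relative information: the total count of a
sequencing sample is an artifact of library depth, so two rows that differ
by a positive scalar are the same composition.  Every transformation here is
therefore either explicitly normalizing (closure) or scale-invariant (CLR,
total variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "EmptyFeatureSetError",
    "filter_features",
    "replace_zeros",
    "closure",
    "clr",
    "total_variance",
    "read_table",
    "read_labels",
]


class EmptyFeatureSetError(ValueError):
    """Raised when filtering removes every feature."""


@dataclass
class CompositionTable:
    """A sample-by-feature table of nonnegative abundances.

    Parameters
    ----------
    values : ndarray of shape (N, D)
        Nonnegative counts or proportions; samples in rows.
    sample_ids : sequence of N unique identifiers.
    feature_ids : sequence of D unique identifiers.
    labels : ndarray of shape (N,), optional
        Binary group tag per sample; exactly two distinct values, each with
        at least two samples.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample-by-feature matrix")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValueError(f"need N >= 2 samples and D >= 2 features, got {n}x{d}")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("abundances must be finite and nonnegative")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i+1}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"f{j+1}" for j in range(d)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match the row count")
        if len(self.feature_ids) != d or len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids must be unique and match the column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per sample")
            groups, counts = np.unique(self.labels, return_counts=True)
            if len(groups) != 2 or counts.min() < 2:
                raise ValueError(
                    "labels must take exactly 2 values with >= 2 samples each"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: Sequence[int]) -> "CompositionTable":
        """Row subset (e.g. a training split); label validation is relaxed
        only in that the subset must still contain two groups."""
        index = np.asarray(index)
        return CompositionTable(
            self.values[index],
            [self.sample_ids[i] for i in index],
            list(self.feature_ids),
            None if self.labels is None else self.labels[index],
        )

    def subset_features(self, keep: Sequence[int]) -> "CompositionTable":
        keep = np.asarray(keep)
        return CompositionTable(
            self.values[:, keep],
            list(self.sample_ids),
            [self.feature_ids[j] for j in keep],
            self.labels,
        )

    def with_values(self, values: np.ndarray) -> "CompositionTable":
        return replace(self, values=values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="sample_id")


def read_table(
    path: str | Path,
    label_column: str | None = None,
    labels_path: str | Path | None = None,
    sep: str | None = None,
) -> CompositionTable:
    """Read a count table (first column sample id, header of feature ids).

    Labels come either from ``label_column`` in the same file or from a
    separate two-column file ``labels_path`` (sample_id, group).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels = None
    if label_column is not None:
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    elif labels_path is not None:
        labels = read_labels(labels_path, df.index)
    table = CompositionTable(df.to_numpy(float), list(df.index), list(df.columns), labels)
    logger.info("read table %s: %d samples x %d features", path, *table.values.shape)
    return table


def read_labels(path: str | Path, sample_ids: Sequence[str]) -> np.ndarray:
    """Read a two-column (sample_id, group) file and align it to sample_ids."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    lab = pd.read_csv(path, sep=sep, index_col=0).iloc[:, 0]
    missing = [s for s in sample_ids if s not in lab.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    return lab.loc[list(sample_ids)].to_numpy()


def filter_features(
    table: CompositionTable,
    top_decile: bool = True,
    max_zero_fraction: float = 0.9,
) -> CompositionTable:
    """Drop features by abundance decile and zero prevalence.

    When ``top_decile`` is set, only the ceil(D/10) features with the largest
    column totals are retained (ties at the threshold are all kept); then any
    feature whose zero fraction strictly exceeds ``max_zero_fraction`` is
    dropped.  Feature order is preserved and the input is not modified.
    """
    if not 0 < max_zero_fraction < 1:
        raise ValueError("max_zero_fraction must lie in (0, 1)")
    d = table.n_features
    keep = np.arange(d)
    if top_decile:
        totals = table.values.sum(axis=0)
        k = int(np.ceil(d / 10))
        threshold = np.sort(totals)[::-1][k - 1]
        keep = keep[totals >= threshold]
        logger.info("decile filter: kept %d/%d features", len(keep), d)
    zero_frac = (table.values[:, keep] == 0).mean(axis=0)
    keep = keep[zero_frac <= max_zero_fraction]
    if len(keep) == 0:
        raise EmptyFeatureSetError("filtering removed every feature (empty feature set)")
    logger.info("zero-prevalence filter: kept %d/%d features", len(keep), d)
    return table.subset_features(keep)


def replace_zeros(table: CompositionTable, delta: float = 0.5) -> CompositionTable:
    """Multiplicative zero replacement on the count scale.

    Every zero cell becomes ``delta`` while the nonzero cells in that row are
    shrunk by a common factor so the row total is preserved.  Rows without
    zeros pass through unchanged.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = table.values.copy()
    zero = x == 0
    row_sums = x.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = np.flatnonzero(row_sums <= 0)[0]
        raise ValueError(
            f"sample {table.sample_ids[bad]!r} is entirely zero; "
            "multiplicative replacement is undefined"
        )
    n_zero = zero.sum(axis=1)
    nonzero_min = np.where(zero, np.inf, x).min(axis=1)
    if np.any((n_zero > 0) & (delta >= nonzero_min)):
        warnings.warn(
            "delta is not smaller than every nonzero entry; replaced zeros may "
            "outrank observed counts",
            stacklevel=2,
        )
    factor = (row_sums - delta * n_zero) / row_sums
    if np.any(factor <= 0):
        raise ValueError("delta too large: replacement would drive counts nonpositive")
    x = x * factor[:, None]
    x[zero] = delta
    logger.info("replaced %d zero cells with delta=%g", int(zero.sum()), delta)
    return table.with_values(x)


def closure(table: CompositionTable) -> CompositionTable:
    """Rescale each row to sum to 1 (the canonical proportion representation)."""
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("closure requires positive row sums")
    return table.with_values(table.values / sums[:, None])


def clr(table: CompositionTable) -> np.ndarray:
    """Centered log ratio transform: log of each part over the row geometric mean.

    Returns a real N x D matrix whose rows sum to zero; invariant to per-row
    rescaling.
    """
    x = table.values
    if np.any(x <= 0):
        raise ValueError(
            "CLR requires strictly positive entries; apply replace_zeros first"
        )
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def total_variance(table: CompositionTable) -> float:
    """Aitchison total variance: the sum of CLR component variances.

    Equals (1/2D) * sum of the pairwise log-ratio variance matrix; both are
    computed with the population convention (denominator N).
    """
    if table.n_samples < 2:
        raise ValueError("total variance needs at least 2 samples")
    z = clr(table)
    return float(z.var(axis=0, ddof=0).sum())
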