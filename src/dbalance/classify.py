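"""Split-resampled LASSO logistic regression benchmark.

The harness repeats a simple protocol over many random train/validation
splits: represent the composition (proportions, CLR, or balances from an
SBP built on the training rows only), fit an L1-penalized logistic
regression with the penalty tuned by stratified cross-validation over a
fixed log-spaced grid, score the held-out rows, and record the validation
AUC.  Medians over splits and pairwise rank-sum comparisons summarize how
the representations stack up.

The penalized fit minimizes

    (1/N) sum_i log(1 + exp(-y_i eta_i)) + lambda * ||w||_1

with an unpenalized intercept, solved by iteratively reweighted least
squares with coordinate descent and warm starts along the lambda path
(the standard algorithm for this problem).  Features are standardized to
unit variance internally and weights are reported on the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .balances import compute_balances
from .compositions import CompositionTable, closure, clr
from .sbp import build_sbp, distal_subset

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "FitResult",
    "BenchmarkResult",
    "METHOD_TAGS",
    "make_splits",
    "lambda_grid",
    "fit_l1_logistic",
    "tune_lambda",
    "evaluate_auc",
    "run_benchmark",
    "compare_methods",
]

BASE_METHODS = ("ACOMP", "CLR", "PBA", "ABA", "RBA", "DBA")
METHOD_TAGS = BASE_METHODS + tuple(f"{m}-distal" for m in ("PBA", "ABA", "RBA", "DBA"))


@dataclass
class SplitScheme:
    """A reproducible collection of stratified train/validation splits."""

    n_splits: int
    validation_fraction: float
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]


@dataclass
class FitResult:
    """A fitted penalized logistic model on the original feature scale."""

    weights: np.ndarray
    intercept: float
    lam: float
    classes: np.ndarray
    method: str | None = None
    auc: float | None = None

    def decision(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights + self.intercept

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Probability of the second (alphabetically larger) class."""
        return expit(self.decision(features))


@dataclass
class BenchmarkResult:
    """Tidy per-split, per-method AUC records."""

    records: pd.DataFrame = field(repr=False)

    def medians(self) -> pd.Series:
        return self.records.groupby("method", sort=False)["auc"].median()

    def aucs(self, method: str) -> np.ndarray:
        sub = self.records[self.records["method"] == method].sort_values("split")
        return sub["auc"].to_numpy()

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)


def make_splits(
    n_samples: int,
    labels: np.ndarray,
    n_splits: int = 50,
    validation_fraction: float = 0.33,
    seed: int = 0,
) -> SplitScheme:
    """Draw stratified random train/validation splits.

    The validation set size is round(validation_fraction * N); stratification
    keeps both groups in every training set.
    """
    labels = np.asarray(labels)
    if n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    if len(labels) != n_samples:
        raise ValueError("labels must match n_samples")
    n_val = int(round(validation_fraction * n_samples))
    sss = StratifiedShuffleSplit(n_splits=n_splits, test_size=n_val, random_state=seed)
    splits = []
    for train, val in sss.split(np.zeros(n_samples), labels):
        if len(np.unique(labels[train])) < 2:
            raise RuntimeError("training split lost a class despite stratification")
        splits.append((np.sort(train), np.sort(val)))
    return SplitScheme(n_splits, validation_fraction, seed, splits)


def lambda_grid(low: float = 0.001, high: float = 5.0, num: int = 100) -> np.ndarray:
    """Log-equispaced penalty grid from ``low`` to ``high`` inclusive."""
    return np.exp(np.linspace(np.log(low), np.log(high), num))


def _cd_path(
    x: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent path on already-standardized features.

    ``lambdas`` must be in decreasing order; fits are warm-started from the
    previous (larger) penalty.  Each quadratic approximation is solved with
    Gram-matrix ("covariance") updates so a sweep costs O(P^2) rather than
    O(N*P).  Returns (coefs with shape (L, P), intercepts).
    """
    n, p = x.shape
    ybar = y.mean()
    w = np.zeros(p)
    b = float(np.log(ybar / (1.0 - ybar)))
    coefs = np.empty((len(lambdas), p))
    intercepts = np.empty(len(lambdas))
    for li, lam in enumerate(lambdas):
        for _ in range(max_outer):
            w_old, b_old = w.copy(), b
            eta = b + x @ w
            prob = expit(eta)
            s = np.maximum(prob * (1.0 - prob), 1e-5)
            z = eta + (y - prob) / s  # working response
            sw = s / s.sum()
            xbar, zbar = sw @ x, float(sw @ z)
            xc = x - xbar
            sn = (s / n)[:, None]
            gram = xc.T @ (xc * sn)
            c = (xc * sn).T @ (z - zbar)
            diag = np.maximum(np.diag(gram).copy(), 1e-12)
            g = gram @ w
            for _sweep in range(200):
                sweep_delta = 0.0
                for j in range(p):
                    wj = w[j]
                    u = c[j] - g[j] + diag[j] * wj
                    new = np.sign(u) * max(abs(u) - lam, 0.0) / diag[j]
                    d = new - wj
                    if d != 0.0:
                        w[j] = new
                        g += gram[:, j] * d
                        sweep_delta = max(sweep_delta, abs(d))
                if sweep_delta < tol:
                    break
            b = zbar - float(xbar @ w)
            if max(float(np.abs(w - w_old).max()), abs(b - b_old)) < tol * 10:
                break
        coefs[li] = w
        intercepts[li] = b
    return coefs, intercepts


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd, mu, sd


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(np.asarray(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    return (np.asarray(labels) == classes[1]).astype(float), classes


def fit_l1_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    penalty: float,
    standardize: bool = True,
) -> FitResult:
    """Fit one L1-penalized logistic regression at a fixed penalty.

    The objective is mean logistic loss plus ``penalty`` times the L1 norm of
    the standardized-scale weights; the intercept is unpenalized.  Weights
    are reported on the original feature scale.
    """
    x = np.asarray(features, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    y, classes = _encode(labels)
    if standardize:
        xs, mu, sd = _standardize(x)
    else:
        xs, mu, sd = x, np.zeros(x.shape[1]), np.ones(x.shape[1])
    # short warm-started path down from the critical penalty for stability
    lam_max = np.abs(xs.T @ (y - y.mean())).max() / len(y)
    if penalty >= lam_max:
        path = np.array([penalty])
    else:
        path = np.geomspace(lam_max, penalty, num=8)
    coefs, intercepts = _cd_path(xs, y, path)
    w_std, b_std = coefs[-1], intercepts[-1]
    w = w_std / sd
    b = float(b_std - (w_std * mu / sd).sum())
    return FitResult(w, b, float(penalty), classes)


def tune_lambda(
    features: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the penalty minimizing mean cross-validated binomial deviance.

    Stratified ``n_folds``-fold CV; the path is fitted with warm starts from
    the largest penalty down.  Ties are broken toward the larger penalty
    (the sparser model).
    """
    if grid is None:
        grid = lambda_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    x = np.asarray(features, dtype=float)
    y, _ = _encode(labels)
    counts = np.bincount(y.astype(int))
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification failure: smallest class has {counts.min()} samples "
            f"for {n_folds}-fold CV"
        )
    desc = grid[::-1]
    deviance = np.zeros(len(grid))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(x, y):
        xs, mu, sd = _standardize(x[tr])
        coefs, intercepts = _cd_path(xs, y[tr], desc)
        xva = (x[va] - mu) / sd
        eta = xva @ coefs.T + intercepts  # (n_va, L)
        prob = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        yy = y[va][:, None]
        dev = -2.0 * (yy * np.log(prob) + (1 - yy) * np.log(1 - prob)).mean(axis=0)
        deviance += dev[::-1]  # back to ascending grid order
    deviance /= n_folds
    best = len(grid) - 1 - int(np.argmin(deviance[::-1]))  # ties -> larger lambda
    return float(grid[best])


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties at 1/2)."""
    y, _ = _encode(labels)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _method_features(
    table: CompositionTable,
    method: str,
    train_idx: np.ndarray,
    labels: np.ndarray,
    linkage: str,
    rba_seed: int,
    sbp_cache: dict,
) -> np.ndarray:
    """Build the N x P feature matrix for one method on one split.

    Proportions and CLR are per-row transforms (no leakage); SBPs are always
    constructed from the training rows only and the resulting balance rule
    is applied to every row.  The SBP is shared between a base method and
    its -distal variant via ``sbp_cache``.
    """
    base, _, suffix = method.partition("-")
    distal = suffix == "distal"
    base = base.upper()
    if base == "ACOMP":
        return closure(table).values
    if base == "CLR":
        return clr(table)
    if base not in ("PBA", "ABA", "RBA", "DBA"):
        raise ValueError(f"unknown method tag {method!r}")
    sbp = sbp_cache.get(base)
    if sbp is None:
        train_table = table.subset_samples(train_idx)
        sbp = build_sbp(
            train_table,
            base,
            labels=labels[train_idx] if base == "DBA" else None,
            seed=rba_seed if base == "RBA" else None,
            linkage=linkage,
        )
        sbp_cache[base] = sbp
    if distal:
        sbp = distal_subset(sbp)
    return compute_balances(table, sbp).values


def run_benchmark(
    table: CompositionTable,
    methods: list[str] | None = None,
    scheme: SplitScheme | None = None,
    labels: np.ndarray | None = None,
    n_splits: int = 50,
    validation_fraction: float = 0.33,
    seed: int = 0,
    linkage: str = "ward",
    grid: np.ndarray | None = None,
) -> BenchmarkResult:
    """Run the full split-resampled benchmark.

    For every split and method: build features (training-only SBPs), tune the
    penalty by 5-fold CV on the training rows, fit, score the validation
    rows, and record the AUC.  All methods see identical splits and identical
    CV folds, so differences are attributable to the representation.
    """
    if labels is None:
        labels = table.labels
    if labels is None:
        raise ValueError("benchmark requires binary labels")
    labels = np.asarray(labels)
    if methods is None:
        methods = list(METHOD_TAGS)
    unknown = [m for m in methods if m not in METHOD_TAGS]
    if unknown:
        raise ValueError(f"unknown method tags: {unknown}")
    if scheme is None:
        scheme = make_splits(
            table.n_samples, labels, n_splits, validation_fraction, seed
        )
    if grid is None:
        grid = lambda_grid()
    rows = []
    for s, (train, val) in enumerate(scheme.splits):
        cv_seed = (scheme.seed * 100_003 + 7 * s + 1) % (2**31)
        rba_seed = (scheme.seed * 999_983 + 13 * s + 3) % (2**31)
        sbp_cache: dict = {}
        for method in methods:
            feats = _method_features(
                table, method, train, labels, linkage, rba_seed, sbp_cache
            )
            lam = tune_lambda(feats[train], labels[train], grid, seed=cv_seed)
            fit = fit_l1_logistic(feats[train], labels[train], lam)
            auc = evaluate_auc(fit.decision(feats[val]), labels[val])
            rows.append({"split": s, "method": method, "lambda": lam, "auc": auc})
            logger.debug("split %d %s: lambda=%.4g auc=%.3f", s, method, lam, auc)
    return BenchmarkResult(pd.DataFrame(rows))


def _rank_sum_interval(
    a: np.ndarray, b: np.ndarray, conf_level: float
) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate with a rank-sum confidence interval.

    The estimate is the median of all cross differences a_i - b_j; the
    interval inverts the Mann-Whitney test via its normal approximation
    (the construction behind R's wilcox.test conf.int).
    """
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    n, m = len(a), len(b)
    est = float(np.median(diffs))
    z = norm.ppf(0.5 + conf_level / 2.0)
    spread = z * np.sqrt(n * m * (n + m + 1) / 12.0)
    k = int(np.floor(n * m / 2.0 - spread))
    k = max(k, 0)
    return est, float(diffs[k]), float(diffs[min(n * m - 1 - k, n * m - 1)])


def compare_methods(
    results: BenchmarkResult, conf_level: float = 0.95
) -> pd.DataFrame:
    """Pairwise method comparison over the split-resampled AUCs.

    Returns a tidy frame (method_a, method_b, median_diff, ci_low, ci_high)
    for every ordered pair; the median-difference table is antisymmetric.
    """
    methods = list(results.records["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    aucs = {m: results.aucs(m) for m in methods}
    counts = {m: len(v) for m, v in aucs.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"mismatched split counts across methods: {counts}")
    rows = []
    for ma in methods:
        for mb in methods:
            if ma == mb:
                est = lo = hi = 0.0
            else:
                est, lo, hi = _rank_sum_interval(aucs[ma], aucs[mb], conf_level)
            rows.append(
                {"method_a": ma, "method_b": mb, "median_diff": est,
                 "ci_low": lo, "ci_high": hi}
            )
    return pd.DataFrame(rows)
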