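"""Synthetic sequencing-style count data with planted discriminative ratios.

The generator follows a logistic-normal-multinomial model, the standard
compositional count model: each sample draws latent log-abundances from a
group-specific multivariate normal, closes them to proportions, and is then
multinomially sampled at a random (log-normal) library depth.  This
produces the sparsity, overdispersion, and depth variation that the
filtering and zero-replacement steps exist to handle, while keeping the
ground truth known: selected feature pairs receive a between-group shift of
size delta in their log-ratio mean, making them the planted discriminative
ratios every downstream stage should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compositions import CompositionTable
from .sbp import SBPMatrix

__all__ = ["SimulationSpec", "simulate_counts", "six_part_example"]


@dataclass
class SimulationSpec:
    """Parameters of the count simulation.

    Defaults emulate a modest targeted-sequencing study: two groups of 100
    samples, 30 features whose baseline log-abundances span several orders
    of magnitude, sample-level log-normal noise of scale ``sigma`` around
    the group mean, and log-normally distributed library depths around
    5000 reads so that rare features drop out as zeros.
    """

    n1: int = 100
    n2: int = 100
    n_features: int = 30
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    sigma: float = 0.5
    pair_rho: float = 0.5
    base_sigma: float = 2.0
    depth_mean: float = 5000.0
    depth_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 4:
            raise ValueError("need at least 4 features")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.depth_mean <= 0 or self.sigma < 0:
            raise ValueError("depths must be positive and sigma nonnegative")
        if not 0 <= self.pair_rho < 1:
            raise ValueError("pair_rho must lie in [0, 1)")
        used: set[int] = set()
        for j, k, delta in self.planted_pairs:
            if j == k or not (0 <= j < self.n_features) or not (0 <= k < self.n_features):
                raise ValueError(f"invalid planted pair ({j}, {k})")
            if not np.isfinite(delta):
                raise ValueError("planted shifts must be finite")
            if j in used or k in used:
                raise ValueError("planted pairs must be disjoint")
            used.update((j, k))


def simulate_counts(spec: SimulationSpec) -> tuple[CompositionTable, dict]:
    """Draw a labeled count table and its ground-truth record.

    Each planted pair is a differentially proportional module: its two
    members share a latent noise component (correlation ``pair_rho``), so
    they covary within groups, and group 2 receives a +delta/2 / -delta/2
    mean offset on the members, shifting the pair's log-ratio mean by delta
    between groups.  The shared component is what makes the planted pair
    itself (rather than a cross-pairing of up- and down-shifted features,
    whose ratio mean also moves by delta) the uniquely most discriminative
    pair: its log ratio has the smallest within-group variance.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    base = rng.normal(0.0, spec.base_sigma, size=d)
    offset = np.zeros(d)
    for j, k, delta in spec.planted_pairs:
        # anchor planted features at the centre of the abundance range so
        # the planted ratio is observable at the simulated depth; a signal
        # planted in a feature that is almost never sequenced has no
        # operational ground truth
        base[j] = base[k] = 0.0
        offset[j] += delta / 2.0
        offset[k] -= delta / 2.0
    n = spec.n1 + spec.n2
    group2 = np.arange(n) >= spec.n1
    means = base + np.where(group2[:, None], offset[None, :], 0.0)
    noise = rng.normal(0.0, spec.sigma, size=(n, d))
    rho = spec.pair_rho
    for j, k, _delta in spec.planted_pairs:
        shared = rng.normal(0.0, spec.sigma, size=n)
        noise[:, j] = np.sqrt(1 - rho) * noise[:, j] + np.sqrt(rho) * shared
        noise[:, k] = np.sqrt(1 - rho) * noise[:, k] + np.sqrt(rho) * shared
    latent = means + noise
    props = np.exp(latent - latent.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    mu = np.log(spec.depth_mean) - spec.depth_sigma**2 / 2.0
    depths = np.maximum(rng.lognormal(mu, spec.depth_sigma, size=n).round(), 10).astype(int)
    counts = np.vstack([rng.multinomial(dep, p) for dep, p in zip(depths, props)])
    labels = np.where(group2, "g2", "g1")
    table = CompositionTable(counts.astype(float), None, None, labels)
    truth = {
        "planted_pairs": [
            {
                "features": [table.feature_ids[j], table.feature_ids[k]],
                "indices": [j, k],
                "delta": float(delta),
            }
            for j, k, delta in spec.planted_pairs
        ],
        "seed": spec.seed,
        "group_sizes": [spec.n1, spec.n2],
    }
    return table, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def six_part_example() -> tuple[CompositionTable, SBPMatrix]:
    """A hand-built six-feature example table and its partition.

    The partition first splits {a, e} from {b, c, d, f}, then peels c off
    {b, d, f}, then b off {d, f}; the distal balances are a|e, d|f and the
    3-part contrast b versus (d, f).  The first sample carries the abundances
    x_b = 3, x_d = 4, x_f = 5 used as the package's worked example.
    """
    features = ["a", "b", "c", "d", "e", "f"]
    #              z1  z2  z3  z4  z5   (root-first)
    signs = np.array(
        [
            [+1,  0,  0,  0, +1],  # a
            [-1, +1, +1,  0,  0],  # b
            [-1, -1,  0,  0,  0],  # c
            [-1, +1, -1, +1,  0],  # d
            [+1,  0,  0,  0, -1],  # e
            [-1, +1, -1, -1,  0],  # f
        ]
    )
    sbp = SBPMatrix(signs, features, heights=np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
    values = np.array(
        [
            [1.0, 3.0, 2.0, 4.0, 1.0, 5.0],
            [2.0, 1.0, 4.0, 2.0, 3.0, 1.0],
            [5.0, 2.0, 1.0, 3.0, 4.0, 2.0],
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        ]
    )
    table = CompositionTable(values, ["s1", "s2", "s3", "s4"], features)
    return table, sbp
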