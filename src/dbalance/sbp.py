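"""Serial binary partitions (SBPs): construction, validation, and trees.

An SBP recursively splits D features into two blocks until every block is a
singleton, yielding D-1 binary contrasts.  It is stored as a D x (D-1) sign
matrix: column z marks the numerator parts of balance z with +1, the
denominator parts with -1, and uninvolved parts with 0.  The first column is
the "trunk" (all D parts); the last columns are the distal "leaves" (2- and
3-part balances).

Four constructions are provided, all by agglomerative clustering of a
pairwise dissimilarity except the random one:

* PBA  - cluster the log-ratio variance matrix T: near-proportional pairs
  merge first, so the trunk approximates the principal balance (most
  variance) and the leaves the least.
* ABA  - cluster max(T) - T: the orientation is reversed, the leaves carry
  the most variance.
* RBA  - a uniformly random binary topology (seeded), as a null reference.
* DBA  - cluster the differential proportionality matrix theta: the most
  discriminative pairs (smallest theta) merge first and land distally,
  making the 2- and 3-part balances the best group separators.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .compositions import CompositionTable
from .variation import theta_matrix, variation_matrix

__all__ = [
    "SBPMatrix",
    "SBPMatrixSubset",
    "MergeTree",
    "build_sbp",
    "sbp_from_tree",
    "distal_subset",
    "sbp_to_newick",
    "sbp_from_newick",
    "linkage_matrix",
]

LINKAGES = ("ward", "average", "complete")


@dataclass
class MergeTree:
    """A binary merge sequence over named leaves, scipy-linkage style.

    Nodes 0..D-1 are the leaves in ``leaf_names`` order; merge k creates node
    D+k from the two listed child nodes at the given height.  Children always
    appear before their parent in the merge list.
    """

    leaf_names: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a binary tree over D leaves has exactly D-1 merges")


@dataclass
class SBPMatrix:
    """D x (D-1) sign matrix encoding a serial binary partition."""

    signs: np.ndarray
    feature_ids: list[str]
    heights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        self.validate()

    @property
    def n_features(self) -> int:
        return self.signs.shape[0]

    @property
    def n_balances(self) -> int:
        return self.signs.shape[1]

    @property
    def balance_ids(self) -> list[str]:
        return [f"z{z+1}" for z in range(self.n_balances)]

    def parts_per_balance(self) -> np.ndarray:
        return (self.signs != 0).sum(axis=0)

    def validate(self) -> None:
        """Check the serial property by replaying the partition refinement.

        Starting from the single block of all features, each column's nonzero
        support must equal one current block, which it splits into its +1 and
        -1 sub-blocks; after D-1 columns every block is a singleton.
        """
        d, z = self.signs.shape
        if d < 2:
            raise ValueError("an SBP needs at least 2 features")
        if z != d - 1:
            raise ValueError(f"expected {d - 1} balance columns, got {z}")
        if len(self.feature_ids) != d or len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids must be unique, one per SBP row")
        if not np.isin(self.signs, (-1, 0, 1)).all():
            raise ValueError("SBP entries must be in {-1, 0, +1}")
        blocks = {frozenset(range(d))}
        for col in self.signs.T:
            plus = frozenset(np.flatnonzero(col == 1))
            minus = frozenset(np.flatnonzero(col == -1))
            if not plus or not minus:
                raise ValueError("every balance needs >= 1 positive and negative part")
            support = plus | minus
            if support not in blocks:
                raise ValueError(
                    "serial property violated: a column's support is not a block "
                    "of the partition induced by the earlier columns"
                )
            blocks.remove(support)
            blocks.add(plus)
            blocks.add(minus)
        if any(len(b) != 1 for b in blocks):
            raise ValueError("SBP does not resolve all features into singletons")

    def subset_columns(self, cols: np.ndarray) -> "SBPMatrixSubset":
        cols = np.asarray(cols)
        return SBPMatrixSubset(
            self.signs[:, cols],
            list(self.feature_ids),
            [f"z{c+1}" for c in cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.signs, index=self.feature_ids, columns=self.balance_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "SBPMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(int), [str(i) for i in df.index])


@dataclass
class SBPMatrixSubset:
    """A column subset of an SBP (e.g. the distal balances).

    Not a full partition, so the serial validator does not apply; each column
    must still contrast two nonempty blocks.
    """

    signs: np.ndarray
    feature_ids: list[str]
    balance_ids: list[str]

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        for col in self.signs.T:
            if not (col == 1).any() or not (col == -1).any():
                raise ValueError("every balance needs >= 1 positive and negative part")

    @property
    def n_features(self) -> int:
        return self.signs.shape[0]

    @property
    def n_balances(self) -> int:
        return self.signs.shape[1]

    def parts_per_balance(self) -> np.ndarray:
        return (self.signs != 0).sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.signs, index=self.feature_ids, columns=self.balance_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def linkage_matrix(
    dissimilarity: np.ndarray, linkage: str = "ward"
) -> list[tuple[int, int, float]]:
    """Agglomerative clustering of a precomputed dissimilarity.

    Lance-Williams updates for ward, average, or complete linkage, applied
    directly to the supplied dissimilarities.  Ties are broken by the
    smallest (row, column) node-index pair so results are fully deterministic
    regardless of input permutation history.  Returns scipy-style merges
    (node ids i < j, merge height).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    diss = np.asarray(dissimilarity, dtype=float)
    n = diss.shape[0]
    if diss.ndim != 2 or diss.shape != (n, n) or not np.isfinite(diss).all():
        raise ValueError("dissimilarity must be a finite square matrix")
    total = 2 * n - 1
    big = np.full((total, total), np.inf)
    big[:n, :n] = np.where(np.triu(np.ones((n, n), bool), 1), diss, np.inf)
    sizes = np.ones(total, dtype=int)
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        new = n + step
        flat = int(np.argmin(big[:new, :new]))  # row-major => smallest (i, j) on ties
        i, j = divmod(flat, new)
        h = float(big[i, j])
        ni, nj = int(sizes[i]), int(sizes[j])
        active[i] = active[j] = False
        ks = np.flatnonzero(active[:new])
        dik = np.where(ks < i, big[ks, i], big[i, ks])
        djk = np.where(ks < j, big[ks, j], big[j, ks])
        nk = sizes[ks]
        if linkage == "ward":
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
        elif linkage == "average":
            dnew = (ni * dik + nj * djk) / (ni + nj)
        else:  # complete
            dnew = np.maximum(dik, djk)
        big[ks, new] = dnew
        big[i, :] = big[:, i] = np.inf
        big[j, :] = big[:, j] = np.inf
        active[new] = True
        sizes[new] = ni + nj
        merges.append((i, j, h))
    return merges


def _aba_dissimilarity(t: np.ndarray) -> np.ndarray:
    off = ~np.eye(t.shape[0], dtype=bool)
    d = t[off].max() - t
    np.fill_diagonal(d, 0.0)
    return d


def _random_merges(d: int, rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """Uniformly random recursive bipartition of d leaves.

    Every nonempty proper split of a block is equally likely (rejection
    sampling on iid signs).  Heights are block sizes, so parents always sit
    strictly above their children; the post-order emission gives the scipy
    id convention.
    """

    def split(members: np.ndarray):
        if len(members) == 1:
            return int(members[0])
        while True:
            mask = rng.integers(0, 2, size=len(members)).astype(bool)
            if 0 < mask.sum() < len(members):
                break
        return (split(members[mask]), split(members[~mask]), len(members))

    merges: list[tuple[int, int, float]] = []

    def emit(node) -> int:
        if isinstance(node, int):
            return node
        left, right = emit(node[0]), emit(node[1])
        merges.append((min(left, right), max(left, right), float(node[2])))
        return d + len(merges) - 1

    emit(split(np.arange(d)))
    return merges


def build_sbp(
    table: CompositionTable,
    method: str,
    labels: np.ndarray | None = None,
    seed: int | None = None,
    linkage: str = "ward",
    invert: bool = False,
) -> SBPMatrix:
    """Construct an SBP by one of the four partition procedures.

    Parameters
    ----------
    method : {"PBA", "ABA", "RBA", "DBA"}
    labels : binary groups, required for DBA (the only supervised method);
        falls back to ``table.labels``.
    seed : required for RBA.
    linkage : agglomeration rule applied to the dissimilarity.
    invert : DBA only; cluster 1 - theta instead of theta, which moves the
        balances with the largest between-group variance to the trunk
        (the ordination-oriented variant).
    """
    method = method.upper()
    if method == "RBA":
        if seed is None:
            raise ValueError("RBA requires a seed")
        merges = _random_merges(table.n_features, np.random.default_rng(seed))
        return sbp_from_tree(MergeTree(list(table.feature_ids), merges))
    if method == "PBA":
        diss = variation_matrix(table).values
    elif method == "ABA":
        diss = _aba_dissimilarity(variation_matrix(table).values)
    elif method == "DBA":
        if labels is None and table.labels is None:
            raise ValueError("DBA is supervised and requires binary labels")
        theta = theta_matrix(table, labels).values.copy()
        if invert:
            theta = 1.0 - theta
        np.fill_diagonal(theta, 0.0)
        diss = theta
    else:
        raise ValueError(f"unknown SBP method {method!r}")
    if not np.isfinite(diss).all():
        raise ValueError("dissimilarity contains non-finite values")
    merges = linkage_matrix(diss, linkage=linkage)
    return sbp_from_tree(MergeTree(list(table.feature_ids), merges))


def sbp_from_tree(tree: MergeTree) -> SBPMatrix:
    """Convert a binary merge tree to its SBP sign matrix.

    Columns are ordered root-first (descending merge height; later merges
    first on ties, which keeps parents ahead of equal-height children), so
    column 1 is the trunk balance over all D parts.  Within a column the
    sub-block containing the smallest feature index is oriented +1;
    orientation only flips balance signs, never magnitudes.
    """
    d = tree.n_leaves
    leaf_sets: dict[int, np.ndarray] = {i: np.array([i]) for i in range(d)}
    columns = []
    for k, (i, j, h) in enumerate(tree.merges):
        li, lj = leaf_sets[i], leaf_sets[j]
        leaf_sets[d + k] = np.concatenate([li, lj])
        col = np.zeros(d, dtype=int)
        if li.min() < lj.min():
            col[li], col[lj] = 1, -1
        else:
            col[lj], col[li] = 1, -1
        columns.append((h, k, col))
    columns.sort(key=lambda c: (-c[0], -c[1]))
    signs = np.stack([c[2] for c in columns], axis=1)
    heights = np.array([c[0] for c in columns])
    return SBPMatrix(signs, list(tree.leaf_names), heights)


def distal_subset(sbp: SBPMatrix, max_parts: int = 3) -> SBPMatrixSubset:
    """Keep only the distal balances: columns with 2..max_parts nonzero parts.

    With the default max_parts=3 these are the cherries (2-part log ratios)
    and singleton-versus-cherry nodes (3-part contrasts) at the leaves of
    the partition dendrogram.
    """
    if max_parts < 2:
        raise ValueError("max_parts must be >= 2")
    parts = sbp.parts_per_balance()
    cols = np.flatnonzero((parts >= 2) & (parts <= max_parts))
    if len(cols) == 0:
        raise ValueError("no balance has between 2 and max_parts parts (empty selection)")
    return sbp.subset_columns(cols)


def _sbp_splits(sbp: SBPMatrix) -> dict[frozenset, tuple[frozenset, frozenset]]:
    """Map each split block to its (+1 sub-block, -1 sub-block)."""
    splits = {}
    for col in sbp.signs.T:
        plus = frozenset(np.flatnonzero(col == 1))
        minus = frozenset(np.flatnonzero(col == -1))
        splits[plus | minus] = (plus, minus)
    return splits


def sbp_to_newick(sbp: SBPMatrix) -> str:
    """Serialize the partition dendrogram implied by an SBP as Newick."""
    splits = _sbp_splits(sbp)
    names = sbp.feature_ids

    def render(block: frozenset) -> str:
        if len(block) == 1:
            (i,) = block
            return names[i]
        plus, minus = splits[block]
        return f"({render(plus)},{render(minus)})"

    return render(frozenset(range(sbp.n_features))) + ";"


def sbp_from_newick(newick: str) -> SBPMatrix:
    """Parse a binary Newick tree into an SBP sign matrix.

    Merge heights come from branch lengths when present, otherwise from the
    merge rank (subtree leaf counts); either way parents sit at or above
    their children, preserving the root-first column order.
    """
    tree = TreeNode.read(io.StringIO(newick))
    for node in tree.non_tips(include_self=True):
        if len(node.children) != 2:
            raise ValueError("SBP trees must be strictly binary")
    leaves = [t.name for t in tree.tips()]
    if any(n is None for n in leaves) or len(set(leaves)) != len(leaves):
        raise ValueError("leaves must carry unique names")
    index = {name: i for i, name in enumerate(leaves)}
    d = len(leaves)
    has_lengths = any(t.length is not None for t in tree.postorder())
    merges: list[tuple[int, int, float]] = []

    def emit(node) -> tuple[int, float, int]:
        """Post-order; returns (scipy node id, height, leaf count)."""
        if node.is_tip():
            return index[node.name], 0.0, 1
        (a, ha, ca), (b, hb, cb) = (emit(c) for c in node.children)
        if has_lengths:
            la = node.children[0].length or 0.0
            lb = node.children[1].length or 0.0
            h = max(ha + la, hb + lb)
        else:
            h = float(ca + cb)
        merges.append((min(a, b), max(a, b), h))
        return d + len(merges) - 1, h, ca + cb

    emit(tree)
    return sbp_from_tree(MergeTree(leaves, merges))
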