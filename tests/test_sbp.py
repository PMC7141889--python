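import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from dbalance import (
    CompositionTable,
    MergeTree,
    SBPMatrix,
    build_sbp,
    compute_balances,
    distal_subset,
    sbp_from_newick,
    sbp_from_tree,
    sbp_to_newick,
    total_variance,
)
from dbalance.sbp import linkage_matrix


def random_positive_table(rng, n=12, d=8, labels=False):
    lab = None
    if labels:
        lab = np.array(["a", "b"])[rng.integers(0, 2, n)]
        lab[:2], lab[-2:] = "a", "b"  # guarantee two per group
    return CompositionTable(rng.lognormal(size=(n, d)), labels=lab)


class TestLinkage:
    def test_matches_scipy_on_distinct_distances(self, rng):
        # average and complete linkage share scipy's semantics exactly
        pts = rng.normal(size=(9, 3))
        diss = squareform(squareform(((pts[:, None] - pts[None]) ** 2).sum(-1)))
        for method in ("average", "complete"):
            ours = linkage_matrix(diss, linkage=method)
            theirs = scipy_linkage(squareform(diss), method=method)
            for (i, j, h), row in zip(ours, theirs):
                assert {i, j} == {int(row[0]), int(row[1])}
                assert h == pytest.approx(row[2], rel=1e-10)

    def test_tie_break_is_smallest_index_pair(self):
        diss = np.ones((4, 4)) - np.eye(4)  # all pairs tied
        merges = linkage_matrix(diss, linkage="complete")
        assert merges[0][:2] == (0, 1)

    def test_rejects_nonfinite(self):
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = np.inf
        with pytest.raises(ValueError):
            linkage_matrix(bad)


class TestSBPMatrixValidation:
    def test_fixture_passes_serial_validator(self, toy):
        _, sbp = toy
        sbp.validate()  # no exception

    def test_column_without_negative_part_rejected(self):
        signs = np.array([[1, 1], [1, 1], [-1, 0]])
        with pytest.raises(ValueError):
            SBPMatrix(signs, ["a", "b", "c"])

    def test_non_serial_support_rejected(self):
        # second column spans features from both blocks of the first split
        signs = np.array([[1, 1, 0], [1, -1, 0], [-1, 0, 1], [-1, 0, -1]])
        signs = signs[:, [0, 1, 2]]
        bad = signs.copy()
        bad[:, 1] = [1, 0, -1, 0]  # mixes the two root blocks
        with pytest.raises(ValueError, match="serial"):
            SBPMatrix(bad, list("abcd"))


class TestBuildSBP:
    def test_pba_puts_proportional_pair_in_a_cherry(self, rng):
        x = rng.lognormal(size=(15, 1))
        other = rng.lognormal(size=(15, 4))
        values = np.hstack([x, other[:, :2], 3.0 * x, other[:, 2:]])
        table = CompositionTable(values)  # features f1 and f4 proportional
        sbp = build_sbp(table, "PBA")
        two_part = [set(np.flatnonzero(col)) for col in sbp.signs.T
                    if (col != 0).sum() == 2]
        assert {0, 3} in two_part

    def test_dba_puts_discriminative_pair_in_a_cherry(self, planted_table):
        table, truth = planted_table
        sbp = build_sbp(table, "DBA")
        cherries = [set(np.flatnonzero(col)) for col in sbp.signs.T
                    if (col != 0).sum() == 2]
        planted = [set(p["indices"]) for p in truth["planted_pairs"]]
        assert any(p in cherries for p in planted)

    def test_dba_requires_labels(self, random_table):
        with pytest.raises(ValueError, match="supervised|labels"):
            build_sbp(random_table, "DBA")

    def test_rba_deterministic_and_varied(self, rng):
        table = random_positive_table(rng, n=6, d=6)
        a = build_sbp(table, "RBA", seed=7)
        b = build_sbp(table, "RBA", seed=7)
        np.testing.assert_array_equal(a.signs, b.signs)
        assert a.n_balances == 5
        topologies = {
            tuple(map(tuple, build_sbp(table, "RBA", seed=s).signs))
            for s in range(12)
        }
        assert len(topologies) > 1
        with pytest.raises(ValueError, match="seed"):
            build_sbp(table, "RBA")

    @pytest.mark.parametrize("method", ["PBA", "ABA", "RBA", "DBA"])
    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    def test_all_constructions_yield_valid_sbps(self, rng, method, linkage):
        table = random_positive_table(rng, n=14, d=9, labels=method == "DBA")
        sbp = build_sbp(table, method, seed=3, linkage=linkage)
        sbp.validate()
        assert (sbp.signs[:, 0] != 0).all()  # trunk involves every part

    def test_trunk_variance_dominates_for_pba(self, rng):
        # the first principal-balance approximation should hold at least
        # the average per-balance share of the total variance
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            table = CompositionTable(r.lognormal(0, 1, size=(20, 8)))
            sbp = build_sbp(table, "PBA")
            coords = compute_balances(table, sbp).values
            variances = coords.var(axis=0)
            if variances[0] >= variances.mean():
                hits += 1
        assert hits >= 9

    def test_permutation_equivariance(self, rng):
        table = random_positive_table(rng, n=10, d=7)
        perm = rng.permutation(7)
        permuted = CompositionTable(
            table.values[:, perm], feature_ids=[table.feature_ids[j] for j in perm]
        )
        a = build_sbp(table, "PBA").to_dataframe().sort_index()
        b = build_sbp(permuted, "PBA").to_dataframe().sort_index()
        np.testing.assert_array_equal(np.abs(a.to_numpy()), np.abs(b.to_numpy()))


class TestDistalSubset:
    def test_fixture_distal_columns(self, toy):
        _, sbp = toy
        distal = distal_subset(sbp)
        assert distal.n_balances == 3
        assert list(distal.parts_per_balance()) == [3, 2, 2]

    def test_two_feature_sbp_keeps_its_column(self):
        sbp = SBPMatrix(np.array([[1], [-1]]), ["a", "b"])
        assert distal_subset(sbp).n_balances == 1

    def test_larger_columns_excluded(self, toy):
        _, sbp = toy
        parts = distal_subset(sbp, max_parts=3).parts_per_balance()
        assert parts.max() <= 3

    def test_every_full_sbp_has_a_cherry(self, rng):
        # the final merge of two singletons guarantees a 2-part balance,
        # so the distal subset of a full SBP is never empty
        for seed in range(5):
            table = random_positive_table(rng, n=6, d=8)
            sbp = build_sbp(table, "RBA", seed=seed)
            assert distal_subset(sbp, max_parts=2).n_balances >= 1


class TestTreesAndNewick:
    def test_fixture_topology_first_split(self, toy):
        _, sbp = toy
        col = sbp.signs[:, 0]
        idx = {f: i for i, f in enumerate(sbp.feature_ids)}
        assert col[idx["a"]] == col[idx["e"]]
        assert col[idx["b"]] == col[idx["c"]] == col[idx["d"]] == col[idx["f"]]
        assert col[idx["a"]] != col[idx["b"]]

    def test_two_leaf_tree(self):
        tree = MergeTree(["a", "b"], [(0, 1, 1.0)])
        sbp = sbp_from_tree(tree)
        np.testing.assert_array_equal(sbp.signs, [[1], [-1]])
        assert sbp_to_newick(sbp) == "(a,b);"

    def test_newick_roundtrip_preserves_topology(self, rng):
        # equal-height columns may come back permuted, so compare the sets
        # of splits (each split keeps its sign orientation)
        def split_set(sbp):
            return {
                (
                    frozenset(sbp.feature_ids[i] for i in np.flatnonzero(col == 1)),
                    frozenset(sbp.feature_ids[i] for i in np.flatnonzero(col == -1)),
                )
                for col in sbp.signs.T
            }

        table = random_positive_table(rng, n=8, d=7)
        for seed in range(5):
            sbp = build_sbp(table, "RBA", seed=seed)
            back = sbp_from_newick(sbp_to_newick(sbp))
            back.validate()
            assert split_set(back) == split_set(sbp)

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            sbp_from_newick("(a,(b,c);")

    def test_nonbinary_tree_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            sbp_from_newick("(a,b,c);")

    def test_any_tree_gives_d_minus_one_columns(self, rng):
        for d in (2, 4, 6, 9):
            table = random_positive_table(rng, n=6, d=d)
            sbp = build_sbp(table, "RBA", seed=d)
            assert sbp.n_balances == d - 1


def test_orientation_flip_changes_sign_only(toy):
    table, sbp = toy
    flipped = SBPMatrix(sbp.signs * np.where(np.arange(5) == 2, -1, 1),
                        list(sbp.feature_ids))
    a = compute_balances(table, sbp).values
    b = compute_balances(table, flipped).values
    np.testing.assert_allclose(b[:, 2], -a[:, 2], atol=1e-12)
    np.testing.assert_allclose(np.delete(b, 2, 1), np.delete(a, 2, 1), atol=1e-12)
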