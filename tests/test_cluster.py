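"""Pearson-distance complete-linkage clustering and bootstrap support."""

import numpy as np
import pandas as pd
import pytest

import icrcall as ic
from icrcall.exceptions import InputError, UndefinedCorrelationError
from conftest import brute_force_complete_linkage, make_truths, random_distance_matrix


def frame(rows, index=None):
    idx = index or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx)


class TestPearsonDistance:
    def test_identical_profiles_distance_zero(self):
        D = ic.pearson_distance(frame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]]))
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reflected_profile_distance_two(self):
        D = ic.pearson_distance(frame([[0.1, 0.5, 0.9], [0.9, 0.5, 0.1]]))
        assert D.iloc[0, 1] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        D = ic.pearson_distance(frame(rng.random((5, 10))))
        M = D.to_numpy()
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 0)
        assert M.min() >= 0 and M.max() <= 2

    def test_constant_profile_named_in_error(self):
        with pytest.raises(UndefinedCorrelationError, match="flatliner"):
            ic.pearson_distance(
                frame([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]],
                      index=["flatliner", "ok"])
            )


class TestCompleteLinkage:
    def test_two_samples_single_merge_at_distance(self):
        D = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = ic.complete_linkage(D)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.3)

    def test_three_sample_hand_execution(self):
        labels = ["A", "B", "C"]
        D = pd.DataFrame(
            [[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]],
            index=labels, columns=labels,
        )
        tree = ic.complete_linkage(D)
        sets = tree.cluster_leaf_sets()
        assert sets[0] == frozenset({"A", "B"})
        assert tree.merges[0, 2] == pytest.approx(0.1)
        assert tree.merges[1, 2] == pytest.approx(1.0)

    def test_two_blob_distances(self):
        labels = list("abcd")
        # blobs {a,b} and {c,d}: tight within, far across
        D = np.array(
            [
                [0.0, 0.1, 1.8, 1.9],
                [0.1, 0.0, 1.7, 1.6],
                [1.8, 1.7, 0.0, 0.15],
                [1.9, 1.6, 0.15, 0.0],
            ]
        )
        tree = ic.complete_linkage(pd.DataFrame(D, index=labels, columns=labels))
        heights = sorted(tree.merges[:, 2])
        assert heights[0] < 0.2 and heights[1] < 0.2 and heights[2] > 1.5

    def test_nan_distance_rejected(self):
        D = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(InputError):
            ic.complete_linkage(D)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_agrees_with_brute_force_oracle(self, n):
        """Merge sequence and heights match a naive agglomeration."""
        rng = np.random.default_rng(100 + n)
        D = random_distance_matrix(n, rng)
        labels = [str(i) for i in range(n)]
        tree = ic.complete_linkage(pd.DataFrame(D, index=labels, columns=labels))
        expected = brute_force_complete_linkage(D)
        got_sets = tree.cluster_leaf_sets()
        for k, (a, b, h) in enumerate(expected):
            merged = frozenset(str(i) for i in a | b)
            assert got_sets[k] == merged
            assert tree.merges[k, 2] == pytest.approx(h)

    def test_cophenetic_dominates_pairwise_distance(self):
        rng = np.random.default_rng(5)
        D = random_distance_matrix(7, rng)
        labels = [str(i) for i in range(7)]
        tree = ic.complete_linkage(pd.DataFrame(D, index=labels, columns=labels))
        C = tree.cophenetic().to_numpy()
        assert (C + 1e-9 >= D).all()

    def test_column_permutation_leaves_tree_invariant(self):
        truths = make_truths({ic.Genotype.NORMAL: 4, ic.Genotype.ICR1_GOM: 4})
        bm = ic.simulate_beta_cohort(truths, seed=9)
        rng = np.random.default_rng(1)
        perm = bm.beta.iloc[:, rng.permutation(bm.beta.shape[1])]
        t1 = ic.complete_linkage(ic.pearson_distance(bm.beta))
        t2 = ic.complete_linkage(ic.pearson_distance(perm))
        assert np.allclose(t1.merges, t2.merges)


class TestCut:
    @pytest.fixture
    def tree(self):
        rng = np.random.default_rng(2)
        D = random_distance_matrix(6, rng)
        labels = [f"s{i}" for i in range(6)]
        return ic.complete_linkage(pd.DataFrame(D, index=labels, columns=labels))

    def test_k_equals_n_singletons(self, tree):
        labels = tree.cut(6)
        assert sorted(labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_one_single_group(self, tree):
        assert set(tree.cut(1).values()) == {1}

    def test_k_out_of_range(self, tree):
        with pytest.raises(InputError):
            tree.cut(0)
        with pytest.raises(InputError):
            tree.cut(7)

    def test_two_blob_cut_matches_planted_genotypes(self):
        truths = make_truths({ic.Genotype.NORMAL: 5, ic.Genotype.ICR1_GOM: 5})
        bm = ic.simulate_beta_cohort(truths, seed=4)
        tree = ic.complete_linkage(ic.pearson_distance(bm.beta))
        labels = tree.cut(2)
        normals = {labels[t.sample_id] for t in truths[:5]}
        goms = {labels[t.sample_id] for t in truths[5:]}
        assert len(normals) == 1 and len(goms) == 1 and normals != goms


class TestBootstrapConsistency:
    def test_root_cluster_always_supported(self):
        truths = make_truths({ic.Genotype.NORMAL: 3, ic.Genotype.ICR1_GOM: 3})
        bm = ic.simulate_beta_cohort(truths, seed=2)
        cons = ic.bootstrap_consistency(bm.beta, n_bootstrap=50, seed=0)
        root = frozenset(bm.sample_ids)
        assert cons.proportions[root] == 1.0

    def test_fixed_seed_reproducible(self):
        truths = make_truths({ic.Genotype.NORMAL: 4, ic.Genotype.ICR1_GOM: 4})
        bm = ic.simulate_beta_cohort(truths, seed=2)
        a = ic.bootstrap_consistency(bm.beta, n_bootstrap=60, seed=5)
        b = ic.bootstrap_consistency(bm.beta, n_bootstrap=60, seed=5)
        assert a.proportions == b.proportions

    def test_too_few_columns_rejected(self):
        df = pd.DataFrame({"c": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        with pytest.raises(InputError):
            ic.bootstrap_consistency(df, n_bootstrap=10, seed=0)


class TestNewickExport:
    def test_round_trips_through_dendropy(self):
        truths = make_truths({ic.Genotype.NORMAL: 3, ic.Genotype.ICR1_GOM: 3})
        bm = ic.simulate_beta_cohort(truths, seed=6)
        tree = ic.complete_linkage(ic.pearson_distance(bm.beta))
        import dendropy

        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                   preserve_underscores=True)
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(bm.sample_ids)
        # root-to-leaf path length equals the final merge height everywhere
        root_h = tree.merges[-1, 2]
        for leaf in parsed.leaf_node_iter():
            dist = leaf.distance_from_root()
            assert dist == pytest.approx(root_h, rel=1e-5)
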