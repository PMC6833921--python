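import numpy as np
import pytest

from scgnmf import (
    SolverConfig,
    assign_classes,
    factorize,
    membership_matrix,
    planted_matrix,
    sample_correlation,
    select_rank,
    shared_genes,
    top_genes,
)
from scgnmf.errors import UnassignableSampleError, UndefinedMembershipError

from conftest import true_partition


class TestMembershipMatrix:
    def test_single_class_gives_all_ones(self, rng):
        W = rng.random((5, 1)) + 0.1
        H = rng.random((1, 3)) + 0.1
        R = membership_matrix(W, H)
        np.testing.assert_allclose(R.R, np.ones((1, 3)))

    def test_two_gene_identity_case(self):
        # disjoint genes: per-gene shares are (1,0) and (0,1); average 0.5
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        H = np.array([[2.0], [1.0]])
        R = membership_matrix(W, np.column_stack([H, H]))
        np.testing.assert_allclose(R.R[:, 0], [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((20, 4))
        H = rng.random((4, 6))
        R = membership_matrix(W, H)
        np.testing.assert_allclose(R.R.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(R.R >= 0) and np.all(R.R <= 1 + 1e-12)

    def test_zero_reconstruction_sample_rejected(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        H = np.array([[1.0, 0.0], [0.0, 0.0]])  # sample 2 reconstructs to zero
        with pytest.raises(UndefinedMembershipError, match="s2"):
            membership_matrix(W, H, sample_ids=("s1", "s2"))

    def test_zero_denominator_genes_excluded(self):
        # gene 2 reconstructs to zero for sample 1 but not sample 2
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        H = np.array([[1.0, 1.0], [0.0, 1.0]])
        R = membership_matrix(W, H)
        assert R.included_gene_count[0] == 1
        assert R.included_gene_count[1] == 2
        np.testing.assert_allclose(R.R.sum(axis=0), 1.0, atol=1e-12)


class TestAssignClasses:
    # membership columns as printed for the trained 8-sample cohort
    def test_published_membership_column_bsbl2(self):
        col = np.array([0.0, 0.3713, 0.0, 0.0, 0.0, 0.6287])
        res = assign_classes(col[:, None], sample_ids=("BSBL2",), source="R")
        assert res.assignment["BSBL2"] == 6

    def test_published_membership_column_tcl2(self):
        col = np.array([0.0, 0.1597, 0.0, 0.0, 0.8403, 0.0])
        res = assign_classes(col[:, None], sample_ids=("TCL2",), source="R")
        assert res.assignment["TCL2"] == 5

    def test_tie_breaks_to_lowest_class(self):
        col = np.array([0.5, 0.5])
        res = assign_classes(col[:, None], sample_ids=("x",))
        assert res.assignment["x"] == 1

    def test_all_zero_column_rejected(self):
        with pytest.raises(UnassignableSampleError):
            assign_classes(np.array([[0.0], [0.0]]), sample_ids=("x",))

    def test_ratio_gap_infinite_when_unique_support(self):
        res = assign_classes(np.array([[1.0], [0.0]]), sample_ids=("x",))
        assert res.ratio_gap["x"] == np.inf

    def test_h_and_r_agree_on_balanced_basis(self, planted_clean):
        # balanced W column magnitudes: classification by H and by R match
        x, truth = planted_clean
        model = factorize(x, 4, SolverConfig(seed=5, max_outer_iter=40))
        by_h = assign_classes(model.H, x.sample_ids, source="H")
        by_r = assign_classes(membership_matrix(model.W, model.H, x.sample_ids))
        assert by_h.partition == by_r.partition == true_partition(truth.labels)

    def test_h_and_r_can_disagree_on_unbalanced_basis(self):
        # rows of W spanning orders of magnitude break the H/R equivalence:
        # H picks the class with the larger coordinate, R the class carrying
        # the larger share of reconstructed signal across genes
        W = np.array([[1e4, 0.1], [1e4, 0.1], [0.5, 0.2]])
        H = np.array([[0.001, 1.0], [2.0, 0.001]])
        by_h = assign_classes(H, ("a", "b"))
        by_r = assign_classes(membership_matrix(W, H, ("a", "b")))
        # sample "a": H picks class 2 (coordinate 2.0 vs 0.001) but most of
        # the reconstructed signal flows through class 1's huge basis entries
        assert by_h.assignment["a"] == 2
        assert by_r.assignment["a"] == 1


class TestSelectRank:
    def test_recovers_three_planted_classes(self):
        x, _ = planted_matrix(n=500, m=9, r=3, noise_sigma=0.02, seed=21)
        cfg = SolverConfig(seed=0, max_outer_iter=60)
        r_star, diags, separated = select_rank(x, range(2, 6), cfg)
        assert r_star == 3
        assert separated
        assert set(diags) == {2, 3, 4, 5}

    def test_rerun_with_shifted_seeds_is_stable(self):
        x, _ = planted_matrix(n=500, m=9, r=3, noise_sigma=0.02, seed=21)
        cfg = SolverConfig(seed=77, max_outer_iter=60)
        r_star, _, _ = select_rank(x, range(2, 6), cfg)
        assert r_star == 3

    def test_structureless_data_flagged(self, rng):
        # one class only: every extra class splits noise; warn via flag
        u = rng.random(80) + 0.5
        A = np.outer(u, np.ones(6)) + rng.normal(0, 0.01, (80, 6))
        A = np.maximum(A, 0)
        r_star, diags, separated = select_rank(
            A, [2, 3], SolverConfig(seed=0, max_outer_iter=30)
        )
        assert not separated

    def test_empty_range_rejected(self, cfg):
        with pytest.raises(ValueError):
            select_rank(np.ones((4, 3)), [], cfg)


class TestSampleCorrelation:
    def test_duplicated_column_fully_correlated(self, rng):
        col = rng.random(10)
        A = np.column_stack([col, col, rng.random(10)])
        corr = sample_correlation(A)
        assert corr[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_anticorrelated_complement(self, rng):
        col = rng.random(10)
        A = np.column_stack([col, 2.0 - col])
        corr = sample_correlation(A)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        A = rng.random((10, 4))
        corr = sample_correlation(A)
        for i in range(4):
            for j in range(4):
                x, y = A[:, i], A[:, j]
                expected = np.mean((x - x.mean()) * (y - y.mean())) / (
                    x.std() * y.std()
                )
                assert corr[i, j] == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_column_flagged(self):
        A = np.column_stack([np.ones(5), np.arange(5.0)])
        corr = sample_correlation(A)
        assert np.isnan(corr[0, :]).all()
        assert np.isnan(corr[:, 0]).all()

    def test_spearman_available(self, rng):
        A = rng.random((20, 3))
        corr = sample_correlation(A, method="spearman")
        assert corr.shape == (3, 3)
        np.testing.assert_allclose(np.diag(corr), 1.0)


class TestTopGenes:
    def test_order_forced(self):
        W = np.array([[0.1], [0.9], [0.5]])
        lists = top_genes(W, ["g1", "g2", "g3"], k=2)
        assert lists[0] == ["g2", "g3"]

    def test_full_k_is_permutation(self, rng):
        W = rng.random((10, 2))
        lists = top_genes(W, [f"g{i}" for i in range(10)], k=10)
        for lst in lists:
            assert sorted(lst) == sorted(f"g{i}" for i in range(10))

    def test_proportional_columns_identical_lists(self, rng):
        col = rng.random(15)
        W = np.column_stack([col, 3.7 * col])
        lists = top_genes(W, [f"g{i}" for i in range(15)], k=5)
        assert lists[0] == lists[1]

    def test_ties_break_by_gene_index(self):
        W = np.array([[0.5], [0.5], [1.0]])
        lists = top_genes(W, ["a", "b", "c"], k=3)
        assert lists[0] == ["c", "a", "b"]

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            top_genes(rng.random((3, 1)), ["a", "b", "c"], k=4)


class TestSharedGenes:
    @pytest.mark.parametrize(
        "lists, classes, expected_count, expected_set",
        [
            ([["a", "b"], ["c", "d"]], [1, 2], 0, set()),
            ([["a", "b", "c"], ["a", "b", "c"]], [1, 2], 3, {"a", "b", "c"}),
            (
                [["a", "b", "c"], ["b", "c", "d"], ["c", "e"]],
                [1, 2, 3],
                1,
                {"c"},
            ),
        ],
    )
    def test_intersections(self, lists, classes, expected_count, expected_set):
        count, genes = shared_genes(lists, classes)
        assert count == expected_count
        assert genes == expected_set

    def test_monotone_in_class_count(self, rng):
        lists = [list(rng.choice(50, size=20, replace=False).astype(str)) for _ in range(4)]
        prev = None
        for upto in range(1, 5):
            count, _ = shared_genes(lists, list(range(1, upto + 1)))
            if prev is not None:
                assert count <= prev
            prev = count

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            shared_genes([["a"]], [2])
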