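import itertools

import numpy as np
import pytest

from svphylo.metrics import (
    clone_number_distance,
    coclustering_average_precision,
    match_clones,
    normalized_rf,
    rmse_matrices,
)
from svphylo.model import CloneTree


class TestMatching:
    def test_recovers_row_permutation_with_zero_cost(self):
        rng = np.random.default_rng(0)
        C = rng.integers(0, 4, size=(5, 9)).astype(float)
        perm = rng.permutation(5)
        m = match_clones(C, C[perm])
        assert m.cost == 0.0
        assert all(perm[e] == t for e, t in m.est_to_true.items())

    def test_single_clone_unique_matching(self):
        m = match_clones(np.array([[1.0, 2.0]]), np.array([[0.0, 1.0]]))
        assert m.est_to_true == {0: 0} and m.cost == 2.0

    def test_matches_brute_force_over_permutations(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 3, size=(4, 6))
        B = rng.uniform(0, 3, size=(4, 6))
        m = match_clones(A, B)
        best = min(
            sum(np.abs(B[i] - A[p[i]]).sum() for i in range(4))
            for p in itertools.permutations(range(4))
        )
        assert m.cost == pytest.approx(best)

    def test_cost_invariant_under_permutations_of_either_argument(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 3, size=(4, 5))
        B = rng.uniform(0, 3, size=(4, 5))
        base = match_clones(A, B).cost
        for _ in range(3):
            pa, pb = rng.permutation(4), rng.permutation(4)
            assert match_clones(A[pa], B[pb]).cost == pytest.approx(base)


class TestRmse:
    def test_identical_matrices_zero(self):
        C = np.arange(12.0).reshape(3, 4)
        U = np.random.default_rng(0).dirichlet(np.ones(3), size=2)
        m = match_clones(C, C)
        assert rmse_matrices(C, C, U, U, m) == (0.0, 0.0)

    def test_single_entry_off_by_two(self):
        C1 = np.array([[1.0, 1.0, 1.0, 1.0]])
        C2 = np.array([[3.0, 1.0, 1.0, 1.0]])
        m = match_clones(C1, C2)
        rc, _ = rmse_matrices(C1, C2, np.ones((1, 1)), np.ones((1, 1)), m)
        assert rc == pytest.approx(1.0)  # sqrt(4/4)

    def test_agrees_with_direct_definition(self):
        rng = np.random.default_rng(3)
        Ct = rng.integers(0, 4, size=(4, 7)).astype(float)
        Ce = rng.integers(0, 4, size=(4, 7)).astype(float)
        Ut = rng.dirichlet(np.ones(4), size=3)
        Ue = rng.dirichlet(np.ones(4), size=3)
        m = match_clones(Ct, Ce)
        rc, ru = rmse_matrices(Ct, Ce, Ut, Ue, m)
        dc = np.array([Ce[e] - Ct[t] for e, t in zip(m.rows, m.cols)])
        du = np.array([Ue[:, e] - Ut[:, t] for e, t in zip(m.rows, m.cols)])
        assert rc == pytest.approx(np.sqrt((dc**2).mean()))
        assert ru == pytest.approx(np.sqrt((du**2).mean()))


def _tree(n, parents):
    return CloneTree.from_parents(n, parents)


def _identity_matching(n_total):
    from svphylo.metrics import CloneMatching

    return CloneMatching({i: i for i in range(n_total)}, 0.0,
                         np.arange(n_total), np.arange(n_total))


class TestNormalizedRF:
    def test_identical_trees_zero(self):
        # caterpillar on 4 leaves: root 6 -> (5, 3); 5 -> (4, 2); 4 -> (0, 1)
        t = _tree(4, [4, 4, 5, 6, 5, 6, -1])
        assert normalized_rf(t, t, _identity_matching(7)) == 0.0

    def test_disjoint_cluster_sets_distance_one(self):
        t1 = _tree(4, [4, 4, 5, 6, 5, 6, -1])  # clusters {0,1}, {0,1,2}
        t2 = _tree(4, [6, 5, 4, 4, 5, 6, -1])  # clusters {2,3}, {1,2,3}
        m = _identity_matching(7)
        d = normalized_rf(t1, t2, m)
        assert d == 1.0

    def test_agrees_with_dendropy_on_random_trees(self):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        from svphylo.simulate import simulate_tree

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            t1 = simulate_tree(n, rng)
            t2 = simulate_tree(n, rng)
            ours = normalized_rf(t1, t2, _identity_matching(t1.N))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.newick(), schema="newick",
                                   taxon_namespace=tns, rooting="force-rooted")
            d2 = dendropy.Tree.get(data=t2.newick(), schema="newick",
                                   taxon_namespace=tns, rooting="force-rooted")
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            sym = treecompare.symmetric_difference(d1, d2)
            # dendropy counts the same symmetric difference of clusters
            denom = 2 * (n - 2)
            expected = sym / denom if denom else 0.0
            assert ours == pytest.approx(expected), (t1.newick(), t2.newick())


class TestAveragePrecision:
    def test_identical_assignments_give_one(self):
        a = np.array([0, 0, 1, 1, 2])
        assert coclustering_average_precision(a, a, "all") == 1.0

    def test_degenerate_truth_without_positives_is_nan(self):
        a_true = np.array([0, 1, 2, 3])
        a_est = np.zeros(4, dtype=int)
        assert np.isnan(coclustering_average_precision(a_true, a_est, "all"))

    def test_matches_sklearn_average_precision(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        for _ in range(10):
            at = rng.integers(0, 3, size=12)
            ae = rng.integers(0, 3, size=12)
            ii, jj = np.triu_indices(12, k=1)
            y = (at[ii] == at[jj]).astype(int)
            s = (ae[ii] == ae[jj]).astype(int)
            if y.sum() == 0:
                continue
            ours = coclustering_average_precision(at, ae, "all")
            ref = sk.average_precision_score(y, s)
            assert ours == pytest.approx(ref)

    def test_blocks_partition_pairs(self):
        at = np.array([0, 0, 1, 1])
        ae = np.array([0, 1, 1, 1])
        nbp = 2  # variants 0,1 are breakpoints; 2,3 SNVs
        for block in ("bp-bp", "snv-snv", "bp-snv"):
            v = coclustering_average_precision(at, ae, block, n_breakpoints=nbp)
            assert np.isnan(v) or 0.0 <= v <= 1.0


class TestCloneNumber:
    @pytest.mark.parametrize(
        "kt,ke,expected", [(5, 5, 0.0), (5, 9, -0.8), (4, 1, 0.75)]
    )
    def test_signed_relative_distance(self, kt, ke, expected):
        assert clone_number_distance(kt, ke) == pytest.approx(expected)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            clone_number_distance(0, 3)


def test_all_metrics_perfect_when_estimate_equals_truth(make_cohort):
    for seed in range(10):
        gt = make_cohort(seed=seed, n_leaves=3, lambda_total=4, snv_rate=5)
        C, U = gt.profiles.C, gt.freqs.U
        m = match_clones(C, C)
        assert m.cost == 0.0
        assert rmse_matrices(C, C, U, U, m) == (0.0, 0.0)
        assert normalized_rf(gt.tree, gt.tree, m) == 0.0
        intro = gt.variant_intro_node
        if len(intro) >= 2 and len(set(intro)) < len(intro):
            assert coclustering_average_precision(intro, intro, "all") == 1.0
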