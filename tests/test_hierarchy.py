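import numpy as np
import pytest
import scipy.cluster.hierarchy as sch

from coexhier import (
    DegenerateDistanceError,
    DistanceMatrix,
    average_linkage,
    cophenetic_correlation,
    cophenetic_matrix,
    group_ccc_pipeline,
    normalized_ccc,
    shuffled_ccc_null,
)
from coexhier.hierarchy import ccc_norm_of_matrix
from coexhier.simulate import make_two_group_dataset

from conftest import make_network


def dist(D, tag="resistance"):
    D = np.asarray(D, dtype=float)
    return DistanceMatrix([f"n{i}" for i in range(D.shape[0])], D, tag)


def naive_upgma_cophenetic(D):
    """O(N^3) reference UPGMA: literal average of original pairwise
    distances between clusters, lowest-index pair merged first on ties."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    T = np.zeros((n, n))
    next_id = n
    while len(members) > 1:
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in members[a] for j in members[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        for i in members[a]:
            for j in members[b]:
                T[i, j] = T[j, i] = d
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return T


class TestAverageLinkage:
    def test_hand_run_two_merges(self):
        D = dist([[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        tree = average_linkage(D)
        Z = tree.linkage
        assert set(Z[0, :2]) == {0.0, 1.0}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(4.0)  # average of 4 and 4

    def test_equidistant_tie_break(self):
        D = dist([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        Z = average_linkage(D).linkage
        assert set(Z[0, :2]) == {0.0, 1.0}  # lowest-index pair first
        assert Z[1, 2] == pytest.approx(1.0)

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            M = rng.uniform(0.5, 3.0, size=(8, 8))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = average_linkage(dist(D))
            T = cophenetic_matrix(tree).T
            np.testing.assert_allclose(
                T, naive_upgma_cophenetic(D), atol=1e-8
            )

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        from coexhier import ValidationError
        with pytest.raises(ValidationError):
            average_linkage(dist(D))


class TestCopheneticMatrix:
    def test_read_off_from_hand_tree(self):
        D = dist([[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        T = cophenetic_matrix(average_linkage(D)).T
        assert T[0, 1] == pytest.approx(1.0)
        assert T[0, 2] == pytest.approx(4.0)
        assert T[1, 2] == pytest.approx(4.0)

    def test_perfect_binary_tree(self):
        D = dist([[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]])
        T = cophenetic_matrix(average_linkage(D)).T
        assert T[0, 1] == T[2, 3] == pytest.approx(1.0)
        assert T[0, 2] == T[1, 3] == pytest.approx(2.0)

    def test_symmetric_zero_diagonal(self, rng):
        M = rng.uniform(1, 2, size=(6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        T = cophenetic_matrix(average_linkage(dist(D))).T
        np.testing.assert_allclose(T, T.T)
        assert np.all(np.diagonal(T) == 0)


class TestCCC:
    def test_ultrametric_is_fixed_point(self):
        D = dist([[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]])
        T = cophenetic_matrix(average_linkage(D))
        assert cophenetic_correlation(D, T) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_guard(self):
        D = dist([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        T = cophenetic_matrix(average_linkage(D))
        with pytest.raises(DegenerateDistanceError):
            cophenetic_correlation(D, T)

    def test_matches_direct_formula_and_scipy(self, rng):
        M = rng.uniform(0.5, 3.0, size=(6, 6))
        Dm = (M + M.T) / 2
        np.fill_diagonal(Dm, 0)
        D = dist(Dm)
        tree = average_linkage(D)
        T = cophenetic_matrix(tree)
        ccc = cophenetic_correlation(D, T)
        # direct product-moment evaluation over the condensed pairs
        x, y = D.condensed(), T.condensed()
        direct = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert ccc == pytest.approx(direct, abs=1e-12)
        c_scipy, _ = sch.cophenet(tree.linkage, D.condensed())
        assert ccc == pytest.approx(float(c_scipy), abs=1e-10)

    def test_affine_invariance(self, rng):
        M = rng.uniform(0.5, 3.0, size=(7, 7))
        Dm = (M + M.T) / 2
        np.fill_diagonal(Dm, 0)
        ccc1 = cophenetic_correlation(
            dist(Dm), cophenetic_matrix(average_linkage(dist(Dm)))
        )
        Dm2 = 2.5 * Dm + 1.0
        np.fill_diagonal(Dm2, 0)
        ccc2 = cophenetic_correlation(
            dist(Dm2), cophenetic_matrix(average_linkage(dist(Dm2)))
        )
        assert ccc1 == pytest.approx(ccc2, abs=1e-10)


class TestShuffledNull:
    def test_entry_multiset_conserved_and_deterministic(self, rng):
        M = rng.uniform(0.5, 3.0, size=(5, 5))
        Dm = (M + M.T) / 2
        np.fill_diagonal(Dm, 0)
        D = dist(Dm)
        reps1, mean1 = shuffled_ccc_null(D, n_rand=10, seed=7)
        reps2, mean2 = shuffled_ccc_null(D, n_rand=10, seed=7)
        np.testing.assert_array_equal(reps1, reps2)
        assert mean1 == mean2
        assert len(reps1) == 10

    def test_three_nodes_well_defined(self, rng):
        Dm = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        reps, mean = shuffled_ccc_null(dist(Dm), n_rand=5, seed=0)
        assert np.all(np.isfinite(reps))
        assert -1 <= mean <= 1

    def test_iid_distances_make_null_unbiased(self, rng):
        # for exchangeable D entries the observed CCC and the shuffled-null
        # mean estimate the same quantity; their average difference -> 0
        diffs = []
        for _ in range(200):
            y = rng.uniform(1.0, 2.0, size=45)  # N=10 condensed
            from scipy.spatial.distance import squareform
            D = dist(squareform(y))
            from coexhier.hierarchy import _ccc_of_condensed
            ccc = _ccc_of_condensed(y)
            _, m = shuffled_ccc_null(D, n_rand=5, rng=rng)
            diffs.append(ccc - m)
        diffs = np.asarray(diffs)
        band = 4 * diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < band


class TestNormalizedCCC:
    @pytest.mark.parametrize(
        "ccc, rand, expected",
        [(1.0, 0.4, 1.0), (0.6, 0.6, 0.0), (0.9, 0.6, 0.75)],
    )
    def test_arithmetic(self, ccc, rand, expected):
        assert normalized_ccc(ccc, rand) == pytest.approx(expected)

    def test_degenerate_null(self):
        with pytest.raises(DegenerateDistanceError):
            normalized_ccc(0.9, 1.0)


@pytest.fixture(scope="module")
def dataset():
    return make_two_group_dataset(
        n_genes=20, n_a=8, n_b=8, h_a=0.9, h_b=0.0, seed=5
    )


class TestPipeline:
    def test_result_identity_and_provenance(self, dataset):
        expr, pheno, sets = dataset
        res = group_ccc_pipeline(
            expr, sets["simulated_set"], pheno, "A", seed=3
        )
        expected = (res.ccc - res.ccc_rand_mean) / (1 - res.ccc_rand_mean)
        assert res.ccc_norm == expected  # exact identity by construction
        assert len(res.ccc_rand_replicates) == 10
        assert res.n_genes == 20 and res.n_samples == 8
        assert -1 <= res.ccc <= 1

    def test_uniform_expression_rescaling_identical_result(self, dataset):
        expr, pheno, sets = dataset
        scaled = type(expr)(
            list(expr.gene_ids), list(expr.sample_ids), 10.0 * expr.values
        )
        for metric in ("ectd", "resistance"):
            r1 = group_ccc_pipeline(expr, sets["simulated_set"], pheno, "A",
                                    metric=metric, seed=9)
            r2 = group_ccc_pipeline(scaled, sets["simulated_set"], pheno, "A",
                                    metric=metric, seed=9)
            assert r1.ccc == pytest.approx(r2.ccc, abs=1e-12)
            assert r1.ccc_norm == pytest.approx(r2.ccc_norm, abs=1e-9)

    def test_gene_and_sample_order_invariance(self, dataset, rng):
        expr, pheno, sets = dataset
        gperm = rng.permutation(expr.n_genes)
        sperm = rng.permutation(expr.n_samples)
        shuffled = type(expr)(
            [expr.gene_ids[i] for i in gperm],
            [expr.sample_ids[j] for j in sperm],
            expr.values[np.ix_(gperm, sperm)],
        )
        pheno_s = type(pheno)(
            [pheno.labels[j] for j in sperm],
            [pheno.sample_ids[j] for j in sperm],
        )
        r1 = group_ccc_pipeline(expr, sets["simulated_set"], pheno, "A", seed=2)
        r2 = group_ccc_pipeline(shuffled, sets["simulated_set"], pheno_s, "A",
                                seed=2)
        # same gene-set order is restored during subsetting, so the distance
        # matrix (and hence the CCC) is reproduced exactly
        assert r1.ccc == pytest.approx(r2.ccc, abs=1e-12)
        assert r1.ccc_norm == pytest.approx(r2.ccc_norm, abs=1e-12)

    def test_weights_null_mode(self, dataset):
        expr, pheno, sets = dataset
        res = group_ccc_pipeline(expr, sets["simulated_set"], pheno, "A",
                                 seed=4, null_shuffle="weights")
        assert np.isfinite(res.ccc_norm)

    def test_hierarchical_group_detected(self):
        # strong tree-structured covariance yields positive normalized CCC
        hits = 0
        for s in range(10):
            expr, pheno, sets = make_two_group_dataset(
                n_genes=30, n_a=12, n_b=3, h_a=0.9, h_b=0.0, seed=100 + s
            )
            res = group_ccc_pipeline(expr, sets["simulated_set"], pheno, "A",
                                     seed=s)
            hits += res.ccc_norm > 0
        assert hits >= 9


def test_matrix_level_entry_point_matches_pipeline(rng):
    expr, pheno, sets = make_two_group_dataset(
        n_genes=15, n_a=8, n_b=8, h_a=0.5, h_b=0.5, seed=21
    )
    res = group_ccc_pipeline(expr, sets["simulated_set"], pheno, "A", seed=6)
    sub = expr.subset(samples=[s for s, l in zip(expr.sample_ids, pheno.labels)
                               if l == "A"])
    ccc, reps, rand_mean, norm = ccc_norm_of_matrix(sub, seed=6)
    assert ccc == pytest.approx(res.ccc, abs=1e-12)
    assert norm == pytest.approx(res.ccc_norm, abs=1e-12)
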