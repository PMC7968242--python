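import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexalign.alignment import (
    AlignmentResult,
    DistanceMatrix,
    anchor_consistency_test,
    cosine_distance,
    distance_matrix,
    hungarian_match,
    match_fraction,
)
from coexalign.anchoring import is_artificial


class TestCosineDistance:
    def test_identities(self):
        a = np.array([1.0, 2.0, -3.0])
        assert cosine_distance(a, a) == 0.0
        assert cosine_distance(a, -a) == 1.0
        assert cosine_distance([1, 0], [0, 1]) == 0.5

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_scale_invariance_and_symmetry(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert cosine_distance(a, b) == pytest.approx(cosine_distance(b, a))
        assert cosine_distance(3.7 * a, b) == pytest.approx(cosine_distance(a, b))

    def test_range_on_random_pairs(self, rng):
        for _ in range(1000):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            d = cosine_distance(a, b)
            assert -1e-12 <= d <= 1.0 + 1e-12


def brute_force_min_cost(D):
    n_rows, n_cols = D.shape
    best = np.inf
    if n_rows <= n_cols:
        for perm in itertools.permutations(range(n_cols), n_rows):
            best = min(best, sum(D[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_rows), n_cols):
            best = min(best, sum(D[i, j] for j, i in enumerate(perm)))
    return best


class TestHungarianMatch:
    def test_zero_diagonal(self):
        dm = DistanceMatrix(["r0", "r1"], ["c0", "c1"], [[0, 1], [1, 0]])
        res = hungarian_match(dm)
        assert res.mapping == {"r0": "c0", "r1": "c1"}
        assert res.global_distance == 0.0
        assert res.unmatched == []

    def test_two_by_two_off_diagonal_optimum(self):
        # hand-checked: 0.2+0.4=0.6 versus 0.1+0.3=0.4
        dm = DistanceMatrix(["r0", "r1"], ["c0", "c1"], [[0.2, 0.1], [0.3, 0.4]])
        res = hungarian_match(dm)
        assert res.mapping == {"r0": "c1", "r1": "c0"}
        assert sum(d for *_, d in res.pairs) == pytest.approx(0.4)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 8))
            m = int(rng.integers(2, 8))
            D = rng.random((n, m))
            dm = DistanceMatrix([f"r{i}" for i in range(n)],
                                [f"c{j}" for j in range(m)], D)
            res = hungarian_match(dm)
            total = sum(d for *_, d in res.pairs)
            assert total == pytest.approx(brute_force_min_cost(D), abs=1e-12)
            assert len(res.pairs) == min(n, m)
            assert len(res.unmatched) == abs(n - m)
            assert res.global_distance == pytest.approx(total / min(n, m))

    def test_partial_bijection(self, rng):
        D = rng.random((4, 6))
        res = hungarian_match(DistanceMatrix(list("abcd"), list("uvwxyz"), D))
        assert len({g for g, _, _ in res.pairs}) == 4
        assert len({g for _, g, _ in res.pairs}) == 4

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match(DistanceMatrix([], [], np.empty((0, 0))))


class TestMatchFraction:
    def make_result(self, pairs):
        return AlignmentResult([(a, b, 0.1) for a, b in pairs], 0.1, [])

    def test_fractions(self):
        truth = {"a": "a", "b": "b", "c": "c", "d": "d"}
        assert match_fraction(self.make_result([("a", "a"), ("b", "b")]), truth) == 1.0
        assert match_fraction(self.make_result([("a", "b"), ("b", "a")]), truth) == 0.0
        assert match_fraction(
            self.make_result([("a", "a"), ("b", "c"), ("c", "c"), ("d", "a")]), truth
        ) == 0.5

    def test_genes_outside_truth_are_excluded(self):
        truth = {"a": "a"}
        res = self.make_result([("a", "a"), ("x", "y")])
        assert match_fraction(res, truth) == 1.0
        with pytest.raises(ValueError):
            match_fraction(self.make_result([("x", "y")]), truth)


class TestDistanceMatrix:
    def test_shape_range_and_artificial_exclusion(self, line_selfcmp):
        res = line_selfcmp
        dm = res.distances
        assert dm.D.shape == (50, 50)
        assert np.all((dm.D >= 0) & (dm.D <= 1))
        assert not any(is_artificial(g) for g in dm.row_genes + dm.col_genes)

    def test_single_gene_self_distance(self, line_selfcmp):
        res = line_selfcmp
        tag1, tag2 = (n.graph["tag"] for n in res.augmented)
        dangle = next(n for n in res.augmented[0] if is_artificial(n))
        dm = distance_matrix(
            res.embedding, [dangle], [dangle], res.token_map, tag1, tag2,
            include_artificial=True,
        )
        assert dm.D.shape == (1, 1)
        assert dm.D[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_gene_raises(self, line_selfcmp):
        res = line_selfcmp
        tag1, tag2 = (n.graph["tag"] for n in res.augmented)
        with pytest.raises(KeyError):
            distance_matrix(res.embedding, ["nope"], ["g1"], res.token_map, tag1, tag2)


class TestAnchorConsistency:
    def test_dangling_nodes_beat_random_sets(self, line_selfcmp):
        res = line_selfcmp
        tag1, tag2 = (n.graph["tag"] for n in res.augmented)
        all_nodes = sorted(res.augmented[0].nodes)
        dm = distance_matrix(
            res.embedding, all_nodes, all_nodes, res.token_map, tag1, tag2,
            include_artificial=True,
        )
        dangles = [n for n in all_nodes if is_artificial(n)]
        observed, null, p = anchor_consistency_test(dm, dangles, n_random=1000, seed=0)
        assert null.shape == (1000,)
        assert observed < null.min()
        assert p == pytest.approx(1 / 1001)
        assert p < 0.001

    def test_random_sets_give_uniformish_p(self, line_selfcmp, rng):
        # statistic on sets that are themselves random: p has no signal
        res = line_selfcmp
        dm = res.distances
        pool = dm.row_genes
        ps = []
        for k in range(40):
            fake = list(rng.choice(pool, size=8, replace=False))
            _, _, p = anchor_consistency_test(dm, fake, n_random=99, seed=k)
            ps.append(p)
        from scipy.stats import kstest

        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_argument_validation(self, line_selfcmp):
        dm = line_selfcmp.distances
        with pytest.raises(ValueError, match="absent"):
            anchor_consistency_test(dm, ["nope"], n_random=10)
        with pytest.raises(ValueError, match="set_size"):
            anchor_consistency_test(dm, ["g1"], n_random=10, set_size=10**6)
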