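import itertools

import numpy as np
import pytest

from grazenet.nestedness import (
    discrepancy,
    matrix_temperature,
    nodf,
    weighted_nodf,
    wine,
    wnoda,
)

STAIRCASE = np.array([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]])
CHECKER = (np.indices((4, 4)).sum(axis=0) % 2).astype(int)
W_STAIR = np.outer([4, 3, 2, 1], [4, 3, 2, 1]) * STAIRCASE


# -- independent oracles (bitmask / direct-formula reimplementations) -------


def nodf_oracle(mat, sort):
    """Pure-python pairwise NODF, rows as bitmasks."""
    rows = [int("".join("1" if v else "0" for v in r), 2) for r in np.asarray(mat)]
    ncol = np.asarray(mat).shape[1]
    cols = [int("".join("1" if v else "0" for v in c), 2) for c in np.asarray(mat).T]

    def margin(masks):
        fills = [bin(m).count("1") for m in masks]
        order = sorted(range(len(masks)), key=lambda i: (-fills[i], i)) if sort \
            else list(range(len(masks)))
        total = 0.0
        for a in range(len(masks) - 1):
            for b in range(a + 1, len(masks)):
                i, j = order[a], order[b]
                if fills[j] >= fills[i] or fills[j] == 0:
                    continue
                total += 100.0 * bin(masks[i] & masks[j]).count("1") / fills[j]
        n = len(masks)
        return total, n * (n - 1) // 2

    tr, nr = margin(rows)
    tc, nc = margin(cols)
    return (tr + tc) / (nr + nc)


def discrepancy_oracle(mat, sort):
    """Set-difference count against the uniquely packed matrix."""
    B = np.asarray(mat)
    if sort:
        B = B[:, sorted(range(B.shape[1]), key=lambda j: (-B[:, j].sum(), j))]
    moved = 0
    for row in B:
        k = int(row.sum())
        packed = set(range(k))
        present = {j for j, v in enumerate(row) if v}
        moved += len(present - packed)
    return moved


def all_binary_matrices(r, c):
    for bits in range(2 ** (r * c)):
        yield np.array([(bits >> k) & 1 for k in range(r * c)]).reshape(r, c)


class TestNodf:
    def test_perfect_staircase_scores_100(self):
        assert nodf(STAIRCASE) == pytest.approx(100.0)

    def test_identical_rows_score_zero(self):
        assert nodf(np.ones((3, 3))) == pytest.approx(0.0)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = (rng.random((5, 5)) < rng.uniform(0.2, 0.8)).astype(int)
            if not m.any():
                continue
            for variant, sort in (("as_is", False), ("sorted", True)):
                assert nodf(m, variant) == pytest.approx(nodf_oracle(m, sort))

    def test_vegan_reference_value(self):
        # frozen cross-check: vegan::nestednodf(order=TRUE) gives 46.0
        m = np.array([
            [1, 1, 1, 0, 1, 0],
            [0, 1, 0, 1, 0, 0],
            [1, 1, 0, 1, 1, 1],
            [0, 0, 1, 0, 0, 0],
            [1, 0, 1, 1, 0, 1],
        ])
        assert nodf(m, "sorted") == pytest.approx(46.0, abs=1e-6)

    def test_transpose_symmetry_on_square(self):
        rng = np.random.default_rng(3)
        m = (rng.random((5, 5)) < 0.5).astype(int)
        assert nodf(m, "sorted") == pytest.approx(nodf(m.T, "sorted"))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            nodf(np.array([[1, 0, 1]]))
        with pytest.raises(ValueError):
            nodf(np.zeros((3, 3)))


class TestWeightedNodf:
    def test_decreasing_staircase_scores_100(self):
        assert weighted_nodf(W_STAIR) == pytest.approx(100.0)

    def test_equal_weights_score_zero(self):
        assert weighted_nodf(STAIRCASE.astype(float)) == pytest.approx(0.0)

    def test_matches_direct_formula_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.integers(0, 6, size=(4, 5)).astype(float)
            if not w.any():
                continue

            def direct(m):
                fills = (m > 0).sum(axis=1)
                totals = m.sum(axis=1)
                order = sorted(range(m.shape[0]),
                               key=lambda i: (-fills[i], -totals[i], i))
                m = m[order]
                fills = (m > 0).sum(axis=1)
                s = 0.0
                for i, j in itertools.combinations(range(m.shape[0]), 2):
                    if fills[j] >= fills[i] or fills[j] == 0:
                        continue
                    s += 100.0 * ((m[j] > 0) & (m[j] < m[i])).sum() / fills[j]
                return s, m.shape[0] * (m.shape[0] - 1) // 2

            sr, nr = direct(w)
            sc, nc = direct(w.T)
            assert weighted_nodf(w) == pytest.approx((sr + sc) / (nr + nc))


class TestWnoda:
    def test_decreasing_staircase_scores_100(self):
        assert wnoda(W_STAIR) == pytest.approx(100.0)

    def test_checkerboard_is_anti_nested(self):
        assert wnoda(CHECKER.astype(float)) < 20.0

    def test_hand_worked_3x3(self):
        # W = [[5,3,0],[2,1,0],[0,0,1]]
        # row pairs: (0,1) totals 8>3, both cells strictly dominated -> 100;
        # (0,2) and (1,2): the poorer row's only link is unmatched -> 0.
        # column pairs mirror this: 100, 0, 0. Mean over 6 pairs = 33.33.
        w = np.array([[5.0, 3, 0], [2, 1, 0], [0, 0, 1]])
        assert wnoda(w) == pytest.approx(200.0 / 6.0)

    def test_range(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = rng.integers(0, 5, size=(4, 6)).astype(float)
            if not w.any():
                continue
            assert 0.0 <= wnoda(w) <= 100.0


class TestWine:
    def test_hand_worked_2x2(self):
        # W=[[4,2],[1,0]] sorted already; distances 0,1,1,sqrt2.
        # d_w = (4*0+2*1+1*1)/7 = 3/7; d_rnd = (0+1+1+sqrt2)/4;
        # packing assigns (4,2,1) to distances (0,1,1) -> d_pack = 3/7;
        # matrix is already maximally packed -> eta = 1.
        res = wine(np.array([[4.0, 2.0], [1.0, 0.0]]))
        assert res.d_w == pytest.approx(3 / 7)
        assert res.d_rnd == pytest.approx((2 + np.sqrt(2)) / 4)
        assert res.eta == pytest.approx(1.0)

    def test_corner_weight_does_not_decrease_statistic(self):
        rng = np.random.default_rng(4)
        w = rng.integers(0, 5, size=(4, 5)).astype(float)
        w[0, 0] = 6.0  # ensure distinct totals keep the corner in place
        before = wine(w).eta
        w2 = w.copy()
        w2[0, 0] += 5.0
        assert wine(w2).eta >= before - 1e-9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0, 3, size=(4, 5))  # continuous -> distinct totals
        base = wine(w)
        sh = w[rng.permutation(4)][:, rng.permutation(5)]
        assert wine(sh).d_w == pytest.approx(base.d_w)
        assert wine(sh).eta == pytest.approx(base.eta)

    def test_staircase_is_almost_maximally_nested(self):
        assert wine(W_STAIR.astype(float)).eta > 0.95

    def test_no_links_raises(self):
        with pytest.raises(ValueError):
            wine(np.zeros((2, 2)))


class TestTemperature:
    def test_shuffled_staircase_recovers_packing(self):
        rng = np.random.default_rng(0)
        sh = STAIRCASE[rng.permutation(4)][:, rng.permutation(4)]
        assert matrix_temperature(sh, budget=5000, seed=1) <= 1.0

    def test_checkerboard_is_hot(self):
        assert matrix_temperature(CHECKER, budget=5000, seed=1) > 50.0

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(6)
        m = (rng.random((5, 6)) < 0.4).astype(int)
        a = matrix_temperature(m, budget=3000, seed=9)
        b = matrix_temperature(m, budget=3000, seed=9)
        assert a == b

    def test_permutation_invariance_within_two_units(self):
        rng = np.random.default_rng(7)
        m = (rng.random((5, 6)) < 0.45).astype(int)
        base = matrix_temperature(m, budget=8000, seed=0)
        for k in range(3):
            sh = m[rng.permutation(5)][:, rng.permutation(6)]
            assert abs(matrix_temperature(sh, budget=8000, seed=0) - base) < 2.0

    def test_range(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            m = (rng.random((4, 5)) < 0.5).astype(int)
            if not m.any():
                continue
            assert 0.0 <= matrix_temperature(m, budget=2000, seed=0) <= 100.0


class TestDiscrepancy:
    def test_perfectly_nested_is_zero(self):
        assert discrepancy(STAIRCASE) == 0

    def test_single_displaced_presence_costs_one(self):
        # exhaustively move one packed presence out of its prefix
        for i in range(4):
            k = int(STAIRCASE[i].sum())
            for src in range(k):
                for dst in range(k, 4):
                    m = STAIRCASE.copy()
                    m[i, src], m[i, dst] = 0, 1
                    assert discrepancy(m, "fixed_order") == 1

    def test_bounded_by_presence_count(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = (rng.random((4, 5)) < 0.5).astype(int)
            for variant in ("fixed_order", "fill_sorted"):
                d = discrepancy(m, variant)
                assert 0 <= d <= m.sum()

    def test_matches_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            m = (rng.random((4, 5)) < 0.5).astype(int)
            assert discrepancy(m, "fixed_order") == discrepancy_oracle(m, False)
            assert discrepancy(m, "fill_sorted") == discrepancy_oracle(m, True)


class TestOrderingSanity:
    def test_staircase_to_checkerboard_interpolation_is_monotone(self):
        # flip packed presences into checkerboard positions one at a time;
        # every metric should (weakly) report decreasing nestedness
        path = [STAIRCASE.copy()]
        cur = STAIRCASE.copy()
        diff = np.argwhere(STAIRCASE != CHECKER)
        for (i, j) in diff:
            cur = cur.copy()
            cur[i, j] = CHECKER[i, j]
            path.append(cur)
        nodfs = [nodf(m, "sorted") for m in path if m.any()]
        # allow small local non-monotonicity from discreteness, require trend
        assert nodfs[0] == pytest.approx(100.0)
        assert nodfs[-1] < nodfs[0] - 50
        temps = [matrix_temperature(m, budget=3000, seed=2) for m in (path[0], path[-1])]
        assert temps[0] < temps[-1]
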