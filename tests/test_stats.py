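"""Statistical wrappers checked against independent brute-force oracles."""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agrisk.stats import (
    chi_square_frequencies,
    fdr_adjust,
    ks_two_sample,
    mann_whitney_u,
    normality_check,
    spearman,
)

# ---------------------------------------------------------------------------
# Oracles


def mw_exact_oracle(a, b, tail):
    """Exact U p-value by enumerating every group assignment of the pooled
    sample (valid for tie-free data)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    if tail == "one_greater":
        return u_obs, p_ge
    if tail == "one_less":
        return u_obs, p_le
    return u_obs, min(1.0, 2.0 * min(p_ge, p_le))


def ks_d_oracle(a, b):
    """Maximum ECDF gap by direct scan over pooled points."""
    pts = np.concatenate([a, b])
    gaps = [
        abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts
    ]
    return max(gaps)


def midrank(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd ** 2).sum() * (yd ** 2).sum()))


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_textbook_separated_pairs(self):
        u, p = mann_whitney_u([1, 2], [3, 4], tail="two")
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_constant_samples(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5, 5], tail="two")
        assert p == 1.0

    @pytest.mark.parametrize("tail", ["two", "one_greater", "one_less"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_oracle(self, tail, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1, 6)
        b = rng.normal(0.0, 1, 6)
        u, p = mann_whitney_u(a, b, tail=tail)
        u_oracle, p_oracle = mw_exact_oracle(a, b, tail)
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_one_tailed_direction(self):
        rng = np.random.default_rng(4)
        hi = rng.normal(2, 1, 40)
        lo = rng.normal(0, 1, 40)
        _, p_correct = mann_whitney_u(hi, lo, tail="one_greater")
        _, p_wrong = mann_whitney_u(hi, lo, tail="one_less")
        assert p_correct < 0.01 < p_wrong

    def test_rejects_empty_and_bad_tail(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney_u([1.0], [2.0], tail="sideways")


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated(self):
        d, _ = ks_two_sample([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_statistic_matches_ecdf_scan(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(ks_d_oracle(a, b), abs=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)
        r, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_midrank_ties_match_hand_computation(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [1, 1, 2, 2, 3, 3]
        r, _ = spearman(x, y)
        assert r == pytest.approx(16 / np.sqrt(280), abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 3])
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = x * 0.5 + rng.normal(size=6)
        r_obs, p = spearman(x, y)
        ry = midrank(y)
        rx = midrank(x)
        hits = sum(
            1
            for perm in permutations(range(6))
            if abs(pearson(rx, ry[list(perm)])) >= abs(r_obs) - 1e-12
        )
        assert p == pytest.approx(hits / 720, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = x + 0.5 * rng.normal(size=60)
        r, p = spearman(x, y)
        assert 0 < p < 0.01
        assert 0 < r < 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


class TestChiSquare:
    def test_independent_table_is_zero(self):
        stat, p = chi_square_frequencies([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, _ = chi_square_frequencies([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_frequencies([[0, 0], [5, 10]])


class TestNormality:
    def test_null_simulation_mostly_passes(self):
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(100):
            _, p = normality_check(rng.normal(size=100))
            hits += p > 0.05
        assert hits >= 90

    def test_bimodal_sample_fails(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        _, p = normality_check(x)
        assert p < 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0, 3.0, 4.0, 5.0])


class TestFDR:
    def bh_oracle(self, p):
        """Step-up BH implemented from the definition."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * m / rank_from_top)
            adj[i] = running
        return adj

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=7)
        np.testing.assert_allclose(fdr_adjust(p), self.bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_adjusted_dominates_raw_and_keeps_order(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.3])
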