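"""Oracle tests for the statistical battery.

Every exact branch is checked against a hand-written brute-force
enumeration of the null distribution; conventions (zero-difference
dropping, two-sided tails) are pinned by worked examples.
"""

import itertools
import math

import numpy as np
import numpy.testing as npt
import pytest
from scipy.stats import rankdata

from nemasleep.stats import (benjamini_hochberg, fisher_exact,
                             mann_whitney_u, summarize, two_sample_t,
                             wilcoxon_signed_rank)


# ---------------------------------------------------------------- oracles

def wilcoxon_oracle(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.array([r[np.array(signs, bool)].sum()
                   for signs in itertools.product([0, 1], repeat=d.size)])
    n = ws.size
    p = 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / n
    return min(p, 1.0)


def mwu_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments.

    Two-sided means twice the smaller tail (the convention exact rank tests
    use); with ties the permutation distribution of U need not be
    symmetric, so the tails are counted from the enumerated distribution
    itself.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = rankdata(pooled)
    idx = range(pooled.size)
    us = np.array([ranks[list(c)].sum() - n1 * (n1 + 1) / 2
                   for c in itertools.combinations(idx, n1)])
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    eps = 1e-9
    p = 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean())
    return min(p, 1.0)


def fisher_oracle(table):
    """Two-sided p as the sum of probabilities of tables (fixed margins) no
    more probable than the observed, with the pmf built from binomials."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(kmin, kmax + 1)
                        if pmf(k) <= p_obs * (1 + 1e-12)))


def bh_oracle(p, q):
    """Step-up rule applied literally."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    kmax = 0
    for i, j in enumerate(order, start=1):
        if p[j] <= i / m * q:
            kmax = i
    reject[order[:kmax]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m, 0, -1):
        running = min(running, m * p[order[i - 1]] / i)
        adj[order[i - 1]] = running
    return reject, adj


# ------------------------------------------------------------- wilcoxon

class TestWilcoxon:
    def test_all_zero_differences_gives_p_one(self):
        res = wilcoxon_signed_rank(np.zeros(8))
        assert res.p == 1.0

    def test_six_positive_pairs_exact_tail(self):
        # all signs positive: one of 2^6 orderings per tail -> 2/64
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_sign_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, n)
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(wilcoxon_oracle(d), abs=1e-12)

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -3.0])
        assert wilcoxon_signed_rank(d).p == pytest.approx(
            wilcoxon_oracle(d), abs=1e-12)


# ---------------------------------------------------------- mann-whitney

class TestMannWhitney:
    def test_identical_samples_p_one(self, rng):
        a = rng.normal(size=6)
        res = mann_whitney_u(a, a.copy())
        assert res.statistic == pytest.approx(18.0)  # n1*n2/2
        assert res.p == 1.0

    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2/C(6,3)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            res = mann_whitney_u(a, b)
            assert res.p == pytest.approx(mwu_oracle(a, b), abs=1e-9)

    def test_ties_use_exact_permutation_branch(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 5).astype(float)
            b = rng.integers(1, 5, 5).astype(float)
            res = mann_whitney_u(a, b)
            assert "permutation" in res.note or "exact" in res.note
            assert res.p == pytest.approx(mwu_oracle(a, b), abs=1e-9)


# ------------------------------------------------------------------ t test

class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_welch_closed_form(self):
        from scipy.stats import t as tdist
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        tstat = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        p = 2 * tdist.sf(abs(tstat), df)
        res = two_sample_t(a, b)
        assert res.statistic == pytest.approx(tstat)
        assert res.p == pytest.approx(p)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=12)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(a + 10, b + 10)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_constant_equal_groups_convention(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]).p == 1.0


# ------------------------------------------------------------------ fisher

class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]).p == 1.0

    def test_perfect_separation(self):
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p == pytest.approx(2 / 184756, rel=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 9, (2, 2))
            if t.sum() == 0:
                continue
            res = fisher_exact(t)
            assert res.p == pytest.approx(fisher_oracle(t), abs=1e-10)


# ---------------------------------------------------------------------- BH

class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        reject, adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.5], q=0.05)
        npt.assert_array_equal(reject, [True, True, False, False])

    def test_none_rejected_when_all_one(self):
        reject, _ = benjamini_hochberg(np.ones(5))
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, adj = benjamini_hochberg([0.01])
        assert reject[0] and adj[0] == pytest.approx(0.01)

    def test_matches_hand_rule_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            reject, adj = benjamini_hochberg(p, q=0.05)
            oreject, oadj = bh_oracle(p, 0.05)
            npt.assert_array_equal(reject, oreject)
            npt.assert_allclose(adj, oadj, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


# ----------------------------------------------------------- summaries

class TestSummarize:
    def test_worked_example(self):
        s = summarize([0.0, 2.0, 4.0], ["A", "A", "B"])
        assert s.per_worm == {"A": 1.0, "B": 4.0}
        assert s.mean == pytest.approx(2.5)
        assert s.sem == pytest.approx(1.5)

    def test_one_value_per_worm_is_plain_mean(self, rng):
        v = rng.normal(size=6)
        s = summarize(v, [f"w{i}" for i in range(6)])
        assert s.mean == pytest.approx(v.mean())

    def test_constant_values_have_zero_sem(self):
        s = summarize([3.0, 3.0, 3.0], ["a", "b", "c"])
        assert s.sem == 0.0


# ------------------------------------------------- order invariance property

@pytest.mark.parametrize("test", ["mwu", "t", "fisher"])
def test_order_invariance(test, rng):
    a = rng.normal(size=8)
    b = rng.normal(size=9)
    perm = rng.permutation(8)
    if test == "mwu":
        assert mann_whitney_u(a, b).p == mann_whitney_u(a[perm], b).p
    elif test == "t":
        assert two_sample_t(a, b).p == pytest.approx(two_sample_t(a[perm], b).p)
    else:
        assert fisher_exact([[4, 6], [7, 2]]).p == pytest.approx(
            fisher_exact([[7, 2], [4, 6]]).p)  # row order symmetric


# --------------------------------------------------- type-I error control

class TestTypeIError:
    """Null rejection rates at alpha=0.05 over seeded simulations.

    Tests on continuous data should attain the nominal level; Fisher's
    exact test is an exact conditional test and therefore conservative by
    construction, so it is held to validity (never anticonservative), not
    to attaining the level.
    """

    REPS = 2000

    def test_continuous_tests_attain_nominal_level(self):
        rng = np.random.default_rng(202)
        rej = {"wilcoxon": 0, "mwu": 0, "t": 0}
        for _ in range(self.REPS):
            rej["wilcoxon"] += wilcoxon_signed_rank(rng.normal(0, 1, 30)).p < 0.05
            rej["mwu"] += mann_whitney_u(rng.normal(0, 1, 25),
                                         rng.normal(0, 1, 25)).p < 0.05
            rej["t"] += two_sample_t(rng.normal(0, 1, 15),
                                     rng.normal(0, 1, 15)).p < 0.05
        for name, k in rej.items():
            assert 0.035 <= k / self.REPS <= 0.065, (name, k / self.REPS)

    def test_fisher_valid_and_conservative(self):
        rng = np.random.default_rng(203)
        rej = 0
        for _ in range(self.REPS):
            a, b = rng.binomial(100, 0.5, 2)
            rej += fisher_exact([[a, 100 - a], [b, 100 - b]]).p < 0.05
        rate = rej / self.REPS
        assert 0.0 < rate <= 0.065
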