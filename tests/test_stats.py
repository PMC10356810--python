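"""Binomial and Monte Carlo selection tests, mid-CDF transform, CDF shift."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import missel as ms
from missel.errors import (
    DegenerateFeatureError,
    EmptyObservationError,
)

from conftest import make_toy_catalogue


def exact_minlike_pvalue(k: int, n: int, p0: Fraction) -> Fraction:
    """Exact-rational two-sided binomial p (minimum-likelihood convention)."""
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k])


class TestBinomialPvalue:
    def test_hand_enumerated_example(self):
        # Binomial(4, 1/4): outcomes no likelier than k=3 are k=3 and k=4
        assert ms.binom_minlike_pvalue(3, 4, 0.25) == pytest.approx(
            0.05078125, abs=1e-12)

    def test_central_outcome_is_one(self):
        assert ms.binom_minlike_pvalue(5, 10, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 3, 7, 12])
    @pytest.mark.parametrize("num", [1, 5, 13, 25])
    def test_matches_exact_fraction_oracle(self, n, num):
        p0 = Fraction(num, 26)
        for k in range(n + 1):
            exact = float(exact_minlike_pvalue(k, n, p0))
            assert ms.binom_minlike_pvalue(k, n, float(p0)) == pytest.approx(
                exact, abs=1e-9)

    def test_cross_check_scipy_binomtest(self):
        for k, n, p0 in [(3, 20, 0.1), (15, 40, 0.5), (0, 9, 0.3), (7, 7, 0.6)]:
            ours = ms.binom_minlike_pvalue(k, n, p0)
            theirs = sps.binomtest(k, n, p0, alternative="two-sided").pvalue
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_never_zero(self):
        p = ms.binom_minlike_pvalue(100, 100, 1e-6)
        assert p > 0

    def test_degenerate_p0(self):
        with pytest.raises(DegenerateFeatureError):
            ms.binom_minlike_pvalue(0, 10, 0.0)


class TestExpectedCountCi:
    def test_p0_zero(self):
        assert ms.expected_count_ci(50, 0.0) == (0, 0)

    def test_symmetric_interval_contains_mean(self):
        lo, hi = ms.expected_count_ci(100, 0.5)
        assert lo <= 50 <= hi
        assert 50 - lo == hi - 50

    def test_matches_pmf_accumulation_oracle(self):
        n, p0 = 20, 0.3
        pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
        cdf = np.cumsum(pmf)
        lo_oracle = next(i for i in range(n + 1) if cdf[i] >= 0.025)
        hi_oracle = next(i for i in range(n + 1) if cdf[i] >= 0.975)
        assert ms.expected_count_ci(n, p0) == (lo_oracle, hi_oracle)


class TestBinomialFeatureTest:
    def test_expected_observed_and_p(self, catalogue, neutral_observed):
        res = ms.binomial_feature_test(neutral_observed, catalogue, "strong")
        p0 = catalogue.prob[catalogue.entries["strong"]].sum()
        assert res.expected_summary == pytest.approx(p0)
        assert res.n == neutral_observed.n
        assert 0 < res.p_two_tailed <= 1

    def test_empty_observed_errors(self, catalogue):
        empty = ms.ObservedMutationSet(
            region_id=catalogue.region_id,
            counts=np.zeros(len(catalogue.entries), dtype=int))
        with pytest.raises(EmptyObservationError):
            ms.binomial_feature_test(empty, catalogue, "strong")

    def test_degenerate_feature_errors(self, catalogue, neutral_observed):
        catalogue.entries["always"] = True
        try:
            with pytest.raises(DegenerateFeatureError):
                ms.binomial_feature_test(neutral_observed, catalogue, "always")
        finally:
            catalogue.entries.drop(columns="always", inplace=True)

    def test_recurrence_weighting_consistency(self, catalogue):
        """Duplicating every record with count 1 equals doubling counts."""
        rng = np.random.default_rng(21)
        base = rng.multinomial(50, catalogue.prob)
        doubled = ms.ObservedMutationSet(catalogue.region_id, base * 2)
        duplicated = ms.ObservedMutationSet(catalogue.region_id, base + base)
        r1 = ms.binomial_feature_test(doubled, catalogue, "strong")
        r2 = ms.binomial_feature_test(duplicated, catalogue, "strong")
        assert r1.p_two_tailed == r2.p_two_tailed
        assert r1.n == r2.n == 100


class TestMonteCarloTest:
    def test_central_value_gives_p_near_one(self):
        cat = make_toy_catalogue(np.ones(9), np.arange(9.0))
        # observed set concentrated at the null median
        counts = np.zeros(9, dtype=int)
        counts[4] = 5
        obs = ms.ObservedMutationSet("toy", counts)
        res = ms.monte_carlo_test(obs, cat, "ddg", n_draws=20000, seed=0)
        assert res.p_two_tailed > 0.5

    def test_p_floor(self):
        cat = make_toy_catalogue([0.98, 0.01, 0.01], [0.0, 5.0, 9.0])
        counts = np.array([0, 0, 4])
        obs = ms.ObservedMutationSet("toy", counts)
        res = ms.monte_carlo_test(obs, cat, "ddg", n_draws=10000, seed=1)
        assert res.p_two_tailed >= 2 / (10000 + 1)

    def test_matches_exhaustive_enumeration(self):
        """MC p within 3 binomial SE of exact enumeration (3 entries, n=2)."""
        probs = np.array([0.5, 0.3, 0.2])
        scores = np.array([0.0, 2.0, 5.0])
        cat = make_toy_catalogue(probs, scores)
        counts = np.array([0, 1, 1])
        obs = ms.ObservedMutationSet("toy", counts)
        obs_stat = np.median(np.repeat(scores, counts))

        ge = le = 0.0
        for i, j in itertools.product(range(3), repeat=2):
            w = probs[i] * probs[j]
            stat = np.median([scores[i], scores[j]])
            if stat >= obs_stat:
                ge += w
            if stat <= obs_stat:
                le += w
        p_exact = min(1.0, 2 * min(ge, le))

        n_draws = 100_000
        res = ms.monte_carlo_test(obs, cat, "ddg", n_draws=n_draws, seed=2)
        tail = min(ge, le)
        se = 2 * np.sqrt(tail * (1 - tail) / n_draws)
        assert abs(res.p_two_tailed - p_exact) <= 3 * se + 2 / n_draws

    def test_constant_score_warns_p_one(self):
        cat = make_toy_catalogue(np.ones(4), np.full(4, 1.5))
        obs = ms.ObservedMutationSet("toy", np.array([1, 0, 2, 0]))
        with pytest.warns(UserWarning, match="constant"):
            res = ms.monte_carlo_test(obs, cat, "ddg", n_draws=100, seed=3)
        assert res.p_two_tailed == 1.0

    def test_seed_mandatory_and_reproducible(self, catalogue, neutral_observed):
        with pytest.raises(ValueError, match="seed"):
            ms.monte_carlo_test(neutral_observed, catalogue, "ddg")
        a = ms.monte_carlo_test(neutral_observed, catalogue, "ddg",
                                n_draws=2000, seed=4)
        b = ms.monte_carlo_test(neutral_observed, catalogue, "ddg",
                                n_draws=2000, seed=4)
        assert a.p_two_tailed == b.p_two_tailed

    def test_unscored_entries_dropped_from_both_sides(self, catalogue):
        cat = ms.SnvCatalogue(
            region_id=catalogue.region_id,
            entries=catalogue.entries.copy(),
            class_filter=catalogue.class_filter)
        cat.entries.loc[cat.entries.index[:20], "ddg"] = np.nan
        counts = np.zeros(len(cat.entries), dtype=int)
        counts[:20] = 1  # all on unscored entries
        counts[30:40] = 2
        obs = ms.ObservedMutationSet(cat.region_id, counts)
        res = ms.monte_carlo_test(obs, cat, "ddg", n_draws=1000, seed=5)
        assert res.n == 20  # only the scored observations remain
        assert res.n_unscored_dropped == 20

    def test_pvalues_roughly_uniform_under_null(self):
        """Scaled-down calibration: with the near-continuous mean-CDF
        statistic the null p-values are approximately uniform; the discrete
        median statistic may be conservative but never anti-conservative."""
        rng = np.random.default_rng(6)
        m = 60
        cat = make_toy_catalogue(rng.uniform(0.5, 1.5, m), rng.normal(size=m))
        pvals = {"mean_cdf": [], "median": []}
        for stat in pvals:
            for _ in range(300):
                counts = rng.multinomial(100, cat.prob)
                obs = ms.ObservedMutationSet("toy", counts)
                res = ms.monte_carlo_test(obs, cat, "ddg", statistic=stat,
                                          n_draws=2000, seed=rng)
                pvals[stat].append(res.p_two_tailed)
        ks = sps.kstest(pvals["mean_cdf"], "uniform").statistic
        assert ks < 0.1
        assert np.mean(np.array(pvals["mean_cdf"]) <= 0.05) <= 0.08
        assert np.mean(np.array(pvals["median"]) <= 0.05) <= 0.08


class TestCdfTransform:
    def test_uniform_three_values(self):
        f = ms.cdf_transform(np.array([1.0, 2.0, 3.0]), np.full(3, 1 / 3))
        assert f[1] == pytest.approx(1 / 3 + 1 / 6)

    def test_minimum_value_is_half_its_mass(self):
        probs = np.array([0.2, 0.5, 0.3])
        f = ms.cdf_transform(np.array([-1.0, 0.0, 1.0]), probs)
        assert f[0] == pytest.approx(0.1)

    def test_ties_share_mass(self):
        f = ms.cdf_transform(np.array([1.0, 1.0, 2.0]),
                             np.array([0.25, 0.25, 0.5]))
        assert f[0] == f[1] == pytest.approx(0.25)
        assert f[2] == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=40), st.integers(0, 2**32 - 1))
    def test_null_mean_is_half(self, m, seed):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0.01, 1.0, m)
        probs /= probs.sum()
        values = rng.choice(np.arange(10.0), size=m)  # forces ties
        f = ms.cdf_transform(values, probs)
        assert float(probs @ f) == pytest.approx(0.5, abs=1e-12)


class TestCdfShift:
    def test_null_against_itself_is_zero(self, catalogue):
        res = ms.cdf_shift(catalogue.prob, catalogue, "ddg")
        assert res.shift == pytest.approx(0.0, abs=1e-12)

    def test_all_observed_at_maximum(self):
        probs = np.array([0.45, 0.45, 0.1])
        cat = make_toy_catalogue(probs, [0.0, 1.0, 7.0])
        obs = ms.ObservedMutationSet("toy", np.array([0, 0, 10]))
        res = ms.cdf_shift(obs, cat, "ddg")
        assert res.shift == pytest.approx(0.5 - probs[2] / 2, abs=1e-12)

    def test_all_observed_at_minimum(self):
        probs = np.array([0.1, 0.45, 0.45])
        cat = make_toy_catalogue(probs, [-3.0, 1.0, 7.0])
        obs = ms.ObservedMutationSet("toy", np.array([10, 0, 0]))
        res = ms.cdf_shift(obs, cat, "ddg")
        assert res.shift == pytest.approx(-(0.5 - probs[0] / 2), abs=1e-12)

    def test_limit_approaches_half_as_mass_shrinks(self):
        shifts = []
        for p_max in (1e-2, 1e-4, 1e-6):
            probs = np.array([1 - p_max, p_max])
            cat = make_toy_catalogue(probs, [0.0, 5.0])
            obs = ms.ObservedMutationSet("toy", np.array([0, 3]))
            shifts.append(ms.cdf_shift(obs, cat, "ddg").shift)
        assert shifts == sorted(shifts)
        assert shifts[-1] == pytest.approx(0.5, abs=1e-5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=2, max_value=60), st.integers(0, 2**32 - 1))
    def test_bounded(self, m, seed):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(1e-6, 1.0, m)
        cat = make_toy_catalogue(probs, rng.normal(size=m))
        counts = rng.multinomial(rng.integers(1, 50), np.ones(m) / m)
        if counts.sum() == 0:
            counts[0] = 1
        res = ms.cdf_shift(ms.ObservedMutationSet("toy", counts), cat, "ddg")
        assert -0.5 <= res.shift <= 0.5

    def test_empty_errors(self):
        cat = make_toy_catalogue(np.ones(3), [1.0, 2.0, 3.0])
        obs = ms.ObservedMutationSet("toy", np.zeros(3, dtype=int))
        with pytest.raises(EmptyObservationError):
            ms.cdf_shift(obs, cat, "ddg")


class TestAggregateGeneShift:
    def _shift(self, value, gene="G"):
        return ms.CdfShiftResult(shift=value, n=10, gene_id=gene)

    def test_single_structure_identity(self):
        agg = ms.aggregate_gene_shift([self._shift(0.3)])
        assert agg.shift == 0.3

    def test_mean_of_two(self):
        agg = ms.aggregate_gene_shift([self._shift(0.2), self._shift(0.4)])
        assert agg.shift == pytest.approx(0.3)

    def test_order_invariance(self):
        shifts = [self._shift(s) for s in (0.1, -0.2, 0.45)]
        a = ms.aggregate_gene_shift(shifts)
        b = ms.aggregate_gene_shift(list(reversed(shifts)))
        assert a.shift == pytest.approx(b.shift)

    def test_empty_errors(self):
        with pytest.raises(EmptyObservationError):
            ms.aggregate_gene_shift([])


class TestCorrelateShiftDnds:
    def test_collinear_gives_r_one(self):
        genes = {f"G{i}": 0.1 * i for i in range(5)}
        dnds = {g: float(np.exp(2 * s + 1)) for g, s in genes.items()}
        r, p, n = ms.correlate_shift_dnds(genes, dnds)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_matches_textbook_pearson(self):
        shifts = {"A": 0.1, "B": -0.2, "C": 0.4, "D": 0.0, "E": 0.25}
        dnds = {"A": 1.5, "B": 0.4, "C": 6.0, "D": 1.0, "E": 2.0}
        x = np.array([shifts[g] for g in "ABCDE"])
        y = np.log([dnds[g] for g in "ABCDE"])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        r, _, n = ms.correlate_shift_dnds(shifts, dnds)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert n == 5

    def test_nonpositive_dnds_excluded_with_warning(self):
        shifts = {"A": 0.1, "B": -0.2, "C": 0.4, "D": 0.0}
        dnds = {"A": 1.5, "B": 0.4, "C": 6.0, "D": 0.0}
        with pytest.warns(UserWarning, match="non-positive"):
            _, _, n = ms.correlate_shift_dnds(shifts, dnds)
        assert n == 3
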