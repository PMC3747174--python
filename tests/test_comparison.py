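"""The global test model/results: statistic, p-value, CI, power."""

import warnings

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from funcomp import (AnnotationIndex, ContractedProfile, ExpandedProfile,
                     PairDecomposition, PairPopulation, ProfileComparison,
                     approx_power, compare_lists, global_statistic,
                     random_population, shifted_population, simulate_pair)


class TestGlobalStatistic:
    def test_identical_profiles_zero(self):
        P = ContractedProfile(10, [0.5, 0.2], ["A1", "A2"])
        assert global_statistic(P, P, 10, 10) == 0.0

    def test_hand_value(self):
        P = ContractedProfile(100, [0.5, 0.5, 0.5], ["A1", "A2", "A3"])
        Q = ContractedProfile(100, [0.25, 0.5, 0.75], ["A1", "A2", "A3"])
        assert global_statistic(P, Q, 100, 100) == pytest.approx(6.25)

    def test_scales_linearly_with_sample_size(self):
        P = ContractedProfile(50, [0.3, 0.6], ["A1", "A2"])
        Q = ContractedProfile(80, [0.5, 0.4], ["A1", "A2"])
        v1 = global_statistic(P, Q, 50, 80)
        v2 = global_statistic(P, Q, 100, 160)
        assert v2 == pytest.approx(2 * v1)


class TestCompareLists:
    def test_identical_lists_never_reject(self, toy_ann, toy_genes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_lists(toy_genes, toy_genes, toy_ann)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.reject

    def test_symmetry_in_list_order(self):
        rng = np.random.default_rng(2)
        pop = random_population(6, rng)
        dec = simulate_pair(PairPopulation.null(pop), 80, 60, 20, rng)
        rev = PairDecomposition(n=dec.m, m=dec.n, k=dec.k, P0=dec.P0,
                                P1=dec.Q1, Q1=dec.P1,
                                class_order=dec.class_order)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = ProfileComparison.from_decomposition(dec).fit()
            r2 = ProfileComparison.from_decomposition(rev).fit()
        assert r1.d == pytest.approx(r2.d, abs=1e-14)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        np.testing.assert_allclose(r1.beta, r2.beta, atol=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_single_class_matches_two_proportion_z_test(self):
        """With one target class the global p-value reduces exactly to the
        unpooled two-sample z-test p-value referred to chi2_1."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(30):
            n, m = (int(v) for v in rng.integers(20, 80, 2))
            pa, pb = rng.uniform(0.2, 0.8, 2)
            genesA = [f"a{i}" for i in range(n)]
            genesB = [f"b{i}" for i in range(m)]
            hitsA = {g for g in genesA if rng.random() < pa}
            hitsB = {g for g in genesB if rng.random() < pb}
            ann = AnnotationIndex(
                {g: ({"A1"} if g in hitsA | hitsB else set())
                 for g in genesA + genesB}, ["A1"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = compare_lists(genesA, genesB, ann, include_unannotated=True)
            phat, qhat = len(hitsA) / n, len(hitsB) / m
            va, vc = phat * (1 - phat), qhat * (1 - qhat)
            if va + vc == 0:
                continue
            z2 = (phat - qhat) ** 2 / (va / n + vc / m)
            assert res.p_value == pytest.approx(chi2.sf(z2, 1), abs=1e-10)
            checked += 1
        assert checked >= 20

    def test_pvalues_approximately_uniform_under_null(self):
        """Under profile equality with overlapping lists, the p-value
        distribution is close to uniform (KS distance <= 0.05)."""
        rng = np.random.default_rng(42)
        pop = random_population(12, rng)
        pair = PairPopulation.null(pop)
        pvals = np.empty(2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in range(2000):
                dec = simulate_pair(pair, 120, 120, 30, rng)
                pvals[r] = ProfileComparison.from_decomposition(dec).fit().p_value
        ks = kstest(pvals, "uniform").statistic
        assert ks <= 0.05


class TestDistanceCI:
    def _fit(self, dec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ProfileComparison.from_decomposition(dec).fit()

    def test_identical_profiles_zero_interval(self, toy_ann, toy_genes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_lists(toy_genes, toy_genes, toy_ann)
        assert (res.ci_lower, res.ci_upper) == (0.0, 0.0)
        assert res.sigma_hat == 0.0

    def test_width_shrinks_as_root_sample_size(self):
        # scaling all counts by 4 keeps profiles and covariances fixed,
        # so the half-width must exactly halve
        order = ["A1", "A2"]

        def dec_scaled(f):
            P1 = ExpandedProfile(20 * f, {(0,): 12 * f, (1,): 8 * f}, order)
            Q1 = ExpandedProfile(30 * f, {(0,): 9 * f, (0, 1): 21 * f}, order)
            empty = ExpandedProfile(0, {}, order)
            return PairDecomposition(n=20 * f, m=30 * f, k=0, P0=empty,
                                     P1=P1, Q1=Q1, class_order=order)

        r1, r4 = self._fit(dec_scaled(1)), self._fit(dec_scaled(4))
        assert r1.d == pytest.approx(r4.d, abs=1e-14)
        half1 = (r1.ci_upper - r1.ci_lower) / 2
        half4 = (r4.ci_upper - r4.ci_lower) / 2
        assert half4 == pytest.approx(half1 / 2, rel=1e-10)

    def test_interval_contains_estimate(self):
        rng = np.random.default_rng(14)
        pop = random_population(5, rng)
        dec = simulate_pair(PairPopulation.null(pop), 100, 90, 0, rng)
        res = self._fit(dec)
        assert res.ci_lower <= res.d <= res.ci_upper


class TestApproxPower:
    def _populations(self, s, shift, seed):
        rng = np.random.default_rng(seed)
        popP = random_population(s, rng)
        popQ = shifted_population(popP, shift, rng)
        return PairPopulation(pop0=None, pop1=popP, popQ1=popQ)

    def test_limits_and_monotonicity(self):
        pair = self._populations(6, 0.5, 1)
        big = approx_power(pair, 4000, 4000, 0, alpha=0.05)
        assert big > 0.999
        powers = [approx_power(pair, 100, 100, 0, alpha=a)
                  for a in (0.2, 0.05, 0.01, 0.001)]
        assert all(np.diff(powers) < 1e-12)

    def test_zero_distance_error(self):
        rng = np.random.default_rng(3)
        pop = random_population(4, rng)
        with pytest.raises(ValueError, match="distance is zero"):
            approx_power(PairPopulation.null(pop), 50, 50, 0)

    def test_agrees_with_empirical_power(self):
        """Moderate alternative: normal-approximation power within 0.05 of
        the simulated rejection rate."""
        pair = self._populations(10, 0.35, 8)
        n = m = 200
        predicted = approx_power(pair, n, m, 0, alpha=0.05)
        rng = np.random.default_rng(77)
        hits = 0
        reps = 1500
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(reps):
                dec = simulate_pair(pair, n, m, 0, rng)
                hits += ProfileComparison.from_decomposition(dec).fit().reject
        assert predicted == pytest.approx(hits / reps, abs=0.05)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(10)
        popP = random_population(5, rng)
        powers = []
        for shift in (0.1, 0.3, 0.6):
            rng_dir = np.random.default_rng(55)  # same direction each time
            popQ = shifted_population(popP, shift, rng_dir)
            pair = PairPopulation(pop0=None, pop1=popP, popQ1=popQ)
            powers.append(approx_power(pair, 150, 150, 0))
        assert powers[0] <= powers[1] <= powers[2]


class TestResultsObject:
    def test_summary_and_serialisation(self, toy_ann):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_lists(["g1", "g2", "g3"], ["g2", "g3", "g4"], toy_ann)
        text = res.summary()
        for token in ("squared distance", "p-value", "CI"):
            assert token in text
        d = res.to_dict()
        assert d["n"] == 3 and d["m"] == 3 and d["k"] == 2
        assert "p_value" in res.to_json()
        header, row = res.to_tsv().strip().split("\n")
        assert len(header.split("\t")) == len(row.split("\t"))

    def test_invariants(self):
        rng = np.random.default_rng(6)
        pop = random_population(7, rng)
        dec = simulate_pair(PairPopulation.null(pop), 90, 70, 10, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ProfileComparison.from_decomposition(dec).fit(alpha=0.1)
        expected_v = res.d * res.n * res.m / (res.n + res.m)
        assert res.statistic == pytest.approx(expected_v, rel=1e-12)
        assert res.reject == (res.p_value < res.alpha)
        if res.sigma_hat > 0:
            assert res.ci_lower <= res.d <= res.ci_upper
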