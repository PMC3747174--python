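"""Fisher/Holm classwise tests, chi-square comparator, decision procedure."""

import math
import warnings
from fractions import Fraction

import numpy as np
import pytest

from statsmodels.stats.multitest import multipletests

from funcomp import (chisq_homogeneity, class_fisher_tests, combined_procedure,
                     fisher_two_sided, holm_adjust)
from conftest import tilted_single_class_lists


def fisher_enumeration_oracle(a, b, n, m):
    """Exact integer-arithmetic two-sided Fisher p-value by enumeration."""
    r = a + b
    denom = math.comb(n + m, n)
    p_obs = Fraction(math.comb(r, a) * math.comb(n + m - r, n - a), denom)
    total = Fraction(0)
    for x in range(max(0, r - m), min(r, n) + 1):
        p = Fraction(math.comb(r, x) * math.comb(n + m - r, n - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_two_sided(5, 5, 10, 10) == pytest.approx(1.0)

    def test_extreme_table_hand_value(self):
        # [[10, 0], [0, 10]]: only the two extreme tables are as unlikely
        assert fisher_two_sided(10, 0, 10, 10) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-10)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(150):
            n, m = (int(v) for v in rng.integers(2, 31, 2))
            a, b = int(rng.integers(0, n + 1)), int(rng.integers(0, m + 1))
            if a + b == 0 or (n - a) + (m - b) == 0:
                continue
            ours = fisher_two_sided(a, b, n, m)
            oracle = fisher_enumeration_oracle(a, b, n, m)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(13)
        for _ in range(60):
            n, m = (int(v) for v in rng.integers(3, 80, 2))
            a, b = int(rng.integers(0, n + 1)), int(rng.integers(0, m + 1))
            if a + b == 0 or (n - a) + (m - b) == 0:
                continue
            expected = fisher_exact([[a, b], [n - a, m - b]])[1]
            assert fisher_two_sided(a, b, n, m) == pytest.approx(expected, abs=1e-10)


class TestHolm:
    def test_hand_examples(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])
        np.testing.assert_allclose(holm_adjust([0.02] * 4), [0.08] * 4)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 25)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            expected = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(holm_adjust(p), expected, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestChisqHomogeneity:
    def test_identical_rows(self):
        stat, df, p = chisq_homogeneity([10, 20, 30], [10, 20, 30])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        stat, df, p = chisq_homogeneity([10, 20], [20, 10])
        assert stat == pytest.approx(20 / 3, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(0.00982, abs=5e-6)

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = int(rng.integers(2, 8))
            cP = rng.integers(1, 50, s)
            cQ = rng.integers(1, 50, s)
            stat, df, p = chisq_homogeneity(cP, cQ)
            ref = chi2_contingency(np.array([cP, cQ]), correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert df == ref.dof
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_columns_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-count"):
            stat, df, p = chisq_homogeneity([10, 0, 20], [15, 0, 15])
        assert df == 1

    def test_all_but_one_empty_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="at least two"):
                chisq_homogeneity([10, 0], [15, 0])


class TestClassFisherTable:
    def test_table_shape_and_flags(self, toy_ann):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = class_fisher_tests(["g1", "g2"], ["g3", "g4"], toy_ann)
        assert list(table["class_id"]) == ["A1", "A2", "A3"]
        assert np.all(table["holm_p"] >= table["raw_p"] - 1e-15)
        # no gene of either list is annotated in A1 on the B side only:
        # degenerate flag fires only for empty margins
        assert not table.loc[0, "degenerate"]

    def test_empty_margin_flagged(self):
        from funcomp import AnnotationIndex
        ann = AnnotationIndex({"a": {"A1"}, "b": {"A1"}}, ["A1", "A2"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = class_fisher_tests(["a"], ["b"], ann)
        assert table.loc[1, "degenerate"]
        assert table.loc[1, "raw_p"] == 1.0


class TestCombinedProcedure:
    def test_step1_gate_blocks_classwise(self, toy_ann, toy_genes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = combined_procedure(toy_genes, toy_genes, toy_ann)
        assert dec.outcome == "no_difference"
        assert dec.classwise is None
        assert dec.significant_classes() == []

    def test_step2_identifies_classes(self):
        from funcomp import AnnotationIndex
        classes = ["A1", "A2", "A3"]
        mapping, A, B = {}, [], []
        g = 0
        for counts, lst in (((25, 5, 10), A), ((5, 25, 10), B)):
            for i, c in enumerate(counts):
                for _ in range(c):
                    mapping[f"g{g}"] = {classes[i]}
                    lst.append(f"g{g}")
                    g += 1
        ann = AnnotationIndex(mapping, classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = combined_procedure(A, B, ann)
        assert dec.outcome == "classes_identified"
        assert set(dec.significant_classes()) == {"A1", "A2"}

    def test_step3_suggests_smallest_raw_p(self):
        A, B, ann = tilted_single_class_lists(s=20, base=10, tilt=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = combined_procedure(A, B, ann)
        assert dec.outcome == "suggested_class"
        assert dec.global_result.reject
        assert not dec.classwise["significant"].any()
        best = dec.classwise.loc[dec.classwise["raw_p"].idxmin(), "class_id"]
        assert dec.suggested_class == best

    def test_step3_uplevel_option(self):
        A, B, ann = tilted_single_class_lists(s=20, base=10, tilt=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = combined_procedure(A, B, ann, step3="uplevel")
        assert dec.outcome == "recommend_higher_level"
        assert dec.suggested_class is None

    def test_invalid_step3(self, toy_ann, toy_genes):
        with pytest.raises(ValueError):
            combined_procedure(toy_genes, toy_genes, toy_ann, step3="bogus")
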