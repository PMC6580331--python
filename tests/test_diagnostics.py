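"""Unit, oracle and property tests for the diagnostic accuracy machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from thioburden.diagnostics import (
    ContingencyTable,
    DipGroup,
    build_contingency,
    compute_dip,
    delong_test,
    dichotomize,
    group_tests,
    mcnemar_test,
    metrics,
    roc_auc,
    youden_cutpoint,
)


def bruteforce_auc(scores, outcomes):
    """All-pairs concordance count (ties 0.5) — the Mann-Whitney AUC."""
    pos = [s for s, o in zip(scores, outcomes) if o]
    neg = [s for s, o in zip(scores, outcomes) if not o]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestDip:
    @pytest.mark.parametrize(
        "actual, planned, expected",
        [(50, 50, 100.0), (11.85, 50, 23.7), (7, 50, 14.0), (0, 50, 0.0)],
    )
    def test_worked_values(self, actual, planned, expected):
        assert compute_dip(actual, planned) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_planned_errors(self):
        with pytest.raises(ValueError):
            compute_dip(10, 0)

    @pytest.mark.parametrize(
        "dip, thr, expected",
        [
            (25.0, 25, DipGroup.AT_OR_BELOW),  # inclusive boundary
            (25.01, 25, DipGroup.ABOVE),
            (5.712, 25, DipGroup.AT_OR_BELOW),
        ],
    )
    def test_dichotomize(self, dip, thr, expected):
        assert dichotomize(dip, thr) is expected


class TestContingency:
    def test_from_paired_vectors(self):
        preds = [True] * 55 + [False] * 189
        outcomes = [True] * 9 + [False] * 46 + [True] * 10 + [False] * 179
        tab = build_contingency(preds, outcomes)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (9, 46, 10, 179)

    def test_all_negative(self):
        tab = build_contingency([False] * 10, [False] * 10)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (0, 0, 0, 10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_contingency([True], [True, False])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_star_predictor_table(self):
        m = metrics(ContingencyTable(tp=9, fp=46, fn=10, tn=179))
        assert m.sensitivity == pytest.approx(100 * 9 / 19, abs=1e-9)
        assert m.specificity == pytest.approx(100 * 179 / 225, abs=1e-9)
        assert m.ppv == pytest.approx(100 * 9 / 55, abs=1e-9)
        assert m.npv == pytest.approx(100 * 179 / 189, abs=1e-9)
        assert m.accuracy == pytest.approx(100 * 188 / 244, abs=1e-9)

    def test_burden_predictor_table(self):
        m = metrics(ContingencyTable(tp=10, fp=42, fn=9, tn=183))
        assert round(m.sensitivity, 2) == 52.63
        assert round(m.specificity, 2) == 81.33
        assert round(m.ppv, 2) == 19.23
        assert round(m.npv, 2) == 95.31
        assert round(m.accuracy, 2) == 79.10

    def test_zero_denominators_reported_missing(self):
        m = metrics(ContingencyTable(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 100.0 and m.accuracy == 100.0

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_algebraic_identities(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        tab = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        m = metrics(tab)
        assert m.accuracy * tab.total == pytest.approx(100 * (tp + tn))
        # PPV consistent with Bayes' rule given prevalence
        if m.sensitivity is not None and m.specificity is not None and m.ppv is not None:
            prev = (tp + fn) / tab.total
            se, sp = m.sensitivity / 100, m.specificity / 100
            denom = se * prev + (1 - sp) * (1 - prev)
            if denom > 0:
                assert m.ppv / 100 == pytest.approx(se * prev / denom, abs=1e-9)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_uninformative_ties(self):
        auc, _ = roc_auc([1.0] * 6, [True, False, True, False, False, True])
        assert auc == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(4, 51))
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)
            outcomes = rng.random(n) < 0.4
            if outcomes.all() or not outcomes.any():
                continue
            auc, _ = roc_auc(scores, outcomes)
            assert auc == pytest.approx(bruteforce_auc(scores, outcomes), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.random(40)
        outcomes = rng.random(40) < 0.5
        auc, _ = roc_auc(scores, outcomes)
        assert auc == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-12)

    def test_lower_score_orientation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.9, 1.0], [True, True, False, False],
                         higher_score_means_event=False)
        assert auc == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(25)
        outcomes = rng.random(25) < 0.5
        if outcomes.all() or not outcomes.any():
            return
        a1, _ = roc_auc(scores, outcomes)
        a2, _ = roc_auc(np.exp(3 * scores) + 1, outcomes)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestDeLong:
    def test_identical_classifiers_p_one(self):
        s = [0.1, 0.4, 0.35, 0.8, 0.7]
        o = [False, False, True, True, True]
        assert delong_test(s, s, o) == 1.0

    def test_opposite_classifiers_on_separable_data(self):
        rng = np.random.default_rng(3)
        n = 80
        o = np.arange(n) < 40
        good = o * 1.0 + rng.normal(0, 0.1, n)
        bad = -good
        assert delong_test(good, bad, o) < 0.05

    def test_agrees_with_bootstrap_on_rejection(self):
        """Decision at alpha=0.05 matches a paired bootstrap of AUC differences."""
        rng = np.random.default_rng(11)
        n = 60
        o = rng.random(n) < 0.5
        if o.all() or not o.any():
            o[0] = ~o[0]
        a = o + rng.normal(0, 0.8, n)
        b = rng.normal(0, 1, n)  # uninformative
        p = delong_test(a, b, o)
        diffs = []
        idx = np.arange(n)
        for _ in range(2000):
            s = rng.choice(idx, size=n, replace=True)
            if o[s].all() or not o[s].any():
                continue
            diffs.append(bruteforce_auc(a[s], o[s]) - bruteforce_auc(b[s], o[s]))
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        bootstrap_rejects = not (lo <= 0.0 <= hi)
        assert (p < 0.05) == bootstrap_rejects


class TestYouden:
    def test_separating_threshold_classifies_perfectly(self):
        scores = [0.9, 0.8, 0.75, 0.2, 0.1]
        outcomes = [True, True, True, False, False]
        cut = youden_cutpoint(scores, outcomes)
        assert all((s >= cut) == o for s, o in zip(scores, outcomes))

    def test_tie_prefers_more_specific_bin(self):
        # both thresholds 0.3 and 0.5 give J=1 here; 0.5 is more specific
        scores = [0.5, 0.9, 0.1, 0.2]
        outcomes = [True, True, False, False]
        assert youden_cutpoint(scores, outcomes) == 0.5

    def test_degenerate_scores_warn(self):
        with pytest.warns(UserWarning):
            cut = youden_cutpoint([0.4] * 4, [True, False, True, False])
        assert cut == 0.4

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=30)
        outcomes = rng.random(30) < 0.4
        cut = youden_cutpoint(scores, outcomes)
        best = max(
            np.unique(scores),
            key=lambda t: (
                sum((scores >= t) & outcomes) / outcomes.sum()
                + sum((scores < t) & ~outcomes) / (~outcomes).sum(),
                t,
            ),
        )
        assert cut == best

    def test_burden_cutpoint_on_paperlike_cohort(self, defs):
        """On a cohort with the default effect structure the Youden-optimal
        combined-GVB cutpoint lands at the 0.3 bin boundary."""
        from thioburden.simulate import CohortSimParams, simulate_cohort

        cohort = simulate_cohort(CohortSimParams(n_patients=3000, seed=17), defs)
        gvb = cohort.truth["combined_gvb"].to_numpy()
        events = cohort.truth["dip"].to_numpy() <= 25
        cut = youden_cutpoint(gvb, events, higher_score_means_event=False)
        assert 0.25 <= cut <= 0.35


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = group_tests(vals, groups)
        assert res["mannwhitney_a_vs_b"].pvalue > 0.9

    def test_monotone_values_give_perfect_rank_correlation(self):
        vals = [1, 2, 3, 4, 5, 6]
        groups = ["a", "b", "c", "d", "e", "f"]
        res = group_tests(vals, groups)
        assert res["spearman"].statistic == pytest.approx(1.0)
        assert res["kendall"].statistic == pytest.approx(1.0)

    def test_mannwhitney_exact_matches_enumeration(self):
        """scipy's exact Mann-Whitney p equals a brute-force enumeration."""
        va = [1.3, 2.1, 5.2, 7.7]
        vb = [0.5, 3.3, 4.1, 9.9]
        res = group_tests(va + vb, ["a"] * 4 + ["b"] * 4, exact=True)
        pooled = va + vb
        n_a = len(va)

        def u_stat(a_vals):
            return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a_vals for y in pooled if y not in a_vals)

        obs_u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in va for y in vb)
        m = n_a * len(vb)
        count = total = 0
        for comb in itertools.combinations(pooled, n_a):
            rest = list(pooled)
            for c in comb:
                rest.remove(c)
            u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in comb for y in rest)
            total += 1
            if abs(u - m / 2) >= abs(obs_u - m / 2) - 1e-12:
                count += 1
        assert res["mannwhitney_a_vs_b"].pvalue == pytest.approx(count / total, abs=1e-6)

    def test_kruskal_exact_matches_scipy_permutation(self):
        """The in-house exact Kruskal-Wallis permutation p equals scipy's
        exhaustive permutation_test on the same statistic."""
        va = [1.0, 4.0, 2.5]
        vb = [3.0, 6.0]
        vc = [5.0, 8.0, 7.0]
        res = group_tests(va + vb + vc, ["a"] * 3 + ["b"] * 2 + ["c"] * 3, exact=True)

        def stat(x, y, z):
            return sps.kruskal(x, y, z).statistic

        ref = sps.permutation_test(
            (va, vb, vc), stat, permutation_type="independent",
            alternative="greater", n_resamples=np.inf, rng=0,
        )
        assert res["kruskal_wallis"].pvalue == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_group_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="thioburden.diagnostics"):
            res = group_tests([1.0, 2.0], ["a", "a"])
        assert res == {}


class TestMcNemar:
    def test_identical_vectors(self):
        assert mcnemar_test([True, False, True], [True, False, True]) == 1.0

    def test_five_zero_discordance(self):
        # 5 discordant pairs all in one direction: p = 2 * 0.5^5
        a = [True] * 5 + [True] * 3
        b = [False] * 5 + [True] * 3
        assert mcnemar_test(a, b) == pytest.approx(0.0625, abs=1e-12)

    def test_matches_binomial_closed_form(self):
        rng = np.random.default_rng(13)
        a = rng.random(30) < 0.6
        b = rng.random(30) < 0.6
        n01 = int((~a & b).sum())
        n10 = int((a & ~b).sum())
        p = mcnemar_test(a, b)
        k, n = min(n01, n10), n01 + n10
        expected = min(1.0, 2.0 * sps.binom.cdf(k, n, 0.5)) if n else 1.0
        # exact two-sided binomial with equal tails
        assert p == pytest.approx(expected, abs=1e-9)
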