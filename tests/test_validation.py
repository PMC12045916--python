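"""Contingency construction, exact intervals, weighted variants, baseline,
and the two-proportion comparison."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ldctscreen import (
    ContingencyTable,
    MissingGoldError,
    UnablePolicy,
    accuracy_metrics,
    build_contingency,
    clopper_pearson,
    compare_proportions,
    cpt_baseline,
    percent,
    weighted_metrics,
)

from tests.conftest import calls_from_counts, make_result


class TestBuildContingency:
    def test_reconstructs_published_panel(self):
        calls, gold = calls_from_counts(87, 5, 3, 19)
        t = build_contingency(calls, gold, UnablePolicy.EXCLUDE)
        assert (t.tp, t.fp, t.fn, t.tn) == (87, 5, 3, 19)
        assert t.n_unable_included == 0

    def test_unable_as_nonscreening_moves_unable_into_bottom_row(self):
        calls, gold = calls_from_counts(87, 5, 3, 19, unable_nonscreening=22, unable_screening=11)
        t = build_contingency(calls, gold, "unable_as_nonscreening")
        assert (t.tp, t.fp, t.fn, t.tn) == (87, 5, 14, 41)
        assert t.n_unable_included == 33

    def test_exclude_policy_drops_unable_and_counts_them(self):
        calls, gold = calls_from_counts(1, 0, 0, 1, unable_nonscreening=2, unable_screening=1)
        t = build_contingency(calls, gold, UnablePolicy.EXCLUDE)
        assert t.total == 2 and t.n_unable_dropped == 3

    def test_empty_input(self):
        t = build_contingency([], {}, UnablePolicy.EXCLUDE)
        assert t.total == 0

    def test_excluded_calls_and_unknown_gold_dropped(self):
        calls = [make_result("a", "excluded"), make_result("b", "screening")]
        t = build_contingency(calls, {"b": "unknown"}, UnablePolicy.EXCLUDE)
        assert t.total == 0 and t.n_excluded == 1 and t.n_unknown_gold == 1

    def test_missing_gold_lists_scan_ids(self):
        calls = [make_result("a", "screening"), make_result("b", "non_screening")]
        with pytest.raises(MissingGoldError) as exc:
            build_contingency(calls, {"a": "screening"})
        assert exc.value.scan_ids == ["b"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=0)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (87, 90), (19, 24), (1, 1), (3, 7)])
    def test_matches_independent_beta_oracle(self, k, n):
        lo, hi = clopper_pearson(k, n)
        olo, ohi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(0.0 if k == 0 else olo, abs=1e-12)
        assert hi == pytest.approx(1.0 if k == n else ohi, abs=1e-12)

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0
        lo, _ = clopper_pearson(5, 5)
        assert lo == pytest.approx(0.4781762, abs=1e-6)  # (alpha/2)^(1/n) closed form

    def test_contains_point_and_width_shrinks_with_n(self):
        for k, n in [(3, 10), (30, 100), (300, 1000)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi
        widths = [np.diff(clopper_pearson(3 * m, 10 * m))[0] for m in (1, 10, 100)]
        assert widths[0] > widths[1] > widths[2]

    @pytest.mark.parametrize("k,n", [(-1, 5), (6, 5), (0, 0)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            clopper_pearson(k, n)


class TestAccuracyMetrics:
    def test_published_panel_point_estimates_and_identities(self):
        calls, gold = calls_from_counts(87, 5, 3, 19)
        t = build_contingency(calls, gold)
        r = accuracy_metrics(t)
        assert r.sensitivity.point == pytest.approx(87 / 90)
        assert r.specificity.point == pytest.approx(19 / 24)
        assert r.ppv.point == pytest.approx(87 / 92)
        assert r.npv.point == pytest.approx(19 / 22)
        for est, denom in [(r.sensitivity, 90), (r.specificity, 24), (r.ppv, 92), (r.npv, 22)]:
            assert est.point * denom == pytest.approx(est.numerator)
            assert est.lower <= est.point <= est.upper

    def test_zero_denominator_flagged_not_raised(self):
        r = accuracy_metrics(ContingencyTable(tp=5, fp=0, fn=0, tn=0))
        assert r.sensitivity.defined and r.sensitivity.point == 1.0
        assert r.sensitivity.lower == pytest.approx(0.4781762, abs=1e-6)
        assert not r.specificity.defined and not r.npv.defined
        assert math.isnan(r.specificity.point)

    def test_ppv_invariant_to_unable_policy(self):
        calls, gold = calls_from_counts(141, 16, 7, 96, unable_nonscreening=55, unable_screening=20)
        excl = accuracy_metrics(build_contingency(calls, gold, "exclude_unable"))
        incl = accuracy_metrics(build_contingency(calls, gold, "unable_as_nonscreening"))
        assert incl.ppv.point == excl.ppv.point  # unable scans never enter the screening row
        assert incl.npv.point < excl.npv.point


class TestWeightedMetrics:
    def test_equal_weights_degenerate_to_unweighted(self):
        calls, gold = calls_from_counts(8, 2, 1, 5)
        weights = {c.scan_id: 1.0 for c in calls}
        unw = accuracy_metrics(build_contingency(calls, gold))
        w = weighted_metrics(calls, gold, weights)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(w, name).point == getattr(unw, name).point
            assert getattr(w, name).lower == pytest.approx(getattr(unw, name).lower, abs=1e-12)

    def test_scale_invariance(self):
        calls, gold = calls_from_counts(8, 2, 1, 5)
        w1 = weighted_metrics(calls, gold, {c.scan_id: 1.0 for c in calls})
        w2 = weighted_metrics(calls, gold, {c.scan_id: 2.0 for c in calls})
        assert w2.ppv.point == w1.ppv.point

    def test_two_scan_toy_weights(self):
        calls, gold = calls_from_counts(1, 1, 0, 0)
        tp_id, fp_id = calls[0].scan_id, calls[1].scan_id
        assert weighted_metrics(calls, gold, {tp_id: 1.0, fp_id: 3.0}).ppv.point == 0.25
        assert weighted_metrics(calls, gold, {tp_id: 3.0, fp_id: 1.0}).ppv.point == 0.75

    def test_missing_weight_rejected(self):
        calls, gold = calls_from_counts(1, 1, 0, 0)
        with pytest.raises(ValueError, match="weight"):
            weighted_metrics(calls, gold, {calls[0].scan_id: 1.0})


class TestCptBaseline:
    def test_gold_screening_fraction_is_the_ppv(self):
        labels = ["screening"] * 101 + ["non_screening"] * 46
        r = cpt_baseline(labels)
        assert r.ppv.point == pytest.approx(101 / 147)
        assert percent(r.ppv.point) == 69
        assert not r.sensitivity.defined and not r.npv.defined

    def test_degenerate_all_one_class(self):
        assert cpt_baseline(["screening"] * 5).ppv.point == 1.0
        assert cpt_baseline(["non_screening"] * 5).ppv.point == 0.0


class TestCompareProportions:
    def test_identical_proportions_give_p_one(self):
        r = compare_proportions(10, 20, 10, 20)
        assert r.pvalue == pytest.approx(1.0)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_fisher_exact_order_of_magnitude(self):
        # exact oracle: 2 / C(20,10) by enumeration of the extreme tables
        fisher_p = stats.fisher_exact([[0, 10], [10, 0]])[1]
        assert fisher_p == pytest.approx(2 / math.comb(20, 10))
        r = compare_proportions(0, 10, 10, 10)
        assert 1e-6 < r.pvalue < 1e-3  # same order of magnitude as 1.08e-5

    def test_continuity_correction_flag(self):
        with_c = compare_proportions(10, 40, 20, 40)
        without = compare_proportions(10, 40, 20, 40, correction=False)
        assert without.statistic > with_c.statistic

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compare_proportions(5, 4, 1, 2)
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 2)


def test_clopper_pearson_coverage_simulation():
    """95% CP intervals cover the true p in at least 95% of simulated
    binomial draws (conservative by construction)."""
    rng = np.random.default_rng(20240918)
    n, p, reps = 50, 0.8, 2000
    ks = rng.binomial(n, p, size=reps)
    covered = 0
    for k in ks:
        lo, hi = clopper_pearson(int(k), n)
        covered += lo <= p <= hi
    assert covered / reps >= 0.95
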