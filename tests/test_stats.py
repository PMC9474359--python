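"""Tests for the two-sample statistics layer."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from etmorph import (
    SummaryStats,
    ValidationError,
    compare_cohorts,
    fisher_exact_2x2,
    generate_cohort,
    measure_cohort,
    measurements_to_frame,
    min_sample_size,
    t_test_from_samples,
    t_test_from_summary,
)


class TestTTestFromSummary:
    def test_cohort_headline_angle_comparison(self):
        """60 vs 60 ears, means 33.0/27.8, SDs 6.1/5.1: pooled t ~ 5.07 on
        118 df, p ~ 1.5e-6 (scipy's summary t-test is the oracle)."""
        r = t_test_from_summary(SummaryStats(60, 33.0, 6.1),
                                SummaryStats(60, 27.8, 5.1))
        oracle = sps.ttest_ind_from_stats(33.0, 6.1, 60, 27.8, 5.1, 60)
        assert r.statistic == pytest.approx(oracle.statistic, abs=1e-9)
        assert r.p_value == pytest.approx(oracle.pvalue, rel=1e-9)
        assert r.statistic == pytest.approx(5.066, abs=2e-3)
        assert r.df == 118
        assert r.p_value == pytest.approx(1.5e-6, rel=0.05)
        assert r.p_value <= 1e-4

    def test_identical_groups_give_p_one(self):
        s = SummaryStats(60, 33.0, 5.0)
        r = t_test_from_summary(s, s)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_plane_equivalence_comparison_is_nonsignificant(self):
        """60 vs 60 ears, 33.0 (5.3) vs 34.7 (5.2): |t| ~ 1.77, p ~ 0.08."""
        r = t_test_from_summary(SummaryStats(60, 33.0, 5.3),
                                SummaryStats(60, 34.7, 5.2))
        assert abs(r.statistic) == pytest.approx(1.773, abs=2e-3)
        assert r.p_value == pytest.approx(0.0788, abs=2e-3)

    def test_welch_matches_scipy(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(3, 40, 2)
            xs, ys = rng.normal(0, 2, n1), rng.normal(0.5, 3, n2)
            mine = t_test_from_samples(xs, ys, "welch")
            oracle = sps.ttest_ind(xs, ys, equal_var=False)
            assert mine.statistic == pytest.approx(oracle.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_zero_variance_conventions(self):
        assert t_test_from_summary(SummaryStats(5, 1.0, 0.0),
                                   SummaryStats(5, 1.0, 0.0)).p_value == 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            r = t_test_from_summary(SummaryStats(5, 1.0, 0.0),
                                    SummaryStats(5, 2.0, 0.0))
        assert r.p_value == 0.0

    def test_group_swap_flips_sign_and_scaling_leaves_invariant(self, rng):
        xs, ys = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        a = t_test_from_samples(xs, ys)
        b = t_test_from_samples(ys, xs)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        c = t_test_from_samples(3.7 * xs, 3.7 * ys)
        assert c.statistic == pytest.approx(a.statistic, abs=1e-9)
        assert c.p_value == pytest.approx(a.p_value, abs=1e-9)

    def test_welch_equals_student_for_balanced_equal_sd(self):
        a, b = SummaryStats(30, 10.0, 2.5), SummaryStats(30, 11.0, 2.5)
        s = t_test_from_summary(a, b, "student")
        w = t_test_from_summary(a, b, "welch")
        assert s.statistic == pytest.approx(w.statistic, abs=1e-9)
        assert s.p_value == pytest.approx(w.p_value, abs=1e-9)
        assert s.df == pytest.approx(w.df, abs=1e-9)


class TestTTestFromSamples:
    def test_identical_samples(self):
        assert t_test_from_samples([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_reduces_to_summary_path(self):
        xs, ys = [1, 2, 3, 4], [11, 12, 13, 14]
        raw = t_test_from_samples(xs, ys)
        summ = t_test_from_summary(SummaryStats.from_samples(xs),
                                   SummaryStats.from_samples(ys))
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)
        assert SummaryStats.from_samples(xs).sd == pytest.approx(
            math.sqrt(5 / 3), abs=1e-12)

    def test_within_group_order_irrelevant(self, rng):
        xs, ys = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        a = t_test_from_samples(xs, ys)
        b = t_test_from_samples(xs[::-1], rng.permutation(ys))
        assert a == b

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            t_test_from_samples([1.0], [1.0, 2.0])


class TestFisherExact:
    def test_demographics_sex_table(self):
        """14/30 vs 10/30 females: two-sided p ~ 0.43."""
        r = fisher_exact_2x2(14, 16, 10, 20)
        assert r.p_value == pytest.approx(0.43, abs=0.005)

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5).p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b + c + d == 0:
                continue
            mine = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            oracle = sps.fisher_exact([[a, b], [c, d]])
            assert mine.p_value == pytest.approx(oracle.pvalue, rel=1e-9, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(1, -1, 2, 3)

    def test_equals_brute_force_enumeration_small_margins(self):
        """Exhaustive oracle: on every table with margins <= 9, the p-value
        equals a direct enumeration of all tables with the same margins."""
        for a in range(10):
            for b in range(10 - a):
                for c in range(10 - a):
                    for d in range(10 - b if 10 - b < 10 - c else 10 - c):
                        if a + b + c + d == 0:
                            continue
                        got = fisher_exact_2x2(a, b, c, d).p_value
                        assert got == pytest.approx(
                            _brute_force_fisher(a, b, c, d), rel=1e-9, abs=1e-12)


def _brute_force_fisher(a, b, c, d):
    """Enumerate all tables with the observed margins; sum the probabilities
    of those no more likely than the observed table."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(k):
        return (math.comb(r1, k) * math.comb(n - r1, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


class TestSampleSize:
    def test_reproduces_twenty_four_ears(self):
        """sd 4.8, delta 3.9, alpha 0.05, power 0.8 -> 23.8 raw, 24 ears."""
        r = min_sample_size(sd=4.8, delta=3.9)
        assert r.n_per_group == 24
        assert r.n_unrounded == pytest.approx(23.78, abs=0.02)

    def test_unit_effect_size_needs_sixteen(self):
        r = min_sample_size(sd=1.0, delta=1.0)
        assert r.n_per_group == 16
        assert r.n_unrounded == pytest.approx(15.70, abs=0.01)

    def test_doubling_delta_quarters_unrounded_n(self):
        a = min_sample_size(sd=4.8, delta=2.0)
        b = min_sample_size(sd=4.8, delta=4.0)
        assert a.n_unrounded == pytest.approx(4 * b.n_unrounded, rel=1e-12)

    def test_power_simulation_validates_n(self, rng):
        """The computed n delivers approximately the nominal 80% power: the
        simulated detection rate matches the exact noncentral-t power (the
        normal approximation sits a hair below nominal, ~0.787 here)."""
        sd, delta = 4.8, 3.9
        n = min_sample_size(sd, delta).n_per_group
        df = 2 * n - 2
        ncp = delta / (sd * math.sqrt(2.0 / n))
        crit = sps.t.ppf(0.975, df)
        exact = sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
        assert exact == pytest.approx(0.80, abs=0.05)
        hits = 0
        reps = 2000
        for _ in range(reps):
            xs = rng.normal(0.0, sd, n)
            ys = rng.normal(delta, sd, n)
            if t_test_from_samples(xs, ys).p_value < 0.05:
                hits += 1
        se = math.sqrt(exact * (1 - exact) / reps)
        assert hits / reps == pytest.approx(exact, abs=3 * se)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            min_sample_size(sd=0.0, delta=1.0)
        with pytest.raises(ValidationError):
            min_sample_size(sd=1.0, delta=-1.0)


class TestCompareCohorts:
    def _measure(self, preset, seed, plane="kc", n=30):
        c = generate_cohort(preset, n, seed)
        return (measurements_to_frame(measure_cohort(c.landmark_sets(), plane)),
                c)

    def test_identical_cohorts_all_p_one(self):
        df, _ = self._measure("normal_ci", 5)
        report = compare_cohorts(df, df.copy())
        assert report.measures["angle_deg"].student.p_value == 1.0
        assert report.measures["length_mm"].student.p_value == 1.0

    def test_diseased_vs_normal_cohorts_strongly_separated(self):
        """Simulated cholesteatoma ears are flatter and shorter than the
        cochlear-implant cohort: both p-values < 0.001 at 30 vs 30 subjects."""
        da, ca = self._measure("normal_ci", 7)
        db, cb = self._measure("cholesteatoma", 7)
        import pandas as pd

        demo = lambda c: pd.DataFrame(
            [{"subject_id": s.subject_id, "age_yr": s.age_yr, "sex": s.sex}
             for s in c.subjects])
        report = compare_cohorts(da, db, demo(ca), demo(cb),
                                 group_labels=("CI", "CH"))
        assert report.measures["angle_deg"].a.n == 60
        assert report.measures["angle_deg"].b.n == 60
        assert report.measures["angle_deg"].student.p_value < 1e-3
        assert report.measures["length_mm"].student.p_value < 1e-3
        assert report.sex_fisher is not None and report.age is not None
        assert any("multiple-testing" in n for n in report.notes)
        # report serializes cleanly
        import json

        json.dumps(report.to_dict())
        assert len(report.to_table()) == 4

    def test_mixed_planes_rejected(self):
        da, _ = self._measure("normal_ci", 5, plane="kc", n=4)
        db, _ = self._measure("normal_ci", 6, plane="reids", n=4)
        with pytest.raises(ValidationError, match="mixed"):
            compare_cohorts(da, db)


def test_p_value_display_convention():
    from etmorph.stats import TestResult

    assert TestResult(5.0, 10.0, 3e-7, "student").display_p() == "0.0001"
    assert TestResult(1.0, 10.0, 0.4312, "student").display_p() == "0.43"
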