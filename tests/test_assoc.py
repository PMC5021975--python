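"""Tests for the association scan: RR curves, chi-squared test, BH FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seawas import (
    EffectSpec,
    MonthlyContingency,
    PopulationSpec,
    ScanConfig,
    benjamini_hochberg,
    birth_month_association_test,
    generate_cohort,
    monthly_relative_risk,
    run_scan,
    shared_condition_set,
)
from seawas.assoc import read_scan_results, write_scan_results

from conftest import make_patient, random_contingency


def brute_force_chi2(cases, population):
    """Independent oracle: cell-by-cell sum of (O - E)^2 / E on the 2xk table."""
    cases = np.asarray(cases, float)
    population = np.asarray(population, float)
    keep = population > 0
    obs = np.vstack([cases[keep], population[keep] - cases[keep]])
    N = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / N
            chi2 += (obs[i, j] - e) ** 2 / e
    return chi2


def brute_force_bh(p):
    """Independent oracle: literal step-up rule q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestMonthlyRelativeRisk:
    def test_uniform_table_gives_unit_rr(self, uniform_contingency):
        rr, lo, hi = monthly_relative_risk(uniform_contingency)
        assert np.allclose(rr, 1.0)
        assert np.all(lo <= rr) and np.all(rr <= hi)

    def test_hand_computed_values_on_toy_table(self, toy_contingency):
        rr, _, _ = monthly_relative_risk(toy_contingency)
        assert rr[0] == pytest.approx(2.0, abs=1e-12)
        assert rr[1] == pytest.approx(11.0 / 12.0, abs=1e-12)

    def test_katz_ci_brackets_rr_and_uses_stated_se(self, toy_contingency):
        rr, lo, hi = monthly_relative_risk(toy_contingency, ci_level=0.95)
        assert np.all(lo < rr) and np.all(rr < hi)
        # January by the stated formula: se = sqrt(1/20 - 1/100 + 1/110 - 1/1100)
        se = np.sqrt(1 / 20 - 1 / 100 + 1 / 110 - 1 / 1100)
        assert np.log(hi[0] / rr[0]) == pytest.approx(1.959963984540054 * se, rel=1e-9)

    def test_zero_case_month_stays_finite_via_continuity(self):
        t = MonthlyContingency((0,) + (10,) * 11, (100,) * 12)
        rr, lo, hi = monthly_relative_risk(t)
        assert np.all(np.isfinite(rr)) and np.all(rr > 0)
        assert np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))
        # unaffected months keep the exact uncorrected value
        assert rr[1] == pytest.approx((10 / 100) / (100 / 1100), abs=1e-12)

    def test_empty_month_population_is_error(self):
        t = MonthlyContingency((0,) + (10,) * 11, (0,) + (100,) * 11)
        with pytest.raises(ValueError, match="month"):
            monthly_relative_risk(t)

    def test_population_weighted_rate_reconstructs_overall_prevalence(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = random_contingency(rng)
            c = np.array(t.cases_by_month, float)
            n = np.array(t.population_by_month, float)
            weighted = np.sum((n / t.total_population) * (c / n))
            assert weighted == pytest.approx(t.total_cases / t.total_population, rel=1e-12)


class TestAssociationTest:
    def test_homogeneous_table_gives_zero_statistic(self, uniform_contingency):
        chi2, df, p = birth_month_association_test(uniform_contingency)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 11
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_summation(self, toy_contingency):
        chi2, df, _ = birth_month_association_test(toy_contingency)
        assert chi2 == pytest.approx(
            brute_force_chi2(toy_contingency.cases_by_month,
                             toy_contingency.population_by_month),
            abs=1e-9,
        )
        assert df == 11

    def test_two_month_table_reproduces_classic_2x2_chi2(self):
        """A table concentrated in 2 months must equal the closed-form 2x2 statistic."""
        c = (30, 10) + (0,) * 10
        n = (100, 80) + (0,) * 10
        chi2, df, _ = birth_month_association_test(MonthlyContingency(c, n))
        a, b = 30, 10
        c2, d = 70, 70
        n_tot = 180
        closed = (n_tot * (a * d - b * c2) ** 2) / (
            (a + b) * (c2 + d) * (a + c2) * (b + d)
        )
        assert df == 1
        assert chi2 == pytest.approx(closed, rel=1e-12)

    def test_single_populated_month_is_error(self):
        t = MonthlyContingency((5,) + (0,) * 11, (100,) + (0,) * 11)
        with pytest.raises(ValueError):
            birth_month_association_test(t)

    def test_zero_population_months_reduce_df(self):
        c = (10, 12, 8) + (0,) * 9
        n = (100, 100, 100) + (0,) * 9
        _, df, _ = birth_month_association_test(MonthlyContingency(c, n))
        assert df == 2


class TestBenjaminiHochberg:
    def test_hand_worked_step_up_example(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_ones(self):
        assert np.allclose(benjamini_hochberg([1.0] * 5), 1.0)

    def test_out_of_range_p_reports_index(self):
        with pytest.raises(ValueError, match="index 2"):
            benjamini_hochberg([0.1, 0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_adjusted_values_monotone_in_rank(self, p):
        q = benjamini_hochberg(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= np.asarray(p) - 1e-15)  # p_fdr >= p_raw
        assert np.all(q <= 1.0)


class TestRunScan:
    def _cohort_with_counts(self, counts: dict[str, int], n: int):
        """n patients spread over months; the first `count` carry each code."""
        patients = [make_patient(i, (i % 12) + 1) for i in range(n)]
        for code, count in counts.items():
            for p in patients[:count]:
                p.condition_codes.add(code)
        return patients

    def test_inclusion_threshold_is_inclusive_of_exactly_1000(self):
        patients = self._cohort_with_counts({"AT": 1000, "BELOW": 999}, 3000)
        results = run_scan(patients, ScanConfig(min_patients_per_condition=1000))
        assert [r.condition_code for r in results] == ["AT"]

    def test_single_condition_fdr_equals_raw(self):
        patients = self._cohort_with_counts({"X": 1200}, 3000)
        (res,) = run_scan(patients)
        assert res.p_fdr == pytest.approx(res.p_raw)

    def test_empty_scan_when_nothing_passes(self, caplog):
        patients = self._cohort_with_counts({"X": 10}, 100)
        with caplog.at_level("WARNING", logger="seawas.assoc"):
            assert run_scan(patients) == []
        assert any("no condition" in m for m in caplog.messages)

    def test_scan_fields_are_consistent(self, small_effect_cohort):
        results = run_scan(small_effect_cohort.patients,
                           ScanConfig(min_patients_per_condition=100))
        assert results == sorted(results, key=lambda r: r.condition_code)
        for r in results:
            assert r.max_rr == pytest.approx(r.rr.max())
            assert r.rr[r.max_rr_month - 1] == pytest.approx(r.max_rr)
            assert np.all(r.rr_ci_low <= r.rr + 1e-12)
            assert np.all(r.rr <= r.rr_ci_high + 1e-12)
            assert r.p_fdr >= r.p_raw - 1e-15

    def test_injected_effect_found_with_correct_peak(self):
        ds = generate_cohort(
            PopulationSpec(n_patients=200_000),
            [EffectSpec("CVD", 0.05, 0.3, peak_month_phi=4)],
            seed=21,
        )
        (res,) = run_scan(ds.patients)
        assert res.p_fdr < 1e-6
        assert res.max_rr_month in (3, 4, 5)

    def test_round_trip_through_tsv(self, tmp_path, small_effect_cohort):
        results = run_scan(small_effect_cohort.patients,
                           ScanConfig(min_patients_per_condition=100))
        path = tmp_path / "scan.tsv"
        write_scan_results(results, path)
        back = read_scan_results(path)
        assert [r.condition_code for r in back] == [r.condition_code for r in results]
        for orig, rt in zip(results, back):
            assert np.allclose(rt.rr, orig.rr)
            assert rt.p_fdr == pytest.approx(orig.p_fdr, rel=1e-12)
            assert rt.n_cases == orig.n_cases


class TestSharedConditionSet:
    def _assoc(self, code, n_cases):
        from seawas.assoc import ConditionAssociation
        return ConditionAssociation(
            condition_code=code, condition_label=code, n_cases=n_cases,
            rr=np.ones(12), rr_ci_low=np.ones(12), rr_ci_high=np.ones(12),
            chi2_stat=0.0, df=11, p_raw=1.0, p_fdr=1.0,
            max_rr=1.0, max_rr_month=1, min_rr_month=1,
        )

    def test_disjoint_sets_give_empty(self):
        a = [self._assoc("A", 2000)]
        b = [self._assoc("B", 2000)]
        assert shared_condition_set(a, b) == []

    def test_identical_scans_give_all_passing(self):
        scan = [self._assoc("A", 2000), self._assoc("B", 500)]
        assert shared_condition_set(scan, scan) == ["A"]

    def test_hand_fixture_threshold_at_both_sites(self):
        a = [self._assoc("A", 1500), self._assoc("B", 1200), self._assoc("C", 2000)]
        b = [self._assoc("A", 900), self._assoc("B", 1300), self._assoc("C", 1000)]
        assert shared_condition_set(a, b, threshold=1000) == ["B", "C"]
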