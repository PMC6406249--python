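"""Cohort filtering/classification, KM/log-rank, Cox and sample-size planning."""

import numpy as np
import pandas as pd
import pytest

from chemopanel import (
    CohortSimSpec,
    SurvivalCohort,
    classify_cohort,
    compare_survival,
    cox_fit,
    filter_cohort,
    gen_cohort,
    km_curve,
    logrank_test,
    schoenfeld_sample_size,
)


def make_cohort(times, events, treated=None, n_genes=3, seed=0, **covariates):
    n = len(times)
    ids = [f"p{i}" for i in range(n)]
    clin = pd.DataFrame({"time": np.asarray(times, dtype=float),
                         "event": np.asarray(events, dtype=int)}, index=ids)
    if treated is not None:
        clin["treated"] = treated
    for k, v in covariates.items():
        clin[k] = v
    expr = pd.DataFrame(np.random.default_rng(seed).normal(size=(n_genes, n)),
                        index=[f"g{i}" for i in range(n_genes)], columns=ids)
    return SurvivalCohort(expression=expr, clinical=clin)


class TestFilterCohort:
    def test_exactly_thirty_days_is_excluded(self):
        cohort = make_cohort([30, 31, 100], [1, 1, 0], treated=[1, 1, 1])
        kept = filter_cohort(cohort)
        assert kept.patient_ids == ["p1", "p2"]

    def test_untreated_patients_are_dropped(self):
        cohort = make_cohort([100] * 10, [1] * 10, treated=[0, 0, 0] + [1] * 7)
        assert filter_cohort(cohort).n_patients == 7

    def test_identity_when_all_qualify(self):
        cohort = make_cohort([100, 200], [1, 0], treated=[1, 1])
        kept = filter_cohort(cohort)
        assert kept.patient_ids == cohort.patient_ids

    def test_empty_result_is_an_error(self):
        cohort = make_cohort([10, 20], [1, 1], treated=[1, 1])
        with pytest.raises(ValueError, match="no patients"):
            filter_cohort(cohort)


class TestClassifyCohort:
    def test_recovers_generating_groups(self, trained_model):
        spec = CohortSimSpec(n_patients=200, expression_effect=2.0, rng_seed=7)
        cohort, truth = gen_cohort(spec, trained_model)
        labels = classify_cohort(trained_model, cohort)
        assert (labels == truth).mean() >= 0.90

    def test_invariant_to_positive_affine_transforms(self, trained_model):
        spec = CohortSimSpec(n_patients=60, rng_seed=3)
        cohort, _ = gen_cohort(spec, trained_model)
        before = classify_cohort(trained_model, cohort)
        rng = np.random.default_rng(4)
        scale = rng.uniform(0.5, 20.0, size=(cohort.expression.shape[0], 1))
        shift = rng.normal(0, 50.0, size=(cohort.expression.shape[0], 1))
        import dataclasses
        warped = dataclasses.replace(cohort, expression=cohort.expression * scale + shift)
        after = classify_cohort(trained_model, warped)
        assert (before == after).all()

    def test_missing_panel_gene_is_named(self, trained_model):
        spec = CohortSimSpec(n_patients=20, rng_seed=1)
        cohort, _ = gen_cohort(spec, trained_model)
        import dataclasses
        gone = trained_model.panel.genes[0]
        cohort = dataclasses.replace(cohort,
                                     expression=cohort.expression.drop(index=gone))
        with pytest.raises(KeyError, match=gone):
            classify_cohort(trained_model, cohort)


def km_oracle(times, events, t):
    """Brute-force product over risk sets at distinct event times <= t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        d = ((times == u) & (events == 1)).sum()
        at_risk = (times >= u).sum()
        s *= 1 - d / at_risk
    return s


class TestKMCurve:
    def test_two_events_by_hand(self):
        curve = km_curve([1, 2], [1, 1])
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(1.0) == 0.5
        assert curve.survival_at(2.5) == 0.0

    def test_all_censored_is_flat_one(self):
        curve = km_curve([3, 5, 9], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_duplicating_every_observation_changes_nothing(self):
        t, e = [1, 3, 4, 7], [1, 0, 1, 1]
        a, b = km_curve(t, e), km_curve(t + t, e + e)
        np.testing.assert_allclose(a.times, b.times)
        np.testing.assert_allclose(a.survival, b.survival)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        times = rng.integers(1, 15, size=18).astype(float)
        events = rng.integers(0, 2, size=18)
        curve = km_curve(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(km_oracle(times, events, t))

    def test_monotone_non_increasing_from_one(self):
        rng = np.random.default_rng(9)
        curve = km_curve(rng.exponential(5, 40), rng.integers(0, 2, 40))
        assert curve.survival[0] <= 1.0 and curve.survival_at(0 - 1e-9) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_statistic_zero(self):
        t = [2, 4, 6, 8]
        e = [1, 1, 1, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_detects_a_strong_hazard_ratio(self):
        # HR 0.3, n = 200 per group, light censoring: significant in >=95% of reps
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            ta = rng.exponential(1 / 0.3, 200)
            tb = rng.exponential(1.0, 200)
            c = rng.exponential(10.0, 200), rng.exponential(10.0, 200)
            a, ea = np.minimum(ta, c[0]), (ta <= c[0]).astype(int)
            b, eb = np.minimum(tb, c[1]), (tb <= c[1]).astype(int)
            hits += logrank_test(a, ea, b, eb)[1] < 0.05
        assert hits >= 0.95 * reps

    def test_all_zero_times_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            logrank_test([0, 0], [1, 1], [1, 2], [1, 1])

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test([], [], [1], [1])


class TestCoxFit:
    @staticmethod
    def _two_group_cohort(hr=0.5, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1.0 / (0.01 * hr ** x))
        c = rng.exponential(1.0 / 0.004, n)
        return make_cohort(np.minimum(t, c), (t <= c).astype(int),
                           treated=np.ones(n, dtype=int), group=x, seed=seed)

    def test_recovers_a_planted_hazard_ratio(self):
        cohort = self._two_group_cohort(hr=0.5, n=500, seed=10)
        res = cox_fit(cohort, ["group"], "univariate")
        hr = res.table.loc["group", "hazard_ratio"]
        assert 0.40 <= hr <= 0.62
        assert res.table.loc["group", "ci_lower"] <= 0.5 <= res.table.loc["group", "ci_upper"]

    def test_swapped_coding_inverts_the_hazard_ratio(self):
        cohort = self._two_group_cohort(hr=0.5, n=300, seed=11)
        hr = cox_fit(cohort, ["group"], "univariate").table.loc["group", "hazard_ratio"]
        import dataclasses
        flipped_clin = cohort.clinical.assign(group=1 - cohort.clinical["group"])
        flipped = dataclasses.replace(cohort, clinical=flipped_clin)
        hr_flipped = cox_fit(flipped, ["group"], "univariate").table.loc["group", "hazard_ratio"]
        assert hr_flipped == pytest.approx(1 / hr, rel=1e-6)

    def test_null_covariate_ci_contains_one_most_of_the_time(self):
        covered = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            n = 150
            t = rng.exponential(100, n)
            x = rng.binomial(1, 0.5, n)
            cohort = make_cohort(t, np.ones(n, dtype=int), noise=x, seed=rep)
            tab = cox_fit(cohort, ["noise"], "univariate").table
            covered += tab.loc["noise", "ci_lower"] <= 1 <= tab.loc["noise", "ci_upper"]
        assert covered >= 0.85 * reps

    def test_single_level_covariate_is_an_error(self):
        cohort = make_cohort([5, 6, 7, 8], [1, 1, 1, 0], flat=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="single level"):
            cox_fit(cohort, ["flat"], "univariate")

    def test_multivariate_fits_all_terms_jointly(self, trained_model):
        spec = CohortSimSpec(n_patients=250, rng_seed=21)
        cohort, truth = gen_cohort(spec, trained_model)
        res = cox_fit(cohort, ["panel_model", "residual_tumor_lt_1cm", "figo_advanced",
                               "grade_high", "histology"], "multivariate", labels=truth)
        assert res.model_type == "multivariate"
        assert "panel_model" in res.table.index
        assert any(ix.startswith("histology_") for ix in res.table.index)
        assert not any(ix.endswith("serous") for ix in res.table.index)  # reference level

    def test_model_term_codings(self, trained_model):
        spec = CohortSimSpec(n_patients=200, hazard_ratio=0.4, rng_seed=31)
        cohort, truth = gen_cohort(spec, trained_model)
        default = cox_fit(cohort, ["panel_model"], "univariate", labels=truth)
        high_low = cox_fit(cohort, ["panel_model"], "univariate", labels=truth,
                           model_coding="high_vs_low")
        # responders are protected under both codings; high-vs-low is stronger
        assert default.table.loc["panel_model", "hazard_ratio"] < 1
        assert (high_low.table.loc["panel_model", "hazard_ratio"]
                < default.table.loc["panel_model", "hazard_ratio"])


class TestCompareSurvival:
    def test_protective_group_detected(self, trained_model):
        spec = CohortSimSpec(n_patients=400, hazard_ratio=0.3, censoring_rate=0.1,
                             rng_seed=41)
        cohort, truth = gen_cohort(spec, trained_model)
        res = compare_survival(cohort, truth, group_a="high", group_b="low")
        assert res.p_value < 0.01
        assert res.hazard_ratio < 1
        assert res.hr_ci[0] <= res.hazard_ratio <= res.hr_ci[1]
        assert set(res.curves) == {"high", "low"}


class TestSchoenfeldSampleSize:
    def test_planning_example_hr_052(self):
        n = schoenfeld_sample_size(0.52, alpha=0.05, power=0.70,
                                   event_probability=1.0, group_proportion=0.776)
        assert n == 84

    def test_closed_form_hr_05_power_08(self):
        # (1.96 + 0.8416)^2 / (0.25 * ln(0.5)^2) = 65.35 -> 66
        n = schoenfeld_sample_size(0.5, alpha=0.05, power=0.80,
                                   event_probability=1.0, group_proportion=0.5)
        assert n == 66

    def test_monotone_in_power_and_event_probability(self):
        ns = [schoenfeld_sample_size(0.6, power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.99)]
        assert ns == sorted(ns)
        n_full = schoenfeld_sample_size(0.6, event_probability=1.0)
        n_half = schoenfeld_sample_size(0.6, event_probability=0.5)
        assert n_half >= n_full

    def test_unit_hazard_ratio_is_an_error(self):
        with pytest.raises(ValueError, match="infinite"):
            schoenfeld_sample_size(1.0)
        with pytest.raises(ValueError, match="positive"):
            schoenfeld_sample_size(-0.5)
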