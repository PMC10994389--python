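"""Jackknife pseudo-observations and the pseudo-value GEE."""

import numpy as np
import pandas as pd
import patsy
import pytest
import statsmodels.api as sm

import cpfrisk as ck
from cpfrisk.pseudo import PseudoValueGEE

from conftest import make_cohort, random_cohort


class TestPseudoValues:
    def test_grouped_matches_naive_reference(self, rng):
        for trial in range(4):
            coh = random_cohort(rng, 80, day_ties=bool(trial % 2))
            grid = (3.0, 8.0, 15.0, 30.0)
            a = ck.compute_pseudo_values(coh, grid=grid, method="grouped")
            b = ck.compute_pseudo_values(coh, grid=grid, method="naive")
            assert np.max(np.abs(a.values - b.values)) < 1e-8

    def test_indicator_reduction_single_cause_no_censoring(self, rng):
        times = rng.uniform(1, 28, 120)
        coh = make_cohort(times, np.ones(120))
        pv = ck.compute_pseudo_values(coh, grid=(10.0, 20.0))
        for j, t in enumerate((10.0, 20.0)):
            assert np.allclose(pv.values[:, j], (times <= t).astype(float),
                               atol=1e-10)

    def test_column_means_near_cpf(self):
        coh = ck.simulate_cohort(ck.or_recovery_scenario(200, seed=4))
        pv = ck.compute_pseudo_values(coh)
        assert np.max(np.abs(pv.values.mean(axis=0) - pv.cpf_at_grid)) < 0.02

    def test_unchanged_estimate_gives_pv_equal_cpf(self):
        # before the first event the CPF is 0 regardless of which subject
        # is removed, so every pseudo-value equals the estimate itself
        coh = make_cohort([10, 12, 15, 20], [1, 1, 2, 1])
        pv = ck.compute_pseudo_values(coh, grid=(5.0,))
        assert pv.cpf_at_grid[0] == 0.0
        assert np.allclose(pv.values[:, 0], 0.0, atol=1e-14)

    def test_values_can_exceed_unit_interval(self, rng):
        coh = random_cohort(rng, 60, p_censor=0.4)
        pv = ck.compute_pseudo_values(coh)
        assert np.isfinite(pv.values).all()
        assert (pv.values.max() > 1.0) or (pv.values.min() < 0.0)

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            ck.compute_pseudo_values(make_cohort([1.0], [1]))

    def test_grid_beyond_last_time_flagged(self):
        coh = make_cohort([1, 2, 3], [1, 1, 1])
        pv = ck.compute_pseudo_values(coh, grid=(30.0,))
        assert pv.beyond_last_time


class TestGEE:
    def test_intercept_only_constant_pv(self):
        from cpfrisk.pseudo import PseudoValueTable
        n = 40
        tab = PseudoValueTable(
            grid=np.array([30.0]), values=np.full((n, 1), 0.3),
            subject_ids=np.array([f"s{i}" for i in range(n)]), n=n,
            cpf_at_grid=np.array([0.3]))
        coh = make_cohort(np.arange(n) + 1.0, np.ones(n))
        res = PseudoValueGEE(tab, coh, formula="1").fit()
        assert float(res.params.iloc[0]) == pytest.approx(np.log(0.3 / 0.7),
                                                          abs=1e-8)
        assert float(res.bse.iloc[0]) == pytest.approx(0.0, abs=1e-8)

    def test_linear_reduction_to_logistic_regression(self, rng):
        # one cause, no censoring, single grid time: the whole pipeline
        # must reproduce ordinary logistic regression of 1{T <= t}
        n = 400
        times = rng.exponential(12, n)
        age = np.clip(rng.normal(83, 8, n), 60, 105)
        exposure = rng.choice(["early", "late"], n)
        coh = make_cohort(times, np.ones(n), exposure=exposure, age=age)
        pv = ck.compute_pseudo_values(coh, grid=(10.0,))
        res = PseudoValueGEE(pv, coh, formula="early + age").fit()
        df = coh.data.assign(ind=(times <= 10.0).astype(float),
                             early=(coh.data["exposure"] == "early").astype(float))
        y, X = patsy.dmatrices("ind ~ early + age", data=df,
                               return_type="dataframe")
        glm = sm.GLM(np.asarray(y).ravel(), X,
                     family=sm.families.Binomial()).fit()
        assert np.max(np.abs(res.params.to_numpy() - glm.params.to_numpy())) < 1e-6

    def test_sandwich_equals_model_based_in_saturated_bernoulli_case(self, rng):
        n = 300
        times = rng.exponential(12, n)
        exposure = rng.choice(["early", "late"], n)
        coh = make_cohort(times, np.ones(n), exposure=exposure)
        pv = ck.compute_pseudo_values(coh, grid=(10.0,))
        res = PseudoValueGEE(pv, coh, formula="early").fit()
        df = coh.data.assign(ind=(times <= 10.0).astype(float),
                             early=(coh.data["exposure"] == "early").astype(float))
        y, X = patsy.dmatrices("ind ~ early", data=df, return_type="dataframe")
        glm = sm.GLM(np.asarray(y).ravel(), X,
                     family=sm.families.Binomial()).fit()
        assert np.max(np.abs(np.asarray(res.cov_robust)
                             - np.asarray(glm.cov_params()))) < 1e-6

    def test_or_inverts_exactly_under_reference_relabel(self, rng):
        coh = random_cohort(rng, 250)
        grid = (5.0, 15.0, 30.0)
        r1 = PseudoValueGEE.from_cohort(coh, formula="early", grid=grid).fit()
        r2 = PseudoValueGEE.from_cohort(coh, formula="late", grid=grid).fit()
        or1 = float(r1.odds_ratios().loc["early", "or"])
        or2 = float(r2.odds_ratios().loc["late", "or"])
        assert or1 == pytest.approx(1.0 / or2, rel=1e-8)

    def test_covariance_symmetric_psd(self, rng):
        coh = random_cohort(rng, 200)
        res = PseudoValueGEE.from_cohort(coh, formula="early + depression").fit()
        cov = np.asarray(res.cov_robust)
        assert np.allclose(cov, cov.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-10

    def test_collinear_term_dropped_and_reported(self, rng):
        coh = random_cohort(rng, 100)
        coh.data["dup"] = (coh.data["exposure"] == "early").astype(float)
        res = PseudoValueGEE.from_cohort(coh, formula="early + dup",
                                         grid=(10.0, 30.0)).fit()
        assert res.dropped_terms == ["dup"]

    def test_complete_case_filter_logged(self, rng):
        coh = random_cohort(rng, 120)
        age = np.full(120, 80.0)
        age[:10] = np.nan
        coh.data["age"] = age
        model = PseudoValueGEE.from_cohort(coh, formula="early + age",
                                           grid=(10.0, 30.0))
        assert model.complete_case_log["age"] == 10
        assert model.pv.n == 110


class TestSubgroupAnalysis:
    def test_single_stratum_reports_no_interaction(self):
        coh = ck.simulate_cohort(ck.or_recovery_scenario(600, seed=2))
        rep = ck.run_subgroup_and_interaction_analysis(coh, adjustment=None)
        assert rep.interaction is None
        assert any("fewer than two strata" in n for n in rep.notices)
        assert set(rep.per_stratum["stratum"]) == {"no_depression"}

    def test_small_stratum_skipped_with_notice(self):
        coh = ck.simulate_cohort(ck.or_recovery_scenario(600, seed=2))
        extra = make_cohort([5, 6, 7, 8], [1, 1, 1, 1],
                            exposure=["early", "late", "early", "late"],
                            stratum="depression")
        extra.data["subject_id"] = [f"x{i}" for i in range(4)]
        merged = ck.Cohort(pd.concat([coh.data, extra.data],
                                     ignore_index=True))
        rep = ck.run_subgroup_and_interaction_analysis(merged, adjustment=None)
        assert any("complete cases" in n for n in rep.notices)

    def test_registry_scenario_or_pattern(self):
        coh = ck.truncate_at_horizon(
            ck.simulate_cohort(ck.nhfd_like_scenario(6000, seed=21)), 30)
        rep = ck.run_subgroup_and_interaction_analysis(coh, adjustment=None)
        unadj = rep.per_stratum[rep.per_stratum["model"] == "unadjusted"]
        assert (unadj["or"] > 1).all()
        assert (unadj["ci_lower"] > 1).all()
        assert rep.interaction is not None
        assert rep.trajectories is not None
        assert len(rep.trajectories) == 18  # 9 grid times x 2 strata
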