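"""Aalen-Johansen CIFs and the conditional probability function."""

import numpy as np
import pytest

import cpfrisk as ck
from cpfrisk.nonparametric import estimate_cif, estimate_cpf

from conftest import make_cohort, random_cohort


def brute_force_cpf(times, events, at):
    """No-censoring oracle: (#discharges <= t) / (n - #deaths <= t)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(times)
    disch = ((events == 1) & (times <= at)).sum()
    deaths = ((events == 2) & (times <= at)).sum()
    return disch / (n - deaths) if n > deaths else 1.0


class TestCIF:
    def test_crude_proportions_without_censoring(self):
        # 6 discharges and 2 deaths by day 30, 2 still in hospital
        times = [3, 5, 7, 9, 11, 13, 4, 8, 30, 30]
        events = [1, 1, 1, 1, 1, 1, 2, 2, 0, 0]
        cif = estimate_cif(make_cohort(times, events))
        assert cif.cif_at(1, 30.0) == pytest.approx(0.6, abs=1e-12)
        assert cif.cif_at(2, 30.0) == pytest.approx(0.2, abs=1e-12)

    def test_single_subject_step(self):
        cif = estimate_cif(make_cohort([5.0], [1]))
        assert cif.cif_at(1, 4.9) == 0.0
        assert cif.cif_at(1, 5.0) == 1.0

    def test_additivity_invariant(self, rng):
        coh = random_cohort(rng, 300)
        cif = estimate_cif(coh)
        total = cif.cif_discharge + cif.cif_death + cif.survival
        assert np.max(np.abs(total - 1.0)) < 1e-10

    def test_all_censored_is_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            cif = estimate_cif(make_cohort([5, 6], [0, 0]))
        assert cif.all_censored
        assert np.all(cif.cif_discharge == 0)

    def test_matches_lifelines_aalen_johansen(self, rng):
        lifelines = pytest.importorskip("lifelines")
        # continuous times: lifelines resolves ties by random jitter,
        # which would defeat an exact comparison
        coh = random_cohort(rng, 150, day_ties=False)
        cif = estimate_cif(coh)
        t = coh.data["time"].to_numpy()
        e = coh.data["event"].to_numpy()
        for cause in (1, 2):
            fitter = lifelines.AalenJohansenFitter(calculate_variance=False)
            fitter.fit(t, e, event_of_interest=cause)
            grid = np.unique(t)
            theirs = (fitter.cumulative_density_
                      .reindex(np.concatenate([[0.0], grid]))
                      .ffill().to_numpy().ravel()[1:])
            assert np.allclose(cif.cif_at(cause, grid), theirs, atol=1e-10)

    def test_large_sample_recovery_of_closed_form(self):
        cell = ("no_depression", "early")
        cfg = ck.SimulationConfig(
            n_per_cell={cell: 5000},
            hazards={cell: ck.CellHazards(0.10, 0.01, 0.02)}, seed=8)
        cif = estimate_cif(ck.simulate_cohort(cfg))
        gt = ck.ground_truth(cfg)
        grid = np.linspace(0.5, 30, 60)
        assert np.max(np.abs(cif.cif_at(1, grid) - gt.cif_discharge(grid, cell))) < 0.02
        assert np.max(np.abs(cif.cif_at(2, grid) - gt.cif_death(grid, cell))) < 0.02


class TestCPF:
    def test_ratio_arithmetic(self):
        times = [3, 5, 7, 9, 11, 13, 4, 8, 30, 30]
        events = [1, 1, 1, 1, 1, 1, 2, 2, 0, 0]
        curve = estimate_cpf(estimate_cif(make_cohort(times, events)),
                             ci_method=None)
        assert curve.cpf_at(30.0) == pytest.approx(0.6 / 0.8, abs=1e-12)

    def test_single_cause_reduces_to_ecdf(self, rng):
        times = rng.uniform(1, 25, 80)
        curve = estimate_cpf(estimate_cif(make_cohort(times, np.ones(80))),
                             ci_method=None)
        for t in (5.0, 10.0, 20.0):
            assert curve.cpf_at(t) == pytest.approx((times <= t).mean(), abs=1e-12)

    def test_no_censoring_oracle_exact(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 50))
            coh = random_cohort(rng, n, p_censor=0.0)
            curve = estimate_cpf(estimate_cif(coh), ci_method=None)
            for t in np.unique(coh.data["time"]):
                assert curve.cpf_at(t) == pytest.approx(
                    brute_force_cpf(coh.data["time"], coh.data["event"], t),
                    abs=1e-12)

    def test_monotone_and_bracketed_ci(self, rng):
        coh = random_cohort(rng, 400)
        curve = estimate_cpf(estimate_cif(coh))
        assert np.all(np.diff(curve.cpf) >= -1e-12)
        assert np.all(curve.ci_lower <= curve.cpf + 1e-12)
        assert np.all(curve.cpf <= curve.ci_upper + 1e-12)
        assert np.all((curve.ci_lower >= 0) & (curve.ci_upper <= 1))

    def test_time_scaling_invariance(self, rng):
        coh = random_cohort(rng, 120)
        curve = estimate_cpf(estimate_cif(coh), ci_method=None)
        scaled = make_cohort(coh.data["time"] * 3.0, coh.data["event"],
                             horizon=90.0)
        curve3 = estimate_cpf(estimate_cif(scaled), ci_method=None)
        assert np.allclose(curve3.cpf_at(curve.times * 3.0),
                           curve.cpf_at(curve.times), atol=1e-12)

    def test_everyone_dead_is_degenerate(self):
        curve = estimate_cpf(estimate_cif(make_cohort([2, 4], [2, 2])),
                             ci_method=None)
        assert curve.degenerate_from == 4.0
        assert curve.cpf_at(5.0) == 1.0

    def test_alternative_denominator(self):
        times = [3, 5, 7, 9, 11, 13, 4, 8, 30, 30]
        events = [1, 1, 1, 1, 1, 1, 2, 2, 0, 0]
        curve = estimate_cpf(estimate_cif(make_cohort(times, events)),
                             ci_method=None, denominator="cif_sum")
        assert curve.cpf_at(30.0) == pytest.approx(0.6 / 0.8, abs=1e-12)
        # by day 6: discharges at 3, 5 (CIF1=0.2) and one death at 4 (CIF2=0.1)
        assert curve.cpf_at(6.0) == pytest.approx(0.2 / 0.3, abs=1e-12)

    def test_estimator_consistency_mae_shrinks(self):
        cell = ("no_depression", "early")
        truth = None
        maes = {}
        for n in (500, 5000):
            errs = []
            for rep in range(60):
                cfg = ck.SimulationConfig(
                    n_per_cell={cell: n},
                    hazards={cell: ck.CellHazards(0.05, 0.008, 0.02)},
                    seed=10_000 + rep)
                if truth is None:
                    truth = float(ck.ground_truth(cfg).cpf(30, cell))
                curve = estimate_cpf(estimate_cif(ck.simulate_cohort(cfg)),
                                     ci_method=None)
                errs.append(abs(curve.cpf_at(30.0) - truth))
            maes[n] = np.mean(errs)
        assert maes[5000] < maes[500]


class TestGroupedCPF:
    def test_empty_cells_flagged_others_estimated(self):
        coh = make_cohort([1, 2, 3], [1, 1, 1], exposure="early",
                          stratum=["depression", "depression", "no_depression"])
        grouped = ck.cpf_by_group(coh, ci_method=None)
        assert ("depression", "early") in grouped.curves
        assert grouped.errors[("depression", "late")] == "empty cell"
        assert grouped.errors[("no_depression", "late")] == "empty cell"

    def test_cells_match_single_cell_estimates(self, rng):
        coh = random_cohort(rng, 400)
        grouped = ck.cpf_by_group(coh, ci_method=None)
        for (s, e), curve in grouped.curves.items():
            mask = ((coh.data["stratum"] == s)
                    & (coh.data["exposure"] == e)).to_numpy()
            solo = estimate_cpf(estimate_cif(coh.select(mask)), ci_method=None)
            assert np.array_equal(curve.times, solo.times)
            assert np.allclose(curve.cpf, solo.cpf, atol=0)

    def test_registry_scenario_orders_early_above_late(self):
        coh = ck.truncate_at_horizon(
            ck.simulate_cohort(ck.nhfd_like_scenario(10_000, seed=2)), 30)
        grouped = ck.cpf_by_group(coh, ci_method=None)
        for s in ("depression", "no_depression"):
            assert (grouped[(s, "early")].cpf_at(30.0)
                    > grouped[(s, "late")].cpf_at(30.0))
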