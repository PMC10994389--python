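"""Pepe-Mori style two-sample comparison of CPF curves."""

import numpy as np
import pytest

import cpfrisk as ck

from conftest import make_cohort


def _two_arms(cfg):
    coh = ck.simulate_cohort(cfg)
    early = coh.select((coh.data["exposure"] == "early").to_numpy())
    late = coh.select((coh.data["exposure"] == "late").to_numpy())
    return early, late


def test_identical_cohorts_give_zero_statistic():
    coh = make_cohort([2, 5, 9, 14, 30], [1, 1, 2, 1, 0])
    res = ck.pepe_mori_test(coh, coh, method="permutation",
                            n_permutations=200, seed=1)
    assert res.statistic == 0.0
    assert res.p_value > 0.9


def test_swap_antisymmetry():
    a, b = _two_arms(ck.or_recovery_scenario(400, seed=3))
    r1 = ck.pepe_mori_test(a, b, method="analytic")
    r2 = ck.pepe_mori_test(b, a, method="analytic")
    assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_permutation_reproducible_under_seed():
    a, b = _two_arms(ck.null_scenario(120, seed=5))
    r1 = ck.pepe_mori_test(a, b, n_permutations=300, seed=42)
    r2 = ck.pepe_mori_test(a, b, n_permutations=300, seed=42)
    assert r1.p_value == r2.p_value
    assert r1.p_value >= 1.0 / 301


def test_requires_events_and_seed():
    coh = make_cohort([2, 3], [1, 1])
    cens = make_cohort([2, 3], [0, 0])
    with pytest.raises(ValueError):
        ck.pepe_mori_test(coh, cens)
    with pytest.raises(ValueError):
        ck.pepe_mori_test(coh, coh, method="permutation", seed=None)


def test_tied_times_handled(rng):
    cfg = ck.null_scenario(80, seed=2)
    cfg.round_days = True
    a, b = _two_arms(cfg)
    res = ck.pepe_mori_test(a, b, n_permutations=200, seed=9)
    assert 0 < res.p_value <= 1


def test_vectorised_engine_matches_reference_statistic(rng):
    """The per-position permutation engine must reproduce the tied
    unique-time estimator exactly (telescoping within ties)."""
    from cpfrisk.twosample import _engine_block, _statistic

    checked = 0
    for _ in range(150):
        n_a, n_b = rng.integers(5, 60, 2)
        t = np.floor(rng.uniform(0, 35, n_a + n_b))
        e = rng.integers(0, 3, n_a + n_b)
        if not (e[:n_a] != 0).any() or not (e[n_a:] != 0).any():
            continue
        checked += 1
        _, ref = _statistic(t[:n_a], e[:n_a], t[n_a:], e[n_a:], 30.0, True)
        order = np.lexsort((e == 0, t))
        ts, es = t[order], e[order]
        ga = (np.arange(n_a + n_b)[order] < n_a)[:, None]
        upper = np.concatenate([ts[1:], [max(30.0, ts[-1])]])
        dt = np.maximum(np.minimum(upper, 30.0) - np.minimum(ts, 30.0), 0.0)
        first = np.searchsorted(ts, ts, side="left")
        n = n_a + n_b
        got = _engine_block(
            ts, (es != 0).astype(float), (es == 1).astype(float),
            (es == 0).astype(float), ga, dt, first, n_a / n, n_b / n,
            np.sqrt(n_a * n_b / n), True)[0]
        assert abs(ref - got) < 1e-10
    assert checked > 100


def test_unweighted_variant_matches_weighted_when_uncensored(rng):
    t_a = rng.uniform(1, 25, 100)
    t_b = rng.uniform(1, 25, 100) * 0.8
    a = make_cohort(t_a, np.ones(100))
    b = make_cohort(t_b, np.ones(100))
    rw = ck.pepe_mori_test(a, b, method="analytic", weighted=True)
    ru = ck.pepe_mori_test(a, b, method="analytic", weighted=False)
    assert rw.statistic == pytest.approx(ru.statistic, rel=1e-10)


def test_analytic_agrees_with_permutation_on_large_samples():
    for seed in (1, 2):
        a, b = _two_arms(ck.null_scenario(500, seed=seed, censoring=0.02))
        ra = ck.pepe_mori_test(a, b, method="analytic")
        rp = ck.pepe_mori_test(a, b, method="permutation",
                               n_permutations=2000, seed=seed)
        assert abs(ra.p_value - rp.p_value) < 0.02


def test_power_increases_with_effect_size():
    rejections = {}
    for hr in (1.2, 1.6):
        base = ck.CellHazards(discharge=0.04, death=0.006, censoring=0.02)
        boosted = ck.CellHazards(discharge=0.04 * hr, death=0.006,
                                 censoring=0.02)
        count = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = ck.SimulationConfig(
                n_per_cell={("no_depression", "early"): 200,
                            ("no_depression", "late"): 200},
                hazards={("no_depression", "early"): boosted,
                         ("no_depression", "late"): base},
                seed=50_000 + rep)
            a, b = _two_arms(cfg)
            res = ck.pepe_mori_test(a, b, n_permutations=200, seed=rep)
            count += res.p_value < 0.05
        rejections[hr] = count / n_rep
    assert rejections[1.6] > rejections[1.2]


class TestStratified:
    def test_registry_effect_detected_in_both_strata(self):
        coh = ck.truncate_at_horizon(
            ck.simulate_cohort(ck.nhfd_like_scenario(10_000, seed=6)), 30)
        results = ck.run_stratified_tests(coh, n_permutations=999, seed=17)
        # early discharges faster in both strata; the small depression
        # stratum (~830 subjects) has less power than the full registry
        for s in ("depression", "no_depression"):
            assert results[s].statistic > 0
            assert results[s].p_value < 0.05
        assert results["no_depression"].p_value <= 0.005

    def test_missing_arm_reported_other_tested(self):
        coh = ck.simulate_cohort(ck.null_scenario(100, seed=1))
        # drop the whole depression stratum's late arm analogue:
        # null_scenario populates no_depression only
        results = ck.run_stratified_tests(coh, n_permutations=100, seed=3)
        assert results["depression"] == "missing exposure arm"
        assert hasattr(results["no_depression"], "p_value")
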