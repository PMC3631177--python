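import math

import numpy as np
import pytest

from anchorsig import (
    SyntheticParams,
    km_estimate,
    logrank_test,
    marker_pvalue_table,
    simulate_expression,
    simulate_survival,
    stratify_and_test,
)
from anchorsig.stratify import CutpointConfig, dichotomize
from anchorsig.survival import survival_past_time_chisq


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_km(times, events):
    """Explicit risk-set recomputation at every event time."""
    times = list(map(float, times))
    events = list(map(int, events))
    ev_times = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out = {}
    for u in ev_times:
        at_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1.0 - d / at_risk
        out[u] = s
    return out


def brute_force_logrank_2group(t1, e1, t2, e2):
    """Scalar accumulation of (O-E) and hypergeometric variance, group 1."""
    all_t = list(t1) + list(t2)
    all_e = list(e1) + list(e2)
    grp = [0] * len(t1) + [1] * len(t2)
    ev_times = sorted({t for t, e in zip(all_t, all_e) if e == 1})
    o_minus_e, var = 0.0, 0.0
    for u in ev_times:
        n_t = sum(1 for t in all_t if t >= u)
        n_1 = sum(1 for t, g in zip(all_t, grp) if t >= u and g == 0)
        d_t = sum(1 for t, e in zip(all_t, all_e) if t == u and e == 1)
        d_1 = sum(1 for t, e, g in zip(all_t, all_e, grp) if t == u and e == 1 and g == 0)
        o_minus_e += d_1 - d_t * n_1 / n_t
        if n_t > 1:
            var += d_t * (n_t - d_t) / (n_t - 1) * (n_1 / n_t) * (1 - n_1 / n_t)
    if var == 0.0:
        return 0.0  # degenerate risk sets: no information, statistic is zero
    return o_minus_e**2 / var


def random_survival_fixture(rng, n_max=25):
    n = int(rng.integers(3, n_max))
    times = np.round(rng.exponential(12, n), 1)
    events = rng.integers(0, 2, n)
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([5, 10, 15], [0, 1, 1])
        assert curve.survival_at(10) == pytest.approx(0.5)
        assert curve.survival_at(15) == pytest.approx(0.0)
        assert curve.survival_at(0) == 1.0

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([3, 6, 9], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_single_subject_event(self):
        curve = km_estimate([7.0], [1])
        assert curve.survival_at(7.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0], [1])

    def test_curve_invariants(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t, e = random_survival_fixture(rng)
            if e.sum() == 0:
                continue
            curve = km_estimate(t, e)
            assert np.all(np.diff(curve.event_times) > 0)
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all((curve.survival >= 0) & (curve.survival <= 1))
            assert np.all(np.diff(curve.at_risk) <= 0)

    def test_matches_brute_force_on_200_fixtures(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            t, e = random_survival_fixture(rng)
            curve = km_estimate(t, e)
            expected = brute_force_km(t, e)
            assert len(expected) == curve.event_times.size
            for u, s in expected.items():
                assert curve.survival_at(u) == pytest.approx(s, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(23)
        for _ in range(20):
            t, e = random_survival_fixture(rng)
            if e.sum() == 0:
                continue
            curve = km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            for u in curve.event_times:
                assert curve.survival_at(u) == pytest.approx(
                    float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
                )

    def test_permutation_invariant(self):
        rng = np.random.default_rng(24)
        t, e = random_survival_fixture(rng)
        perm = rng.permutation(len(t))
        a = km_estimate(t, e)
        b = km_estimate(t[perm], e[perm])
        np.testing.assert_array_equal(a.event_times, b.event_times)
        np.testing.assert_allclose(a.survival, b.survival, atol=1e-15)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3.0, 6.0, 9.0, 12.0]
        e = [1, 0, 1, 1]
        res = logrank_test([(t, e), (t, e)])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_fixture(self):
        """All-events two-group fixture checked against scalar tabulation."""
        t1, e1 = [3.0, 6.0, 9.0], [1, 1, 1]
        t2, e2 = [12.0, 15.0, 18.0], [1, 1, 1]
        res = logrank_test([(t1, e1), (t2, e2)])
        expected = brute_force_logrank_2group(t1, e1, t2, e2)
        assert res.chi_square == pytest.approx(expected, abs=1e-10)
        assert sum(res.observed) == 6
        assert sum(res.expected) == pytest.approx(6.0)

    def test_matches_brute_force_on_200_fixtures(self):
        rng = np.random.default_rng(25)
        checked = 0
        while checked < 200:
            t1, e1 = random_survival_fixture(rng)
            t2, e2 = random_survival_fixture(rng)
            if e1.sum() + e2.sum() == 0:
                continue
            res = logrank_test([(t1, e1), (t2, e2)])
            expected = brute_force_logrank_2group(t1, e1, t2, e2)
            assert res.chi_square == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_matches_lifelines_multigroup(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(26)
        for _ in range(25):
            groups = [random_survival_fixture(rng) for _ in range(3)]
            if sum(e.sum() for _, e in groups) == 0:
                continue
            res = logrank_test(groups)
            t_all = np.concatenate([t for t, _ in groups])
            e_all = np.concatenate([e for _, e in groups])
            g_all = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
            ll = multivariate_logrank_test(t_all, g_all, e_all)
            assert res.chi_square == pytest.approx(ll.test_statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ll.p_value, abs=1e-8)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([([1.0, 2.0], [0, 0]), ([3.0], [0])])

    def test_expected_sums_to_observed_total(self):
        rng = np.random.default_rng(27)
        t1, e1 = random_survival_fixture(rng)
        t2, e2 = random_survival_fixture(rng)
        e1[0] = 1
        res = logrank_test([(t1, e1), (t2, e2)])
        assert sum(res.expected) == pytest.approx(sum(res.observed), abs=1e-9)


def _simulated_logrank_p(seed: int, gamma: float, n_tumor: int = 200) -> float:
    params = SyntheticParams(
        n_tumor=n_tumor, n_control=2, n_module=3, n_background=5,
        anti_gene_count=1, gamma=gamma, seed=seed,
    )
    cohort, meta, _, truth = simulate_expression(params)
    meta = simulate_survival(cohort, truth, params, meta)
    surv = [m for m in meta if m.survival_months is not None]
    ids = [m.sample_id for m in surv]
    strat = dichotomize(
        cohort, [(truth.anchor_probe, "high_is_hit")], CutpointConfig("median"), scope=ids
    )
    months = np.array([m.survival_months for m in surv])
    ev = np.array([m.event for m in surv])
    hit = (strat.calls[truth.anchor_probe] == "hit").to_numpy()
    return logrank_test([(months[hit], ev[hit]), (months[~hit], ev[~hit])]).p_value


class TestCalibration:
    def test_power_monotone_in_hazard(self):
        """Rejection rate grows with the per-SD log hazard (200 reps per level)."""
        seeds = np.random.SeedSequence(555).generate_state(200) % (2**31)
        rates = []
        for gamma in (0.0, 0.3, 0.7, 1.2):
            rej = sum(_simulated_logrank_p(int(s), gamma, 100) < 0.05 for s in seeds)
            rates.append(rej / len(seeds))
        assert rates == sorted(rates)
        assert rates[0] < 0.15 and rates[-1] > 0.8


# ---------------------------------------------------------------------------
# Marker stratification
# ---------------------------------------------------------------------------


def survival_cohort(seed=30, n_tumor=200, gamma=math.log(2.5)):
    params = SyntheticParams(
        n_tumor=n_tumor, n_control=5, n_module=10, n_background=20,
        gamma=gamma, seed=seed,
    )
    cohort, meta, _, truth = simulate_expression(params)
    meta = simulate_survival(cohort, truth, params, meta)
    return cohort, meta, truth


class TestStratifyAndTest:
    def test_single_scheme_separates_prognosis(self):
        cohort, meta, truth = survival_cohort()
        res = stratify_and_test(cohort, meta, truth.anchor_probe, scheme="single")
        assert set(res.strata.values()) <= {"H", "L"}
        assert res.tests["H_vs_L"].p_value < 0.05

    def test_combined_scheme_reports_four_strata_and_contrast(self):
        cohort, meta, truth = survival_cohort()
        res = stratify_and_test(
            cohort, meta, truth.module_probes[0], truth.anchor_probe, scheme="combined"
        )
        assert set(res.strata.values()) <= {"H/H", "H/L", "L/H", "L/L"}
        assert "all_strata" in res.tests
        assert "AhighBhigh_vs_AhighBlow" in res.tests

    def test_duplicate_marker_combined_is_degenerate(self):
        cohort, meta, truth = survival_cohort()
        res = stratify_and_test(
            cohort, meta, truth.anchor_probe, truth.anchor_probe, scheme="combined"
        )
        assert "combined" in res.skipped
        # only H/H and L/L strata exist when both markers coincide
        assert set(res.strata.values()) <= {"H/H", "L/L"}

    def test_too_few_survival_samples_rejected(self):
        cohort, meta, truth = survival_cohort(n_tumor=5)
        with pytest.raises(ValueError, match="floor"):
            stratify_and_test(cohort, meta, truth.anchor_probe)

    def test_horizon_censors_late_followup(self):
        cohort, meta, truth = survival_cohort()
        res = stratify_and_test(cohort, meta, truth.anchor_probe, scheme="single", horizon=60.0)
        for curve in res.curves.values():
            assert curve.event_times.max() <= 60.0

    def test_independent_second_marker_adds_nothing(self):
        """With marker_b unrelated to hazard, the combined contrast p is ~uniform."""
        ps = []
        for seed in range(40):
            params = SyntheticParams(
                n_tumor=120, n_control=5, n_module=3, n_background=10, seed=seed
            )
            cohort, meta, _, truth = simulate_expression(params)
            meta = simulate_survival(cohort, truth, params, meta)
            res = stratify_and_test(
                cohort, meta, truth.anchor_probe, truth.background_probes[0],
                scheme="combined",
            )
            t = res.tests.get("AhighBhigh_vs_AhighBlow")
            if t is not None:
                ps.append(t.p_value)
        # mean of a uniform sample is 0.5; allow generous sampling slack
        assert 0.3 <= np.mean(ps) <= 0.7

    def test_marker_pvalue_table_shape(self):
        cohort, meta, truth = survival_cohort()
        table = marker_pvalue_table(
            cohort, meta, truth.module_probes[:3], combine_with=truth.anchor_probe
        )
        assert list(table.columns) == ["marker", "p_single", "p_combined"]
        assert len(table) == 3
        assert table["p_single"].between(0, 1).all()

    def test_contingency_chisq_audit_variant_runs(self):
        cohort, meta, truth = survival_cohort()
        surv = [m for m in meta if m.survival_months is not None]
        t = np.array([m.survival_months for m in surv])
        e = np.array([m.event for m in surv])
        half = len(t) // 2
        chi2, p = survival_past_time_chisq(
            [(t[:half], e[:half]), (t[half:], e[half:])], horizon=float(np.median(t))
        )
        assert chi2 >= 0 and 0 <= p <= 1
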