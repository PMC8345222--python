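"""Log-rank, optimal cut-points, Cox regression, FDR, and Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest

import geoihc as g
from geoihc.survival import (cox_fit, fdr_adjust, km_estimate,
                             logrank_statistic, optimal_cutpoint,
                             run_survival_screen)
from .conftest import brute_logrank


class TestLogrank:
    def test_duplicated_cohort_gives_zero_statistic(self, rng):
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        times = np.concatenate([t, t])
        events = np.concatenate([e, e])
        groups = np.repeat([0, 1], 80)
        stat, p = logrank_statistic(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_complete_separation(self):
        times = np.concatenate([np.full(40, 1.0), np.full(40, 10.0)])
        events = np.concatenate([np.ones(40), np.zeros(40)]).astype(int)
        groups = np.repeat([0, 1], 40)
        stat, p = logrank_statistic(times, events, groups)
        assert stat > 30 and p < 1e-8

    def test_matches_risk_table_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 80))
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n)
            if len(np.unique(groups)) < 2:
                continue
            got, _ = logrank_statistic(times, events, groups)
            assert got == pytest.approx(brute_logrank(times, events, groups),
                                        rel=1e-10, abs=1e-12)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        groups = rng.integers(0, 2, 60)
        if len(np.unique(groups)) < 2:
            groups[0], groups[1] = 0, 1
        s1, _ = logrank_statistic(times, events, groups)
        s2, _ = logrank_statistic(times, events, 1 - groups)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_no_events_gives_null(self):
        stat, p = logrank_statistic([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0],
                                    [0, 0, 1, 1])
        assert (stat, p) == (0.0, 1.0)


def exhaustive_cutpoint(values, times, events, min_prop=0.1):
    """Oracle: evaluate the risk-table log-rank at every admissible split."""
    values = np.asarray(values, float)
    n = len(values)
    distinct = np.unique(values)
    best = (None, -np.inf)
    for c in (distinct[:-1] + distinct[1:]) / 2:
        high = values > c
        prop = high.sum() / n
        if not (min_prop <= prop <= 1 - min_prop):
            continue
        stat = brute_logrank(times, events, high.astype(int))
        if stat > best[1]:
            best = (c, stat)
    return best


class TestOptimalCutpoint:
    def test_separable_construction(self, rng):
        # low metric values survive long, high values fail early
        values = np.concatenate([rng.uniform(0, 4.9, 20), rng.uniform(5.1, 10, 20)])
        times = np.concatenate([rng.uniform(50, 100, 20), rng.uniform(1, 10, 20)])
        events = np.ones(40, dtype=int)
        cp = optimal_cutpoint(values, times, events)
        assert values[values <= cp.cutoff].max() < cp.cutoff < values[values > cp.cutoff].min()
        # the selected split separates the two survival regimes exactly
        assert cp.n_high == 20 and np.all(values[values > cp.cutoff] > 5.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(5):
            values = rng.normal(size=40)
            times = rng.exponential(20, 40)
            events = rng.integers(0, 2, 40)
            if events.sum() == 0:
                events[0] = 1
            cp = optimal_cutpoint(values, times, events)
            c_star, s_star = exhaustive_cutpoint(values, times, events)
            assert cp.cutoff == pytest.approx(c_star)
            assert cp.statistic == pytest.approx(s_star, rel=1e-10)

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError, match="admissible"):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0),
                             np.ones(20, dtype=int))

    def test_group_size_constraint_respected(self, rng):
        values = rng.normal(size=60)
        times = rng.exponential(20, 60)
        events = np.ones(60, dtype=int)
        cp = optimal_cutpoint(values, times, events, min_prop=0.25)
        assert 15 <= cp.n_high <= 45

    def test_too_few_patients_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            optimal_cutpoint(rng.normal(size=5), rng.exponential(10, 5),
                             np.ones(5, dtype=int))


class TestCoxFit:
    def make_cohort(self, rng, n, true_hr):
        group = rng.integers(0, 2, n).astype(float)
        lp = math.log(true_hr) * group
        t = rng.exponential(1.0 / (0.02 * np.exp(lp)))
        c = rng.exponential(120, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        age = rng.normal(60, 8, n)
        imdc = rng.choice(["favorable", "intermediate", "poor"], n)
        return times, events, group, age, imdc

    def test_null_group_recovers_hr_one(self, rng):
        times, events, group, age, imdc = self.make_cohort(rng, 500, 1.0)
        res = cox_fit(times, events, group, age, imdc)
        assert res.ci_low < 1.0 < res.ci_high
        assert res.hr == pytest.approx(1.0, abs=0.3)

    def test_recovers_planted_binary_hr(self, rng):
        hrs = []
        for _ in range(5):
            times, events, group, age, imdc = self.make_cohort(rng, 500, 2.0)
            hrs.append(cox_fit(times, events, group, age, imdc).hr)
        assert 1.8 <= float(np.median(hrs)) <= 2.2

    def test_ci_brackets_hr_and_p_valid(self, rng):
        times, events, group, age, imdc = self.make_cohort(rng, 200, 1.5)
        res = cox_fit(times, events, group, age, imdc)
        assert res.ci_low <= res.hr <= res.ci_high
        assert 0.0 <= res.p <= 1.0 and res.hr > 0

    def test_minimal_input_never_silent(self):
        # two patients, one event: either a finite fit or an informative error
        try:
            res = cox_fit([5.0, 10.0], [1, 0], [0.0, 1.0], [60.0, 65.0],
                          ["favorable", "favorable"])
            assert res.hr > 0
        except Exception as err:  # noqa: BLE001 - contract: no silent failure
            assert str(err)

    def test_constant_exposure_rejected(self, rng):
        times, events, group, age, imdc = self.make_cohort(rng, 50, 1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(times, events, np.ones(50), age, imdc)

    def test_imdc_reference_is_favorable(self, rng):
        times, events, group, age, imdc = self.make_cohort(rng, 300, 1.0)
        res = cox_fit(times, events, group, age, imdc)
        assert "imdc_intermediate" in res.covariates
        assert "imdc_favorable" not in res.covariates


class TestFdrAdjust:
    def test_step_up_hand_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_decreases_and_preserves_order(self, rng):
        p = rng.uniform(size=30)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_passthrough(self):
        q = fdr_adjust([0.01, np.nan, 0.04])
        assert math.isnan(q[1]) and not math.isnan(q[0])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])["all"]
        assert np.all(km["survival"] == 1.0) and math.isnan(km["median"])

    def test_four_distinct_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])["all"]
        assert np.allclose(km["survival"], [1.0, 0.75, 0.5, 0.25, 0.0])
        assert km["median"] == pytest.approx(2.0)

    def test_censored_mixture_matches_product_limit_oracle(self, rng):
        times = rng.integers(1, 10, 20).astype(float)
        events = rng.integers(0, 2, 20)
        km = km_estimate(times, events)["all"]
        # hand product-limit over distinct event times
        s = 1.0
        expected = {}
        for u in np.unique(times[events == 1]):
            n_at = (times >= u).sum()
            d = ((times == u) & (events == 1)).sum()
            s *= 1.0 - d / n_at
            expected[u] = s
        for u, s_u in expected.items():
            i = np.searchsorted(km["times"], u)
            assert km["survival"][i] == pytest.approx(s_u)

    def test_curve_monotone_from_one(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        km = km_estimate(times, events)["all"]
        assert km["survival"][0] <= 1.0
        assert np.all(np.diff(km["survival"]) <= 1e-12)


class TestSurvivalScreen:
    def test_output_shape_and_planted_signal(self):
        cfg = g.CohortSimConfig(n_patients=150,
                                coefficients={"hscore_Ki67": math.log(2.2)})
        sim = g.simulate_cohort(cohort_cfg=cfg, seed=11)
        table = run_survival_screen(sim.metrics_observed, sim.clinical)
        assert len(table) == 27
        assert set(table["endpoint"]) == {"OS", "OS-IT", "OS-TT"}
        os_rows = table[table["endpoint"] == "OS"].set_index("metric")
        assert os_rows["fdr_p"].idxmin() == "hscore_Ki67"

    def test_insufficient_metric_yields_missing_row(self):
        sim = g.simulate_cohort(cohort_cfg=g.CohortSimConfig(n_patients=30),
                                seed=5)
        obs = sim.metrics_observed.copy()
        obs["hscore_aSMA"] = np.nan
        table = run_survival_screen(obs, sim.clinical)
        row = table[(table["metric"] == "hscore_aSMA")
                    & (table["endpoint"] == "OS")].iloc[0]
        assert math.isnan(row["hr"]) and math.isnan(row["cutoff"])
        assert len(table) == 27
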