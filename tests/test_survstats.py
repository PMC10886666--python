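"""Kaplan–Meier, log-rank, cut-off search, Cox regression, subgroup tests."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from wsimil.survstats import (
    best_cutoff,
    cox_combinations,
    cox_multiple,
    cox_univariate,
    group_tests,
    km_estimate,
    logrank_one_sided,
)


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = km_estimate([3, 5, 8], [0, 0, 0])
        assert np.all(km.survival_prob == 1.0)

    def test_hand_product_limit(self):
        # n=4, events at t=1 and t=2: S(2) = (3/4)(2/3) = 1/2
        km = km_estimate([1, 2, 3, 4], [1, 1, 0, 0])
        s = dict(zip(km.event_times, km.survival_prob))
        assert s[1.0] == pytest.approx(0.75)
        assert s[2.0] == pytest.approx(0.5)

    def test_mass_event_drops_to_zero(self):
        km = km_estimate([7, 7, 7], [1, 1, 1])
        assert km.survival_prob[-1] == 0.0

    def test_probabilities_nonincreasing(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rng.integers(1, 50, 40), rng.integers(0, 2, 40))
        assert np.all(np.diff(km.survival_prob) <= 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_half(self):
        t, e = [1, 2, 3, 4], [1, 0, 1, 0]
        out = logrank_one_sided(t, e, t, e)
        assert out["p"] == 0.5
        assert out["statistic"] == 0.0

    def test_statistic_matches_lifelines_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            na, nb = rng.integers(3, 25, size=2)
            ta = rng.integers(1, 30, size=na).astype(float)
            tb = rng.integers(1, 30, size=nb).astype(float)
            ea = rng.integers(0, 2, size=na)
            eb = rng.integers(0, 2, size=nb)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            mine = logrank_one_sided(ta, ea, tb, eb, two_sided=True)
            ref = _ll_logrank(ta, tb, ea, eb)
            assert mine["statistic"] == pytest.approx(
                ref.test_statistic, abs=1e-8)
            assert mine["p"] == pytest.approx(ref.p_value, abs=1e-8)

    def test_one_sided_direction(self):
        # group A relapses much earlier -> small one-sided p
        ta = np.arange(1, 21, dtype=float)
        tb = ta + 100
        out = logrank_one_sided(ta, np.ones(20), tb, np.ones(20))
        assert out["p"] < 1e-6
        # flipped direction: p near 1
        flipped = logrank_one_sided(tb, np.ones(20), ta, np.ones(20))
        assert flipped["p"] > 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_one_sided([], [], [1], [1])


class TestBestCutoff:
    def _exhaustive(self, risks, times, events, min_n):
        risks = np.asarray(risks)
        uniq = np.unique(risks)
        best = (np.inf, None)
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            hi = risks > cut
            if hi.sum() < min_n or (~hi).sum() < min_n:
                continue
            p = logrank_one_sided(times[hi], events[hi],
                                  times[~hi], events[~hi])["p"]
            if p < best[0] - 1e-15:
                best = (p, cut)
        return best

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 40
            risks = rng.normal(size=n)
            times = np.maximum(1, rng.exponential(
                200 * np.exp(-risks), size=n)).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            out = best_cutoff(risks, times, events)
            p_ref, cut_ref = self._exhaustive(risks, times, events, 4)
            assert out["p"] == pytest.approx(p_ref, abs=1e-12)
            assert out["cutoff"] == pytest.approx(cut_ref)

    def test_separating_risks_put_cutoff_between_clusters(self):
        risks = np.r_[np.full(10, -2.0), np.full(10, 2.0)]
        times = np.r_[np.full(10, 1000.0), np.full(10, 50.0)]
        events = np.r_[np.zeros(10, int), np.ones(10, int)]
        out = best_cutoff(risks, times, events)
        assert -2.0 < out["cutoff"] < 2.0
        assert out["p"] < 1e-4

    def test_constant_risks_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            best_cutoff(np.ones(20), np.arange(1, 21), np.ones(20, int))

    def test_minimum_group_size_respected(self):
        # the outlier split would give the smallest p but leaves 1 patient
        risks = np.r_[[-5.0], np.linspace(0, 1, 19)]
        times = np.arange(1, 21, dtype=float)
        events = np.ones(20, int)
        out = best_cutoff(risks, times, events, min_group_frac=0.25)
        hi = risks > out["cutoff"]
        assert min(hi.sum(), (~hi).sum()) >= 5


class TestCox:
    def test_independent_covariate_has_unit_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n = 800
        x = rng.normal(size=n)
        t = rng.exponential(100, size=n)
        res = cox_univariate(x, t, np.ones(n, int))
        assert res.hazard_ratio[0] == pytest.approx(1.0, abs=0.1)
        assert res.ci95_low[0] <= res.hazard_ratio[0] <= res.ci95_high[0]

    def test_recovers_known_hazard_ratio(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.integers(0, 2, size=n)
            t = rng.exponential(1.0 / (0.01 * 5.0**x))
            c = rng.exponential(150, size=n)
            obs = np.minimum(t, c)
            e = (t <= c).astype(int)
            res = cox_univariate(x, obs, e)
            if 3.5 <= res.hazard_ratio[0] <= 7.0:
                hits += 1
        assert hits >= 9

    def test_matches_lifelines_maximizer_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 30
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.5 * x))  # continuous: no ties
            e = rng.integers(0, 2, size=n)
            if e.sum() < 2:
                e[:2] = 1
            res = cox_univariate(x, t, e)
            df = pd.DataFrame({"t": t, "e": e, "x": x})
            cph = CoxPHFitter().fit(df, "t", "e")
            assert np.log(res.hazard_ratio[0]) == pytest.approx(
                cph.params_["x"], abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate(np.ones(10), np.arange(1, 11), np.ones(10, int))

    def test_scale_invariance_of_wald_p(self):
        rng = np.random.default_rng(5)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x))
        e = np.ones(n, int)
        r1 = cox_univariate(x, t, e)
        r2 = cox_univariate(10.0 * x, t, e)
        assert r1.p_value[0] == pytest.approx(r2.p_value[0], abs=1e-8)
        assert np.log(r2.hazard_ratio[0]) == pytest.approx(
            np.log(r1.hazard_ratio[0]) / 10.0, abs=1e-6)


class TestCoxCombinations:
    def _data(self, seed=0, n=250):
        rng = np.random.default_rng(seed)
        signal = rng.integers(0, 2, size=n)
        noise = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.01 * np.exp(1.2 * signal)))
        c = rng.exponential(200, size=n)
        frame = pd.DataFrame({"signal": signal, "noise": noise})
        return frame, np.minimum(t, c), (t <= c).astype(int)

    def test_enumerates_all_subsets(self):
        frame, t, e = self._data()
        frame["extra"] = np.random.default_rng(9).normal(size=len(frame))
        kept = cox_combinations(frame, t, e, alpha=1.0)
        assert len(kept) == 7  # 2^3 - 1 subsets, none filtered at alpha=1

    def test_noise_features_are_filtered_out(self):
        frame, t, e = self._data()
        kept = cox_combinations(frame, t, e)
        assert all("noise" not in m.covariates or
                   m.p_value[m.covariates.index("noise")] < 0.05 for m in kept)
        assert any(m.covariates == ["signal"] for m in kept)

    def test_adding_noise_feature_tends_to_raise_aic(self):
        worse = 0
        for seed in range(12):
            frame, t, e = self._data(seed)
            base = cox_multiple(frame[["signal"]], t, e)
            full = cox_multiple(frame[["signal", "noise"]], t, e)
            if full.aic > base.aic:
                worse += 1
        assert worse >= 8  # a pure-noise covariate raises AIC most of the time


class TestGroupTests:
    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            na, nb = rng.integers(3, 20, size=2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            out = group_tests(np.r_[a, b], np.r_[np.zeros(na), np.ones(nb)])
            u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert out["statistic"] == pytest.approx(u_brute)

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(7)
        out = group_tests(rng.normal(size=30), np.repeat([0, 1, 2], 10))
        assert out["test"] == "kruskal"

    def test_identical_groups_are_insignificant(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        out = group_tests(vals, np.repeat([0, 1], 10))
        assert out["p"] > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], [0, 0])
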