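"""Kaplan-Meier, log-rank and Cox against hand/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from arid1a_hcc.errors import InvalidArgumentError
from arid1a_hcc.survival import cox_fit, km_estimate, logrank_test


def numpy_logrank_statistic(time, event, in_a):
    """Hand-coded two-group log-rank chi-square (hypergeometric variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_a = np.asarray(in_a, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKM:
    def test_hand_product_limit(self):
        """(1,e),(2,e),(3,c),(4,e),(5,c): S = 0.8, 0.6, 0.3 after events."""
        time = pd.Series([1, 2, 3, 4, 5], dtype=float)
        event = pd.Series([1, 1, 0, 1, 0])
        km = km_estimate(time, event)
        assert km.event_times.tolist() == [1.0, 2.0, 4.0]
        assert np.allclose(km.survival, [0.8, 0.6, 0.3])
        assert km.at_risk.tolist() == [5, 4, 2]

    def test_all_censored_stays_at_one(self):
        km = km_estimate(pd.Series([1.0, 2.0, 3.0]), pd.Series([0, 0, 0]))
        assert len(km.event_times) == 0
        assert km.survival_at(99.0) == 1.0

    def test_single_time_mass(self):
        km = km_estimate(pd.Series([2.0] * 6), pd.Series([1, 1, 1, 1, 0, 0]))
        assert np.allclose(km.survival, [(6 - 4) / 6])

    def test_order_invariance(self, rng):
        time = pd.Series(rng.exponential(5, 40) + 0.01)
        event = pd.Series(rng.integers(0, 2, 40))
        km_a = km_estimate(time, event)
        perm = rng.permutation(40)
        km_b = km_estimate(time.iloc[perm], event.iloc[perm])
        assert np.allclose(km_a.survival, km_b.survival)
        assert np.allclose(km_a.event_times, km_b.event_times)

    def test_monotone_non_increasing(self, rng):
        time = pd.Series(rng.exponential(5, 100) + 0.01)
        event = pd.Series(rng.integers(0, 2, 100))
        km = km_estimate(time, event)
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(InvalidArgumentError):
            km_estimate(pd.Series([], dtype=float), pd.Series([], dtype=int))
        with pytest.raises(InvalidArgumentError):
            km_estimate(pd.Series([0.0, 1.0]), pd.Series([1, 1]))


class TestLogRank:
    def test_identical_groups_give_null(self):
        time = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        event = pd.Series([1, 1, 0, 1] * 2)
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        res = logrank_test(time, event, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_group_label_symmetry(self, rng):
        time = pd.Series(rng.exponential(5, 30) + 0.01)
        event = pd.Series(rng.integers(0, 2, 30))
        groups = pd.Series(rng.choice(["x", "y"], 30))
        a = logrank_test(time, event, groups)
        b = logrank_test(time, event, groups.map({"x": "y", "y": "x"}))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_matches_hand_statistic_and_permutation_p(self, rng):
        """20-sample toy set: statistic equals the longhand formula and the
        chi-square p agrees with a 10,000-draw permutation null."""
        time = rng.exponential(5, 20) + 0.01
        event = rng.integers(0, 2, 20)
        in_a = np.arange(20) < 10
        res = logrank_test(pd.Series(time), pd.Series(event),
                           pd.Series(np.where(in_a, "a", "b")))
        observed = numpy_logrank_statistic(time, event, in_a)
        assert res.statistic == pytest.approx(observed, rel=1e-8)

        draws = np.empty(10_000)
        for i in range(10_000):
            draws[i] = numpy_logrank_statistic(time, event, rng.permutation(in_a))
        perm_p = float((draws >= observed - 1e-12).mean())
        mc_se = np.sqrt(perm_p * (1 - perm_p) / 10_000)
        assert abs(res.p_value - perm_p) < max(4 * mc_se, 0.02)

    def test_one_group_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            logrank_test(pd.Series([1.0, 2.0]), pd.Series([1, 1]),
                         pd.Series(["a", "a"]))


class TestCox:
    def test_matches_grid_search_on_tiny_example(self):
        """4 records, one binary covariate, no ties: the Newton fit equals a
        brute-force scan of the written-out partial likelihood."""
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0],
                           "event": [1, 1, 1, 0],
                           "x": [1.0, 0.0, 1.0, 0.0]})

        def log_partial_likelihood(beta):
            order = np.argsort(df["time"].to_numpy())
            t, e, x = (df[c].to_numpy()[order] for c in ("time", "event", "x"))
            ll = 0.0
            for i in range(len(t)):
                if e[i] == 1:
                    risk = x[i:]  # later times = still at risk (no ties)
                    ll += beta * x[i] - np.log(np.exp(beta * risk).sum())
            return ll

        coarse = np.linspace(-5, 5, 2001)
        beta_grid = coarse[np.argmax([log_partial_likelihood(b) for b in coarse])]
        # refine around the coarse optimum
        fine = np.linspace(beta_grid - 0.02, beta_grid + 0.02, 4001)
        beta_star = fine[np.argmax([log_partial_likelihood(b) for b in fine])]
        fit = cox_fit(df, ["x"])
        assert fit.table.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-3)

    def test_ci_brackets_hr(self, rng):
        n = 200
        x = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        df = pd.DataFrame({"time": time, "event": np.ones(n, int), "x": x})
        fit = cox_fit(df, ["x"])
        row = fit.table.loc["x"]
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]
        assert row["hr"] > 0

    def test_score_test_equals_logrank_without_censoring(self, rng):
        """At beta=0 with one binary covariate and no censoring, the Cox score
        statistic is the log-rank chi-square."""
        n = 30
        time = rng.exponential(5, n) + 0.01
        x = (np.arange(n) % 2).astype(float)

        order = np.argsort(time)
        t, xv = time[order], x[order]
        u, info = 0.0, 0.0
        for i in range(n):
            risk = xv[i:]
            u += xv[i] - risk.mean()
            info += risk.var()  # population variance of x over the risk set
        score_stat = u ** 2 / info
        lr = logrank_test(pd.Series(time), pd.Series(np.ones(n, int)),
                          pd.Series(np.where(x == 1, "a", "b")))
        assert lr.statistic == pytest.approx(score_stat, rel=1e-8)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0],
                           "x": [1.0, 1.0, 1.0]})
        with pytest.raises(InvalidArgumentError):
            cox_fit(df, ["x"])
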