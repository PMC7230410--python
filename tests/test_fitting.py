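"""Multi-start least-squares identification and fit diagnostics."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from glycofit.fitting import (
    FitConfig,
    GlucoseResponseModel,
    GTT_GRID,
    TimeSeries,
    fit_model,
    goodness_of_fit,
    runs_test_pvalue,
)
from glycofit.model import ModelParameters, evaluate


def make_series(params, grid=GTT_GRID, test="GTT", noise=None, rng=None, sid="s1"):
    t = np.array(grid)
    y = np.asarray(evaluate(params, t))
    if noise:
        y = y + rng.normal(0, noise, size=len(t))
    return TimeSeries(sid, "young_male", test, t, y)


TRUTH = ModelParameters(0.03, 0.0012, 6.0, 5.0, 0.9)


class TestTimeSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            TimeSeries("a", "g", "GTT", [0, 10, 10], [5, 6, 7])  # not increasing
        with pytest.raises(ValueError):
            TimeSeries("a", "g", "GTT", [5, 10, 20], [5, 6, 7])  # no t=0
        with pytest.raises(ValueError):
            TimeSeries("a", "g", "GTT", [0, 10, 20], [5, -6, 7])  # negative glucose
        with pytest.raises(ValueError):
            TimeSeries("a", "g", "XTT", [0, 10, 20], [5, 6, 7])  # bad test label


class TestFitModel:
    def test_noiseless_round_trip(self):
        res = fit_model(make_series(TRUTH), FitConfig(seed=1))
        assert res.rss < 1e-10
        assert res.converged and res.acceptable
        truth = TRUTH.as_array()
        rel = np.abs(res.params.as_array() - truth) / np.abs(truth)
        assert np.max(rel) < 1e-4

    def test_constant_series_degenerate(self):
        ts = TimeSeries("c", "young_male", "GTT", GTT_GRID, [5.0] * 8)
        res = fit_model(ts)
        assert res.rss == 0.0
        assert res.params.mu == 5.0 and res.params.g_stab == 5.0
        assert res.params.nu == 0.0
        assert not res.acceptable  # alpha, omega0_sq unidentifiable
        assert np.allclose(np.asarray(evaluate(res.params, np.array(GTT_GRID))), 5.0)

    def test_too_few_points(self):
        ts = TimeSeries("a", "g", "GTT", [0, 15, 30, 45, 60], [5, 6, 7, 6, 5])
        with pytest.raises(ValueError):
            fit_model(ts)

    def test_deterministic_given_seed(self, rng):
        ts = make_series(TRUTH, noise=0.2, rng=rng)
        r1 = fit_model(ts, FitConfig(seed=7))
        r2 = fit_model(ts, FitConfig(seed=7))
        assert r1.params == r2.params and r1.rss == r2.rss

    def test_more_starts_never_worse(self, rng):
        ts = make_series(TRUTH, noise=0.3, rng=rng)
        few = fit_model(ts, FitConfig(alpha_starts=(0.05,), n_random_starts=0))
        many = fit_model(ts, FitConfig(alpha_starts=(0.05, 0.01, 0.1, 0.2),
                                       n_random_starts=4))
        assert many.rss <= few.rss + 1e-12

    def test_both_regimes_reachable(self, rng):
        over = ModelParameters(0.12, 0.0025, 6.0, 5.2, 0.8)  # alpha^2 > w2
        under = ModelParameters(0.02, 0.0012, 6.0, 5.2, 0.5)
        for truth, regime in ((over, "overdamped"), (under, "underdamped")):
            res = fit_model(make_series(truth), FitConfig(seed=3))
            assert res.regime == regime
            assert res.rss < 1e-8

    def test_recovery_with_sign_correct_nu(self, rng):
        """Over simulated curves spanning both regimes at sigma=0.2, at
        least 90% of acceptable fits recover the sign of nu and G0 within
        1 mmol/L."""
        from tests.conftest import protocol_params

        ok, total = 0, 0
        truths = protocol_params(rng, 100, nu_range=(0.2, 1.2)) + protocol_params(
            rng, 100, nu_range=(-0.6, -0.1)
        )
        for i, truth in enumerate(truths):
            test = "GTT" if truth.nu > 0 else "ITT"
            ts = make_series(truth, test=test, noise=0.2, rng=rng, sid=f"r{i}")
            res = fit_model(ts, FitConfig(seed=i, n_random_starts=2))
            if not res.acceptable:
                continue
            total += 1
            if (
                np.sign(res.params.nu) == np.sign(truth.nu)
                and abs(res.params.g_stab - truth.g_stab) < 1.0
            ):
                ok += 1
        assert total >= 100
        assert ok / total >= 0.9


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        ts = make_series(TRUTH)
        gof = goodness_of_fit(ts, TRUTH)
        assert gof["rss"] == pytest.approx(0.0, abs=1e-18)
        assert gof["r2"] == pytest.approx(1.0, abs=1e-12)
        assert gof["est_var"] == pytest.approx(0.0, abs=1e-18)

    def test_est_var_denominator(self, rng):
        ts = make_series(TRUTH, noise=0.5, rng=rng)
        gof = goodness_of_fit(ts, TRUTH)
        assert gof["est_var"] == pytest.approx(gof["rss"] / 3.0)  # m=8, p=5

    def test_direct_summation_oracle(self, rng):
        y = rng.uniform(3, 12, size=8)
        ts = TimeSeries("o", "young_male", "GTT", GTT_GRID, y)
        p = ModelParameters(0.04, 0.002, 6.0, 5.5, 0.3)
        hand = sum((float(evaluate(p, t)) - yi) ** 2 for t, yi in zip(ts.times, y))
        assert goodness_of_fit(ts, p)["rss"] == pytest.approx(hand, abs=1e-10)

    def test_zero_variance_nonzero_rss(self):
        ts = TimeSeries("z", "young_male", "GTT", GTT_GRID, [5.0] * 8)
        p = ModelParameters(0.04, 0.002, 6.0, 6.5, 0.3)
        assert goodness_of_fit(ts, p)["r2"] == -math.inf


class TestRunsScreen:
    def test_matches_enumeration(self):
        """Exact runs-test p equals brute-force enumeration over all
        orderings of the sign multiset."""
        for signs in ([1, 1, 1, -1, -1, -1], [1, -1, 1, -1, 1, -1], [1, 1, -1, 1, -1, -1]):
            signs = np.array(signs)
            obs_runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            runs_of = lambda s: 1 + sum(s[i] != s[i - 1] for i in range(1, len(s)))
            space = set(permutations(signs.tolist()))
            dist = {}
            for s in space:
                dist[runs_of(s)] = dist.get(runs_of(s), 0) + 1
            total = sum(dist.values())
            lo = sum(v for r, v in dist.items() if r <= obs_runs) / total
            hi = sum(v for r, v in dist.items() if r >= obs_runs) / total
            expected = min(1.0, 2 * min(lo, hi))
            assert runs_test_pvalue(signs) == pytest.approx(expected, abs=1e-12)

    def test_one_sided_sign_pattern_undefined(self):
        assert runs_test_pvalue(np.array([1, 1, 1, 1])) is None


class TestModelResultsSurface:
    def test_from_dataframe_and_summary(self):
        t = np.array(GTT_GRID)
        y = np.asarray(evaluate(TRUTH, t))
        df = pd.DataFrame(
            {
                "subject_id": ["r1"] * 8,
                "group": ["young_male"] * 8,
                "test": ["GTT"] * 8,
                "time_min": t,
                "glucose_mmol_per_l": y,
            }
        )
        res = GlucoseResponseModel.from_dataframe(df, "r1", "GTT").fit()
        assert res.predict(0.0) == pytest.approx(res.params.mu)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        text = res.summary()
        for token in ("alpha", "omega0_sq", "R^2", "G_max", "model AUC"):
            assert token in text
        feats = res.features()
        assert feats.test == "GTT"
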