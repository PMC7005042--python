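"""Rank tests, correlation screen, logistic fits, variable selection, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcamorph.cohort import default_table1_specs, generate_cohort
from mcamorph.stats import (
    fit_logistic,
    mann_whitney_u,
    pearson_correlation_matrix,
    roc_analysis,
    select_model_variables,
    univariate_screen,
    wilcoxon_signed_rank,
)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples(self):
        x = np.arange(10.0)
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_samples_extreme_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, 200)
        y = rng.normal(0, 1, 200)
        _, p = mann_whitney_u(x, y)
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_exact_all_positive(self):
        _, p = wilcoxon_signed_rank([0.5, 1.0, 1.5, 2.0, 2.5])
        assert p == pytest.approx(2 / 32, abs=1e-12)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank([-1.5, 1.5])
        assert p == pytest.approx(1.0)

    def test_zeros_dropped_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        d = rng.normal(5, 1, 100)
        _, p = wilcoxon_signed_rank(d)
        assert p < 0.001


class TestPearsonMatrix:
    def test_self_correlation_and_symmetry(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        r, p = pearson_correlation_matrix(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == r.loc["b", "a"]
        assert 0 <= p.loc["a", "b"] <= 1

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["x", "y"])
        r, _ = pearson_correlation_matrix(df)
        assert abs(r.loc["x", "y"]) < 0.05

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        r, _ = pearson_correlation_matrix(df)
        assert np.isnan(r.loc["x", "y"])

    def test_flow_rate_tracks_trunk_area_in_mechanistic_cohort(self):
        # VFR = vm * p0 / 100 with vm independent of r0: strong positive
        # coupling, attenuated by the printed vm coefficient of variation
        c = generate_cohort(default_table1_specs(), seed=11, mode="mechanistic")
        r, _ = pearson_correlation_matrix(c.data, ["vfr", "p0"])
        assert r.loc["vfr", "p0"] > 0.7


class TestLogistic:
    def test_symmetric_data_gives_unit_odds_ratio(self):
        fit = fit_logistic([0, 1, 0, 1], pd.DataFrame({"x": [0, 0, 1, 1]}))
        t = fit.terms.loc["x"]
        assert t["coef"] == pytest.approx(0.0, abs=1e-6)
        assert t["odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        t = fit.terms.loc["x"]
        assert t["ci_low"] < t["odds_ratio"] < t["ci_high"]
        assert t["ci_low"] == pytest.approx(
            np.exp(t["coef"] - 1.96 * t["se"]), rel=1e-9
        )

    def test_matches_grid_likelihood_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.4 + 0.8 * x)))).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        b0_hat = fit.terms.loc["const", "coef"]
        b1_hat = fit.terms.loc["x", "coef"]

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        # coarse scan then a 1e-3 grid: independent likelihood maximisation
        b0s = np.arange(-5, 5, 0.1)
        b1s = np.arange(-5, 5, 0.1)
        ll = np.array([[loglik(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0f = np.arange(b0s[i] - 0.1, b0s[i] + 0.1, 1e-3)
        b1f = np.arange(b1s[j] - 0.1, b1s[j] + 0.1, 1e-3)
        llf = np.array([[loglik(a, b) for b in b1f] for a in b0f])
        i2, j2 = np.unravel_index(np.argmax(llf), llf.shape)
        assert abs(b0_hat - b0f[i2]) < 2e-3
        assert abs(b1_hat - b1f[j2]) < 2e-3
        assert loglik(b0_hat, b1_hat) >= llf.max() - 1e-9

    def test_perfect_separation_flagged(self):
        fit = fit_logistic(
            [0, 0, 0, 1, 1, 1],
            pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]}),
        )
        assert fit.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1, 1, 1], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0, 1, 0, 1], pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}))


class TestSelection:
    def _screen(self, pvals):
        rows = {}
        for v, p in pvals.items():
            rng = np.random.default_rng(0)
            x = rng.normal(size=40)
            y = (rng.random(40) < 0.5).astype(int)
            fit = fit_logistic(y, pd.DataFrame({v: x}))
            fit.terms.loc[v, "p"] = p  # inject the screening p-value
            rows[v] = fit
        return rows

    def test_threshold_rule(self):
        screen = self._screen({"a": 0.02, "b": 0.5})
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        retained, audit = select_model_variables(screen, corr)
        assert retained == ["a"]
        assert any(e["variable"] == "b" for e in audit)

    def test_correlated_pair_drops_larger_p(self):
        screen = self._screen({"a": 0.01, "b": 0.02})
        corr = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        retained, audit = select_model_variables(screen, corr)
        assert retained == ["a"]
        dropped = [e for e in audit if e["variable"] == "b"]
        assert dropped and "0.9" in dropped[0]["reason"]

    def test_tie_drops_later_variable(self):
        screen = self._screen({"a": 0.02, "b": 0.02})
        corr = pd.DataFrame(
            [[1.0, 0.8], [0.8, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        retained, _ = select_model_variables(screen, corr)
        assert retained == ["a"]


class TestRoc:
    def test_separated_samples(self):
        res = roc_analysis([5, 6, 7], [1, 2, 3])
        assert res.auc == 1.0
        assert res.cutoff == pytest.approx(4.0)
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        assert roc_analysis(x, y).auc == pytest.approx(0.5, abs=0.03)

    def test_binormal_closed_form(self):
        rng = np.random.default_rng(7)
        from scipy.stats import norm

        cases = rng.normal(1, 1, 30_000)
        controls = rng.normal(0, 1, 30_000)
        expected = norm.cdf(1 / np.sqrt(2))
        assert roc_analysis(cases, controls).auc == pytest.approx(expected, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([], [1.0])

    @given(
        cases=st.lists(st.integers(0, 8), min_size=1, max_size=30),
        controls=st.lists(st.integers(0, 8), min_size=1, max_size=30),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_auc_equals_mann_whitney_identity(self, cases, controls):
        # integer scores force heavy ties; identity must hold exactly
        res = roc_analysis(cases, controls)
        c = np.asarray(cases, float)[:, None]
        k = np.asarray(controls, float)[None, :]
        u = np.sum(c > k) + 0.5 * np.sum(c == k)
        assert res.auc == pytest.approx(u / (len(cases) * len(controls)), abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.normal(1, 1, 40)
        controls = rng.normal(0, 1, 50)
        a = roc_analysis(cases, controls)
        b = roc_analysis(np.exp(cases), np.exp(controls))
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert b.sensitivity_at_cutoff == pytest.approx(a.sensitivity_at_cutoff)
        assert b.specificity_at_cutoff == pytest.approx(a.specificity_at_cutoff)


class TestUnivariateScreenOnCohort:
    def test_noise_column_ci_spans_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"is_case": np.r_[np.ones(100), np.zeros(100)],
             "noise": rng.normal(size=200)}
        )
        hits = 0
        for seed in range(10):
            df["noise"] = np.random.default_rng(seed).normal(size=200)
            fit = univariate_screen(df, "is_case", ["noise"])["noise"]
            t = fit.terms.loc["noise"]
            hits += t["ci_low"] <= 1.0 <= t["ci_high"]
        assert hits >= 9  # ~95% coverage under the null
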