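"""Correlations, regression, capacity fitting, shuffle nulls, Wilcoxon."""

import numpy as np
import pytest

from momentfba import (
    ValidationError,
    build_moment,
    chain_toy,
    compare_condition_sets,
    correlate,
    fit_capacity,
    growth_vs_sqrt_yield,
    mean_flux_across_media,
    regress_flux,
    shuffle_null,
    solve_moment,
)


class TestCorrelate:
    def test_collinear_in_log_space(self):
        rep = correlate({"a": 1, "b": 10, "c": 100}, {"a": 2, "b": 20, "c": 200})
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.spearman_r == pytest.approx(1.0)
        assert rep.n == 3 and rep.dropped == 0

    def test_perfect_anticorrelation_without_min_n(self):
        rep = correlate({"a": 1, "b": 10}, {"a": 10, "b": 1}, min_n=2)
        assert rep.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_under_log_dropped_and_counted(self):
        rep = correlate(
            {"a": 1, "b": 10, "c": 100, "d": 5},
            {"a": 2, "b": 20, "c": 200, "d": 0.0},
        )
        assert rep.n == 3 and rep.dropped == 1

    def test_absolute_values_under_log(self):
        rep = correlate(
            {"a": 1, "b": 10, "c": 100}, {"a": -2, "b": -20, "c": -200}
        )
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            correlate({"a": 1, "b": 2}, {"a": 1, "b": 2})


class TestRegressFlux:
    def test_flux_proportional_to_kcat(self):
        keys = [f"r{i}" for i in range(20)]
        kcat = {k: float(2 ** i) for i, k in enumerate(keys)}
        flux = {k: 3.0 * v for k, v in kcat.items()}
        mw = {k: 1.0 + (i % 5) for i, k in enumerate(keys)}
        rep = regress_flux(flux, kcat, mw)
        assert rep.R == pytest.approx(1.0, abs=1e-9)
        assert rep.coefficients["kcat"] == pytest.approx(1.0, abs=1e-9)
        assert rep.coefficients["mw"] == pytest.approx(0.0, abs=1e-7)

    def test_multiplicative_construction_recovers_unit_coefficients(self):
        rng = np.random.default_rng(0)
        keys = [f"r{i}" for i in range(30)]
        kcat = {k: 10.0 ** rng.uniform(0, 3) for k in keys}
        mw = {k: 10.0 ** rng.uniform(0, 2) for k in keys}
        flux = {k: kcat[k] * mw[k] for k in keys}
        rep = regress_flux(flux, kcat, mw)
        assert rep.R == pytest.approx(1.0, abs=1e-9)
        assert rep.coefficients["kcat"] == pytest.approx(1.0, abs=1e-9)
        assert rep.coefficients["mw"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_predictors_give_low_R(self):
        rng = np.random.default_rng(12345)
        keys = [f"r{i}" for i in range(50)]
        flux = {k: 10.0 ** rng.normal(0, 1) for k in keys}
        kcat = {k: 10.0 ** rng.normal(0, 1) for k in keys}
        mw = {k: 10.0 ** rng.normal(0, 1) for k in keys}
        rep = regress_flux(flux, kcat, mw)
        assert rep.R < 0.4

    def test_adding_predictor_never_lowers_R(self):
        rng = np.random.default_rng(7)
        keys = [f"r{i}" for i in range(40)]
        kcat = {k: 10.0 ** rng.normal(0, 1) for k in keys}
        flux = {k: kcat[k] ** 0.5 * 10.0 ** rng.normal(0, 0.3) for k in keys}
        mw = {k: 10.0 ** rng.normal(0, 1) for k in keys}
        r1 = regress_flux(flux, kcat).R
        r2 = regress_flux(flux, kcat, mw).R
        assert r2 >= r1 - 1e-12


class TestFitCapacity:
    def test_closed_form_example(self):
        fit = fit_capacity({"m1": 1.0, "m2": 2.0}, {"m1": 2.0, "m2": 2.0}, C0=1.0)
        assert fit.C_star == pytest.approx(1.2, abs=1e-12)

    def test_exact_match_returns_C0(self):
        p = {"a": 0.3, "b": 0.7, "c": 1.1}
        fit = fit_capacity(p, dict(p), C0=0.27)
        assert fit.C_star == pytest.approx(0.27, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-15)

    def test_doubled_measurements_double_C(self):
        p = {"a": 0.3, "b": 0.7}
        m = {k: 2 * v for k, v in p.items()}
        fit = fit_capacity(p, m, C0=0.27)
        assert fit.C_star == pytest.approx(0.54, abs=1e-12)

    def test_all_zero_predictions_rejected(self):
        with pytest.raises(ValidationError):
            fit_capacity({"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0}, C0=1.0)

    def test_refit_closes_linear_scaling_loop(self):
        """Re-predicting at C* reproduces the scaled predictions exactly."""
        toys = {
            "fast": chain_toy((100.0,), (1.0,), C=0.5),
            "slow": chain_toy((10.0,), (1.0,), C=0.5),
        }
        preds = {
            name: solve_moment(build_moment(t.model, t.params, t.medium)).growth
            for name, t in toys.items()
        }
        meas = {"fast": 0.8 * preds["fast"], "slow": 0.4 * preds["slow"]}
        fit = fit_capacity(preds, meas, C0=0.5)
        for name, t in toys.items():
            sol2 = solve_moment(
                build_moment(t.model, t.params.scaled(fit.scale), t.medium)
            )
            assert sol2.growth == pytest.approx(fit.scale * preds[name], rel=1e-9)


class TestShuffleNull:
    def test_exhaustive_three_monotone_pairs(self):
        kc = {"a": 1.0, "b": 2.0, "c": 3.0}
        res = shuffle_null(kc, dict(kc), exhaustive=True)
        # only the identity permutation attains r = 1
        assert res.n_shuffles == 6
        assert res.p_strict == pytest.approx(0.0)
        assert res.p_geq == pytest.approx(1.0 / 6.0)

    def test_worst_case_observed(self):
        kc = {"a": 1.0, "b": 2.0, "c": 3.0}
        res = shuffle_null(kc, dict(kc), exhaustive=True, observed=-1.0)
        assert res.p_strict == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        keys = [f"r{i}" for i in range(12)]
        kc = {k: float(10 ** rng.uniform(0, 2)) for k in keys}
        ref = {k: kc[k] * float(10 ** rng.normal(0, 0.5)) for k in keys}
        a = shuffle_null(kc, ref, n_shuffles=200, seed=7)
        b = shuffle_null(kc, ref, n_shuffles=200, seed=7)
        assert np.array_equal(a.null_values, b.null_values)
        c = shuffle_null(kc, ref, n_shuffles=200, seed=8)
        assert not np.array_equal(a.null_values, c.null_values)

    def test_pipeline_statistic_callback(self):
        kc = {"a": 1.0, "b": 2.0, "c": 4.0}
        res = shuffle_null(
            kc, {}, exhaustive=True, statistic=lambda d: d["a"], observed=1.0
        )
        # 2 of 6 permutations put a larger value on key 'a'... each of b,c
        # leads 2 permutations: 4/6 strictly greater
        assert res.p_strict == pytest.approx(4.0 / 6.0)

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValidationError):
            shuffle_null({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0}, n_shuffles=10)

    def test_null_p_value_roughly_uniform(self):
        """Under the null (kcats exchangeable), p is ~ Uniform[0,1]."""
        rng = np.random.default_rng(2024)
        keys = [f"r{i}" for i in range(8)]
        ps = []
        for rep in range(50):
            kc = {k: float(10 ** rng.uniform(0, 2)) for k in keys}
            ref = {k: float(10 ** rng.uniform(0, 2)) for k in keys}
            res = shuffle_null(kc, ref, n_shuffles=100, seed=int(rng.integers(2**31)))
            ps.append(res.p_strict)
        mean_p = float(np.mean(ps))
        # binomial-style CI around 0.5 for 50 replicates
        assert 0.3 < mean_p < 0.7


class TestGrowthVsSqrtYield:
    class _Sol:
        def __init__(self, growth, uptake):
            self.growth, self.uptake, self.optimal = growth, uptake, True

    def test_growth_linear_in_sqrt_yield_gives_r1(self):
        # growth = 2 * sqrt(yield) exactly -> the paired points are collinear
        sols = {}
        for i, y in enumerate((0.25, 0.5, 1.0, 2.0)):
            growth = 2.0 * y ** 0.5
            sols[f"m{i}"] = self._Sol(growth, growth / y)
        rep = growth_vs_sqrt_yield(sols)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.spearman_r == pytest.approx(1.0)

    def test_antimonotone_spearman(self):
        sols = {
            "m1": self._Sol(1.0, 1.0 / 4.0),
            "m2": self._Sol(2.0, 2.0 / 2.0),
            "m3": self._Sol(3.0, 3.0 / 1.0),
        }
        rep = growth_vs_sqrt_yield(sols)
        assert rep.spearman_r == pytest.approx(-1.0)

    def test_degenerate_identical_media_rejected(self):
        sols = {f"m{i}": self._Sol(1.0, 2.0) for i in range(4)}
        with pytest.raises(ValidationError, match="variance"):
            growth_vs_sqrt_yield(sols)

    def test_zero_uptake_rejected(self):
        sols = {
            "m1": self._Sol(1.0, 0.0),
            "m2": self._Sol(2.0, 1.0),
            "m3": self._Sol(3.0, 1.0),
        }
        with pytest.raises(ValidationError, match="uptake"):
            growth_vs_sqrt_yield(sols)


class TestCompareConditionSets:
    def test_identical_lists_p_one(self):
        a = [0.1 * i for i in range(8)]
        assert compare_condition_sets(a, list(a)) == pytest.approx(1.0)

    def test_uniform_shift_significant(self):
        b = [0.05 * i for i in range(10)]
        a = [x + 1.0 for x in b]
        # all 10 signed ranks positive: exact two-sided p = 2/2^10
        p = compare_condition_sets(a, b)
        assert p == pytest.approx(2.0 / 1024.0, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            compare_condition_sets([1, 2, 3], [3, 2, 1])


def test_mean_flux_across_media_absolute_pre_log():
    fx = {
        "m1": {"R1": 2.0, "R2": -4.0},
        "m2": {"R1": 4.0},
    }
    out = mean_flux_across_media(fx)
    assert out == {"R1": 3.0, "R2": 4.0}
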