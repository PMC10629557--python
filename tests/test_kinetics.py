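"""Arrival-model fitting, survival analysis, and binomial summaries."""

import math

import numpy as np
import pytest

from cosmofret import (binomial_fraction, empirical_first_binding,
                       first_binding_cdf, fit_first_binding,
                       fit_first_binding_ls, survival_curve)
from cosmofret.kinetics import lrt_specific_binding


def _mixture_arrivals(rng, n, k_a, A_f, k_ns, T):
    """Sample first-arrival times from the specific+background model."""
    active = rng.random(n) < A_f
    lam = np.where(active, k_a + k_ns, k_ns)
    with np.errstate(divide="ignore"):
        t = rng.exponential(1.0, n) / lam
    return np.minimum(t, np.inf), np.where(t < T, t, np.inf)


class TestEmpiricalCurve:
    def test_step_positions_and_plateau(self):
        curve = empirical_first_binding(np.array([10.0, 20.0, np.inf]), 100.0)
        assert curve.at(5.0) == 0.0
        assert curve.at(10.0) == pytest.approx(1 / 3)
        assert curve.at(20.0) == pytest.approx(2 / 3)
        assert curve.at(99.0) == pytest.approx(2 / 3)

    def test_eventless_locations_give_flat_zero(self):
        curve = empirical_first_binding(np.full(5, np.inf), 100.0)
        assert curve.at(50.0) == 0.0
        assert len(curve.times) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            empirical_first_binding(np.array([]), 100.0)

    def test_large_sample_inside_dkw_band(self, rng):
        # DKW: sup |F_n - F| < sqrt(log(2/alpha)/(2n)) w.p. 1-alpha
        r, n, T = 0.003, 10_000, 1560.0
        t = rng.exponential(1 / r, n)
        curve = empirical_first_binding(np.where(t < T, t, np.inf), T)
        grid = np.linspace(0, T - 1, 200)
        eps = math.sqrt(math.log(2 / 1e-6) / (2 * n))
        assert np.max(np.abs(curve.at(grid) - (1 - np.exp(-r * grid)))) < eps


class TestFirstBindingFit:
    def test_reduces_to_exponential_mle_without_background(self, rng):
        # A_f=1, k_ns=0, no censoring: joint MLE collapses to 1/mean
        T, k = 1560.0, 0.02
        t = rng.exponential(1 / k, 400)
        assert t.max() < T
        fit = fit_first_binding(t, np.full(300, np.inf), T)
        assert fit.k_ns == 0.0
        assert fit.A_f == pytest.approx(1.0, abs=1e-3)
        assert fit.k_a == pytest.approx(1.0 / t.mean(), rel=1e-3)
        assert "low signal" not in " ".join(fit.flags)

    def test_censoring_adjusted_exponential_mle(self, rng):
        # with record-end censoring the rate stays near events/exposure;
        # A_f absorbs part of the censored mass, so agreement is within SE
        T, k = 1560.0, 0.004
        t = rng.exponential(1 / k, 400)
        fit = fit_first_binding(np.where(t < T, t, np.inf),
                                np.full(300, np.inf), T)
        mle = (t < T).sum() / np.minimum(t, T).sum()
        assert abs(fit.k_a - mle) < fit.se_k_a

    def test_parameter_recovery_within_two_se(self, rng):
        T = 1560.0
        k_a, A_f, k_ns = 0.0047, 0.8, 2e-4
        _, dna = _mixture_arrivals(rng, 1000, k_a, A_f, k_ns, T)
        ctrl = rng.exponential(1 / k_ns, 1000)
        fit = fit_first_binding(dna, np.where(ctrl < T, ctrl, np.inf), T)
        assert abs(fit.k_a - k_a) < 2 * fit.se_k_a
        assert abs(fit.A_f - A_f) < 2 * fit.se_A_f
        assert abs(fit.k_ns - k_ns) < 2 * fit.se_k_ns

    def test_median_relative_bias_below_five_percent(self):
        # 100 replicates at the default condition scale
        T, k_a, A_f, k_ns = 1560.0, 0.0047, 0.8, 2e-4
        rel = {"k_a": [], "A_f": [], "k_ns": []}
        for rep in range(100):
            r = np.random.Generator(np.random.PCG64(900 + rep))
            _, dna = _mixture_arrivals(r, 500, k_a, A_f, k_ns, T)
            ctrl = r.exponential(1 / k_ns, 1000)
            fit = fit_first_binding(dna, np.where(ctrl < T, ctrl, np.inf), T)
            rel["k_a"].append(fit.k_a / k_a - 1)
            rel["A_f"].append(fit.A_f / A_f - 1)
            rel["k_ns"].append(fit.k_ns / k_ns - 1)
        for name, v in rel.items():
            assert abs(np.median(v)) < 0.05, name

    def test_least_squares_agrees_with_mle_within_one_se(self, rng):
        T = 1560.0
        _, dna = _mixture_arrivals(rng, 2000, 0.0047, 0.8, 2e-4, T)
        ctrl = rng.exponential(1 / 2e-4, 1000)
        ctrl = np.where(ctrl < T, ctrl, np.inf)
        mle = fit_first_binding(dna, ctrl, T)
        ls = fit_first_binding_ls(dna, ctrl, T)
        assert abs(ls.k_a - mle.k_a) < mle.se_k_a
        assert abs(ls.A_f - mle.A_f) < mle.se_A_f

    def test_no_specific_binding_is_not_significant(self):
        # k_a = 0 truth: LRT non-significant at alpha=0.05 >= 90% of runs
        T, k_ns = 1560.0, 5e-4
        n_ns = 0
        for rep in range(100):
            r = np.random.Generator(np.random.PCG64(3000 + rep))
            dna = r.exponential(1 / k_ns, 300)
            ctrl = r.exponential(1 / k_ns, 1000)
            p = lrt_specific_binding(np.where(dna < T, dna, np.inf),
                                     np.where(ctrl < T, ctrl, np.inf), T)
            n_ns += p > 0.05
        assert n_ns >= 90

    def test_model_cdf_limits(self):
        t = np.array([0.0, 1e7])
        full = first_binding_cdf(t, 0.005, 0.7, 1e-4)
        assert full[0] == 0.0 and full[1] == pytest.approx(1.0)
        no_bg = first_binding_cdf(t, 0.005, 0.7, 0.0)
        assert no_bg[1] == pytest.approx(0.7)
        grid = np.linspace(0, 5000, 200)
        f = first_binding_cdf(grid, 0.005, 0.7, 1e-4)
        assert np.all(np.diff(f) >= 0)

    def test_low_signal_flagged(self, rng):
        T = 1560.0
        dna = rng.exponential(1 / 5e-4, 300)
        ctrl = rng.exponential(1 / 5e-4, 300)
        fit = fit_first_binding(np.where(dna < T, dna, np.inf),
                                np.where(ctrl < T, ctrl, np.inf), T)
        assert any("low signal" in f for f in fit.flags)


class TestSurvival:
    def test_uncensored_median(self):
        sc = survival_curve([1.0, 2.0, 3.0])
        assert sc.median == pytest.approx(2.0)
        assert not sc.median_is_lower_bound

    def test_all_censored_curve_is_one(self):
        sc = survival_curve([5.0, 5.0, 5.0], [True, True, True])
        assert np.all(sc.survival == 1.0)
        assert math.isinf(sc.median)
        assert sc.median_label == "> 5 s"

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        d = rng.exponential(100.0, 200)
        sc = survival_curve(d)
        # independent oracle: hand-rolled empirical survival function
        for t, s in zip(sc.times, sc.survival):
            assert s == pytest.approx(np.mean(d > t), abs=1e-12)

    def test_censored_exponential_median_recovered(self, rng):
        # 5,000 Exp(mean 584 s) dwells censored at 1,560 s
        mean, T = 584.0, 1560.0
        d = rng.exponential(mean, 5000)
        sc = survival_curve(np.minimum(d, T), d >= T)
        true_med = mean * math.log(2)
        se = 1.2533 * true_med / math.sqrt(5000)  # asymptotic KM median SE scale
        assert abs(sc.median - true_med) < 3 * se


class TestBinomial:
    @pytest.mark.parametrize("k,n,pct,sem", [
        (46, 223, 20.6, 2.7),
        (0, 162, 0.0, 0.0),
        (112, 160, 70.0, 3.6),
        (62, 171, 36.3, 3.7),
        (94, 191, 49.2, 3.6),
    ])
    def test_worked_examples(self, k, n, pct, sem):
        b = binomial_fraction(k, n)
        assert b.percent == pytest.approx(pct, abs=0.05)
        assert b.sem_percent == pytest.approx(sem, abs=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_fraction(1, 0)
        with pytest.raises(ValueError):
            binomial_fraction(5, 3)
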