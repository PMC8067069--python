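"""Zeta decline, exact/Monte-Carlo agreement and AIC model selection."""

import math

import numpy as np
import pytest

from beltdiv import (
    FormatError,
    ZetaDecline,
    fit_decline,
    select_model,
    zeta_decline,
)
from beltdiv.zeta_diversity import DeclineFit, gaussian_aic

from oracles import brute_zeta, random_incidence


def _decline_from_values(zeta_mean):
    zeta_mean = np.asarray(zeta_mean, dtype=float)
    orders = np.arange(1, len(zeta_mean) + 1)
    zeros = np.zeros_like(zeta_mean)
    return ZetaDecline(orders=orders, zeta_mean=zeta_mean, zeta_sd=zeros,
                       ci_low=zeta_mean, ci_high=zeta_mean,
                       n_subsets=np.ones(len(zeta_mean), dtype=np.int64),
                       mode="exact", seed=None)


def test_fixture_zeta_by_full_enumeration(table3):
    matrix, _ = table3
    decline = zeta_decline(matrix, 3, mode="exact")
    assert decline.zeta_mean == pytest.approx([7.0, 11 / 3, 3.0])


def test_ubiquitous_species_gives_constant_zeta(rng):
    matrix = random_incidence(rng, 8, 1, p=2.0)  # p>1: all present
    decline = zeta_decline(matrix, 8, mode="exact")
    assert decline.zeta_mean == pytest.approx(np.ones(8))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_exact_mode_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_units = int(rng.integers(4, 13))
    matrix = random_incidence(rng, n_units, int(rng.integers(3, 9)), p=0.45)
    decline = zeta_decline(matrix, min(5, n_units), mode="exact")
    values = matrix.values()
    for idx, order in enumerate(decline.orders):
        mean, sd = brute_zeta(values, int(order))
        assert decline.zeta_mean[idx] == pytest.approx(mean, abs=1e-12)
        assert decline.zeta_sd[idx] == pytest.approx(sd, abs=1e-10)


def test_monte_carlo_agrees_with_exact_within_three_se(rng):
    matrix = random_incidence(rng, 10, 8, p=0.5)
    exact = zeta_decline(matrix, 5, mode="exact")
    n_samples = 5000
    mc = zeta_decline(matrix, 5, mode="monte_carlo", n_samples=n_samples,
                      seed=7)
    for idx in range(5):
        se = mc.zeta_sd[idx] / math.sqrt(n_samples)
        tol = max(3 * se, 1e-9)
        assert abs(mc.zeta_mean[idx] - exact.zeta_mean[idx]) <= tol


def test_monte_carlo_is_seed_deterministic(rng):
    matrix = random_incidence(rng, 10, 8, p=0.5)
    a = zeta_decline(matrix, 4, mode="monte_carlo", n_samples=200, seed=11)
    b = zeta_decline(matrix, 4, mode="monte_carlo", n_samples=200, seed=11)
    assert np.array_equal(a.zeta_mean, b.zeta_mean)
    assert np.array_equal(a.zeta_sd, b.zeta_sd)


def test_zeta_non_increasing_on_random_matrices():
    for seed in range(50):
        rng = np.random.default_rng(seed)
        matrix = random_incidence(rng, int(rng.integers(3, 10)),
                                  int(rng.integers(2, 12)), p=0.5)
        decline = zeta_decline(matrix, matrix.n_units, mode="exact")
        assert np.all(np.diff(decline.zeta_mean) <= 1e-12)
        assert np.all(decline.zeta_mean >= 0)


def test_zeta_order_one_is_mean_richness(table3):
    matrix, _ = table3
    decline = zeta_decline(matrix, 1, mode="exact")
    assert decline.zeta_mean[0] == pytest.approx(float(matrix.richness().mean()))


def test_order_bounds_are_enforced(table3):
    matrix, _ = table3
    with pytest.raises(FormatError):
        zeta_decline(matrix, 4)
    with pytest.raises(FormatError):
        zeta_decline(matrix, 0)


class TestDeclineFits:
    def test_exponential_series_recovered_exactly(self):
        i = np.arange(1, 6)
        decline = _decline_from_values(8.0 * np.exp(-0.5 * i))
        exp_fit, _ = fit_decline(decline)
        assert exp_fit.slope == pytest.approx(-0.5, abs=1e-10)
        assert exp_fit.rss < 1e-20

    def test_power_law_series_recovered_exactly(self):
        i = np.arange(1, 6)
        decline = _decline_from_values(6.0 * i ** (-1.0))
        _, pl_fit = fit_decline(decline)
        assert pl_fit.slope == pytest.approx(-1.0, abs=1e-10)
        assert pl_fit.rss < 1e-20

    def test_constant_zeta_is_indeterminate(self):
        decline = _decline_from_values([4.0] * 5)
        exp_fit, pl_fit = fit_decline(decline)
        assert exp_fit.slope == pytest.approx(0.0, abs=1e-12)
        assert pl_fit.slope == pytest.approx(0.0, abs=1e-12)
        assert exp_fit.rss == pytest.approx(0.0, abs=1e-20)
        selection = select_model(exp_fit, pl_fit)
        assert selection.delta_aic == 0.0
        assert selection.verdict == "indeterminate"

    def test_zero_orders_truncated(self):
        decline = _decline_from_values([4.0, 2.0, 1.0, 0.0, 0.0])
        exp_fit, pl_fit = fit_decline(decline)
        assert exp_fit.n_points == 3
        assert np.array_equal(exp_fit.orders, [1.0, 2.0, 3.0])

    def test_too_few_positive_orders_is_an_error(self):
        decline = _decline_from_values([4.0, 2.0, 0.0, 0.0, 0.0])
        with pytest.raises(FormatError, match="3 orders"):
            fit_decline(decline)

    def test_bernoulli_expectation_recovers_log_occupancy_slope(self):
        # independent occupancy with common p: E[zeta_i] = S p^i, so the
        # exponential fit of the expectation recovers slope ln p
        p, s_species = 0.37, 11
        i = np.arange(1, 7)
        decline = _decline_from_values(s_species * p ** i)
        exp_fit, _ = fit_decline(decline)
        assert exp_fit.slope == pytest.approx(math.log(p), abs=1e-12)
        assert exp_fit.intercept == pytest.approx(math.log(s_species), abs=1e-10)


class TestModelSelection:
    def test_exponential_preferred_verdict(self):
        exp_fit = DeclineFit("exponential", 1.0, -0.5, 0.01,
                             gaussian_aic(0.01, 5), 5, np.arange(1, 6))
        pl_fit = DeclineFit("power_law", 1.0, -1.0, 0.25,
                            gaussian_aic(0.25, 5), 5, np.arange(1, 6))
        selection = select_model(exp_fit, pl_fit)
        assert selection.aic_exponential < selection.aic_power_law
        assert selection.verdict == "stochastic"

    def test_power_law_preferred_by_wide_margin(self):
        exp_fit = DeclineFit("exponential", 1.0, -0.5, 0.25,
                             gaussian_aic(0.25, 5), 5, np.arange(1, 6))
        pl_fit = DeclineFit("power_law", 1.0, -1.0, 0.01,
                            gaussian_aic(0.01, 5), 5, np.arange(1, 6))
        assert select_model(exp_fit, pl_fit).verdict == "niche_driven"

    def test_mismatched_points_rejected(self):
        exp_fit = DeclineFit("exponential", 1.0, -0.5, 0.1,
                             gaussian_aic(0.1, 5), 5, np.arange(1, 6))
        pl_fit = DeclineFit("power_law", 1.0, -1.0, 0.1,
                            gaussian_aic(0.1, 4), 4, np.arange(1, 5))
        with pytest.raises(FormatError, match="same orders"):
            select_model(exp_fit, pl_fit)

    def test_delta_aic_invariant_to_response_rescaling(self):
        # rescaling zeta (e.g. switching logarithm base) shifts both AICs
        # equally, so the verdict cannot depend on it
        values = np.array([6.1, 3.2, 1.9, 1.2, 0.8])
        base = select_model(*fit_decline(_decline_from_values(values)))
        for scale in (10.0, 0.01):
            scaled = select_model(
                *fit_decline(_decline_from_values(scale * values)))
            assert scaled.delta_aic == pytest.approx(base.delta_aic,
                                                     abs=1e-9)
            assert scaled.verdict == base.verdict
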