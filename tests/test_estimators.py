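"""Hájek estimation and the simplified Hansen-Hurwitz variance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allema.estimators import (estimate_mean, fpc_overestimation_factor,
                               hajek_mean, hansen_hurwitz_variance, nhat,
                               square_totals)


# -------------------------------------------------------------- Hájek mean

def test_constant_response_estimated_exactly_for_any_weights():
    rng = np.random.default_rng(0)
    pi = rng.uniform(0.01, 1.0, 30)
    assert hajek_mean(np.full(30, 3.7), pi) == pytest.approx(3.7)


def test_hand_weighted_two_plot_example():
    # (1/0.5 + 3/0.25) / (1/0.5 + 1/0.25) = 14/6 = 7/3
    assert hajek_mean([1, 3], [0.5, 0.25]) == pytest.approx(7 / 3)


def test_census_indicator_recovers_exact_proportion():
    y = np.array([1, 0, 1, 1, 0, 0, 0, 1])
    assert hajek_mean(y, np.ones(8)) == pytest.approx(0.5)


def test_empty_or_invalid_sample_raises():
    with pytest.raises(ValueError):
        hajek_mean([], [])
    with pytest.raises(ValueError):
        hajek_mean([1.0], [0.0])


@settings(max_examples=40, derandomize=True)
@given(st.floats(0.1, 10.0))
def test_hajek_invariant_to_weight_scaling(c):
    """Multiplying all pi by a constant does not change the estimate."""
    y = np.array([1.0, 2.0, 5.0])
    pi = np.array([0.2, 0.5, 0.8])
    scaled = np.clip(pi * c, 1e-9, 1.0)
    if np.all(pi * c <= 1.0):
        assert hajek_mean(y, scaled) == pytest.approx(hajek_mean(y, pi))


def test_area_shares_over_exhaustive_categories_sum_to_one():
    rng = np.random.default_rng(1)
    n = 200
    pi = rng.uniform(0.002, 0.02, n)
    cats = rng.integers(0, 5, n)
    shares = [hajek_mean((cats == k).astype(float), pi) for k in range(5)]
    assert sum(shares) == pytest.approx(1.0, abs=1e-12)


# ----------------------------------------------------------- square totals

def test_single_plot_total_is_reciprocal_of_conditional_probability():
    plots = pd.DataFrame({"square_id": ["a"], "pi2_given_s1": [0.004]})
    tot = square_totals(np.array([1.0]), plots, "habitat")
    assert tot["a"] == pytest.approx(250.0)


def test_vegetation_reduces_to_habitat_when_third_stage_is_certain():
    plots = pd.DataFrame({
        "square_id": ["a", "a", "b"],
        "pi2_given_s1": [0.004, 0.004, 0.08],
        "pi3_given_s2": [1.0, 1.0, 1.0],
    })
    y = np.array([1.0, 2.0, 3.0])
    pd.testing.assert_series_equal(square_totals(y, plots, "vegetation"),
                                   square_totals(y, plots, "habitat"))


def test_polygon_weight_zero_removes_the_plot_contribution():
    plots = pd.DataFrame({
        "square_id": ["a", "a"],
        "pi2e_given_s1": [0.1, 0.1],
        "pi3e_given_s2": [0.5, 0.5],
    })
    tot = square_totals(np.array([1.0, 1.0]), plots, "efa",
                        w=np.array([0.0, 1.0]))
    assert tot["a"] == pytest.approx(1.0 / 0.05)
    with pytest.raises(ValueError, match="w_j"):
        square_totals(np.array([1.0, 1.0]), plots, "efa")


# ---------------------------------------------------- Hansen-Hurwitz variance

def literal_variance_oracle(Yi, pi1, m, n_hat):
    """Direct transcription of the single-sum variance formula."""
    p = np.asarray(pi1) / m
    Yhat = sum(y / q for y, q in zip(Yi, pi1))
    ss = sum((y / pk - Yhat) ** 2 for y, pk in zip(Yi, p))
    return ss / (n_hat ** 2 * m * (m - 1))


def test_matches_literal_formula_oracle_on_three_square_toy():
    Yi = np.array([120.0, 250.0, 80.0])
    pi1 = np.array([0.02, 0.05, 0.01])
    n_hat = 15000.0
    got = hansen_hurwitz_variance(Yi, pi1, 3, n_hat)
    want = literal_variance_oracle(Yi, pi1, 3, n_hat)
    assert got == pytest.approx(want, abs=1e-12 * max(want, 1))


def test_zero_between_square_dispersion_gives_zero_variance():
    pi1 = np.array([0.01, 0.02, 0.04])
    Yi = pi1 * 100.0  # Yi / p_i identical for all squares
    assert hansen_hurwitz_variance(Yi, pi1, 3, 1000.0) == pytest.approx(0.0)


def test_variance_scales_quadratically_with_the_response():
    rng = np.random.default_rng(3)
    Yi = rng.uniform(10, 100, 5)
    pi1 = rng.uniform(0.01, 0.1, 5)
    v1 = hansen_hurwitz_variance(Yi, pi1, 5, 500.0)
    v2 = hansen_hurwitz_variance(2 * Yi, pi1, 5, 500.0)
    assert v2 == pytest.approx(4 * v1)


def test_small_samples_rejected():
    with pytest.raises(ValueError):
        hansen_hurwitz_variance([1.0], [0.5], 1, 10.0)


# --------------------------------------------------------------------- fpc

def test_fpc_factor_printed_value():
    assert fpc_overestimation_factor(15688, 170) == pytest.approx(
        1.010891, abs=5e-7)


def test_fpc_limits():
    assert fpc_overestimation_factor(1000, 1) == pytest.approx(1.0)
    assert fpc_overestimation_factor(1e12, 170) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        fpc_overestimation_factor(100, 100)


# -------------------------------------------------------------------- N-hat

def test_nhat_census_and_equal_probability():
    assert nhat(np.ones(7)) == pytest.approx(7.0)
    assert nhat(np.full(10, 0.1)) == pytest.approx(100.0)


def test_nhat_polygon_weights_scale_linearly():
    pi = np.full(10, 0.1)
    full = nhat(pi, "efa", w=np.ones(10))
    half = nhat(pi, "efa", w=np.full(10, 0.5))
    assert half == pytest.approx(0.5 * full)


# ----------------------------------------------- two-stage sampling checks

def _two_stage_population(seed=0):
    """12 squares with known plot values; truth = overall plot mean."""
    rng = np.random.default_rng(seed)
    n_plots = rng.integers(20, 60, 12)
    values = [rng.uniform(0, 1, n) + 0.05 * i for i, n in enumerate(n_plots)]
    return n_plots, values


def _draw_two_stage(n_plots, values, rng, m=4, f2=0.4):
    """Select m squares pps-ish and an SRS of plots within each."""
    from allema.sampling import random_pivotal

    sizes = n_plots / n_plots.sum()
    pi1 = np.clip(m * sizes, 0.01, 0.95)
    pi1 *= m / pi1.sum()
    ind = random_pivotal(pi1, rng).indicator
    rows, ys = [], []
    for i in np.flatnonzero(ind == 1):
        k = max(2, int(round(f2 * n_plots[i])))
        chosen = rng.choice(n_plots[i], k, replace=False)
        rows += [{"square_id": i, "pi2_given_s1": k / n_plots[i]}] * k
        ys += [values[i][c] for c in chosen]
    plots = pd.DataFrame(rows)
    squares = pd.DataFrame({"square_id": np.flatnonzero(ind == 1),
                            "pi1": pi1[ind == 1]})
    return np.array(ys), plots, squares


def test_hajek_mean_unbiased_over_replicates():
    """Mean of the estimator over 2,000 two-stage replicates is within 3
    Monte Carlo SE of the true population mean."""
    n_plots, values = _two_stage_population()
    truth = np.concatenate(values).mean()
    rng = np.random.default_rng(10)
    ests = []
    for _ in range(2000):
        y, plots, squares = _draw_two_stage(n_plots, values, rng)
        res = estimate_mean(y, plots, squares, "habitat")
        ests.append(res.estimate)
    ests = np.asarray(ests)
    mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - truth) <= 3 * mc_se + 1e-3


def test_variance_estimator_is_conservative_on_average():
    """Empirical variance of the estimator stays below the mean estimated
    variance times 1.15 (with-replacement assumption is conservative)."""
    n_plots, values = _two_stage_population(seed=5)
    rng = np.random.default_rng(20)
    ests, vars_ = [], []
    for _ in range(1500):
        y, plots, squares = _draw_two_stage(n_plots, values, rng)
        res = estimate_mean(y, plots, squares, "habitat")
        ests.append(res.estimate)
        vars_.append(res.variance)
    emp = np.var(ests, ddof=1)
    assert emp <= np.mean(vars_) * 1.15


def test_estimate_mean_includes_empty_squares_with_zero_totals():
    plots = pd.DataFrame({"square_id": ["a", "a"],
                          "pi2_given_s1": [0.5, 0.5],
                          "pi1": [0.4, 0.4]})
    squares = pd.DataFrame({"square_id": ["a", "b"], "pi1": [0.4, 0.2]})
    res = estimate_mean(np.array([1.0, 1.0]), plots, squares, "habitat")
    assert res.square_totals["b"] == 0.0
    assert res.m == 2


def test_domain_estimation_keeps_full_denominator():
    plots = pd.DataFrame({"square_id": ["a", "a", "b", "b"],
                          "pi2_given_s1": [0.5] * 4,
                          "pi1": [0.4, 0.4, 0.4, 0.4]})
    squares = pd.DataFrame({"square_id": ["a", "b"], "pi1": [0.4, 0.4]})
    y = np.array([1.0, 1.0, 1.0, 1.0])
    dom = np.array([True, True, False, False])
    res = estimate_mean(y, plots, squares, "habitat", domain=dom)
    assert res.estimate == pytest.approx(0.5)  # half the area is in-domain
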