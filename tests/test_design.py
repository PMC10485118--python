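"""The three-stage baseline design: probabilities, grids, covariates."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import allema.design as dsn
from allema.design import (DemGrid, DesignConfig, build_plot_grid,
                           derive_plot_covariates, first_stage_sample,
                           frame_filter, initial_probabilities,
                           plot_polygon_coverage, self_weighting_diagnostic,
                           third_stage_sample)
from allema.sampling import solve_capped_inclusion
from allema.simulate import (calibrated_index_for_frame, synthetic_frame,
                             synthetic_plot_frame, synthetic_raw_frame)


# ------------------------------------------------------------ initial stage

def test_initial_probabilities_match_grid_densities():
    frame = pd.DataFrame({"density_class": ["dense", "regular"]})
    pi0 = initial_probabilities(frame)
    assert pi0[0] == pytest.approx(0.01880208, abs=5e-9)
    assert pi0[1] == pytest.approx(0.00940104, abs=5e-9)
    assert pi0[0] / pi0[1] == pytest.approx(2.0)


def test_unknown_density_class_raises():
    with pytest.raises(ValueError, match="sparse"):
        initial_probabilities(pd.DataFrame({"density_class": ["sparse"]}))


def test_frame_filter_retains_accessible_squares():
    raw, flags = synthetic_raw_frame(seed=3)
    assert len(raw) == 509
    filtered = frame_filter(raw, flags)
    assert len(filtered) == 455


def test_frame_filter_identity_and_empty():
    raw, _ = synthetic_raw_frame(seed=3)
    same = frame_filter(raw, {})
    assert len(same) == len(raw)
    empty = frame_filter(raw, {"all": np.ones(len(raw), bool)})
    assert empty.empty


# ------------------------------------------------------------- second stage

def test_plot_grid_geometry_and_probabilities(toy_square, config):
    grid = build_plot_grid(toy_square, None, config)
    assert len(grid) == 361
    xs = np.sort(grid["x"].unique())
    assert len(xs) == 19
    np.testing.assert_allclose(np.diff(xs), 50.0)
    # symmetric 25-m margins keep the 200 m2 circles inside the square
    assert xs[0] == pytest.approx(-475.0 + 25.0)
    assert grid["pi2_given_s1"].iloc[0] == pytest.approx(0.004)
    ratio = grid["pi2_structure_given_s1"] / grid["pi2_given_s1"]
    np.testing.assert_allclose(ratio, 20.0)
    assert grid["on_agricultural_land"].sum() == 361


def test_plot_grid_counts_plots_inside_mask(toy_square, config):
    mask = box(-475, -475, 0, 475)  # western half of the square
    grid = build_plot_grid(toy_square, mask, config)
    n_i = grid["on_agricultural_land"].sum()
    assert 0 < n_i < 361
    assert n_i == 10 * 19  # 10 of the 19 columns lie at x <= 0


def test_plot_grid_disjoint_mask_warns(toy_square, config, caplog):
    far = box(10_000, 10_000, 11_000, 11_000)
    with caplog.at_level("WARNING"):
        grid = build_plot_grid(toy_square, far, config)
    assert grid["on_agricultural_land"].sum() == 0
    assert "n_i = 0" in caplog.text


# -------------------------------------------------------------- first stage

def test_first_stage_sizes_and_probability_products(frame455, config):
    index = calibrated_index_for_frame(frame455, config)
    draw, probs = first_stage_sample(frame455, index, config, 0)
    assert draw.size == 170
    per_group = probs.groupby("R")["pi1_given_s0"].sum()
    np.testing.assert_allclose(per_group, 34.0, atol=1e-6)
    realized = pd.Series(draw.indicator).groupby(probs["R"].to_numpy()).sum()
    assert set(realized) == {34}
    np.testing.assert_allclose(probs["pi1"],
                               probs["pi0"] * probs["pi1_given_s0"],
                               rtol=0, atol=1e-12)


def test_first_stage_equal_sizes_give_equal_pi_within_group(config):
    frame = synthetic_frame(60, seed=4)
    frame["n_i"] = 200
    cfg = DesignConfig(m=20, r=5)
    index = np.ones(len(frame))
    _, probs = first_stage_sample(frame, index, cfg, 1)
    for _, grp in probs.groupby("R"):
        np.testing.assert_allclose(grp["pi1_given_s0"],
                                   grp["pi1_given_s0"].iloc[0])


def test_first_stage_pi_recovery_and_nipq_balance(small_frame):
    """500 replicates on a 60-square frame: selection frequencies within
    4 SE for nearly all squares, and the HT estimate of the frame total of
    n_i within 5% (n_i is a balancing variable)."""
    frame, cfg = small_frame
    index = calibrated_index_for_frame(frame, cfg)
    rng = np.random.default_rng(42)
    R = 500
    acc = np.zeros(len(frame))
    ht_err = []
    n_i = frame["n_i"].to_numpy(float)
    draw, probs = first_stage_sample(frame, index, cfg, rng)
    pi = probs["pi1_given_s0"].to_numpy()
    total = n_i.sum()
    for _ in range(R):
        ind = first_stage_sample(frame, index, cfg, rng)[0].indicator
        acc += ind
        sel = ind == 1
        ht_err.append(abs(np.sum(n_i[sel] / pi[sel]) - total) / total)
    freq = acc / R
    se = np.sqrt(pi * (1 - pi) / R)
    ok = np.abs(freq - pi) <= 4 * np.maximum(se, 1e-12)
    assert ok.mean() >= 0.95
    assert np.quantile(ht_err, 0.95) < 0.05


def test_first_stage_rejects_undersized_group(config):
    frame = synthetic_frame(60, seed=4)  # 12 squares per rotation group
    with pytest.raises(ValueError, match="rotation group"):
        first_stage_sample(frame, np.ones(60), config, 0)  # needs 34/group


# -------------------------------------------------------------- third stage

def test_quota_square_with_equal_interest(toy_square, config):
    """n_i >= v0 and constant J: pi_3 = 19/n_i and exactly 19 selected."""
    plots = synthetic_plot_frame(toy_square, 100, config, seed=1)
    plots["J"] = 1.0
    draw, out = third_stage_sample(plots, None, config, 3)
    assert draw.size == 19
    np.testing.assert_allclose(out["pi3_given_s2"], 19 / 100)


def test_small_square_taken_exhaustively(toy_square, config):
    plots = synthetic_plot_frame(toy_square, 7, config, seed=2)
    draw, out = third_stage_sample(plots, None, config, 4)
    assert draw.size == 7
    np.testing.assert_allclose(out["pi3_given_s2"], 1.0)
    assert (out["v_i"] == 7).all()


def test_heterogeneous_interest_matches_capping_solver(toy_square, config):
    plots = synthetic_plot_frame(toy_square, 30, config, seed=5)
    _, out = third_stage_sample(plots, None, config, 6)
    oracle = solve_capped_inclusion(plots["J"].to_numpy(), 19)
    np.testing.assert_allclose(out["pi3_given_s2"], oracle.values, atol=1e-12)


def test_total_probability_products_consistent(toy_square, config):
    plots = synthetic_plot_frame(toy_square, 50, config, seed=7)
    plots["pi1"] = 0.3
    _, out = third_stage_sample(plots, None, config, 8)
    np.testing.assert_allclose(
        out["pi_V"],
        out["pi1"] * out["pi2_given_s1"] * out["pi3_given_s2"],
        rtol=0, atol=1e-12)


def test_fixed_quota_in_every_replicate(toy_square, config):
    plots = synthetic_plot_frame(toy_square, 60, config, seed=9)
    sizes = {third_stage_sample(plots, None, config, s)[0].size
             for s in range(30)}
    assert sizes == {19}


# ----------------------------------------------------------- self-weighting

def test_idealized_design_is_exactly_self_weighted(config):
    """pi_1|S0 strictly proportional to n_i (no capping), constant J,
    full quota: the n_i factors cancel and pi_V is constant."""
    rng = np.random.default_rng(1)
    n_i = rng.integers(80, 361, 25)
    c = 0.002  # proportionality constant; c * max(n_i) stays below 1
    probs = pd.DataFrame({
        "square_id": np.repeat([f"s{i}" for i in range(25)], n_i),
        "pi1": np.repeat(c * n_i / n_i.max(), n_i),
        "pi2_given_s1": 0.004,
        "pi3_given_s2": np.repeat(19.0 / n_i, n_i),
    })
    probs["pi_V"] = (probs["pi1"] * probs["pi2_given_s1"]
                     * probs["pi3_given_s2"])
    diag = self_weighting_diagnostic(probs)
    assert diag["cv_pi_v_squares"] < 1e-9
    assert diag["cv_pi_v_plots"] < 1e-9


def test_diagnostic_flags_capped_squares():
    probs = pd.DataFrame({
        "square_id": ["a", "a", "b", "b"],
        "pi1_given_s0": [1.0, 1.0, 0.4, 0.4],
        "pi3_given_s2": [0.5, 0.5, 1.0, 0.5],
        "pi_V": [0.002, 0.002, 0.001, 0.0005],
    })
    diag = self_weighting_diagnostic(probs)
    assert set(diag["capped_squares"]) == {"a", "b"}
    assert diag["cv_pi_v_squares"] > 0


# ------------------------------------------------------- terrain covariates

def _plane_dem(gx, gy, base=1000.0, half=700.0, res=25.0):
    k = int(2 * half / res) + 1
    xs = -half + res * np.arange(k)
    ys = -half + res * np.arange(k)
    XX, YY = np.meshgrid(xs, ys)
    return DemGrid(values=base + gx * XX + gy * YY, x0=xs[0], y0=ys[0],
                   res=res)


def test_plane_tilted_down_to_the_east(config):
    """z decreasing eastward: aspect 90 deg; with the design's printed
    convention east = cos(90) = 0 and north = sin(90) = 1."""
    dem = _plane_dem(gx=-0.1, gy=0.0)
    plots = pd.DataFrame({"x": [0.0, 100.0], "y": [0.0, -50.0]})
    out = derive_plot_covariates(dem, plots, config)
    np.testing.assert_allclose(out["east"], 0.0, atol=1e-12)
    np.testing.assert_allclose(out["north"], 1.0, atol=1e-12)
    np.testing.assert_allclose(out["slope"],
                               np.degrees(np.arctan(0.1)), atol=1e-6)
    np.testing.assert_allclose(out["east"]**2 + out["north"]**2, 1.0)


def test_gis_convention_swaps_components():
    dem = _plane_dem(gx=-0.1, gy=0.0)
    cfg = DesignConfig(gis_aspect_convention=True)
    out = derive_plot_covariates(dem, pd.DataFrame({"x": [0.0], "y": [0.0]}),
                                 cfg)
    np.testing.assert_allclose(out["east"], 1.0, atol=1e-12)  # due east
    np.testing.assert_allclose(out["north"], 0.0, atol=1e-12)


def test_flat_plane_has_undefined_orientation(config):
    dem = _plane_dem(gx=0.0, gy=0.0)
    out = derive_plot_covariates(dem, pd.DataFrame({"x": [0.0], "y": [0.0]}),
                                 config)
    assert out["slope"].iloc[0] == 0.0
    assert bool(out["aspect_undefined"].iloc[0])
    assert out["east"].iloc[0] == 0.0 and out["north"].iloc[0] == 0.0
    assert out["topo"].iloc[0] == 4  # mid-ladder when relief is absent


def test_inclined_plane_slope_matches_closed_form(config):
    gx, gy = 0.06, -0.08  # gradient magnitude 0.1
    dem = _plane_dem(gx=gx, gy=gy)
    pts = pd.DataFrame({"x": [0.0, 50.0, -75.0], "y": [25.0, 0.0, -50.0]})
    out = derive_plot_covariates(dem, pts, config)
    np.testing.assert_allclose(out["slope"],
                               np.degrees(np.arctan(np.hypot(gx, gy))),
                               atol=1e-6)


def test_point_outside_raster_raises(config):
    dem = _plane_dem(gx=0.0, gy=0.0, half=100.0)
    with pytest.raises(ValueError, match="outside"):
        derive_plot_covariates(dem, pd.DataFrame({"x": [5000.0],
                                                  "y": [0.0]}), config)


def test_topo_levels_span_the_ordinal_ladder(toy_square, config):
    plots = synthetic_plot_frame(toy_square, 200, config, seed=11)
    assert plots["topo"].between(1, 8).all()
    assert plots["topo"].nunique() >= 4  # undulating surface uses the ladder


# ------------------------------------------------------------ polygon cover

def test_polygon_coverage_weights(toy_square, config):
    grid = build_plot_grid(toy_square, None, config)
    half = box(-475, -475, 0.1, 475)
    w = plot_polygon_coverage(grid.iloc[:40], half, plot_area=10.0)
    assert np.all((w >= 0) & (w <= 1))
    assert ((w > 0) & (w < 1)).any() or {0.0, 1.0} <= set(np.round(w, 6))
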