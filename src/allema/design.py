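"""Three-stage baseline monitoring design for square-based frames.

The baseline design selects, in order:

1. an *initial* systematic grid of 1-km squares whose density differs
   between regions (the initial inclusion probability ``pi_0`` is the ratio
   of the surveyed square area to the grid cell area);
2. a *first-stage* sample of squares, with inclusion probabilities
   proportional to ``n_i * I_i`` (number of accessible habitat-plot centres
   times a calibrated index of interest), capped at 1, summing to ``m/r``
   within each of ``r`` rotation groups, drawn by stratified, doubly
   balanced spatial sampling;
3. a *second-stage* systematic 50-m grid of nested circular plots
   (10 m² habitat plots, 200 m² structure plots) inside each selected
   square — every grid point on accessible agricultural land is surveyed,
   so the conditional probability is the areal sampling fraction;
4. a *third-stage* unequal-probability subsample of the habitat plots for
   the vegetation survey, guided by a plot-level interest index ``J_j``,
   with a fixed per-square quota ``v_0`` and doubly balanced selection on
   terrain covariates.

Because the squares are selected proportional to ``n_i * I_i`` and the
vegetation quota is constant, the first and third stages are (almost)
self-weighted: the total inclusion probabilities ``pi_V`` of vegetation
plots have very small dispersion.  :func:`self_weighting_diagnostic`
quantifies this.

Frames and plot tables are plain :class:`pandas.DataFrame` objects; see
:mod:`allema.io` for the column contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import InterestIndex
from .sampling import (SampleDraw, local_cube, solve_capped_inclusion,
                       stratified_balanced_sample)

__all__ = [
    "DesignConfig",
    "DemGrid",
    "DENSE_GRID_CELL_KM2",
    "REGULAR_GRID_CELL_KM2",
    "initial_probabilities",
    "frame_filter",
    "build_plot_grid",
    "first_stage_probabilities",
    "first_stage_balancing",
    "first_stage_sample",
    "third_stage_sample",
    "self_weighting_diagnostic",
    "derive_plot_covariates",
    "plot_polygon_coverage",
]

logger = logging.getLogger(__name__)

#: grid cell area (km²) per square in the dense and regular grid regions
DENSE_GRID_CELL_KM2 = 48.0
REGULAR_GRID_CELL_KM2 = 96.0


@dataclass
class DesignConfig:
    """Tunable constants of the baseline design.

    Defaults are the operational configuration: ``m = 170`` squares in
    ``r = 5`` annual rotation groups of 34, a per-square vegetation quota
    ``v_0 = 19``, power-allocation exponent ``alpha = 0.5`` and index
    bounds ``(0.61, 3)``, a 50-m plot grid inside 950-m squares, and nested
    plot areas of 10 and 200 m².
    """

    m: int = 170
    r: int = 5
    v0: int = 19
    alpha: float = 0.5
    bounds: tuple[float, float] = (0.61, 3.0)
    side: float = 950.0
    grid_spacing: float = 50.0
    plot_area: float = 10.0
    structure_area: float = 200.0
    seed: int | None = None
    #: if True, use the GIS convention east=sin(aspect), north=cos(aspect)
    #: instead of the design's printed convention (east=cos, north=sin)
    gis_aspect_convention: bool = False

    def __post_init__(self):
        if self.m % self.r != 0:
            raise ValueError("m must be divisible by r")
        if self.grid_points_per_square < self.v0:
            raise ValueError("v0 exceeds the number of grid positions")

    @property
    def group_size(self) -> int:
        return self.m // self.r

    @property
    def grid_points_per_side(self) -> int:
        # e.g. 19 points at 50-m spacing span 900 m, centred in the 950-m
        # square with symmetric 25-m margins
        return int(round(self.side / self.grid_spacing))

    @property
    def grid_points_per_square(self) -> int:
        return self.grid_points_per_side ** 2


# ---------------------------------------------------------------------------
# initial stage
# ---------------------------------------------------------------------------

def initial_probabilities(frame: pd.DataFrame,
                          surveyed_area_km2: float = 0.9025) -> pd.Series:
    """Initial inclusion probability ``pi_0`` of each square.

    The initial sample is a systematic grid with one square per 48 km² in
    the dense-grid regions and one per 96 km² elsewhere; the surveyed part
    of a square covers 0.9025 km² (950 m x 950 m), so
    ``pi_0 = 0.9025/48 = 0.01880208`` (dense) or ``0.9025/96 = 0.00940104``.
    """
    cls = frame["density_class"].astype(str)
    known = cls.isin(["dense", "regular"])
    if not known.all():
        bad = sorted(cls[~known].unique())
        raise ValueError(f"unknown grid-density class(es): {bad}")
    cell = np.where(cls == "dense", DENSE_GRID_CELL_KM2, REGULAR_GRID_CELL_KM2)
    return pd.Series(surveyed_area_km2 / cell, index=frame.index, name="pi0")


def frame_filter(raw_frame: pd.DataFrame, exclusion_flags) -> pd.DataFrame:
    """Drop squares excluded from the frame; report the counts.

    ``exclusion_flags`` maps a reason label to a boolean vector (True =
    exclude), e.g. fully glacier/lake/inaccessible squares and squares
    without accessible agricultural land.
    """
    keep = np.ones(len(raw_frame), dtype=bool)
    for reason, flag in dict(exclusion_flags).items():
        flag = np.asarray(flag, dtype=bool)
        if flag.shape[0] != len(raw_frame):
            raise ValueError(f"flag '{reason}' has wrong length")
        n = int((flag & keep).sum())
        keep &= ~flag
        logger.info("frame filter: %d squares excluded (%s)", n, reason)
    out = raw_frame.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("frame filter removed every square")
    logger.info("frame filter: %d of %d squares retained",
                len(out), len(raw_frame))
    return out


# ---------------------------------------------------------------------------
# second stage: systematic plot grid
# ---------------------------------------------------------------------------

def build_plot_grid(square, agricultural_mask=None,
                    config: DesignConfig | None = None) -> pd.DataFrame:
    """Candidate plot centres on the systematic grid inside one square.

    The 19 x 19 grid (50-m spacing) is centred in the 950-m square, leaving
    symmetric 25-m margins so the 200 m² circles stay inside.  Each plot
    carries the conditional inclusion probabilities of the habitat plot
    (``pi2_given_s1 = plot_area * 361 / 950² = 0.004`` for 10 m²) and of
    the structure plot (20x larger area, hence 20x the probability).

    Parameters
    ----------
    square : mapping with keys ``square_id``, ``x``, ``y``
        Centre coordinates of the square (m).
    agricultural_mask : shapely geometry, optional
        Accessible agricultural land; plots outside it are flagged
        ``on_agricultural_land=False``.  ``None`` means full coverage.
    """
    config = config or DesignConfig()
    cx, cy = float(square["x"]), float(square["y"])
    sid = square["square_id"]
    k = config.grid_points_per_side
    offs = (np.arange(k) - (k - 1) / 2) * config.grid_spacing
    gx, gy = np.meshgrid(cx + offs, cy + offs, indexing="xy")
    gx, gy = gx.ravel(), gy.ravel()

    if agricultural_mask is None:
        on_land = np.ones(gx.size, dtype=bool)
    else:
        from shapely.geometry import Point
        on_land = np.array([agricultural_mask.covers(Point(x, y))
                            for x, y in zip(gx, gy)])
        if not on_land.any():
            logger.warning("agricultural mask does not overlap square %r; "
                           "n_i = 0", sid)

    denom = config.side ** 2
    n_points = config.grid_points_per_square
    return pd.DataFrame({
        "plot_id": [f"{sid}_{j:03d}" for j in range(gx.size)],
        "square_id": sid,
        "x": gx,
        "y": gy,
        "on_agricultural_land": on_land,
        "pi2_given_s1": config.plot_area * n_points / denom,
        "pi2_structure_given_s1": config.structure_area * n_points / denom,
    })


# ---------------------------------------------------------------------------
# first stage: stratified, doubly balanced square sample
# ---------------------------------------------------------------------------

def first_stage_probabilities(frame: pd.DataFrame, I,
                              config: DesignConfig):
    """Capped conditional probabilities ``pi_1|S0`` per rotation group.

    Within each rotation group ``R_t``, ``pi_1|S0 = min(C_t * n_i * I_i, 1)``
    with the group constant ``C_t`` solved so the group sum equals ``m/r``.
    Returns ``(pi1_s0, capped, C_t)`` with the capping flags and the
    per-group constants.
    """
    if isinstance(I, InterestIndex):
        I = I.I
    I = np.asarray(I, dtype=float)
    if np.any(I <= 0):
        raise ValueError("interest index must be strictly positive")
    n_i = frame["n_i"].to_numpy(dtype=float)
    labels = frame["R"].to_numpy()
    groups = list(dict.fromkeys(labels.tolist()))
    target = config.group_size

    pi1_s0 = np.empty(len(frame))
    capped = np.zeros(len(frame), dtype=bool)
    C_t = {}
    for t in groups:
        idx = np.flatnonzero(labels == t)
        if idx.size < target:
            raise ValueError(
                f"rotation group {t!r} has {idx.size} squares, fewer than "
                f"the group sample size {target}")
        cap = solve_capped_inclusion(n_i[idx] * I[idx], target)
        pi1_s0[idx] = cap.values
        capped[idx] = cap.capped
        C_t[t] = cap.constant
    return pi1_s0, capped, C_t


def first_stage_balancing(frame: pd.DataFrame,
                          pi1_s0: np.ndarray) -> np.ndarray:
    """Balancing matrix of the first stage:
    ``(pi, pi*U_g indicators, pi*V_h indicators, n_i, elev_i, 1)``."""
    U_cols = [pi1_s0 * (frame["U"] == g).to_numpy(float)
              for g in sorted(frame["U"].unique())]
    V_cols = [pi1_s0 * (frame["V"] == h).to_numpy(float)
              for h in sorted(frame["V"].unique())]
    return np.column_stack([pi1_s0, *U_cols, *V_cols,
                            frame["n_i"].to_numpy(float),
                            frame["elev"].to_numpy(float),
                            np.ones(len(frame))])


def first_stage_sample(frame: pd.DataFrame, I, config: DesignConfig,
                       rng_seed=None) -> tuple[SampleDraw, pd.DataFrame]:
    """Select the first-stage sample of squares.

    Conditional probabilities from :func:`first_stage_probabilities`;
    selection by stratified, doubly balanced spatial sampling with the
    balancing vector of :func:`first_stage_balancing` and the square-centre
    coordinates, so each rotation group realizes exactly ``m/r`` squares
    and the whole sample exactly ``m``.

    Returns the draw and a probability table (``pi0``, ``pi1_given_s0``,
    ``pi1``, group constant ``C_t``, capping flag) indexed like ``frame``.
    """
    pi1_s0, capped, C_t = first_stage_probabilities(frame, I, config)
    labels = frame["R"].to_numpy()
    X = first_stage_balancing(frame, pi1_s0)
    coords = frame[["x", "y"]].to_numpy(float)
    draw = stratified_balanced_sample(pi1_s0, X, coords, labels, rng_seed)

    pi0 = initial_probabilities(frame).to_numpy()
    probs = pd.DataFrame({
        "square_id": frame["square_id"].to_numpy(),
        "pi0": pi0,
        "pi1_given_s0": pi1_s0,
        "pi1": pi0 * pi1_s0,
        "C_t": [C_t[t] for t in labels],
        "capped": capped,
        "R": labels,
    }, index=frame.index)
    return draw, probs


# ---------------------------------------------------------------------------
# third stage: doubly balanced vegetation subsample
# ---------------------------------------------------------------------------

def third_stage_sample(plots: pd.DataFrame, J=None,
                       config: DesignConfig | None = None,
                       rng_seed=None) -> tuple[SampleDraw, pd.DataFrame]:
    """Select the vegetation subsample within each square.

    Per square, the quota is ``v_i = min(v_0, n_i)`` (a square with very few
    habitat plots is taken exhaustively); the conditional probabilities are
    ``pi_3|S2 = min(C_3.i * J_j, 1)`` with the square constant solved so
    they sum to ``v_i``.  Selection is doubly balanced on
    ``(pi_3, 1, elev, slope, topo, east, north)`` with spatial spreading on
    the plot coordinates, so every realized draw has exactly ``v_i`` plots
    in each square.

    ``plots`` must contain ``square_id``, ``x``, ``y`` and (unless ``J`` is
    passed separately) a ``J`` column; terrain covariate columns are used
    for balancing when present.  If ``pi1`` and ``pi2_given_s1`` columns are
    present, the total probability ``pi_V`` is attached.
    """
    config = config or DesignConfig()
    plots = plots.reset_index(drop=True)
    if J is None:
        J = plots["J"].to_numpy(float)
    else:
        J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("plot interest index J must be strictly positive")

    rng = np.random.default_rng(rng_seed) \
        if not isinstance(rng_seed, np.random.Generator) else rng_seed
    covar_cols = [c for c in ("elev", "slope", "topo", "east", "north")
                  if c in plots.columns]

    indicator = np.zeros(len(plots), dtype=int)
    pi3 = np.full(len(plots), np.nan)
    C3 = np.full(len(plots), np.nan)
    v_col = np.zeros(len(plots), dtype=int)
    for sid, block in plots.groupby("square_id", sort=False):
        idx = block.index.to_numpy()
        ni = idx.size
        if ni == 0:  # pragma: no cover - groupby never yields empty
            continue
        v_i = min(config.v0, ni)
        v_col[idx] = v_i
        cap = solve_capped_inclusion(J[idx], v_i)
        pi3[idx] = cap.values
        C3[idx] = cap.constant
        if v_i == ni:
            indicator[idx] = 1
            continue
        X = np.column_stack([cap.values, np.ones(ni)]
                            + [block[c].to_numpy(float) for c in covar_cols])
        sub = local_cube(cap.values, X, block[["x", "y"]].to_numpy(float), rng)
        indicator[idx] = sub.indicator

    out = plots.copy()
    out["pi3_given_s2"] = pi3
    out["C3_i"] = C3
    out["v_i"] = v_col
    out["in_s3"] = indicator
    if {"pi1", "pi2_given_s1"} <= set(plots.columns):
        out["pi_V"] = out["pi1"] * out["pi2_given_s1"] * out["pi3_given_s2"]
    seed = None if isinstance(rng_seed, np.random.Generator) else rng_seed
    return SampleDraw(indicator=indicator, algorithm="third_stage_local_cube",
                      seed=seed), out


def self_weighting_diagnostic(probs: pd.DataFrame) -> dict:
    """Dispersion of the total vegetation-plot probabilities ``pi_V``.

    In the idealized configuration — first-stage probabilities strictly
    proportional to ``n_i * I_i`` with no capping, constant ``J``, and the
    full quota ``v_i = v_0`` everywhere — the per-plot factor ``n_i`` in
    ``pi_3|S2 = v_0 / n_i`` cancels the ``n_i`` in ``pi_1``, so ``pi_V`` is
    constant across squares.  Capping and quota adjustments break the exact
    cancellation; this report quantifies the residual dispersion.
    """
    pi_v = probs["pi_V"].to_numpy(float)
    by_square = probs.groupby("square_id")["pi_V"].mean()
    capped_squares: list = []
    for col in ("pi1_given_s0", "pi3_given_s2"):
        if col in probs.columns:
            flag = probs.loc[np.isclose(probs[col], 1.0), "square_id"]
            capped_squares.extend(flag.unique().tolist())

    def _cv(v):
        v = np.asarray(v, dtype=float)
        m = v.mean()
        return float(v.std(ddof=0) / m) if m > 0 else float("nan")

    return {
        "cv_pi_v_plots": _cv(pi_v),
        "cv_pi_v_squares": _cv(by_square.to_numpy()),
        "capped_squares": sorted(set(capped_squares)),
        "n_plots": int(len(probs)),
        "n_squares": int(by_square.size),
    }


# ---------------------------------------------------------------------------
# terrain covariates from an elevation raster
# ---------------------------------------------------------------------------

@dataclass
class DemGrid:
    """Regular elevation raster: ``values[iy, ix]`` at
    ``(x0 + ix*res, y0 + iy*res)``; resolution in metres."""

    values: np.ndarray
    x0: float
    y0: float
    res: float = 25.0
    flat_tol: float = field(default=1e-9)

    def cell_of(self, x, y) -> tuple[int, int]:
        ix = int(round((x - self.x0) / self.res))
        iy = int(round((y - self.y0) / self.res))
        ny, nx = self.values.shape
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise ValueError(f"point ({x}, {y}) outside the elevation raster")
        return iy, ix


def _gradient_at(dem: DemGrid, iy: int, ix: int) -> tuple[float, float]:
    z = dem.values
    ny, nx = z.shape
    x_lo, x_hi = max(ix - 1, 0), min(ix + 1, nx - 1)
    y_lo, y_hi = max(iy - 1, 0), min(iy + 1, ny - 1)
    gx = (z[iy, x_hi] - z[iy, x_lo]) / ((x_hi - x_lo) * dem.res)
    gy = (z[y_hi, ix] - z[y_lo, ix]) / ((y_hi - y_lo) * dem.res)
    return float(gx), float(gy)


def derive_plot_covariates(dem: DemGrid, plots: pd.DataFrame,
                           config: DesignConfig | None = None,
                           topo_radius: float = 100.0) -> pd.DataFrame:
    """Attach terrain covariates (elev, slope, topo, east, north) to plots.

    * ``elev`` — raster elevation at the plot cell (m a.s.l.).
    * ``slope`` — slope angle in degrees from central differences.
    * ``east`` / ``north`` — orientation of the plot as cosine and sine of
      the aspect in degrees (aspect measured clockwise from north, pointing
      downslope).  Flat cells get 0/0 and ``aspect_undefined=True``.  Set
      ``config.gis_aspect_convention`` to use east=sin / north=cos instead.
    * ``topo`` — relative topographic position: elevation minus the mean
      elevation within ``topo_radius``; rescaled to an 8-level ordinal
      ladder (8 = exposed ridge ... 1 = distinct ditch) by equal-frequency
      binning over the plots supplied.
    """
    config = config or DesignConfig()
    out = plots.copy()
    n = len(plots)
    elev = np.empty(n)
    slope = np.empty(n)
    east = np.zeros(n)
    north = np.zeros(n)
    flat = np.zeros(n, dtype=bool)
    rel = np.empty(n)

    ny, nx = dem.values.shape
    xs = dem.x0 + dem.res * np.arange(nx)
    ys = dem.y0 + dem.res * np.arange(ny)
    XX, YY = np.meshgrid(xs, ys)

    for k, (x, y) in enumerate(zip(plots["x"].to_numpy(),
                                   plots["y"].to_numpy())):
        iy, ix = dem.cell_of(x, y)
        elev[k] = dem.values[iy, ix]
        gx, gy = _gradient_at(dem, iy, ix)
        grad = math.hypot(gx, gy)
        slope[k] = math.degrees(math.atan(grad))
        if grad <= dem.flat_tol:
            flat[k] = True
        else:
            # compass aspect of the downslope direction (0 = N, 90 = E)
            aspect = math.degrees(math.atan2(-gx, -gy)) % 360.0
            a = math.radians(aspect)
            if config.gis_aspect_convention:
                east[k], north[k] = math.sin(a), math.cos(a)
            else:
                east[k], north[k] = math.cos(a), math.sin(a)
        near = (XX - x) ** 2 + (YY - y) ** 2 <= topo_radius ** 2
        rel[k] = elev[k] - dem.values[near].mean()

    if np.ptp(rel) <= 1e-12:
        topo = np.full(n, 4, dtype=int)
    else:
        edges = np.quantile(rel, np.linspace(0, 1, 9)[1:-1])
        topo = 1 + np.searchsorted(edges, rel, side="left")

    out["elev"] = elev
    out["slope"] = slope
    out["east"] = east
    out["north"] = north
    out["aspect_undefined"] = flat
    out["topo"] = topo.astype(int)
    out["topo_relative_m"] = rel
    return out


def plot_polygon_coverage(plots: pd.DataFrame, polygon,
                          plot_area: float = 10.0) -> np.ndarray:
    """Proportion ``w_j`` of each circular plot's area inside a polygon."""
    from shapely.geometry import Point
    radius = math.sqrt(plot_area / math.pi)
    w = np.empty(len(plots))
    for k, (x, y) in enumerate(zip(plots["x"].to_numpy(),
                                   plots["y"].to_numpy())):
        circle = Point(x, y).buffer(radius, quad_segs=64)
        w[k] = circle.intersection(polygon).area / circle.area
    return np.clip(w, 0.0, 1.0)
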