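"""Synthetic study populations and Monte Carlo design evaluation.

The toolkit never requires real survey data: this module generates

* square frames with the structure of a national monitoring frame
  (:func:`synthetic_frame`, :func:`synthetic_raw_frame`) — a systematic
  lattice of squares with two cross-cutting 5-class stratifications
  (production zones correlated with elevation, biogeographic regions
  correlated with longitude), variable accessible agricultural area
  ``0 < A_i <= 0.9025`` km², grid-density classes, and rotation groups
  interleaved systematically across the lattice;
* plot frames within a square (:func:`synthetic_plot_frame`) with a
  contiguous accessible-land mask, terrain covariates from a synthetic
  elevation surface, and a positive plot-interest index ``J_j``;
* over-dispersed habitat abundances per square via a *double Poisson*
  model (:func:`double_poisson_population`): the count of habitat ``l`` in
  square ``i`` is ``n_il = 1/2 * Poisson(2) * Poisson(p_lg * n_i)``, with
  ``p_lg`` the expected proportion of the habitat in the square's stratum,
  so ``E[n_il] = p_lg * n_i`` while the product of Poissons adds
  considerable between-square variation;
* Monte Carlo comparisons of first-stage designs
  (:func:`run_design_comparison`): per-habitat coefficients of variation of
  the estimated national area shares across repeated draws, for stratified
  doubly balanced sampling versus pure unequal-probability sampling;
* a cost model (:func:`cost_neutral_scaling`) that trades the number of
  squares against the affordable number of plots per square at equal total
  cost, for clustering studies.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import calibrate_interest_index, stratum_targets
from .design import (DemGrid, DesignConfig, derive_plot_covariates,
                     first_stage_balancing, first_stage_probabilities)
from .sampling import random_pivotal, stratified_balanced_sample

__all__ = [
    "HabitatModelSpec",
    "MonteCarloResult",
    "CostModel",
    "synthetic_frame",
    "synthetic_raw_frame",
    "generate_habitat_spec",
    "double_poisson_population",
    "run_design_comparison",
    "cost_neutral_scaling",
    "synthetic_plot_frame",
    "calibrated_index_for_frame",
]

#: surveyed area of one square (km²), 950 m x 950 m
SQUARE_AREA_KM2 = 0.9025


# ---------------------------------------------------------------------------
# synthetic square frames
# ---------------------------------------------------------------------------

def synthetic_frame(n_squares: int = 455, strata_counts=(5, 5),
                    seed=None) -> pd.DataFrame:
    """Generate a synthetic national square frame.

    Squares sit on a systematic 12 km x 8 km lattice with a small jitter.
    Elevation rises smoothly from south to north with local noise; the
    first stratification ``U`` (production zones) follows elevation
    quantiles, the second ``V`` (biogeographic regions) follows longitude
    bands, so the two stratifications cross-cut.  The accessible
    agricultural area ``A_i`` is Beta-distributed on (0, 0.9025] km² and
    shrinks with elevation; ``n_i = round(361 * A_i / 0.9025)`` (at least
    1).  The two easternmost regions carry the dense grid (one square per
    48 km² instead of 96 km²).  Rotation groups 1..5 interleave
    systematically across the lattice.
    """
    nU, nV = strata_counts
    if n_squares < max(nU, nV):
        raise ValueError("need at least as many squares as strata")
    rng = np.random.default_rng(seed)

    ncol = int(np.ceil(np.sqrt(n_squares * 1.5)))
    nrow = int(np.ceil(n_squares / ncol))
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cols, rows = cols.ravel()[:n_squares], rows.ravel()[:n_squares]
    x = cols * 12_000.0 + rng.uniform(-500, 500, n_squares)
    y = rows * 8_000.0 + rng.uniform(-500, 500, n_squares)

    y_span = max(y.max() - y.min(), 1.0)
    elev = (420.0 + 1900.0 * (y - y.min()) / y_span
            + rng.normal(0.0, 180.0, n_squares))
    elev = np.clip(elev, 200.0, 2800.0)

    U = _quantile_labels(elev, nU, "U")
    V = _quantile_labels(x + rng.normal(0, 1e-6, n_squares), nV, "V")
    dense_regions = {f"V{nV - 1}", f"V{nV}"}
    density = np.where(np.isin(V, list(dense_regions)), "dense", "regular")

    # accessible agricultural area: high at low elevation, small on summits
    base = rng.beta(2.0, 1.3, n_squares)
    elev_factor = 1.0 - 0.55 * (elev - elev.min()) / max(np.ptp(elev), 1.0)
    A = np.clip(base * elev_factor, 0.02, 1.0) * SQUARE_AREA_KM2
    n_i = np.maximum(1, np.round(361.0 * A / SQUARE_AREA_KM2)).astype(int)

    order = np.lexsort((cols, rows))
    R = np.empty(n_squares, dtype=int)
    R[order] = 1 + (np.arange(n_squares) + int(rng.integers(5))) % 5

    return pd.DataFrame({
        "square_id": [f"sq{k:04d}" for k in range(n_squares)],
        "x": x, "y": y,
        "density_class": density,
        "A_i": A,
        "n_i": n_i,
        "elev": elev,
        "U": U, "V": V,
        "R": R,
    })


def _quantile_labels(values: np.ndarray, k: int, prefix: str) -> np.ndarray:
    ranks = np.argsort(np.argsort(values))
    bins = np.minimum((ranks * k) // len(values), k - 1)
    return np.array([f"{prefix}{b + 1}" for b in bins])


def synthetic_raw_frame(seed=None, n_raw: int = 509, n_inaccessible: int = 35,
                        n_no_agriculture: int = 19):
    """A raw frame with exclusion flags, before frame filtering.

    Emulates the situation where the initial systematic grid contains
    squares that are entirely glacier/lake/inaccessible, plus squares
    without any accessible agricultural land; the retained frame has
    ``n_raw - n_inaccessible - n_no_agriculture`` squares.  Returns
    ``(raw_frame, flags)`` with ``flags`` suitable for
    :func:`allema.design.frame_filter`.
    """
    rng = np.random.default_rng(seed)
    frame = synthetic_frame(n_raw, seed=rng)
    # exclusions concentrate at high elevation
    order = np.argsort(-frame["elev"].to_numpy()
                       + rng.normal(0, 150.0, n_raw))
    inaccessible = np.zeros(n_raw, dtype=bool)
    inaccessible[order[:n_inaccessible]] = True
    no_agri = np.zeros(n_raw, dtype=bool)
    no_agri[order[n_inaccessible:n_inaccessible + n_no_agriculture]] = True
    frame.loc[inaccessible | no_agri, ["A_i"]] = 0.0
    frame.loc[inaccessible | no_agri, ["n_i"]] = 0
    flags = {"fully_inaccessible": inaccessible,
             "no_agricultural_land": no_agri}
    return frame, flags


# ---------------------------------------------------------------------------
# synthetic plots within one square
# ---------------------------------------------------------------------------

def synthetic_plot_frame(square, n_i: int, config: DesignConfig | None = None,
                         seed=None) -> pd.DataFrame:
    """Plot table for one square: grid, contiguous land mask, covariates, J.

    The ``n_i`` accessible plots form a contiguous patch (the cells nearest
    to a random interior point), terrain covariates come from a synthetic
    inclined-and-undulating elevation surface at 25-m resolution, and the
    interest index ``J_j`` is log-normal (most plots common habitat, a few
    of high interest).
    """
    from .design import build_plot_grid

    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    grid = build_plot_grid(square, None, config)
    n_pts = len(grid)
    n_i = int(min(max(n_i, 0), n_pts))

    cx, cy = float(square["x"]), float(square["y"])
    seedpt = np.array([cx, cy]) + rng.uniform(-300, 300, 2)
    d2 = (grid["x"] - seedpt[0]) ** 2 + (grid["y"] - seedpt[1]) ** 2
    on_land = np.zeros(n_pts, dtype=bool)
    on_land[np.argsort(d2.to_numpy())[:n_i]] = True
    grid["on_agricultural_land"] = on_land

    plots = grid.loc[on_land].reset_index(drop=True)
    if plots.empty:
        return plots

    # synthetic 25-m DEM over the square (plus margin for neighbourhoods)
    half = config.side / 2 + 150.0
    res = 25.0
    k = int(2 * half / res) + 1
    xs = cx - half + res * np.arange(k)
    ys = cy - half + res * np.arange(k)
    XX, YY = np.meshgrid(xs, ys)
    base = float(square.get("elev", 800.0)) if hasattr(square, "get") else 800.0
    tilt = rng.uniform(-0.25, 0.25, 2)
    wave = rng.uniform(250, 600)
    dem_z = (base + tilt[0] * (XX - cx) + tilt[1] * (YY - cy)
             + 12.0 * np.sin(2 * np.pi * (XX - cx) / wave)
             * np.cos(2 * np.pi * (YY - cy) / wave))
    dem = DemGrid(values=dem_z, x0=xs[0], y0=ys[0], res=res)
    plots = derive_plot_covariates(dem, plots, config)
    plots["J"] = np.clip(rng.lognormal(0.0, 0.6, len(plots)), 0.2, 6.0)
    return plots


# ---------------------------------------------------------------------------
# double Poisson habitat model
# ---------------------------------------------------------------------------

@dataclass
class HabitatModelSpec:
    """Expected habitat proportions per stratum and class aggregation.

    ``p`` is an (L habitats x G strata) matrix of expected proportions;
    ``class_map`` maps each habitat to one of the broader habitat classes;
    ``stratum_labels`` names the columns of ``p`` (matching the frame's
    ``U`` labels).
    """

    p: np.ndarray
    class_map: np.ndarray
    stratum_labels: list
    habitat_names: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.class_map = np.asarray(self.class_map)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("expected proportions p must be in [0, 1]")
        if self.class_map.shape[0] != self.p.shape[0]:
            raise ValueError("class_map must assign every habitat")
        if not self.habitat_names:
            self.habitat_names = [f"h{l:02d}" for l in range(self.p.shape[0])]

    @property
    def n_habitats(self) -> int:
        return self.p.shape[0]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.class_map))


def generate_habitat_spec(n_habitats: int = 67, n_classes: int = 17,
                          stratum_labels=("U1", "U2", "U3", "U4", "U5"),
                          seed=None) -> HabitatModelSpec:
    """A sparse, stratum-structured expected-proportion matrix.

    Each habitat is concentrated in one or two strata (habitats are
    unevenly distributed between production zones); habitat frequencies
    decay so that a few habitats are common and most are rare; per-stratum
    expected proportions are rescaled to sum to at most 0.95.
    """
    rng = np.random.default_rng(seed)
    G = len(stratum_labels)
    # decaying base frequency: a few common habitats, a long rare tail
    base = 0.55 * (np.arange(1, n_habitats + 1) ** -0.9)
    p = np.zeros((n_habitats, G))
    for l in range(n_habitats):
        k = 1 + int(rng.random() < 0.35)  # 1 or 2 host strata
        hosts = rng.choice(G, size=k, replace=False)
        share = rng.dirichlet(np.ones(k))
        p[l, hosts] = base[l] * share * rng.uniform(0.6, 1.4)
    col = p.sum(axis=0)
    over = col > 0.95
    if over.any():
        p[:, over] *= 0.95 / col[over]
    class_map = (np.arange(n_habitats) * n_classes) // n_habitats
    return HabitatModelSpec(p=p, class_map=class_map,
                            stratum_labels=list(stratum_labels), seed=seed)


def double_poisson_population(frame: pd.DataFrame,
                              spec: HabitatModelSpec,
                              seed=None) -> pd.DataFrame:
    """Draw per-square habitat abundances from the double Poisson model.

    ``n_il = 1/2 * Poisson(2) * Poisson(p_lg * n_i)`` independently per
    square and habitat, where ``g`` is the square's ``U`` stratum; the
    halving is applied after the integer draws, so values are multiples of
    one half and the square total varies randomly around ``n_i``.
    Returns a squares x habitats DataFrame.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g_index = np.array([spec.stratum_labels.index(u) for u in frame["U"]])
    n_i = frame["n_i"].to_numpy(float)
    lam = spec.p[:, g_index].T * n_i[:, None]          # (squares, habitats)
    counts = 0.5 * rng.poisson(2.0, size=lam.shape) * rng.poisson(lam)
    return pd.DataFrame(counts, index=frame["square_id"].to_numpy(),
                        columns=spec.habitat_names)


# ---------------------------------------------------------------------------
# Monte Carlo design comparison
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    """Per-target accuracy of a design across repeated sample draws."""

    design: str
    draws: int
    cv_habitat: pd.Series          # CV (%) of each habitat-type share
    cv_class: pd.Series            # CV (%) of each aggregated-class share
    estimates: pd.DataFrame        # per-draw habitat-share estimates
    sampling_rates: pd.DataFrame   # per-draw realized share per U stratum

    def __post_init__(self):
        if self.draws < 2:
            raise ValueError("at least 2 draws are required")


def calibrated_index_for_frame(frame: pd.DataFrame, config: DesignConfig):
    """Calibrate the square-level index of interest for a frame."""
    A = frame["A_i"].to_numpy(float)
    d = A / A.sum()
    # stratum areas in first-appearance order, matching the membership
    # matrix built inside the calibration solver
    orderU = list(dict.fromkeys(frame["U"].tolist()))
    orderV = list(dict.fromkeys(frame["V"].tolist()))
    areas_U = np.array([A[(frame["U"] == g).to_numpy()].sum() for g in orderU])
    areas_V = np.array([A[(frame["V"] == h).to_numpy()].sum() for h in orderV])
    targets = stratum_targets(areas_U, areas_V, config.alpha)
    return calibrate_interest_index(
        d, frame["U"].to_numpy(), frame["V"].to_numpy(),
        (targets.q, targets.p), bounds=config.bounds)


def run_design_comparison(frame: pd.DataFrame, population: pd.DataFrame,
                          designs=("balanced", "ups"), draws: int = 300,
                          seed=None, config: DesignConfig | None = None,
                          class_map=None) -> dict[str, MonteCarloResult]:
    """Monte Carlo accuracy of first-stage designs for habitat shares.

    For each design and draw, a first-stage square sample is selected with
    the *same* conditional probabilities ``pi_1|S0``; the national area
    share of every habitat is estimated by the Hájek ratio
    ``sum_S(n_il / pi) / sum_S(n_i / pi)``; the coefficient of variation
    (%) of each share across draws measures the design's accuracy.
    Supported designs:

    * ``"balanced"`` — stratified, doubly balanced spatial sampling on the
      first-stage balancing vector (the operational design);
    * ``"ups"`` — pure unequal-probability sampling (random pivotal, fixed
      total size, no balancing, no spreading);
    * ``"census"`` — every square selected (zero-variance reference).
    """
    if draws < 2:
        raise ValueError("at least 2 draws are required")
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)

    index = calibrated_index_for_frame(frame, config)
    pi1_s0, _, _ = first_stage_probabilities(frame, index, config)
    X = first_stage_balancing(frame, pi1_s0)
    coords = frame[["x", "y"]].to_numpy(float)
    labels = frame["R"].to_numpy()

    counts = population.to_numpy(float)          # squares x habitats
    n_i = frame["n_i"].to_numpy(float)
    u_strata = sorted(frame["U"].unique())
    u_arr = frame["U"].to_numpy()

    results: dict[str, MonteCarloResult] = {}
    for design in designs:
        est = np.empty((draws, counts.shape[1]))
        rates = np.empty((draws, len(u_strata)))
        for b in range(draws):
            if design == "balanced":
                ind = stratified_balanced_sample(pi1_s0, X, coords, labels,
                                                 rng).indicator
            elif design == "ups":
                ind = random_pivotal(pi1_s0, rng).indicator
            elif design == "census":
                ind = np.ones(len(frame), dtype=int)
            else:
                raise ValueError(f"unknown design {design!r}")
            sel = ind == 1
            pi_sel = pi1_s0[sel] if design != "census" else np.ones(sel.sum())
            w = 1.0 / pi_sel
            denom = np.sum(w * n_i[sel])
            est[b] = (w[:, None] * counts[sel]).sum(axis=0) / denom
            n_sel = max(int(sel.sum()), 1)
            rates[b] = [np.sum(sel & (u_arr == g)) / n_sel for g in u_strata]
        est_df = pd.DataFrame(est, columns=population.columns)
        cv_hab = _cv_percent(est_df)
        if class_map is not None:
            cls = pd.Series(np.asarray(class_map),
                            index=population.columns)
            cls_est = est_df.T.groupby(cls).sum().T
            cv_cls = _cv_percent(cls_est)
        else:
            cv_cls = cv_hab
        results[design] = MonteCarloResult(
            design=design, draws=draws, cv_habitat=cv_hab, cv_class=cv_cls,
            estimates=est_df,
            sampling_rates=pd.DataFrame(rates, columns=u_strata))
    return results


def _cv_percent(df: pd.DataFrame) -> pd.Series:
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * sd / mean
    return cv.where(mean > 0, 0.0)


# ---------------------------------------------------------------------------
# cost-neutral clustering scenarios
# ---------------------------------------------------------------------------

@dataclass
class CostModel:
    """Fixed cost per plot record plus travel terms, with a total budget.

    ``travel_to_square`` is paid once per selected square,
    ``travel_between_plots`` once per surveyed plot (in the same cost units
    as ``record_cost``); ``budget`` is the total affordable cost.
    """

    record_cost: float
    travel_to_square: float
    travel_between_plots: float
    budget: float

    def __post_init__(self):
        for name in ("record_cost", "travel_to_square",
                     "travel_between_plots", "budget"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.record_cost + self.travel_between_plots <= 0:
            raise ValueError("per-plot cost must be positive")

    def total_cost(self, m: int, total_plots: float) -> float:
        return (m * self.travel_to_square
                + total_plots * (self.record_cost + self.travel_between_plots))


def cost_neutral_scaling(m_squares: int, cost_model: CostModel,
                         n_i=None):
    """Affordable plot effort at a given square sample size.

    Solves the budget identity
    ``budget = m * travel_to + T * (record + travel_between)`` for the total
    affordable number of plots ``T``.  With ``n_i`` given, the per-square
    counts are rescaled proportionally (as floats) so their total is ``T``
    and the budget holds exactly; otherwise ``T`` itself is returned.
    Increasing ``m`` with a positive travel-to cost strictly decreases the
    plots per square.
    """
    if m_squares <= 0:
        raise ValueError("m_squares must be positive")
    per_plot = cost_model.record_cost + cost_model.travel_between_plots
    T = (cost_model.budget - m_squares * cost_model.travel_to_square) / per_plot
    if T <= 0:
        raise ValueError(
            f"budget infeasible: travel to {m_squares} squares already "
            f"exceeds the total budget")
    if n_i is None:
        return T
    n_i = np.asarray(n_i, dtype=float)
    if np.any(n_i < 0) or n_i.sum() <= 0:
        raise ValueError("n_i must be non-negative with a positive total")
    return n_i * (T / n_i.sum())
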