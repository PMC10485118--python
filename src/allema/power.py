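"""Change-detection power analysis for permanent (re-measured) plots.

For a monitoring programme that revisits the same squares, the minimum
number of squares needed to detect a relative change ``delta`` in a
current proportion ``Ybar`` at significance ``alpha`` and power
``1 - beta`` is

    m_min = ceil( s^2 (2 - 2 rho) (Z_{1-alpha/2} + Z_{1-beta})^2
                  / (delta * Ybar)^2 ),

where ``s^2`` is the between-square variance of square-level proportions,
``rho`` the correlation between paired square proportions at the two
occasions, and ``Z_p`` the standard-normal quantile.  ``2 - 2 rho`` is the
variance deflation from re-measuring the same squares: perfectly correlated
revisits (``rho = 1``) need no replication at all.

The default ``mode="squared"`` squares the sum of the two Z-quantiles, the
form that makes the achieved power of the paired z-test equal its nominal
target; ``mode="as_printed"`` leaves the Z-term unsquared for literal
reproduction of designs computed that way (the two coincide only when the
Z-term equals 1).

``s^2`` is recovered from the design-based variance of the global mean
square proportion as ``s2 = varhat * m``, and the paired correlation can be
estimated with survey weights (:func:`weighted_paired_correlation`,
defaulting to weights ``1 / pi_1`` per square).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "minimum_squares",
    "s2_from_design_variance",
    "weighted_paired_correlation",
    "detectability_table",
    "simulate_paired_power",
]


@dataclass
class PowerSpec:
    """Parameters of a change-detection analysis for one target quantity."""

    ybar: float          # current proportion (mean) of the target
    s2: float            # between-square variance of square proportions
    rho: float           # correlation of paired square proportions
    delta: float         # relative change to detect
    alpha: float = 0.32  # two-sided significance level
    beta: float = 0.5    # 1 - power

    def __post_init__(self):
        if self.ybar <= 0:
            raise ValueError("ybar must be positive")
        if self.s2 < 0:
            raise ValueError("s2 must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must be in (0, 1)")


def minimum_squares(spec: PowerSpec, mode: str = "squared") -> int:
    """Minimum number of squares to detect the specified change.

    ``mode="squared"`` squares the Z-quantile sum (the standard paired
    sample-size formula); ``mode="as_printed"`` uses the unsquared sum.
    """
    if mode not in ("squared", "as_printed"):
        raise ValueError("mode must be 'squared' or 'as_printed'")
    z = (stats.norm.ppf(1.0 - spec.alpha / 2.0)
         + stats.norm.ppf(1.0 - spec.beta))
    zterm = z ** 2 if mode == "squared" else z
    num = spec.s2 * (2.0 - 2.0 * spec.rho) * zterm
    den = (spec.delta * spec.ybar) ** 2
    if den == 0:
        raise ValueError("delta * ybar must be non-zero")
    return int(math.ceil(num / den))


def s2_from_design_variance(varhat: float, m: int) -> float:
    """Between-square variance implied by a design-based variance estimate.

    If ``varhat`` estimates the variance of the global mean square
    proportion from ``m`` squares, the between-square variance is
    ``s2 = varhat * m``.
    """
    if varhat < 0:
        raise ValueError("varhat must be non-negative")
    if m < 2:
        raise ValueError("m must be at least 2")
    return float(varhat) * m


def weighted_paired_correlation(x_t1, x_t2, weights=None) -> float:
    """Survey-weighted Pearson correlation of paired square proportions.

    Weights default to equal; in design-based use pass ``1 / pi_1`` per
    square.  Raises on zero variance in either occasion.
    """
    x1 = np.asarray(x_t1, dtype=float)
    x2 = np.asarray(x_t2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 pairs")
    w = np.ones_like(x1) if weights is None else np.asarray(weights, float)
    if w.shape != x1.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per pair")
    w = w / w.sum()
    m1 = np.sum(w * x1)
    m2 = np.sum(w * x2)
    v1 = np.sum(w * (x1 - m1) ** 2)
    v2 = np.sum(w * (x2 - m2) ** 2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("correlation undefined: zero variance in an occasion")
    cov = np.sum(w * (x1 - m1) * (x2 - m2))
    return float(np.clip(cov / math.sqrt(v1 * v2), -1.0, 1.0))


def detectability_table(specs: dict, m_available: int,
                        delta_grid=(0.1, 0.2, 0.3),
                        rho_grid=(0.8, 0.9, 0.95),
                        power_grid=(0.5, 0.7, 0.9),
                        alpha: float = 0.32,
                        mode: str = "squared") -> pd.DataFrame:
    """Minimum sample sizes over a (target x delta x rho x power) grid.

    ``specs`` maps a target name (e.g. a habitat type) to a mapping with
    keys ``ybar`` and ``s2``.  Each row reports ``m_min`` and whether the
    change is detectable with the available number of squares.
    """
    rows = []
    for name, sp in specs.items():
        for delta, rho, pw in product(delta_grid, rho_grid, power_grid):
            spec = PowerSpec(ybar=sp["ybar"], s2=sp["s2"], rho=rho,
                             delta=delta, alpha=alpha, beta=1.0 - pw)
            m_min = minimum_squares(spec, mode=mode)
            rows.append({"target": name, "delta": delta, "rho": rho,
                         "power": pw, "m_min": m_min,
                         "detectable": m_min <= m_available})
    return pd.DataFrame(rows)


def simulate_paired_power(spec: PowerSpec, m: int, replicates: int = 2000,
                          seed=None) -> float:
    """Empirical power of the paired z-test at sample size ``m``.

    Simulates paired square proportions at two occasions as bivariate
    normal with means ``(ybar, ybar * (1 + delta))``, common variance
    ``s2`` and correlation ``rho``; tests the mean paired difference
    against zero with a two-sided z-test at level ``alpha`` (variance
    estimated from the sample differences) and returns the rejection rate.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(spec.s2)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    # difference d_i has mean delta*ybar and variance s2*(2-2rho)
    mean_d = spec.delta * spec.ybar
    sd_d = sd * math.sqrt(max(2.0 - 2.0 * spec.rho, 0.0))
    d = rng.normal(mean_d, sd_d, size=(replicates, m))
    dbar = d.mean(axis=1)
    se = d.std(axis=1, ddof=1) / math.sqrt(m)
    reject = np.abs(dbar / se) > z_crit
    return float(reject.mean())
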