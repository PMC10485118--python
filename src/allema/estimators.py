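"""Design-based estimation for multi-stage plot samples.

Point estimation of plot-level means and area shares uses the Hájek
(ratio-of-weighted-sums) estimator

    Ybar_hat = (sum_j y_j / pi_j) / (sum_j 1 / pi_j),

with ``pi_j`` the *total* inclusion probability of plot ``j`` under the
relevant sample (habitat, vegetation, or polygon-targeted).  Applied to 0/1
indicators it estimates the area share of a category; shares over an
exhaustive category set sum to one exactly because the denominator is
shared.

Variance estimation collapses the multi-stage design into two conceptual
stages — squares, then plots — and assumes the squares were drawn with
replacement with drawing probabilities ``p_i = pi_1,i / m`` (the
Hansen-Hurwitz scheme).  The estimator of the variance of a plot mean is
then a single between-square sum of squares:

    var_hat = (1 / N_hat^2) * (1 / (m (m-1))) * sum_i (Yhat_i / p_i - Yhat)^2

with ``Yhat_i`` the estimated within-square total, ``Yhat = sum_i
Yhat_i / pi_1,i`` and ``N_hat`` the estimated plot-count equivalent of the
target area.  The with-replacement assumption ignores the finite-population
correction and the gains from balancing, so the estimator is slightly
conservative; the overestimation factor from the missing correction alone
is ``(M0 - 1)/(M0 - m)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EstimateResult",
    "hajek_mean",
    "square_totals",
    "hansen_hurwitz_variance",
    "fpc_overestimation_factor",
    "nhat",
    "estimate_mean",
]

_SAMPLE_KINDS = ("habitat", "vegetation", "efa")


@dataclass
class EstimateResult:
    """A design-based estimate with its auditable variance decomposition."""

    estimate: float
    variance: float
    n_hat: float
    m: int
    square_totals: pd.Series
    drawing_probs: pd.Series

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def hajek_mean(y, total_pi) -> float:
    """Hájek estimator of a plot-level mean (or area share for 0/1 y)."""
    y = np.asarray(y, dtype=float)
    pi = np.asarray(total_pi, dtype=float)
    if y.size == 0:
        raise ValueError("empty sample")
    if y.shape != pi.shape:
        raise ValueError("y and pi have different lengths")
    if np.any(pi <= 0):
        raise ValueError("all inclusion probabilities must be positive")
    w = 1.0 / pi
    return float(np.sum(w * y) / np.sum(w))


def square_totals(y, plots: pd.DataFrame, sample_kind: str = "habitat",
                  w=None) -> pd.Series:
    """Estimated within-square totals ``Yhat_i``.

    ``plots`` carries the sampled plots with their ``square_id`` and the
    stage-conditional probabilities: ``pi2_given_s1`` always, plus
    ``pi3_given_s2`` for the vegetation sample; for polygon-targeted
    (``efa``) samples, columns ``pi2e_given_s1`` and ``pi3e_given_s2``
    and area-mismatch weights ``w`` (proportion of the plot inside the
    polygon) are used.  Each ``Yhat_i`` divides by the probability of the
    plot *conditional on the square being selected*, so squares enter the
    between-square variance with their own totals; selected squares with no
    sampled plots contribute ``Yhat_i = 0``.
    """
    if sample_kind not in _SAMPLE_KINDS:
        raise ValueError(f"sample_kind must be one of {_SAMPLE_KINDS}")
    y = np.asarray(y, dtype=float)
    if sample_kind == "habitat":
        cond_pi = plots["pi2_given_s1"].to_numpy(float)
    elif sample_kind == "vegetation":
        cond_pi = (plots["pi2_given_s1"].to_numpy(float)
                   * plots["pi3_given_s2"].to_numpy(float))
    else:
        cond_pi = (plots["pi2e_given_s1"].to_numpy(float)
                   * plots["pi3e_given_s2"].to_numpy(float))
        if w is None:
            raise ValueError("efa sample totals require the area-mismatch "
                             "weights w_j")
    if np.any(cond_pi <= 0):
        raise ValueError("conditional inclusion probabilities must be > 0")
    contrib = y / cond_pi
    if w is not None:
        contrib = contrib * np.asarray(w, dtype=float)
    return (pd.Series(contrib, index=plots["square_id"].to_numpy())
            .groupby(level=0).sum())


def hansen_hurwitz_variance(square_totals_, pi_1, m: int,
                            n_hat: float) -> float:
    """Simplified two-stage variance of a plot mean.

    Parameters
    ----------
    square_totals_ : array-like
        ``Yhat_i`` for every first-stage square (zeros for squares without
        sampled plots).
    pi_1 : array-like
        Total first-stage inclusion probability of those squares.
    m : int
        First-stage sample size; the drawing probabilities are
        ``p_i = pi_1,i / m``.
    n_hat : float
        Estimated plot-count equivalent of the target area.
    """
    if m < 2:
        raise ValueError("the variance estimator requires m >= 2")
    Yi = np.asarray(square_totals_, dtype=float)
    pi1 = np.asarray(pi_1, dtype=float)
    if np.any(pi1 <= 0):
        raise ValueError("first-stage probabilities must be positive")
    p = pi1 / m
    Yhat = float(np.sum(Yi / pi1))
    ss = np.sum((Yi / p - Yhat) ** 2)
    return float(ss / (n_hat ** 2 * m * (m - 1)))


def fpc_overestimation_factor(M0: float, m: int) -> float:
    """Variance overestimation factor from ignoring the finite population.

    The with-replacement assumption inflates the variance by roughly
    ``(M0 - 1)/(M0 - m)``, where ``M0`` is the frame-equivalent number of
    squares in the whole target area.
    """
    if M0 <= m:
        raise ValueError("M0 must exceed the sample size m")
    return (M0 - 1.0) / (M0 - m)


def nhat(total_pi, sample_kind: str = "habitat", w=None) -> float:
    """Estimated number of plots covering the target area.

    ``sum_j 1/pi_j`` over the sampled plots (``sum_j w_j/pi_j`` for
    polygon-targeted samples, where ``w_j`` is the proportion of the plot
    inside the polygon).
    """
    if sample_kind not in _SAMPLE_KINDS:
        raise ValueError(f"sample_kind must be one of {_SAMPLE_KINDS}")
    pi = np.asarray(total_pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("all inclusion probabilities must be positive")
    num = 1.0 / pi if w is None else np.asarray(w, dtype=float) / pi
    if sample_kind == "efa" and w is None:
        raise ValueError("efa N-hat requires the area-mismatch weights w_j")
    return float(np.sum(num))


def estimate_mean(y, plots: pd.DataFrame, squares: pd.DataFrame,
                  sample_kind: str = "habitat", w=None,
                  domain=None) -> EstimateResult:
    """Full plot-mean estimate with its Hansen-Hurwitz variance.

    ``plots`` holds the sampled plots (with stage probabilities and a
    ``square_id``); ``squares`` holds the *selected first-stage squares*
    with columns ``square_id`` and ``pi1``.  ``domain`` optionally restricts
    estimation to a subpopulation by zeroing ``y`` outside it while keeping
    the full denominator structure.
    """
    y = np.asarray(y, dtype=float)
    if domain is not None:
        y = np.where(np.asarray(domain, dtype=bool), y, 0.0)
    total_col = {"habitat": "pi_H", "vegetation": "pi_V",
                 "efa": "pi_HVE"}[sample_kind]
    if total_col in plots.columns:
        total_pi = plots[total_col].to_numpy(float)
    else:
        if "pi1" in plots.columns:
            pi1_plot = plots["pi1"].to_numpy(float)
        else:  # look the square's pi1 up from the selected-squares table
            lut = pd.Series(squares["pi1"].to_numpy(float),
                            index=squares["square_id"].to_numpy())
            pi1_plot = lut.loc[plots["square_id"].to_numpy()].to_numpy()
        if sample_kind == "habitat":
            cond = plots["pi2_given_s1"].to_numpy(float)
        elif sample_kind == "vegetation":
            cond = (plots["pi2_given_s1"].to_numpy(float)
                    * plots["pi3_given_s2"].to_numpy(float))
        else:
            cond = (plots["pi2e_given_s1"].to_numpy(float)
                    * plots["pi3e_given_s2"].to_numpy(float))
        total_pi = pi1_plot * cond

    if w is None:
        point = hajek_mean(y, total_pi)
        n_hat = nhat(total_pi, sample_kind)
    else:
        w = np.asarray(w, dtype=float)
        n_hat = nhat(total_pi, sample_kind, w=w)
        point = float(np.sum(w * y / total_pi) / np.sum(w / total_pi))

    yi = square_totals(y, plots, sample_kind, w=w)
    # selected squares without sampled plots contribute zero totals
    yi = yi.reindex(squares["square_id"].to_numpy(), fill_value=0.0)
    pi1 = pd.Series(squares["pi1"].to_numpy(float),
                    index=squares["square_id"].to_numpy())
    m = len(squares)
    var = hansen_hurwitz_variance(yi.to_numpy(), pi1.to_numpy(), m, n_hat)
    return EstimateResult(estimate=point, variance=var, n_hat=n_hat, m=m,
                          square_totals=yi, drawing_probs=pi1 / m)
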