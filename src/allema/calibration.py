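"""Stratum allocation and calibrated indices of interest.

A multi-stage monitoring design that must serve both stratum-level and
national estimation steers its first-stage unequal-probability selection
through a per-unit *index of interest* ``I_i > 0``.  The index is chosen so
that the area-weighted index totals within the strata of two cross-cutting
stratifications hit prescribed sample-share targets::

    sum_{i in U_g} (A_i / A) I_i = q_g      (first stratification)
    sum_{i in V_h} (A_i / A) I_i = p_h      (second stratification)

The targets ``q_g`` / ``p_h`` come from a power allocation
``q_g ∝ A_{U_g}^alpha``, which interpolates between equal stratum sample
sizes (``alpha = 0``) and proportional-to-size allocation (``alpha = 1``).

The index is found by calibration with the bounded logistic distance
function, which keeps every ``I_i`` inside user-chosen bounds
``(L, U)`` with ``L < 1 < U`` and limits its dispersion.  The solver is a
Newton iteration on the dual variables with damped steps; the raking-ratio
solution (``I_i = exp(z_i . lambda)``) is recovered for bounds ``(0, inf)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StratumTargets",
    "InterestIndex",
    "CalibrationInfeasibleError",
    "power_allocation",
    "stratum_targets",
    "calibrate_interest_index",
]

logger = logging.getLogger(__name__)


class CalibrationInfeasibleError(ValueError):
    """Raised when no bounded index can satisfy the stratum constraints."""


@dataclass
class StratumTargets:
    """Sample-share targets for the two stratifications.

    ``q`` and ``p`` each sum to one; ``alpha`` is the power-allocation
    exponent; the stratum surface areas are kept for provenance.
    """

    q: np.ndarray
    p: np.ndarray
    alpha: float
    areas_U: np.ndarray
    areas_V: np.ndarray


@dataclass
class InterestIndex:
    """A calibrated, bounded, strictly positive per-unit index."""

    I: np.ndarray
    bounds: tuple[float, float]
    residuals: np.ndarray
    converged: bool

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))


def power_allocation(stratum_areas, alpha: float) -> np.ndarray:
    """Stratum sample shares proportional to ``area**alpha``.

    ``alpha = 1`` gives proportional-to-size allocation (favouring the
    overall estimate); ``alpha = 0`` gives equal shares in every stratum;
    intermediate values trade the two objectives off.
    """
    areas = np.asarray(stratum_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("at least one stratum area is required")
    if np.any(areas <= 0) or np.any(~np.isfinite(areas)):
        raise ValueError("stratum areas must be positive and finite")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    w = areas ** alpha
    return w / w.sum()


def stratum_targets(areas_U, areas_V, alpha: float) -> StratumTargets:
    """Power-allocation targets for both stratifications at the same alpha."""
    areas_U = np.asarray(areas_U, dtype=float)
    areas_V = np.asarray(areas_V, dtype=float)
    return StratumTargets(q=power_allocation(areas_U, alpha),
                          p=power_allocation(areas_V, alpha),
                          alpha=float(alpha),
                          areas_U=areas_U, areas_V=areas_V)


# ---------------------------------------------------------------------------
# bounded logistic calibration function
# ---------------------------------------------------------------------------

def _logistic_F(u: np.ndarray, L: float, U: float):
    """Calibration function and derivative; F(0) = 1, F'(0) = 1, L < F < U."""
    if L == 0.0 and np.isinf(U):  # raking limit
        F = np.exp(u)
        return F, F
    a = U - 1.0
    b = 1.0 - L
    A = (U - L) / (a * b)
    E = np.exp(np.clip(A * u, -500, 500))
    denom = a + b * E
    F = (L * a + U * b * E) / denom
    dF = A * a * b * (U - L) * E / denom ** 2
    return F, dF


def _membership_matrix(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    cats = list(dict.fromkeys(labels.tolist()))
    Z = np.column_stack([(labels == c).astype(float) for c in cats])
    return Z, cats


def calibrate_interest_index(area_weights, U_membership, V_membership,
                             targets, bounds=(0.61, 3.0),
                             tol: float = 1e-8, max_iter: int = 200,
                             soft_tol: float = 1e-3) -> InterestIndex:
    """Solve for the bounded index of interest under double stratification.

    Parameters
    ----------
    area_weights : array-like
        ``A_i / A`` per unit (accessible-area share of each square; sums to
        one over the frame).
    U_membership, V_membership : array-like
        Stratum labels of each unit under the two stratifications
        (``V_membership=None`` calibrates on a single stratification).
    targets : StratumTargets or tuple of arrays
        Target shares ``(q, p)`` in the stable first-appearance order of the
        labels.
    bounds : (float, float)
        Lower and upper bounds on the index, ``L < 1 < U``; ``(0, inf)``
        selects the unbounded raking solution.
    tol : float
        Residual tolerance for convergence of the stratum constraints.
    soft_tol : float
        If Newton stalls but every residual is below this threshold, the
        closest bounded solution is returned with a warning instead of an
        error (small infeasibilities are unavoidable with a finite frame).

    Returns
    -------
    InterestIndex
        With ``I`` strictly inside the closure of the bounds and constraint
        residuals below ``tol`` (or ``soft_tol`` with ``converged=False``).
    """
    d = np.asarray(area_weights, dtype=float)
    if np.any(d <= 0) or np.any(~np.isfinite(d)):
        raise ValueError("area weights must be positive and finite")
    L, U = float(bounds[0]), float(bounds[1])
    if not (L < 1.0 < U):
        raise ValueError("bounds must bracket 1 (L < 1 < U)")

    ZU, catsU = _membership_matrix(U_membership)
    blocks = [ZU]
    names = [f"U[{c}]" for c in catsU]
    if V_membership is not None:
        ZV, catsV = _membership_matrix(V_membership)
        blocks.append(ZV)
        names += [f"V[{c}]" for c in catsV]
    Z = np.column_stack(blocks)

    if isinstance(targets, StratumTargets):
        t = np.concatenate([targets.q] + ([targets.p] if V_membership is not None else []))
    else:
        t = np.concatenate([np.asarray(x, dtype=float) for x in targets
                            if x is not None])
    if t.size != Z.shape[1]:
        raise ValueError(f"{t.size} targets for {Z.shape[1]} strata")

    # necessary feasibility: each target must lie in [L, U] * stratum weight
    s = Z.T @ d
    lo = L * s
    hi = np.full_like(s, np.inf) if np.isinf(U) else U * s
    bad = (t < lo - tol) | (t > hi + tol)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise CalibrationInfeasibleError(
            f"target for stratum {names[k]} ({t[k]:.6g}) is outside the "
            f"attainable range [{lo[k]:.6g}, {hi[k]:.6g}] under bounds "
            f"({L}, {U})")

    lam = np.zeros(Z.shape[1])
    F, dF = _logistic_F(Z @ lam, L, U)
    r = Z.T @ (d * F) - t
    best = (np.max(np.abs(r)), lam.copy())
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            break
        J = Z.T @ (Z * (d * dF)[:, None])
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        # damped Newton: backtrack until the residual norm decreases
        norm0 = np.linalg.norm(r)
        scale = 1.0
        for _ in range(40):
            lam_new = lam + scale * step
            F, dF = _logistic_F(Z @ lam_new, L, U)
            r_new = Z.T @ (d * F) - t
            if np.linalg.norm(r_new) < norm0:
                break
            scale *= 0.5
        lam, r = lam_new, r_new
        if np.max(np.abs(r)) < best[0]:
            best = (np.max(np.abs(r)), lam.copy())

    max_res = np.max(np.abs(r))
    converged = bool(max_res < tol)
    if not converged:
        _, lam = best
        F, _ = _logistic_F(Z @ lam, L, U)
        r = Z.T @ (d * F) - t
        max_res = np.max(np.abs(r))
        if max_res > soft_tol:
            k = int(np.argmax(np.abs(r)))
            raise CalibrationInfeasibleError(
                f"calibration did not converge: residual {max_res:.3g} on "
                f"stratum {names[k]} exceeds the tolerated deviation "
                f"{soft_tol:g} under bounds ({L}, {U})")
        logger.warning("calibration accepted with residuals up to %.3g "
                       "(exact feasibility not attainable)", max_res)

    I = np.asarray(F, dtype=float)
    return InterestIndex(I=I, bounds=(L, U), residuals=r, converged=converged)
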