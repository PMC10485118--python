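"""Finite-population sampling algorithms.

This module provides the generic building blocks used by multi-stage
environmental survey designs:

* :func:`solve_capped_inclusion` — unequal-probability inclusion proportional
  to a size measure, capped at 1, with the proportionality constant solved so
  that the probabilities sum to a prescribed sample size.
* :func:`cube_flight` / :func:`cube_land` — the cube method for balanced
  sampling: the flight phase resolves most units while conserving the
  Horvitz-Thompson (HT) equations of a set of auxiliary balancing variables;
  the landing phase rounds the few remaining fractional units by sequential
  suppression of balancing variables.
* :func:`local_pivotal` — spatially spread sampling by probability transfers
  between mutually nearest neighbours.
* :func:`local_cube` — doubly balanced sampling: cube pivot steps applied on
  local clusters of nearest neighbours, yielding samples that are both
  balanced on auxiliaries and spatially well spread.
* :func:`stratified_balanced_sample` — the flight phase run separately within
  each stratum (rotation group), the unresolved units pooled and the method
  reapplied to the rounding problem, which keeps exact control of
  within-stratum sample sizes.

All algorithms operate on plain NumPy arrays.  Randomness flows from a single
seed (or an existing :class:`numpy.random.Generator`), and every sampler
records its seed and algorithm identifier in the returned
:class:`SampleDraw`.

Conventions
-----------
A balancing matrix ``X`` has one row per population unit.  The balancing
equations conserved by the flight phase are, for every column ``x`` of ``X``::

    sum_i x_i  ≈  sum_{i in S} x_i / pi_i

If ``X`` contains ``pi`` itself as a column and ``sum(pi)`` is an integer, the
realized sample size is fixed.  When a fixed sample size must survive the
landing phase, place the ``pi`` column *first*: the landing suppresses
balancing variables from the last column backwards, so the first column is
honoured longest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleDraw",
    "CappedInclusion",
    "solve_capped_inclusion",
    "cube_flight",
    "cube_land",
    "cube_sample",
    "local_pivotal",
    "local_cube",
    "stratified_balanced_sample",
    "random_pivotal",
    "multinomial_sample",
    "spatial_balance",
]

logger = logging.getLogger(__name__)

#: snapping tolerance: values within EPS of 0 or 1 are considered resolved
EPS = 1e-9


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seed_of(seed):
    return None if isinstance(seed, np.random.Generator) else seed


def _validate_pi(pi) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1:
        raise ValueError("inclusion probabilities must be a 1-d vector")
    if np.any(~np.isfinite(pi)) or np.any(pi < -EPS) or np.any(pi > 1 + EPS):
        raise ValueError("inclusion probabilities must be finite and in [0, 1]")
    return np.clip(pi, 0.0, 1.0)


def _validate_X(X, n: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(
            f"balancing matrix has {X.shape[0]} rows for {n} population units"
        )
    if np.any(~np.isfinite(X)):
        raise ValueError("balancing matrix contains non-finite values")
    return X


def _validate_coords(coords, n: int) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[0] != n:
        raise ValueError("coordinates must have one row per population unit")
    if np.any(~np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return coords


def _standardize(coords: np.ndarray) -> np.ndarray:
    sd = coords.std(axis=0)
    sd[sd == 0] = 1.0
    return coords / sd


def _snap(pistar: np.ndarray, idx) -> None:
    """Snap near-integer entries of ``pistar`` (in place) for units ``idx``."""
    v = pistar[idx]
    v[v <= EPS * 10] = 0.0
    v[v >= 1 - EPS * 10] = 1.0
    pistar[idx] = v


@dataclass
class SampleDraw:
    """A realized 0/1 sample with provenance.

    Attributes
    ----------
    indicator : ndarray of int
        Selection flag per population unit.
    algorithm : str
        Identifier of the sampling algorithm that produced the draw.
    seed : int or None
        The seed the sampler was called with (``None`` when an existing
        generator was passed in).
    """

    indicator: np.ndarray
    algorithm: str
    seed: int | None = None

    @property
    def selected(self) -> np.ndarray:
        """Indices of the selected units."""
        return np.flatnonzero(self.indicator == 1)

    @property
    def size(self) -> int:
        return int(self.indicator.sum())


# ---------------------------------------------------------------------------
# capped unequal-probability inclusion
# ---------------------------------------------------------------------------

@dataclass
class CappedInclusion:
    """Inclusion probabilities ``min(C * size_i, 1)`` summing to ``target``."""

    values: np.ndarray
    target_size: float
    constant: float
    capped: np.ndarray = field(repr=False)

    @property
    def n_capped(self) -> int:
        return int(self.capped.sum())


def solve_capped_inclusion(sizes, target, tol: float = 1e-9) -> CappedInclusion:
    """Solve ``sum_i min(C * size_i, 1) = target`` for the constant ``C``.

    Implements the iterative-saturation algorithm for
    probability-proportional-to-size inclusion: units whose provisional
    probability exceeds one are fixed at 1 ("always selected") and the
    constant is re-solved exactly on the remaining units, until stable.

    Parameters
    ----------
    sizes : array-like
        Strictly positive size measure per unit (e.g. ``n_i * I_i`` for
        squares, or an interest index ``J_j`` for plots).
    target : float
        Required sum of the inclusion probabilities (the expected sample
        size; an integer for fixed-size designs).
    tol : float
        Tolerance on the achieved sum.

    Returns
    -------
    CappedInclusion
        With ``values`` in (0, 1], ``sum(values) == target`` within ``tol``.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.ndim != 1 or sizes.size == 0:
        raise ValueError("sizes must be a non-empty 1-d vector")
    if np.any(~np.isfinite(sizes)) or np.any(sizes <= 0):
        raise ValueError("all sizes must be finite and strictly positive")
    N = sizes.size
    if not (0 < target <= N):
        raise ValueError(f"target must be in (0, {N}], got {target}")

    capped = np.zeros(N, dtype=bool)
    while True:
        free = ~capped
        remaining = target - capped.sum()
        if remaining <= 0:
            # target met by capped units alone (target integer == n capped)
            break
        C = remaining / sizes[free].sum()
        newly = free & (C * sizes >= 1.0 - tol)
        if not newly.any():
            break
        capped |= newly

    values = np.minimum(C * sizes, 1.0)
    values[capped] = 1.0
    achieved = values.sum()
    if abs(achieved - target) > max(tol, 1e-12 * N):
        raise RuntimeError(
            f"capping solver failed to converge: sum {achieved} != {target}"
        )
    return CappedInclusion(values=values, target_size=float(target),
                           constant=float(C), capped=capped)


# ---------------------------------------------------------------------------
# cube method: flight and landing
# ---------------------------------------------------------------------------

def _kernel_vector(B: np.ndarray) -> np.ndarray:
    """A unit vector in the null space of ``B`` (p x c, c > rank)."""
    # right singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(B, full_matrices=True)
    return vt[-1]


def _pivot_cluster(pistar: np.ndarray, A: np.ndarray, idx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One cube pivot step on the units ``idx``.

    Moves ``pistar[idx]`` along a kernel direction of the restricted
    constraint matrix until at least one unit reaches 0 or 1; the two
    directions are chosen with the martingale probabilities that preserve
    the expectation of every entry.  Returns the indices resolved by the
    step (possibly empty if the kernel direction was degenerate).
    """
    u = _kernel_vector(A[:, idx])
    p = pistar[idx]
    pos = u > EPS
    neg = u < -EPS
    if not pos.any() and not neg.any():
        return np.empty(0, dtype=int)

    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = np.inf
        l2 = np.inf
        if pos.any():
            l1 = min(l1, np.min((1.0 - p[pos]) / u[pos]))
            l2 = min(l2, np.min(p[pos] / u[pos]))
        if neg.any():
            l1 = min(l1, np.min(p[neg] / -u[neg]))
            l2 = min(l2, np.min((1.0 - p[neg]) / -u[neg]))

    if not np.isfinite(l1) or not np.isfinite(l2) or (l1 + l2) <= 0:
        return np.empty(0, dtype=int)

    if rng.random() < l2 / (l1 + l2):
        p = p + l1 * u
    else:
        p = p - l2 * u
    pistar[idx] = np.clip(p, 0.0, 1.0)
    _snap(pistar, idx)
    resolved = idx[(pistar[idx] <= 0.0) | (pistar[idx] >= 1.0)]
    return resolved


def _active_mask(pistar: np.ndarray, subset=None) -> np.ndarray:
    m = (pistar > 0.0) & (pistar < 1.0)
    if subset is not None:
        mm = np.zeros_like(m)
        mm[subset] = m[subset]
        m = mm
    return m


def _flight_pooled(pistar: np.ndarray, A: np.ndarray,
                   rng: np.random.Generator, subset=None) -> None:
    """Fast flight phase on a sliding buffer of rank+1 units (in place)."""
    p = A.shape[0]
    active = np.flatnonzero(_active_mask(pistar, subset))
    stack = list(rng.permutation(active))
    buf: list[int] = []
    guard = 0
    max_iter = 50 * (len(stack) + p + 2)
    while True:
        while len(buf) <= p and stack:
            buf.append(stack.pop())
        if len(buf) <= p:
            break
        resolved = _pivot_cluster(pistar, A, np.asarray(buf), rng)
        if resolved.size:
            rs = set(resolved.tolist())
            buf = [b for b in buf if b not in rs]
        guard += 1
        if guard > max_iter:  # pragma: no cover - numerical safety valve
            logger.warning("flight phase stalled; leaving %d units unresolved",
                           len(buf))
            break


def _flight_local(pistar: np.ndarray, A: np.ndarray, coords: np.ndarray,
                  rng: np.random.Generator, subset=None) -> None:
    """Flight phase with pivot clusters formed by nearest neighbours."""
    p = A.shape[0]
    guard = 0
    n_start = int(_active_mask(pistar, subset).sum())
    max_iter = 50 * (n_start + p + 2)
    while True:
        active = np.flatnonzero(_active_mask(pistar, subset))
        if active.size <= p:
            break
        i = active[rng.integers(active.size)]
        others = active[active != i]
        d2 = np.sum((coords[others] - coords[i]) ** 2, axis=1)
        # stable partial sort: distance, then unit index as tie-break
        order = np.lexsort((others, d2))
        cluster = np.concatenate(([i], others[order[:p]]))
        _pivot_cluster(pistar, A, cluster, rng)
        guard += 1
        if guard > max_iter:  # pragma: no cover - numerical safety valve
            logger.warning("local flight stalled with %d active units",
                           active.size)
            break


def _constraint_matrix(pi: np.ndarray, X: np.ndarray) -> np.ndarray:
    """A = (x_i / pi_i) as columns; frozen units never enter pivots."""
    safe = np.where(pi > 0, pi, 1.0)
    return (X / safe[:, None]).T


def _bernoulli_round(pistar: np.ndarray, rng: np.random.Generator) -> None:
    frac = (pistar > 0.0) & (pistar < 1.0)
    if frac.any():
        pistar[frac] = (rng.random(int(frac.sum())) < pistar[frac]).astype(float)


def cube_flight(pi, X, rng_seed=None) -> np.ndarray:
    """Flight phase of the cube method.

    Returns a vector in ``[0, 1]^N`` with at most ``rank(X)`` fractional
    entries, such that for every balancing column ``x``,
    ``sum(x * out / pi) == sum(x)`` (the HT balancing equations are
    conserved), and every entry equal to 0 or 1 in ``pi`` is unchanged.
    """
    pi = _validate_pi(pi)
    X = _validate_X(X, pi.size)
    rng = _as_rng(rng_seed)
    pistar = pi.copy()
    A = _constraint_matrix(pi, X)
    _flight_pooled(pistar, A, rng)
    return pistar


def _land(pistar: np.ndarray, pi: np.ndarray, X: np.ndarray,
          rng: np.random.Generator, subset=None,
          keep_first: int = 1) -> None:
    """Landing by sequential suppression of balancing variables (in place).

    Columns are dropped from the last backwards down to ``keep_first``
    columns, re-running the flight phase after each suppression; any units
    still fractional afterwards are rounded by independent Bernoulli trials
    (which preserves their marginal expectations).
    """
    p = X.shape[1]
    for k in range(p - 1, keep_first - 1, -1):
        if not _active_mask(pistar, subset).any():
            return
        A = _constraint_matrix(pi, X[:, :k])
        _flight_pooled(pistar, A, rng, subset=subset)
    idx = np.flatnonzero(_active_mask(pistar, subset))
    if idx.size:
        v = pistar[idx]
        pistar[idx] = (rng.random(idx.size) < v).astype(float)


def cube_land(flight_result, pi, X, rng_seed=None) -> SampleDraw:
    """Landing phase of the cube method.

    Rounds the fractional remainder of :func:`cube_flight` to a 0/1 sample
    by sequential suppression of balancing variables (last column dropped
    first, so a leading ``pi`` column — and hence a fixed sample size — is
    preserved longest).  Entries already 0/1 are returned unchanged.
    """
    pi = _validate_pi(pi)
    X = _validate_X(X, pi.size)
    pistar = np.asarray(flight_result, dtype=float).copy()
    if pistar.shape != pi.shape:
        raise ValueError("flight result and pi have different lengths")
    rng = _as_rng(rng_seed)
    _land(pistar, pi, X, rng)
    return SampleDraw(indicator=pistar.round().astype(int),
                      algorithm="cube", seed=_seed_of(rng_seed))


def cube_sample(pi, X, rng_seed=None) -> SampleDraw:
    """Balanced sample by the full cube method (flight + landing)."""
    rng = _as_rng(rng_seed)
    flight = cube_flight(pi, X, rng)
    draw = cube_land(flight, pi, X, rng)
    return SampleDraw(indicator=draw.indicator, algorithm="cube",
                      seed=_seed_of(rng_seed))


# ---------------------------------------------------------------------------
# local pivotal method (LPM1)
# ---------------------------------------------------------------------------

def _pivotal_update(pistar: np.ndarray, i: int, j: int,
                    rng: np.random.Generator) -> None:
    a, b = pistar[i], pistar[j]
    s = a + b
    if s < 1.0:
        if rng.random() < b / s:
            pistar[i], pistar[j] = 0.0, s
        else:
            pistar[i], pistar[j] = s, 0.0
    else:
        if rng.random() < (1.0 - b) / (2.0 - s):
            pistar[i], pistar[j] = 1.0, s - 1.0
        else:
            pistar[i], pistar[j] = s - 1.0, 1.0
    _snap(pistar, np.array([i, j]))


def _nearest(coords: np.ndarray, i: int, candidates: np.ndarray) -> int:
    d2 = np.sum((coords[candidates] - coords[i]) ** 2, axis=1)
    # ties broken by unit index
    k = np.lexsort((candidates, d2))[0]
    return int(candidates[k])


def local_pivotal(pi, coords, rng_seed=None) -> SampleDraw:
    """Spatially balanced sampling by the local pivotal method.

    Repeatedly picks a random unresolved unit, finds its nearest unresolved
    neighbour (standardized Euclidean distance, coordinate ties broken by
    unit index) and, when the two are *mutually* nearest, lets them compete
    in a pivotal probability transfer.  Marginal inclusion probabilities are
    preserved and the realized sample is spatially well spread.
    """
    pi = _validate_pi(pi)
    coords = _standardize(_validate_coords(coords, pi.size))
    rng = _as_rng(rng_seed)
    pistar = pi.copy()
    _snap(pistar, np.arange(pi.size))
    while True:
        active = np.flatnonzero((pistar > 0) & (pistar < 1))
        if active.size <= 1:
            break
        i = int(active[rng.integers(active.size)])
        others = active[active != i]
        j = _nearest(coords, i, others)
        back = active[active != j]
        if _nearest(coords, j, back) == i:  # mutually nearest
            _pivotal_update(pistar, i, j, rng)
    _bernoulli_round(pistar, rng)
    return SampleDraw(indicator=pistar.round().astype(int),
                      algorithm="local_pivotal", seed=_seed_of(rng_seed))


# ---------------------------------------------------------------------------
# doubly balanced (local cube) sampling
# ---------------------------------------------------------------------------

def local_cube(pi, X, coords, rng_seed=None) -> SampleDraw:
    """Doubly balanced sampling: cube balancing with spatial spreading.

    The flight phase performs cube pivot steps on local clusters of
    ``rank(X) + 1`` nearest neighbours, so the realized sample is both
    approximately balanced on the columns of ``X`` and spatially spread.
    The remainder is rounded by the standard landing phase.
    """
    pi = _validate_pi(pi)
    X = _validate_X(X, pi.size)
    coords = _standardize(_validate_coords(coords, pi.size))
    rng = _as_rng(rng_seed)
    pistar = pi.copy()
    _snap(pistar, np.arange(pi.size))
    A = _constraint_matrix(pi, X)
    _flight_local(pistar, A, coords, rng)
    _land(pistar, pi, X, rng)
    return SampleDraw(indicator=pistar.round().astype(int),
                      algorithm="local_cube", seed=_seed_of(rng_seed))


# ---------------------------------------------------------------------------
# stratified balancing (flight per stratum, pooled rounding)
# ---------------------------------------------------------------------------

def stratified_balanced_sample(pi, X, coords, group_labels,
                               rng_seed=None) -> SampleDraw:
    """Doubly balanced sampling with exact within-stratum sample sizes.

    The (local) flight phase is applied separately within each group; the
    units left unresolved are then pooled and the method is reapplied to the
    rounding problem with the balancing matrix augmented by group-wise
    ``pi`` columns, so that whenever ``sum(pi)`` within a group is an
    integer, every realized sample has exactly that many units in the group.

    Parameters
    ----------
    pi, X, coords
        As for :func:`local_cube`; ``X`` should contain ``pi`` as its first
        column for fixed-size behaviour.
    group_labels : array-like
        One label per unit; the labels partition the population (e.g.
        rotation groups of a panel survey).
    """
    pi = _validate_pi(pi)
    X = _validate_X(X, pi.size)
    coords = _standardize(_validate_coords(coords, pi.size))
    labels = np.asarray(group_labels)
    if labels.shape[0] != pi.size:
        raise ValueError("group labels must have one entry per unit")
    groups = list(dict.fromkeys(labels.tolist()))  # stable order
    rng = _as_rng(rng_seed)
    pistar = pi.copy()
    _snap(pistar, np.arange(pi.size))

    # per-group flight phase (spatially clustered pivots)
    A = _constraint_matrix(pi, X)
    for g in groups:
        members = np.flatnonzero(labels == g)
        if members.size == 0:  # pragma: no cover - defensive
            logger.warning("empty group %r skipped", g)
            continue
        sub_pistar = pistar[members]
        sub_A = A[:, members]
        _flight_local(sub_pistar, sub_A, coords[members], rng)
        pistar[members] = sub_pistar

    # pooled rounding problem: group-wise pi columns first (dropped last)
    group_cols = np.column_stack([pi * (labels == g) for g in groups])
    Xp = np.column_stack([group_cols, X])
    unresolved = np.flatnonzero((pistar > 0) & (pistar < 1))
    if unresolved.size:
        Ap = _constraint_matrix(pi, Xp)
        _flight_pooled(pistar, Ap, rng, subset=unresolved)
        # suppress the original balancing variables, keep the group columns
        _suppress_to_groups(pistar, pi, Xp, len(groups), rng, unresolved)
        # final stage: exact per-group fixed-size rounding
        for g in groups:
            members = np.flatnonzero(labels == g)
            if not _active_mask(pistar, members).any():
                continue
            A1 = _constraint_matrix(pi, pi[:, None])
            _flight_pooled(pistar, A1, rng, subset=members)
        _bernoulli_round(pistar, rng)

    return SampleDraw(indicator=pistar.round().astype(int),
                      algorithm="stratified_balanced", seed=_seed_of(rng_seed))


def _suppress_to_groups(pistar, pi, Xp, n_groups, rng, subset) -> None:
    for k in range(Xp.shape[1] - 1, n_groups - 1, -1):
        if not _active_mask(pistar, subset).any():
            return
        A = _constraint_matrix(pi, Xp[:, :k])
        _flight_pooled(pistar, A, rng, subset=subset)


# ---------------------------------------------------------------------------
# reference designs used in efficiency comparisons
# ---------------------------------------------------------------------------

def random_pivotal(pi, rng_seed=None) -> SampleDraw:
    """Unequal-probability fixed-size sampling without balancing or spreading.

    Sequential pivotal method on randomly chosen pairs: preserves the
    inclusion probabilities and (when ``sum(pi)`` is an integer) the sample
    size, but is neither balanced on auxiliaries nor spatially spread.
    Serves as the "pure UPS" reference design in efficiency studies.
    """
    pi = _validate_pi(pi)
    rng = _as_rng(rng_seed)
    pistar = pi.copy()
    _snap(pistar, np.arange(pi.size))
    while True:
        active = np.flatnonzero((pistar > 0) & (pistar < 1))
        if active.size <= 1:
            break
        i, j = rng.choice(active, size=2, replace=False)
        _pivotal_update(pistar, int(i), int(j), rng)
    _bernoulli_round(pistar, rng)
    return SampleDraw(indicator=pistar.round().astype(int),
                      algorithm="random_pivotal", seed=_seed_of(rng_seed))


def multinomial_sample(pi, rng_seed=None) -> SampleDraw:
    """With-replacement multinomial design with the same target ``pi``.

    Draws ``n = round(sum(pi))`` units with replacement with drawing
    probabilities ``pi / sum(pi)`` and returns the indicator of the distinct
    units drawn.  Used as the unspread reference when scoring spatial
    balance.
    """
    pi = _validate_pi(pi)
    rng = _as_rng(rng_seed)
    n = int(round(pi.sum()))
    p = pi / pi.sum()
    counts = rng.multinomial(n, p)
    return SampleDraw(indicator=(counts > 0).astype(int),
                      algorithm="multinomial", seed=_seed_of(rng_seed))


def spatial_balance(indicator, pi, coords) -> float:
    """Voronoi spatial-balance statistic of a realized sample.

    Each population unit is assigned to its nearest selected unit (ties by
    unit index); for a perfectly spread sample the inclusion probabilities
    in each Voronoi cell sum to one.  The statistic is::

        B = (1/n) * sum_{k selected} (sum_{i in cell k} pi_i - 1)^2

    Lower is better; spatially spread designs give systematically smaller B
    than unspread designs with the same ``pi``.
    """
    indicator = np.asarray(indicator)
    pi = _validate_pi(pi)
    coords = _standardize(_validate_coords(coords, pi.size))
    sel = np.flatnonzero(indicator == 1)
    if sel.size == 0:
        raise ValueError("empty sample has no spatial balance")
    d2 = ((coords[:, None, :] - coords[sel][None, :, :]) ** 2).sum(axis=2)
    owner = sel[np.argmin(d2, axis=1)]
    cell_sums = np.array([pi[owner == k].sum() for k in sel])
    return float(np.mean((cell_sums - 1.0) ** 2))
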