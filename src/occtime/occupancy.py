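"""Occupancy-time distributions and moments for target stage sets.

For a target set ``R`` of stages, the occupancy time ``A_R(n)`` counts the
steps ``k < n`` with ``X_k in R``; the lifetime occupancy ``tau_R = A_R(N)``
is the total time spent in ``R`` before death (for the Southern Fulmar
example, the number of breeding attempts over a bird's life).

Two computational routes are provided, both driven by the same
McKendrick–von-Foerster-type recursion for the joint sub-probability
``p^R_j(a, n) = P{A_R(n) = a, X_n = j}``:

* :func:`occupancy_distribution` evolves the full ``(a, n)`` table

  ``p(a, n+1) = B(n) (R p(a-1, n) + (I - R) p(a, n))``

  and accumulates ``P{tau_R = a} = sum_n b(n)^T (R p(a-1, n) + (I-R) p(a, n))``
  (with ``p(-1, .) = 0`` so the same formula yields ``a = 0``);

* :func:`occupancy_moments` never builds the table: it carries only the
  ``K + 1`` moment vectors ``m_k(n) = sum_a a^k p(a, n)``, each step costing
  ``K + 1`` matrix–vector products, and accumulates ``E[tau_R^k]`` directly.

Both truncate when surviving mass drops below ``eps`` (or at ``n_max``) and
report the unassigned mass.  The convention for time 0 is that the starting
stage counts towards occupancy one step later: ``p(0, 0) = v`` regardless of
whether stages in ``R`` carry initial mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chain_core import StageModel, TargetSet
from .lifetime import DEFAULT_EPS, DEFAULT_N_MAX

logger = logging.getLogger(__name__)

# refuse joint tables larger than this many (a, n, j) cells by default
DEFAULT_CELL_BUDGET = 200_000_000

__all__ = [
    "JointOccupancyTable",
    "OccupancyResult",
    "joint_occupancy_table",
    "occupancy_distribution",
    "occupancy_moment_step",
    "occupancy_moments",
    "summary_stats",
    "homogeneous_closed_forms",
]


@dataclass
class JointOccupancyTable:
    """The sub-probability mass ``p^R_j(a, n)`` for all kept time steps.

    ``values[n]`` is an ``(n + 1, d)`` array: row ``a`` holds the vector
    ``p^R(a, n)`` over stages.  Mass at time ``n`` sums to the survival
    probability, not to 1, because death removes mass.
    """

    values: list[np.ndarray]
    target: TargetSet

    def mass_at(self, n: int) -> float:
        return float(self.values[n].sum())


@dataclass
class OccupancyResult:
    """Distribution and/or moments of the lifetime occupancy ``tau_R``.

    ``pmf[a] = P{tau_R = a}`` when the distribution route was run; ``moments``
    maps order ``k`` to ``E[tau_R^k]``.  ``truncation_mass`` is the surviving
    probability left unassigned when iteration stopped at ``n_stop``.
    """

    pmf: np.ndarray | None = None
    moments: dict[int, float] = field(default_factory=dict)
    truncation_mass: float = 0.0
    n_stop: int = 0

    @property
    def mean(self) -> float | None:
        return self.moments.get(1)

    @property
    def variance(self) -> float | None:
        if 1 in self.moments and 2 in self.moments:
            return self.moments[2] - self.moments[1] ** 2
        return None

    @property
    def cv(self) -> float | None:
        """Coefficient of variation sqrt(Var)/mean; NaN when the mean is 0."""
        var = self.variance
        if var is None:
            return None
        if self.moments[1] == 0:
            return math.nan
        return math.sqrt(max(var, 0.0)) / self.moments[1]


def _iterate_table(model, target, eps, n_max):
    """Yield (n, b(n), p_table_at_n) stepping the joint recursion."""
    mask = target.mask
    p = np.zeros((1, model.d))
    p[0] = model.v  # A_R(0) = 0 with probability 1
    n = 0
    while p.sum() >= (eps or 0.0) and n < n_max:
        yield n, model.b(n), p
        B = model.B(n)
        # shifted[a] = p[a-1] restricted to R; unshifted keeps non-R mass at a
        nxt = np.zeros((p.shape[0] + 1, model.d))
        inR = p * mask
        outR = p * ~mask
        nxt[1:, :] += inR
        nxt[:-1, :] += outR
        p = nxt @ B.T
        n += 1
    yield n, None, p  # terminal state for truncation accounting


def joint_occupancy_table(
    model: StageModel,
    target: TargetSet,
    eps: float | None = DEFAULT_EPS,
    n_max: int | None = DEFAULT_N_MAX,
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> JointOccupancyTable:
    """Evolve and keep the full joint table ``p^R_j(a, n)`` for n up to stop.

    Memory grows as ``n^2 d / 2``; for long horizons where only moments are
    needed use :func:`occupancy_moments`, which carries O(K d) state.
    """
    if target.d != model.d:
        raise ValueError(f"target mask length {target.d} != model dimension {model.d}")
    if n_max is None:
        n_max = 10**9
    if n_max * (n_max + 1) // 2 * model.d > cell_budget:
        raise MemoryError(
            f"joint table for n_max={n_max} would exceed the cell budget; "
            "use occupancy_moments, which needs no table"
        )
    tables: list[np.ndarray] = []
    for n, b, p in _iterate_table(model, target, eps, n_max):
        tables.append(p.copy())
    return JointOccupancyTable(tables, target)


def occupancy_distribution(
    model: StageModel,
    target: TargetSet,
    eps: float | None = DEFAULT_EPS,
    n_max: int | None = DEFAULT_N_MAX,
) -> OccupancyResult:
    """Full distribution ``P{tau_R = a}`` of the lifetime occupancy time.

    Accumulates, over every step n, the probability of dying at n+1 having
    accumulated a steps in ``R`` (counting the stage occupied at the moment
    of death).  The pmf sums to 1 minus the reported truncation mass.
    """
    if target.d != model.d:
        raise ValueError(f"target mask length {target.d} != model dimension {model.d}")
    if n_max is None:
        n_max = 10**9
    mask = target.mask
    pmf = np.zeros(1)
    trunc = 0.0
    n_stop = 0
    for n, b, p in _iterate_table(model, target, eps, n_max):
        if b is None:
            trunc = float(p.sum())
            n_stop = n
            break
        # death contribution: stages in R add one final step of occupancy
        contrib = np.zeros(p.shape[0] + 1)
        contrib[1:] += (p * mask) @ b
        contrib[:-1] += (p * ~mask) @ b
        if contrib.size > pmf.size:
            pmf = np.pad(pmf, (0, contrib.size - pmf.size))
        pmf[: contrib.size] += contrib
    if eps is not None and trunc >= eps:
        logger.warning(
            "occupancy distribution truncated at n=%d with surviving mass %.3g",
            n_stop,
            trunc,
        )
    # trim trailing zeros but keep at least P{tau=0}
    last = int(np.flatnonzero(pmf)[-1]) if pmf.any() else 0
    return OccupancyResult(pmf=pmf[: last + 1], truncation_mass=trunc, n_stop=n_stop)


def occupancy_moment_step(
    B: np.ndarray, mask: np.ndarray, m: np.ndarray, binom: np.ndarray
) -> np.ndarray:
    """One step of the moment-vector recursion.

    ``m`` has shape ``(K + 1, d)`` with ``m[k] = m_k(n)``; returns the
    ``(K + 1, d)`` array of ``m_k(n + 1)``:

    ``m_0(n+1) = B(n) m_0(n)``;
    ``m_k(n+1) = B(n) (m_k(n) + R sum_{j=1..k} C(k, j) m_{k-j}(n))``.

    ``binom[k, j]`` holds the binomial coefficients C(k, j), precomputed.
    """
    g = _bracket(mask, m, binom)
    return g @ B.T


def _bracket(mask, m, binom):
    """g_k = m_k + R * sum_{j=1..k} C(k,j) m_{k-j} for k = 0..K."""
    K = m.shape[0] - 1
    g = m.copy()
    for k in range(1, K + 1):
        s = np.zeros(m.shape[1])
        for j in range(1, k + 1):
            s += binom[k, j] * m[k - j]
        g[k] += mask * s
    return g


def occupancy_moments(
    model: StageModel,
    target: TargetSet,
    K: int = 2,
    eps: float | None = DEFAULT_EPS,
    n_max: int | None = DEFAULT_N_MAX,
) -> OccupancyResult:
    """First ``K`` raw moments of ``tau_R`` without building the joint table.

    Iterates the moment-vector recursion while accumulating

    ``E[tau_R^k] += b(n)^T (m_k(n) + R sum_j C(k, j) m_{k-j}(n))``

    for each step n, stopping once surviving mass (= ``1^T m_0(n)``) drops
    below ``eps`` or at ``n_max``.  State is ``(K + 1) x d`` — independent of
    the horizon.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if target.d != model.d:
        raise ValueError(f"target mask length {target.d} != model dimension {model.d}")
    if n_max is None:
        n_max = 10**9
    mask = target.mask.astype(float)
    d = model.d
    binom = np.zeros((K + 1, K + 1))
    for k in range(K + 1):
        for j in range(k + 1):
            binom[k, j] = math.comb(k, j)
    m = np.zeros((K + 1, d))
    m[0] = model.v
    acc = np.zeros(K + 1)
    n = 0
    while m[0].sum() >= (eps or 0.0) and n < n_max:
        b = model.b(n)
        g = _bracket(mask, m, binom)
        acc += g @ b
        m = g @ model.B(n).T
        n += 1
    trunc = float(m[0].sum())
    if eps is not None and trunc >= eps:
        logger.warning(
            "occupancy moments truncated at n=%d with surviving mass %.3g", n, trunc
        )
    moments = {k: float(acc[k]) for k in range(1, K + 1)}
    res = OccupancyResult(moments=moments, truncation_mass=trunc, n_stop=n)
    if K >= 2:
        var = res.variance
        if var < -max(1e-9, 10 * eps if eps else 1e-9):
            raise ArithmeticError(f"negative variance {var!r}: numerical inconsistency")
        if var < 0:
            res.moments[2] = res.moments[1] ** 2  # clip tiny negative variance to 0
    return res


def summary_stats(result: OccupancyResult) -> tuple[float, float, float]:
    """(mean, variance, cv) of an occupancy result with moments of order >= 2.

    An unreachable target (mean 0) yields cv = NaN rather than an exception.
    """
    if 2 not in result.moments:
        raise ValueError("summary_stats needs moments up to order 2")
    return result.moments[1], result.variance, result.cv


def homogeneous_closed_forms(B: np.ndarray, v: np.ndarray, target: TargetSet):
    """Phase-type closed forms for a constant transition matrix.

    For a homogeneous chain the lifetime follows a discrete phase-type
    distribution ``P{N = n} = b^T B^{n-1} v``, and the expected occupancy of
    ``R`` is the fundamental-matrix value ``E[tau_R] = 1^T R (I - B)^{-1} v``.

    Returns ``(pmf_fn, expected_occupancy)`` where ``pmf_fn(n)`` evaluates the
    lifetime pmf at integer ``n >= 1``.  These serve as an independent oracle
    for the iterative machinery in the homogeneous special case.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``I - B`` is singular (death unreachable from some state).
    """
    from .chain_core import absorption_vector, validate_substochastic

    B = validate_substochastic(B)
    v = np.asarray(v, dtype=float)
    b = absorption_vector(B).b
    fundamental = np.linalg.solve(np.eye(B.shape[0]) - B, v)

    def pmf_fn(n: int) -> float:
        if n < 1:
            return 0.0
        return float(b @ np.linalg.matrix_power(B, n - 1) @ v)

    expected = float(target.mask @ fundamental)
    return pmf_fn, expected
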