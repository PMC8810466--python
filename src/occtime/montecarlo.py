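"""Individual-trajectory simulator: the stochastic oracle for the analytics.

Simulates i.i.d. individuals on the extended chain with an explicit death
state: at step ``n`` an individual in stage ``j`` moves according to column
``j`` of ``C(n) = [[B(n), 0], [b(n)^T, 1]]``.  The lifetime ``N`` is the first
hit of the death state and the occupancy ``tau_R`` counts the steps
``k < N`` spent in ``R`` — the same counting convention as the analytic
recursions, so deterministic chains match them exactly.

Sampling is inverse-CDF per column with the fixed stage ordering
``1, ..., d, death``, so a given seed reproduces bit-identical trajectories
wherever the underlying generator (numpy PCG64) produces the same stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chain_core import StageModel, TargetSet, extend_with_death

logger = logging.getLogger(__name__)

__all__ = ["TrajectoryBatch", "simulate_individuals", "empirical_occupancy_stats"]


@dataclass
class TrajectoryBatch:
    """Per-individual lifetimes and occupancies from one simulation run.

    ``capped`` marks individuals still alive at the horizon cap; they carry
    censored (lower-bound) values and are excluded from moment estimates.
    """

    N: np.ndarray
    tau: np.ndarray
    capped: np.ndarray
    n_reps: int
    seed: int

    @property
    def n_capped(self) -> int:
        return int(self.capped.sum())


def _default_horizon(model: StageModel) -> int:
    # ~10x a crude expected-lifetime bound from the worst-case survival rate
    smax = float(model.B(0).sum(axis=0).max())
    if smax >= 1.0:
        return 10_000
    return max(100, int(10.0 / (1.0 - smax)))


def simulate_individuals(
    model: StageModel,
    target: TargetSet,
    n_reps: int,
    seed: int,
    horizon_cap: int | None = None,
) -> TrajectoryBatch:
    """Simulate ``n_reps`` independent life histories under the schedule.

    Each individual starts in a stage drawn from ``v`` and transitions by the
    columns of the extended matrix ``C(n)`` until death or ``horizon_cap``.
    If more than 1% of individuals hit the cap a warning is logged with the
    count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if horizon_cap is None:
        horizon_cap = _default_horizon(model)
    rng = np.random.default_rng(seed)
    d = model.d
    mask = np.append(target.mask, False)  # death state never in R

    # initial stages via inverse CDF on v
    u = rng.random(n_reps)
    state = np.searchsorted(np.cumsum(model.v), u, side="right").clip(max=d - 1)

    N = np.zeros(n_reps, dtype=np.int64)
    tau = np.zeros(n_reps, dtype=np.int64)
    alive = np.ones(n_reps, dtype=bool)
    for n in range(horizon_cap):
        if not alive.any():
            break
        tau[alive] += mask[state[alive]]
        cum = np.cumsum(extend_with_death(model.B(n)), axis=0)  # (d+1, d+1)
        u = rng.random(n_reps)
        cols = cum[:, state[alive]]  # (d+1, n_alive)
        nxt = (u[alive][None, :] >= cols).sum(axis=0).clip(max=d)
        state[alive] = nxt
        died = alive.copy()
        died[alive] = nxt == d
        N[died] = n + 1
        alive &= ~died
    capped = alive
    N[capped] = horizon_cap
    if capped.sum() > 0.01 * n_reps:
        logger.warning(
            "%d of %d individuals reached the horizon cap %d",
            capped.sum(),
            n_reps,
            horizon_cap,
        )
    return TrajectoryBatch(N=N, tau=tau, capped=capped, n_reps=n_reps, seed=seed)


def empirical_occupancy_stats(batch: TrajectoryBatch) -> dict:
    """Empirical pmf of ``tau_R`` with standard errors, plus mean/variance.

    Capped individuals are excluded.  Per-cell standard errors are binomial
    ``sqrt(p(1-p)/n)``; the mean's standard error is ``sqrt(s^2/n)``.
    """
    if batch.n_reps == 0:
        raise ValueError("empty batch")
    tau = batch.tau[~batch.capped]
    n = tau.size
    if n == 0:
        nan = float("nan")
        return {
            "pmf": np.zeros(0), "pmf_se": np.zeros(0), "mean": nan, "mean_se": nan,
            "variance": nan, "variance_se": nan, "n_used": 0, "n_capped": batch.n_capped,
        }
    counts = np.bincount(tau)
    pmf = counts / n
    pmf_se = np.sqrt(pmf * (1 - pmf) / n)
    mean = float(tau.mean())
    var = float(tau.var())  # population convention, matching analytic variance
    mean_se = float(np.sqrt(var / n)) if n > 1 else float("nan")
    # SE of the sample variance via the fourth central moment
    if n > 1:
        m4 = float(((tau - mean) ** 4).mean())
        var_se = float(np.sqrt(max(m4 - var**2, 0.0) / n))
    else:
        var_se = float("nan")
    return {
        "pmf": pmf,
        "pmf_se": pmf_se,
        "mean": mean,
        "mean_se": mean_se,
        "variance": var,
        "variance_se": var_se,
        "n_used": n,
        "n_capped": batch.n_capped,
    }
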