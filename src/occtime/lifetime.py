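"""Distribution and moments of the lifetime ``N`` (time of death).

The lifetime of an individual is the first time the chain hits the implicit
death state.  Its probability mass function is

``P{N = n} = b(n-1)^T Phi(n-1, 0) v``,

computed iteratively by carrying the alive distribution ``x_n = Phi(n, 0) v``
— the full transition operator is never materialised.  The infinite support is
truncated once the surviving mass drops below ``eps`` (or at ``n_max``); the
unassigned tail mass is always reported, never hidden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .chain_core import StageModel

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-12
DEFAULT_N_MAX = 10_000

__all__ = ["LifetimeDistribution", "lifetime_distribution", "lifetime_moments"]


@dataclass
class LifetimeDistribution:
    """Truncated pmf of the lifetime plus the mass beyond the truncation point.

    ``pmf[n]`` is ``P{N = n}`` for ``n = 1 .. n_stop``; ``pmf[0] = 0`` always
    (death takes at least one step).  ``truncation_mass`` is the probability
    of still being alive at ``n_stop``, so the pmf and the tail mass sum to 1.
    """

    pmf: np.ndarray
    truncation_mass: float
    n_stop: int

    def __post_init__(self) -> None:
        total = self.pmf.sum() + self.truncation_mass
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"pmf + truncation mass = {total!r}, expected 1")


def lifetime_distribution(
    model: StageModel,
    eps: float | None = DEFAULT_EPS,
    n_max: int | None = DEFAULT_N_MAX,
) -> LifetimeDistribution:
    """Compute ``P{N = n}`` until surviving mass < ``eps`` or ``n = n_max``.

    At least one of ``eps`` and ``n_max`` must be set.  A chain whose columns
    all sum to exactly 1 (an immortal state reachable from the start) never
    meets ``eps``; it stops at ``n_max`` with the leftover mass flagged.
    """
    if (eps is None or eps <= 0) and n_max is None:
        raise ValueError("set eps > 0 and/or a finite n_max")
    if n_max is None:
        n_max = 10**9
    x = model.v.copy()
    pmf = [0.0]
    n = 0
    while x.sum() >= (eps or 0.0) and n < n_max:
        b = model.b(n)
        pmf.append(float(b @ x))
        x = model.B(n) @ x
        n += 1
    trunc = float(x.sum())
    if eps is not None and trunc >= eps:
        logger.warning(
            "lifetime truncated at n_max=%d with surviving mass %.3g", n_max, trunc
        )
    return LifetimeDistribution(np.array(pmf), trunc, n)


def lifetime_moments(dist: LifetimeDistribution, k_max: int = 2) -> dict[int, float]:
    """Raw moments ``E[N^k] = sum_n n^k P{N = n}`` from the truncated pmf.

    Tail mass inflates true moments, so a non-negligible ``truncation_mass``
    triggers a warning: the returned values are then lower bounds.
    """
    if dist.truncation_mass > 1e-8:
        logger.warning(
            "moments computed on a pmf missing %.3g tail mass; values are lower bounds",
            dist.truncation_mass,
        )
    n = np.arange(dist.pmf.size)
    return {k: float((n**k) @ dist.pmf) for k in range(1, k_max + 1)}
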