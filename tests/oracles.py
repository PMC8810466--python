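"""Independent oracles used by the test suite.

These deliberately avoid the package's recursions: the path oracle
enumerates every stage path explicitly, and the closed-form helpers use
direct linear algebra, so agreement with the iterative machinery is a real
cross-check.
"""

from __future__ import annotations

import numpy as np

from occtime.chain_core import MatrixSchedule, StageModel, TargetSet


def brute_force_occupancy_pmf(model: StageModel, target: TargetSet, horizon: int):
    """Exhaustive path enumeration of P{tau_R = a} for deaths by `horizon`.

    Walks every alive stage path (x_0, ..., x_{n-1}), weights it by the
    product of transition probabilities, and adds the death probability at
    each step to the pmf cell of the path's occupancy count.  Exponential in
    `horizon`; use only on tiny models.

    Returns (pmf array over a = 0..horizon, leftover alive mass).
    """
    d = model.d
    mask = target.mask
    pmf = np.zeros(horizon + 1)
    # paths: list of (last_state, occupancy_count, weight); occupancy counts
    # the states visited so far (x_0..x_{n-1} at time n-1... see below)
    paths = [((j,), model.v[j]) for j in range(d) if model.v[j] > 0]
    for n in range(1, horizon + 1):
        B = model.B(n - 1)
        b = 1.0 - B.sum(axis=0)
        new_paths = []
        for path, w in paths:
            j = path[-1]
            a = sum(int(mask[s]) for s in path)
            pmf[a] += w * b[j]  # dies at time n having visited all of `path`
            for i in range(d):
                if B[i, j] > 0:
                    new_paths.append((path + (i,), w * B[i, j]))
        paths = new_paths
    leftover = sum(w for _, w in paths)
    return pmf, leftover


def random_model(rng: np.random.Generator, d: int | None = None,
                 n_mats: int | None = None, max_colsum: float = 0.95):
    """A random small stage model with reachable death, plus a target set."""
    d = int(d or rng.integers(1, 5))
    n_mats = int(n_mats or rng.integers(1, 4))
    mats = []
    for _ in range(n_mats):
        M = rng.random((d, d))
        M = M / M.sum(axis=0) * rng.uniform(0.3, max_colsum, size=d)
        mats.append(M)
    v = rng.random(d)
    v /= v.sum()
    extend = str(rng.choice(["repeat-last", "cycle"]))
    model = StageModel(MatrixSchedule(mats, extend=extend), v)
    mask = rng.random(d) < 0.5
    if not mask.any():
        mask[rng.integers(d)] = True
    return model, TargetSet(mask)


def pmf_moment(pmf: np.ndarray, k: int) -> float:
    """Raw k-th moment of a pmf indexed by its support 0..len-1."""
    return float(np.arange(pmf.size) ** k @ pmf)
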