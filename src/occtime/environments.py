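"""Random environments: i.i.d. matrix selection and ensemble statistics.

A randomly varying environment is modelled as a probability measure over
sequences of transition matrices.  The shipped implementation draws one
matrix per time step, independently, from a labelled catalog with fixed
selection probabilities (for the Southern Fulmar: favorable / ordinary /
unfavorable ice years with probabilities ``P_f + P_o + P_u = 1``).

Two levels of randomness contribute to the lifetime occupancy time:

* **demographic stochasticity** — an individual's random path given a fixed
  matrix sequence; handled analytically per sequence via the moment
  recursion, no individual-level simulation needed;
* **environmental stochasticity** — the randomness of the sequence itself;
  handled by Monte Carlo over sampled sequences.

The law of total variance splits the total variance of ``tau_R`` into
``E_mu[Var_P(tau_R)] + Var_mu[E_P(tau_R)]`` — the environmental mean of the
demographic variance plus the environmental variance of the demographic mean.
Variances across sequences use the population (divide-by-n) convention so the
identity is exact at the estimator level on the same samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .chain_core import DEFAULT_TOL, MatrixSchedule, StageModel, TargetSet, ValidationError, validate_substochastic
from .lifetime import DEFAULT_EPS, DEFAULT_N_MAX
from .occupancy import occupancy_moments

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentModel",
    "EnsembleResult",
    "build_schedule",
    "sample_iid_environment",
    "ensemble_statistics",
    "variance_decomposition",
    "simplex_grid",
    "simplex_sweep",
]


@dataclass
class EnvironmentModel:
    """Labelled matrix catalog with per-step i.i.d. selection probabilities."""

    catalog: dict[str, np.ndarray]
    probs: dict[str, float]
    seed: int = 0
    horizon: int | None = None
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        self.catalog = {k: validate_substochastic(M, self.tol) for k, M in self.catalog.items()}
        dims = {M.shape[0] for M in self.catalog.values()}
        if len(dims) != 1:
            raise ValidationError(f"catalog matrices have mixed dimensions {sorted(dims)}")
        missing = set(self.probs) - set(self.catalog)
        if missing:
            raise ValidationError(f"probabilities for unknown labels {sorted(missing)}")
        p = np.array([self.probs.get(k, 0.0) for k in self.labels])
        if np.any(p < 0) or abs(p.sum() - 1.0) > max(self.tol, 1e-9):
            raise ValidationError(f"selection probabilities must be nonnegative and sum to 1, got {p}")
        self._p = p

    @property
    def labels(self) -> list[str]:
        return list(self.catalog)

    @property
    def d(self) -> int:
        return next(iter(self.catalog.values())).shape[0]

    def default_horizon(self, eps: float = DEFAULT_EPS, n_max: int = DEFAULT_N_MAX) -> int:
        """Schedule length such that survival mass < eps even under the most
        survivable catalog matrix held constant, making per-sequence
        truncation negligible for any sampled sequence."""
        if self.horizon is not None:
            return self.horizon
        best = 0
        for M in self.catalog.values():
            x = np.full(self.d, 1.0 / self.d)
            n = 0
            while x.sum() >= eps and n < n_max:
                x = M @ x
                n += 1
            best = max(best, n)
        return best


def build_schedule(
    catalog: dict[str, np.ndarray],
    labels: str | list[str],
    extend: str = "repeat-last",
    tol: float = DEFAULT_TOL,
) -> MatrixSchedule:
    """Turn a label string/sequence (e.g. ``"ofu"``) into a matrix schedule."""
    seq = list(labels)
    if not seq:
        raise ValidationError("empty schedule; provide at least one label")
    unknown = sorted(set(seq) - set(catalog))
    if unknown:
        raise ValidationError(f"unknown labels {unknown}; valid labels: {sorted(catalog)}")
    return MatrixSchedule([catalog[l] for l in seq], extend=extend, tol=tol, labels=seq)


def sample_iid_environment(env: EnvironmentModel, n_sequences: int, horizon: int | None = None) -> list[list[str]]:
    """Draw ``n_sequences`` label sequences, one label per step, i.i.d.

    Replicate ``r`` uses an independent substream spawned from
    ``(env.seed, r)``, so results are reproducible and independent of
    evaluation order.
    """
    if horizon is None:
        horizon = env.default_horizon()
    labels = env.labels
    streams = np.random.SeedSequence(env.seed).spawn(n_sequences)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.choice(len(labels), size=horizon, p=env._p)
        out.append([labels[i] for i in idx])
    return out


@dataclass
class EnsembleResult:
    """Ensemble statistics of ``tau_R`` over sampled environment sequences.

    ``per_sequence_mean`` / ``per_sequence_var`` hold the demographic-level
    moments for each sampled sequence; aggregates follow the law of total
    variance (population convention across sequences).
    """

    per_sequence_mean: np.ndarray
    per_sequence_var: np.ndarray
    n_sequences: int
    seed: int
    max_truncation_mass: float = 0.0

    @property
    def mean(self) -> float:
        """E_mu[E_P(tau_R)]: grand mean over both levels of randomness."""
        return float(self.per_sequence_mean.mean())

    @property
    def var_demographic(self) -> float:
        """E_mu[Var_P(tau_R)]: average within-sequence (demographic) variance."""
        return float(self.per_sequence_var.mean())

    @property
    def var_environmental(self) -> float:
        """Var_mu[E_P(tau_R)]: variance of the demographic mean across sequences."""
        return float(self.per_sequence_mean.var())

    @property
    def total_variance(self) -> float:
        return self.var_demographic + self.var_environmental

    @property
    def cv(self) -> float:
        if self.mean == 0:
            return float("nan")
        return float(np.sqrt(self.total_variance) / self.mean)


def ensemble_statistics(
    env: EnvironmentModel,
    v: np.ndarray,
    target: TargetSet,
    n_sequences: int = 2000,
    K: int = 2,
    eps: float = DEFAULT_EPS,
    n_max: int = DEFAULT_N_MAX,
    horizon: int | None = None,
) -> EnsembleResult:
    """Sample environment sequences and aggregate demographic-level moments.

    For each sampled matrix sequence the mean and variance of ``tau_R`` are
    computed **analytically** by the moment recursion — Monte Carlo enters
    only at the environmental level.  Default ensemble size is 2000
    sequences.
    """
    if n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    if K < 2:
        raise ValueError("K >= 2 needed for the variance decomposition")
    if horizon is None:
        horizon = env.default_horizon(eps=eps, n_max=n_max)
    seqs = sample_iid_environment(env, n_sequences, horizon=horizon)
    means = np.empty(n_sequences)
    variances = np.empty(n_sequences)
    worst_trunc = 0.0
    for r, seq in enumerate(seqs):
        model = StageModel(build_schedule(env.catalog, seq, tol=env.tol), v, tol=env.tol)
        res = occupancy_moments(model, target, K=K, eps=eps, n_max=n_max)
        means[r] = res.moments[1]
        variances[r] = res.variance
        worst_trunc = max(worst_trunc, res.truncation_mass)
    if worst_trunc > 1e-8:
        logger.warning("worst per-sequence truncation mass %.3g", worst_trunc)
    return EnsembleResult(
        per_sequence_mean=means,
        per_sequence_var=variances,
        n_sequences=n_sequences,
        seed=env.seed,
        max_truncation_mass=worst_trunc,
    )


def variance_decomposition(result: EnsembleResult) -> tuple[float, float, float]:
    """(demographic, environmental, total) variance components.

    The components sum to the pooled-moment total variance
    ``E_mu[E_P(tau_R^2)] - (E_mu[E_P(tau_R)])^2`` exactly (same samples,
    population convention).
    """
    return result.var_demographic, result.var_environmental, result.total_variance


def simplex_sweep(
    catalog: dict[str, np.ndarray],
    v: np.ndarray,
    target: TargetSet,
    step: float = 0.25,
    n_sequences: int = 2000,
    seed: int = 0,
    eps: float = DEFAULT_EPS,
    n_max: int = DEFAULT_N_MAX,
):
    """Ensemble statistics at every point of a probability-simplex grid.

    The catalog must have exactly three labels; the grid coordinates are
    assigned to the labels in catalog order.  Each grid point gets an
    independent seed derived from ``seed`` and the point index.  Returns a
    ``pandas.DataFrame`` with one row per grid point: the three selection
    probabilities, the grand mean, the two variance components, the total
    variance and the cv.
    """
    import pandas as pd

    labels = list(catalog)
    if len(labels) != 3:
        raise ValidationError(f"simplex sweep needs a 3-matrix catalog, got {labels}")
    rows = []
    for idx, triple in enumerate(simplex_grid(step)):
        env = EnvironmentModel(
            catalog=catalog, probs=dict(zip(labels, triple)), seed=seed + idx
        )
        res = ensemble_statistics(env, v, target, n_sequences=n_sequences,
                                  eps=eps, n_max=n_max)
        row = {f"P_{l}": p for l, p in zip(labels, triple)}
        row.update(
            mean=res.mean,
            var_demographic=res.var_demographic,
            var_environmental=res.var_environmental,
            total_variance=res.total_variance,
            cv=res.cv,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simplex_grid(step: float) -> list[tuple[float, float, float]]:
    """All nonnegative probability triples on a regular grid summing to 1.

    ``step`` must divide 1 (e.g. 0.25 gives 15 triples, 0.1 gives 66).
    Arithmetic is exact (fractions), so every triple sums to exactly 1.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    frac = Fraction(step).limit_denominator(10**6)
    n = Fraction(1) / frac
    if n.denominator != 1:
        raise ValueError(f"step {step} does not divide 1")
    n = int(n)
    grid = []
    for i in range(n + 1):
        for j in range(n - i + 1):
            a, b = i / n, j / n
            # 1 - (a + b) makes the left-to-right float sum exactly 1
            grid.append((a, b, 1.0 - (a + b)))
    return grid
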