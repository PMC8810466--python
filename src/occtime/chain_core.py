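"""Core domain types for absorbing stage-structured Markov chains.

A demographic model is specified by a sequence of column sub-stochastic
matrices ``B(0), B(1), ...``: entry ``B[i, j](n)`` is the probability that an
individual in stage ``j`` at time ``n`` is in stage ``i`` at time ``n + 1``.
Column-sum deficits are per-stage death probabilities, so death never needs to
appear as an explicit stage here.

Conventions (these differ from much row-oriented ecology software):

* state distributions are **column** vectors and evolve as
  ``x_{n+1} = B(n) x_n``;
* the transition operator ``Phi(n, m) = B(n-1) ... B(m)`` is an ordered
  left product, with the empty product ``Phi(m, m)`` taken as the identity;
* user-facing stages are 1-based (``S = {1, ..., d}``) with optional labels;
  internal arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-9

__all__ = [
    "DEFAULT_TOL",
    "ValidationError",
    "StageModel",
    "TargetSet",
    "AbsorptionVector",
    "MatrixSchedule",
    "validate_substochastic",
    "absorption_vector",
    "transition_operator",
    "extend_with_death",
    "survival_mass",
]


class ValidationError(ValueError):
    """A matrix, vector or configuration failed a model invariant."""


def validate_substochastic(M: np.ndarray, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Validate that ``M`` is a column sub-stochastic transition matrix.

    Entries must be nonnegative and every column sum must be at most
    ``1 + tol``.  Column sums in ``(1, 1 + tol]`` are accepted but the column
    is renormalised to sum to exactly 1 (and a warning logged) so that the
    implied death probability is never negative.

    Returns the validated (possibly renormalised) matrix as a float array.

    Raises
    ------
    ValidationError
        If ``M`` is not square, has a negative entry (the offending
        ``(row, col)`` is named) or a column sum exceeding ``1 + tol``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"transition matrix must be square, got shape {M.shape}")
    neg = np.argwhere(M < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative entry {M[i, j]!r} at (row={i + 1}, col={j + 1})"
        )
    sums = M.sum(axis=0)
    bad = np.flatnonzero(sums > 1.0 + tol)
    if bad.size:
        j = bad[0]
        raise ValidationError(
            f"column {j + 1} sums to {sums[j]!r} > 1 + tol (tol={tol!r})"
        )
    over = np.flatnonzero(sums > 1.0)
    if over.size:
        logger.warning(
            "columns %s sum to slightly more than 1 (within tol); renormalising",
            (over + 1).tolist(),
        )
        M = M.copy()
        M[:, over] /= sums[over]
    return M


@dataclass(frozen=True)
class AbsorptionVector:
    """Per-stage death probabilities ``b = 1 - column sums of B`` at one step."""

    b: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if np.any(b < 0) or np.any(b > 1):
            raise ValidationError("absorption probabilities must lie in [0, 1]")
        object.__setattr__(self, "b", b)


def absorption_vector(B: np.ndarray, tol: float = DEFAULT_TOL) -> AbsorptionVector:
    """Death probabilities ``b_j = 1 - sum_i B_ij`` for a validated matrix.

    Values within ``tol`` below zero (float noise from columns summing to
    exactly 1) are clipped to 0.
    """
    B = validate_substochastic(B, tol)
    b = 1.0 - B.sum(axis=0)
    b[(b < 0) & (b > -tol)] = 0.0
    return AbsorptionVector(b)


def extend_with_death(B: np.ndarray, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Extend ``B`` with an explicit absorbing death state.

    Returns the ``(d+1) x (d+1)`` column-stochastic matrix

    ``C = [[B, 0], [b^T, 1]]``

    whose last state is absorbing.  Every column of ``C`` sums to exactly 1.
    """
    B = validate_substochastic(B, tol)
    d = B.shape[0]
    b = absorption_vector(B, tol).b
    C = np.zeros((d + 1, d + 1))
    C[:d, :d] = B
    C[d, :d] = b
    C[d, d] = 1.0
    return C


class MatrixSchedule:
    """Ordered source of transition matrices ``B(n)`` for ``n = 0, 1, 2, ...``.

    A finite list of matrices is extended to all times either by repeating the
    last matrix (``extend="repeat-last"``, the default) or by cycling through
    the list (``extend="cycle"``).  Alternatively a callable ``n -> matrix``
    may be supplied for fully general time dependence.
    """

    def __init__(
        self,
        matrices: Sequence[np.ndarray] | Callable[[int], np.ndarray],
        extend: str = "repeat-last",
        tol: float = DEFAULT_TOL,
        labels: Sequence[str] | None = None,
    ) -> None:
        self.tol = tol
        self.labels = list(labels) if labels is not None else None
        if callable(matrices):
            self._fn = matrices
            self._mats = None
            self.d = validate_substochastic(matrices(0), tol).shape[0]
        else:
            mats = [validate_substochastic(M, tol) for M in matrices]
            if not mats:
                raise ValidationError("schedule must contain at least one matrix")
            dims = {M.shape[0] for M in mats}
            if len(dims) != 1:
                raise ValidationError(f"schedule matrices have mixed dimensions {sorted(dims)}")
            if extend not in ("repeat-last", "cycle"):
                raise ValidationError(f"unknown extension rule {extend!r}")
            self._fn = None
            self._mats = mats
            self.extend = extend
            self.d = mats[0].shape[0]

    def __call__(self, n: int) -> np.ndarray:
        if n < 0:
            raise ValueError("time index must be nonnegative")
        if self._fn is not None:
            return validate_substochastic(self._fn(n), self.tol)
        mats = self._mats
        if n < len(mats):
            return mats[n]
        if self.extend == "cycle":
            return mats[n % len(mats)]
        return mats[-1]


@dataclass
class StageModel:
    """A stage-structured absorbing chain: dimension, labels, schedule, start.

    Parameters
    ----------
    schedule
        A :class:`MatrixSchedule`, a single matrix (constant environment), or
        a list of matrices (extended per ``MatrixSchedule`` defaults).
    v
        Initial probability vector over the ``d`` transient stages;
        nonnegative, summing to 1 within ``tol``.
    labels
        Optional stage names, length ``d``.
    """

    schedule: MatrixSchedule
    v: np.ndarray
    labels: list[str] = field(default_factory=list)
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if isinstance(self.schedule, np.ndarray):
            self.schedule = MatrixSchedule([self.schedule], tol=self.tol)
        elif not isinstance(self.schedule, MatrixSchedule):
            self.schedule = MatrixSchedule(self.schedule, tol=self.tol)
        d = self.schedule.d
        v = np.asarray(self.v, dtype=float)
        if v.shape != (d,):
            raise ValidationError(f"initial vector has shape {v.shape}, expected ({d},)")
        if np.any(v < 0):
            raise ValidationError("initial vector has a negative entry")
        if abs(v.sum() - 1.0) > max(self.tol, 1e-9):
            raise ValidationError(f"initial vector sums to {v.sum()!r}, expected 1")
        self.v = v
        if not self.labels:
            self.labels = [f"stage{i + 1}" for i in range(d)]
        if len(self.labels) != d:
            raise ValidationError(f"{len(self.labels)} labels for {d} stages")

    @property
    def d(self) -> int:
        return self.schedule.d

    def B(self, n: int) -> np.ndarray:
        """Transition matrix in effect from time ``n`` to ``n + 1``."""
        return self.schedule(n)

    def b(self, n: int) -> np.ndarray:
        """Per-stage death probabilities at step ``n``."""
        return absorption_vector(self.B(n), self.tol).b

    def stage_index(self, stage: int | str) -> int:
        """0-based index for a 1-based stage number or a stage label."""
        if isinstance(stage, str):
            try:
                return self.labels.index(stage)
            except ValueError:
                raise ValidationError(
                    f"unknown stage {stage!r}; valid labels: {self.labels}"
                ) from None
        idx = int(stage) - 1
        if not 0 <= idx < self.d:
            raise ValidationError(f"stage number {stage} outside 1..{self.d}")
        return idx


@dataclass(frozen=True)
class TargetSet:
    """A subset ``R`` of the transient stages, as a boolean mask over stages."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 1:
            raise ValidationError("target mask must be a 1-d boolean vector")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_stages(cls, stages: Iterable[int | str], model: StageModel) -> "TargetSet":
        """Build from 1-based stage numbers or labels, resolved via ``model``."""
        mask = np.zeros(model.d, dtype=bool)
        for s in stages:
            mask[model.stage_index(s)] = True
        return cls(mask)

    @property
    def d(self) -> int:
        return self.mask.size

    @property
    def as_diagonal(self) -> np.ndarray:
        """The 0/1 diagonal matrix form of ``R``."""
        return np.diag(self.mask.astype(float))


def transition_operator(model: StageModel, n: int, m: int = 0) -> np.ndarray:
    """Ordered product ``Phi(n, m) = B(n-1) ... B(m)`` (identity when n == m).

    Element ``(i, j)`` is the probability of being in stage ``i`` at time
    ``n`` given stage ``j`` at time ``m``.
    """
    if m < 0 or n < m:
        raise ValueError(f"require n >= m >= 0, got n={n}, m={m}")
    Phi = np.eye(model.d)
    for k in range(m, n):
        Phi = model.B(k) @ Phi
    return Phi


def survival_mass(model: StageModel, n: int) -> float:
    """Probability of still being in a transient stage at time ``n``.

    Equals ``1^T Phi(n, 0) v``; nonincreasing in ``n``.
    """
    x = model.v.copy()
    for k in range(n):
        x = model.B(k) @ x
    return float(x.sum())
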