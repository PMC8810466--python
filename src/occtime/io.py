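"""File formats and run configuration.

Matrices travel as plain CSV, ``d`` rows by ``d`` columns, no header
required: row ``i`` / column ``j`` holds the probability of moving from stage
``j`` to stage ``i``.  A first row of stage labels is accepted.  Floats are
written with full ``repr`` precision so a write/read round trip is exact.

A run configuration (JSON or YAML — JSON is a YAML subset, one loader) names
the matrices, exactly one schedule specification (a label string, a constant
condition, or an i.i.d.-environment block), the initial stage or vector, the
target stages, and the numerical knobs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .chain_core import MatrixSchedule, StageModel, TargetSet, ValidationError, validate_substochastic
from .environments import EnvironmentModel, build_schedule
from .lifetime import DEFAULT_EPS, DEFAULT_N_MAX, LifetimeDistribution
from .occupancy import OccupancyResult

__all__ = ["RunConfig", "load_config", "read_matrix", "write_matrix", "write_results"]


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a transition matrix from CSV; an optional label header is skipped."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                rows.append([float(x) for x in row])
            except ValueError:
                if rows:
                    raise ValidationError(f"non-numeric row {row} in {path}")
                # header row of stage labels
    M = np.array(rows)
    return validate_substochastic(M)


def write_matrix(M: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    """Write a matrix as CSV with full float precision (round-trip exact)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if labels:
            w.writerow(labels)
        for row in np.asarray(M):
            w.writerow([repr(float(x)) for x in row])


@dataclass
class RunConfig:
    """Parsed run configuration; see :func:`load_config` for the file format."""

    matrices: dict[str, np.ndarray]
    schedule: dict[str, Any]
    initial: Any
    target: list[Any] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)
    extend: str = "repeat-last"
    K: int = 2
    eps: float = DEFAULT_EPS
    n_max: int = DEFAULT_N_MAX
    seed: int = 0
    n_sequences: int = 2000
    horizon: int | None = None

    def __post_init__(self) -> None:
        dims = {M.shape[0] for M in self.matrices.values()}
        if len(dims) > 1:
            raise ValidationError(f"matrices in one catalog have mixed dimensions {sorted(dims)}")
        spec_keys = {"labels", "constant", "iid"} & set(self.schedule)
        if len(spec_keys) != 1:
            raise ValidationError(
                "schedule must contain exactly one of 'labels', 'constant', 'iid'"
            )

    @property
    def d(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def initial_vector(self) -> np.ndarray:
        if isinstance(self.initial, (list, tuple, np.ndarray)):
            return np.asarray(self.initial, dtype=float)
        v = np.zeros(self.d)
        if isinstance(self.initial, str):
            if self.initial not in self.stages:
                raise ValidationError(
                    f"unknown initial stage {self.initial!r}; stages: {self.stages}"
                )
            v[self.stages.index(self.initial)] = 1.0
        else:
            v[int(self.initial) - 1] = 1.0
        return v

    def build_model(self) -> StageModel:
        """Resolve a deterministic schedule spec into a StageModel."""
        if "labels" in self.schedule:
            sched = build_schedule(self.matrices, self.schedule["labels"], extend=self.extend)
        elif "constant" in self.schedule:
            label = self.schedule["constant"]
            if label not in self.matrices:
                raise ValidationError(f"unknown matrix label {label!r}")
            sched = MatrixSchedule([self.matrices[label]])
        else:
            raise ValidationError("an 'iid' schedule needs build_environment(), not build_model()")
        return StageModel(sched, self.initial_vector(), labels=list(self.stages))

    def build_environment(self) -> EnvironmentModel:
        if "iid" not in self.schedule:
            raise ValidationError("schedule has no 'iid' block")
        block = self.schedule["iid"]
        return EnvironmentModel(
            catalog=self.matrices,
            probs=dict(block["probs"]),
            seed=int(block.get("seed", self.seed)),
            horizon=block.get("horizon", self.horizon),
        )

    def build_target(self, model: StageModel) -> TargetSet:
        if not self.target:
            raise ValidationError("config names no target stages")
        return TargetSet.from_stages(self.target, model)


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON/YAML run config; matrix entries may be paths or inline lists."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    matrices = {}
    for label, spec in raw.get("matrices", {}).items():
        if isinstance(spec, str):
            p = Path(spec)
            if not p.is_absolute():
                p = path.parent / p
            matrices[label] = read_matrix(p)
        else:
            matrices[label] = validate_substochastic(np.array(spec, dtype=float))
    kwargs = {
        k: raw[k]
        for k in ("schedule", "initial", "target", "stages", "extend", "K", "eps",
                  "n_max", "seed", "n_sequences", "horizon")
        if k in raw
    }
    return RunConfig(matrices=matrices, **kwargs)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_results(result: Any, path: str | Path) -> None:
    """Write a result object to disk.

    ``LifetimeDistribution`` and ``OccupancyResult`` pmfs go to a two-column
    CSV ``(n, probability)`` at ``<path>.csv`` with a JSON summary (moments
    and truncation diagnostics) at ``<path>.json``; other results (ensemble
    statistics, plain dicts) go to ``<path>.json`` alone.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".csv", ".json") else path
    summary: dict[str, Any]
    if isinstance(result, LifetimeDistribution):
        _write_pmf(base.with_suffix(".csv"), result.pmf, col="n")
        summary = {"truncation_mass": result.truncation_mass, "n_stop": result.n_stop}
    elif isinstance(result, OccupancyResult):
        if result.pmf is not None:
            _write_pmf(base.with_suffix(".csv"), result.pmf, col="a")
        summary = {
            "moments": {str(k): v for k, v in result.moments.items()},
            "mean": result.mean,
            "variance": result.variance,
            "cv": result.cv,
            "truncation_mass": result.truncation_mass,
            "n_stop": result.n_stop,
        }
    elif isinstance(result, dict):
        summary = result
    else:  # EnsembleResult and friends expose their statistics as properties
        summary = {
            "mean": result.mean,
            "var_demographic": result.var_demographic,
            "var_environmental": result.var_environmental,
            "total_variance": result.total_variance,
            "cv": result.cv,
            "n_sequences": result.n_sequences,
            "seed": result.seed,
            "max_truncation_mass": result.max_truncation_mass,
        }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")


def _write_pmf(path: Path, pmf: np.ndarray, col: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([col, "probability"])
        for n, p in enumerate(pmf):
            w.writerow([n, repr(float(p))])
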