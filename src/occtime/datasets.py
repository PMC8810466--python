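"""Bundled example data: the Southern Fulmar stage-structured model.

The Southern Fulmar is a long-lived Antarctic sea bird whose yearly
transitions among four life-cycle stages — Pre-breeder, Successful Breeder,
Failed Breeder, Non-breeder — depend on the sea-ice conditions of the year.
Three transition matrices correspond to favorable (``f``), ordinary (``o``)
and unfavorable (``u``) ice years; entry ``(i, j)`` is the probability of
moving from stage ``j`` to stage ``i`` over one year, and the column-sum
deficits are yearly death probabilities.

A breeding attempt is a year spent as Successful or Failed Breeder, so the
occupancy time of ``R = {Successful Breeder, Failed Breeder}`` counts the
breeding attempts over a bird's life.
"""

from __future__ import annotations

import numpy as np

from .chain_core import StageModel, TargetSet

__all__ = [
    "FULMAR_STAGES",
    "FULMAR_BREEDING_STAGES",
    "fulmar_matrices",
    "fulmar_model",
    "fulmar_breeding_target",
]

FULMAR_STAGES = ["Pre-breeder", "Successful Breeder", "Failed Breeder", "Non-breeder"]

FULMAR_BREEDING_STAGES = ["Successful Breeder", "Failed Breeder"]

_U_F = [
    [0.828, 0.0, 0.0, 0.0],
    [0.06624, 0.72912, 0.62244, 0.40176],
    [0.02576, 0.18228, 0.24206, 0.15624],
    [0.0, 0.0186, 0.0455, 0.342],
]

_U_O = [
    [0.9016, 0.0, 0.0, 0.0],
    [0.011408, 0.66737, 0.49312, 0.1809],
    [0.006992, 0.18823, 0.24288, 0.0891],
    [0.0, 0.0744, 0.184, 0.63],
]

_U_U = [
    [0.9154, 0.0, 0.0, 0.0],
    [0.002392, 0.4873, 0.25147, 0.0468],
    [0.002208, 0.1895, 0.23213, 0.0432],
    [0.0, 0.2632, 0.4464, 0.81],
]


def fulmar_matrices() -> dict[str, np.ndarray]:
    """The three ice-condition transition matrices keyed ``f`` / ``o`` / ``u``."""
    return {
        "f": np.array(_U_F),
        "o": np.array(_U_O),
        "u": np.array(_U_U),
    }


def fulmar_model(condition: str = "o", start: str = "Pre-breeder") -> StageModel:
    """A constant-environment fulmar model under one ice condition.

    ``start`` names the stage carrying all initial probability.
    """
    mats = fulmar_matrices()
    if condition not in mats:
        raise ValueError(f"condition must be one of {sorted(mats)}, got {condition!r}")
    v = np.zeros(4)
    v[FULMAR_STAGES.index(start)] = 1.0
    return StageModel(mats[condition], v, labels=list(FULMAR_STAGES))


def fulmar_breeding_target(model: StageModel | None = None) -> TargetSet:
    """Target set for breeding attempts: Successful + Failed Breeder."""
    if model is None:
        model = fulmar_model()
    return TargetSet.from_stages(FULMAR_BREEDING_STAGES, model)
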