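import numpy as np
import pytest

from occtime.chain_core import MatrixSchedule, StageModel, TargetSet


@pytest.fixture
def geometric_model():
    """One transient state with survival 0.5: lifetime is geometric(1/2)."""
    return StageModel(np.array([[0.5]]), np.array([1.0]))


@pytest.fixture
def forced_chain():
    """Deterministic 2-state chain: 1 -> 2 -> death; tau_{2} = 1, N = 2."""
    model = StageModel(np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([1.0, 0.0]))
    target = TargetSet(np.array([False, True]))
    return model, target


@pytest.fixture
def drift_chain():
    """2-state chain [[0.5,0],[0.5,0.5]] started in 1; occupancy of {1} is
    geometric because state 1 is left (by death or transition) w.p. 1/2."""
    model = StageModel(
        np.array([[0.5, 0.0], [0.5, 0.5]]), np.array([1.0, 0.0])
    )
    return model, TargetSet(np.array([True, False]))


@pytest.fixture
def fulmar_ordinary():
    from occtime.datasets import fulmar_breeding_target, fulmar_model

    model = fulmar_model("o", start="Pre-breeder")
    return model, fulmar_breeding_target(model)
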