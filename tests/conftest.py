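import numpy as np
import pytest

from ihas import assoc
from ihas.quantize import encode_discrete


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hard_target(states: np.ndarray) -> np.ndarray:
    """Point-mass trinary posteriors from states in {-1, 0, +1}."""
    states = np.asarray(states, dtype=int)
    probs = np.zeros((states.size, 3))
    probs[np.arange(states.size), states + 1] = 1.0
    return probs


def mutation_effector(codes: np.ndarray, eid: str = "e", direction: str = "+") -> assoc.Effector:
    return assoc.Effector(eid, "mutation", direction, encode_discrete(codes, "mutation"))
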