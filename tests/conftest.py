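import numpy as np
import pytest

from ptemark.hypnogram import Hypnogram, Phase, Stage

S = {"W": Stage.W, "N2": Stage.N2, "N3": Stage.N3, "REM": Stage.REM}


def make_hyp(stage_str, phase=None, animal_id="a", epoch_length_s=30.0):
    """Build a hypnogram from 'W N2 N3 REM ...'; single-phase by default."""
    stages = tuple(S[t] for t in stage_str.split())
    if phase is None:
        phases = tuple(Phase.LIGHTS_ON for _ in stages)
    else:
        phases = tuple(
            Phase.LIGHTS_ON if c == "n" else Phase.LIGHTS_OFF for c in phase.split()
        )
    return Hypnogram(animal_id=animal_id, stages=stages, phase=phases,
                     epoch_length_s=epoch_length_s)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hypnogram(rng):
    """1000 uniformly random epochs, 12 h/12 h phase split irrelevant."""
    stages = tuple(list(Stage)[i] for i in rng.integers(0, 4, size=1000))
    phases = tuple(
        Phase.LIGHTS_ON if i < 500 else Phase.LIGHTS_OFF for i in range(1000)
    )
    return Hypnogram(animal_id="rand", stages=stages, phase=phases)
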