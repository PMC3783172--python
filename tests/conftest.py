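import numpy as np
import pytest

from crescan.motifs import PWM
from crescan.simulate import generate_promoters, isre_like_pwm, plant_motifs


@pytest.fixture
def isre() -> PWM:
    return isre_like_pwm()


@pytest.fixture
def sharp_pwm() -> PWM:
    """A 3-position matrix with hand-computable scores."""
    return PWM(
        matrix_id="V$TOY_01",
        counts=np.array([[10.0, 0, 0, 0], [5.0, 5, 0, 0], [0, 0, 0, 10.0]]),
    )


@pytest.fixture
def planted_promoters(isre):
    """50 promoters with exact-consensus plants and the manifest."""
    proms = generate_promoters(50, seed=101)
    return plant_motifs(proms, isre, lam=1.0, seed=102, consensus_only=True)
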