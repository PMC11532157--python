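import numpy as np
import pytest

from psmcea import base_case_config
from psmcea.survival import Family, ParametricSurvival

#: one representative, hand-picked parameter set per family (months scale)
FAMILY_EXAMPLES = {
    Family.EXPONENTIAL: (0.08,),
    Family.WEIBULL: (1.4, 18.0),
    Family.GOMPERTZ: (0.05, 0.02),
    Family.LOGNORMAL: (2.6, 0.8),
    Family.LOGLOGISTIC: (1.74, 0.0079),
    Family.GAMMA: (1.8, 0.09),
}


@pytest.fixture
def example_models():
    return {f: ParametricSurvival(f, p) for f, p in FAMILY_EXAMPLES.items()}


@pytest.fixture
def base_inputs():
    """Fresh copy of the published base-case inputs."""
    return base_case_config()


@pytest.fixture
def atezo_curves(base_inputs):
    return base_inputs.intervention.pfs, base_inputs.intervention.os


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)
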