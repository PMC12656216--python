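import numpy as np
import pytest

from wqsmix.simulate import EffectTruth, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A reference-sized cohort with no index effects."""
    return generate_cohort(n=201, truth=EffectTruth(), seed=1)


@pytest.fixture(scope="session")
def toxic_signal_truth():
    """Strong negative toxic-index effect driven by Cd and Sb."""
    return EffectTruth(
        weights_toxic=(0.05, 0.5, 0.3, 0.05, 0.05, 0.05),  # As,Cd,Sb,Hg,Pb,Ni
        beta1_tox=-1.0,
        resid_sd=5.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
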