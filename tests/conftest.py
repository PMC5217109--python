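import pytest

from dsbfoot.locus import FAUI, PSTI
from dsbfoot.simulate import synthetic_locus


@pytest.fixture(scope="session")
def cru_locus():
    """PstI-cut synthetic stand-in for the cruciferin-target amplicon."""
    return synthetic_locus("CRU3syn", PSTI, seed=7)


@pytest.fixture(scope="session")
def ppo_locus():
    """FauI-cut synthetic stand-in for the PPO-target amplicon."""
    return synthetic_locus("PPOsyn", FAUI, seed=8)
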