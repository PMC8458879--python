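import numpy as np
import pytest

from cernamut.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with four planted units (one per state) and four
    planted expression drivers."""
    return generate_cohort(
        SimConfig(
            n_samples=60,
            n_genes=80,
            n_lncrnas=4,
            n_mirnas=4,
            n_drivers=4,
            mre_modes=("gain", "up", "loss", "down"),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """Default-condition cohort (180 samples, 12 planted units)."""
    return generate_cohort(SimConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
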