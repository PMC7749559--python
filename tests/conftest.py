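import dataclasses

import numpy as np
import pytest

from heavywater.mida import natural_isotopomer_distribution
from heavywater.simulate import LabelingProtocol, NoiseModel, default_groups, simulate_cohort


@pytest.fixture(scope="session")
def natural_dist():
    return natural_isotopomer_distribution()

@pytest.fixture(scope="session")
def protocol():
    return LabelingProtocol()


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel(isotopomer_sd=0.0, isotopomer_cv=0.0, pool_marker_cv=0.0, ct_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noise_free_cohort(zero_noise):
    """Small noise-free 2x2 cohort with the published planted rate constants."""
    groups = [dataclasses.replace(g, n_animals=3) for g in default_groups()]
    return simulate_cohort(groups, noise=zero_noise, n_fibers=20)
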