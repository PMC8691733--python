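import numpy as np
import pytest

import mcisvm as m


@pytest.fixture(scope="session")
def small_atlas():
    return m.make_atlas((10, 10, 10), n_parcels=8, n_networks=3, seed=7)


@pytest.fixture(scope="session")
def null_cohort(small_atlas):
    """Zero planted effects: classes exchangeable on every feature."""
    effects = m.EffectSpec(seed=11)
    return m.simulate_cohort(small_atlas, n_stable=14, n_decline=7, T=40, effects=effects)


@pytest.fixture(scope="session")
def planted_cohort(small_atlas):
    """Strong structural effect in parcels 1 and 2."""
    effects = m.EffectSpec(
        t1_effect_parcels=(1, 2), t1_effect_size=3.0, noise_sd=1.0, seed=13
    )
    return m.simulate_cohort(small_atlas, n_stable=14, n_decline=7, T=40, effects=effects)


@pytest.fixture(scope="session")
def null_features(null_cohort, small_atlas):
    return m.assemble_features(null_cohort, small_atlas)


@pytest.fixture(scope="session")
def planted_features(planted_cohort, small_atlas):
    return m.assemble_features(planted_cohort, small_atlas)


@pytest.fixture
def labels(null_cohort):
    return np.array([s.label for s in null_cohort])
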