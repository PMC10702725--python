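import numpy as np
import pytest

from bvfusion import CohortSpec, build_feature_sets, generate_cohort


@pytest.fixture(scope="session")
def effect_spec():
    """Small cohort with all three planted effects on ROIs 0-2."""
    return CohortSpec(
        n_per_group=12,
        n_timepoints=80,
        n_rois=10,
        affected_rois=(0, 1, 2),
        mean_shift=2.0,
        var_ratio=2.0,
        osc_amplitude_delta=1.5,
        osc_freq=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_spec):
    return generate_cohort(effect_spec)


@pytest.fixture(scope="session")
def effect_features(effect_cohort):
    return build_feature_sets(effect_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
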