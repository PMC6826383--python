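import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from budscreen import (
    CohortSimSpec,
    MorphologySpec,
    SubsetScreen,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 14-patient cohort (4 events, 2 small images each) for API tests."""
    spec = CohortSimSpec(
        n_patients=14,
        n_events=4,
        images_per_patient=2,
        baseline_mean_count=8.0,
        speck_rate_mean=10.0,
        fragment_rate_mean=12.0,
        cluster_rate_mean=2.0,
        morphology=MorphologySpec(shape=(112, 112)),
    )
    return generate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def small_screen(small_cohort):
    """A fitted small screen over a reduced grid."""
    from budscreen.screening import enumerate_grid

    grid = enumerate_grid(
        binarizations=(250, "auto"),
        circularity_mins=(0.0, 0.8),
        size_mins=(10, 20),
    )
    model = SubsetScreen(
        small_cohort.table, small_cohort.images, grid=grid, bootstrap_B=50
    )
    return model, model.fit(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
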