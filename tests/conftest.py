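import pytest

from popgcn.benchmark import make_splits
from popgcn.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small clinical-dominant cohort: published clinical moments, imaging
    features with heavy NC/MCI overlap (centroid gap 0.5 SD) and a separable
    AD cloud (gap 2 SD)."""
    spec = CohortSpec(
        n_per_class=(20, 40, 60), seed=7, latent_dim=16,
        separation=1.0, noise_sd=1.0, volume_shape=(8, 8, 8),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_plan(small_cohort):
    return make_splits(small_cohort.labels, outer_k=5, inner_k=4, seed=0)


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort whose imaging features alone are nearly linearly separable."""
    spec = CohortSpec(
        n_per_class=(15, 15, 15), seed=3, latent_dim=8,
        separation=6.0, noise_sd=1.0, volume_shape=(8, 8, 8),
    )
    return generate_cohort(spec)
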