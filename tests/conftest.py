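import numpy as np
import pytest

from hipposcn.synthgen import SynthConfig, generate_cohort


def small_config(**kw) -> SynthConfig:
    """A fast cohort configuration on a coarse 3 mm lattice."""
    defaults = dict(
        grid_shape=(12, 16, 12),
        voxel_size_mm=3.0,
        n_subjects=60,
        rng_seed=123,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def planted_cohort():
    """A cohort with the default planted structure at n = 100."""
    return generate_cohort(small_config(n_subjects=100, rng_seed=7))


def seed_table_and_matrix(cohort, exclude_seed_voxels=False):
    """Seed mean densities and the flattened cohort matrix, straight
    from the truth regions (bypasses the template stage on purpose)."""
    reg = cohort.truth["_regions"]
    ant = np.array([im.data[reg["anterior_seed"]].mean()
                    for im in cohort.gm_images])
    post = np.array([im.data[reg["posterior_seed"]].mean()
                     for im in cohort.gm_images])
    if exclude_seed_voxels:
        keep = ~(reg["anterior_seed"] | reg["posterior_seed"])
        X = np.array([im.data[keep] for im in cohort.gm_images])
    else:
        X = np.array([im.data.ravel() for im in cohort.gm_images])
    return np.column_stack([ant, post]), X
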