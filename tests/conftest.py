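import numpy as np
import pytest

from paintransfer import CohortConfig, PipelineConfig, Region, analyze_cohort


def small_regions():
    """Four disjoint 8-voxel blocks on a 6x6x6 grid."""
    def block(x0, y0, z0):
        ix, iy, iz = np.meshgrid(
            np.arange(x0, x0 + 2), np.arange(y0, y0 + 2), np.arange(z0, z0 + 2),
            indexing="ij",
        )
        return np.ravel_multi_index((ix.ravel(), iy.ravel(), iz.ravel()), (6, 6, 6))

    return [
        Region("pos-a", block(0, 0, 0), "positive"),
        Region("pos-b", block(3, 0, 0), "positive"),
        Region("neg", block(0, 3, 0), "negative"),
        Region("het", block(3, 3, 3), "sign_heterogeneous"),
    ]


@pytest.fixture
def small_cfg():
    """Fast 6-individual cohort on a 6^3 grid."""
    return CohortConfig(
        n_individuals=6, grid_shape=(6, 6, 6), regions=small_regions(), seed=7
    )


@pytest.fixture
def homogeneous_cfg():
    """All heterogeneity and noise off; no sign-flipping region, so every
    individual's data is identical."""
    regs = [r for r in small_regions() if r.polarity != "sign_heterogeneous"]
    return CohortConfig(
        n_individuals=4, grid_shape=(6, 6, 6), regions=regs,
        sensitivity_mean_sd=(1.0, 0.0), slope_mean_sd=(1.6, 0.0),
        gain_sd=0.0, rating_noise_sd=0.0, bold_noise_sd=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def default_run():
    """One full analysis of the default 30-individual cohort, shared across
    tests that only read from it."""
    return analyze_cohort(PipelineConfig(cohort=CohortConfig(seed=123)))
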