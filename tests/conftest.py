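import numpy as np
import pandas as pd
import pytest

from rcstroke.simulate import CohortConfig, make_synthetic_atlas, simulate_cohort


@pytest.fixture(scope="session")
def cohort344() -> pd.DataFrame:
    """One synthetic cohort at the study's sample size."""
    return simulate_cohort(CohortConfig(n=344, seed=0))


@pytest.fixture(scope="session")
def big_covariates() -> pd.DataFrame:
    """Large covariate sample for moment/calibration checks."""
    from rcstroke.simulate import sample_covariates

    return sample_covariates(CohortConfig(n=100_000, seed=1))


@pytest.fixture(scope="session")
def atlas():
    return make_synthetic_atlas(seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def simulate_ordinal(rng, n, beta, thresholds, levels=None):
    """Minimal proportional-odds sampler used as an independent test oracle
    (deliberately separate from the package's generator)."""
    p = len(beta)
    X = rng.standard_normal((n, p))
    eta = X @ np.asarray(beta)
    th = np.asarray(thresholds, dtype=float)
    cdf = 1.0 / (1.0 + np.exp(-(th[None, :] - eta[:, None])))
    y_idx = (rng.random(n)[:, None] > cdf).sum(axis=1)
    if levels is None:
        return y_idx, X
    return np.asarray(levels)[y_idx], X
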