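import numpy as np
import pandas as pd
import pytest

from phiec.frrf import FRRfAcquisition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def acquisition():
    """A physically ordinary acquisition with moderate quenching."""
    return FRRfAcquisition(
        F0=0.30, Fm=1.00, F0p=0.28, Fp=0.60, Fmp=0.90,
        sigma_psii=450.0, sigma_psii_p=420.0, E=150.0,
    )


def random_acquisition(rng, no_npq=False):
    """Draw a valid acquisition; with no_npq light yields equal dark yields."""
    Fm = rng.uniform(0.5, 2.0)
    fvfm = rng.uniform(0.2, 0.75)
    F0 = Fm * (1 - fvfm)
    sigma = rng.uniform(200.0, 1000.0)
    if no_npq:
        Fmp, F0p, sigma_p = Fm, F0, sigma
    else:
        q = rng.uniform(0.6, 1.0)
        Fmp, F0p, sigma_p = Fm * q, F0 * q, sigma * rng.uniform(0.7, 1.0)
    Fp = rng.uniform(F0p, Fmp)
    return FRRfAcquisition(
        F0=F0, Fm=Fm, F0p=F0p, Fp=Fp, Fmp=Fmp,
        sigma_psii=sigma, sigma_psii_p=sigma_p, E=rng.uniform(0.0, 1500.0),
    )


@pytest.fixture
def env_table(rng):
    """Small two-cluster environmental table with a phi response."""
    n = 12
    a = rng.normal([5, 30, 4], [0.5, 0.5, 0.5], size=(n, 3))
    b = rng.normal([20, 36, 0.3], [0.5, 0.5, 0.1], size=(n, 3))
    df = pd.DataFrame(
        np.vstack([a, b]), columns=["temperature", "salinity", "NO3"],
        index=[f"s{i}" for i in range(2 * n)],
    )
    df["phi_ec"] = 0.4 * df["temperature"] + 2.0 + rng.normal(0, 0.1, 2 * n)
    return df
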