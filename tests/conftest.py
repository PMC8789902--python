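import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from edna_occupancy import (
    CovariateSpec,
    GenParams,
    ModelConfig,
    fit,
    simulate_survey,
)

# posterior means reported for the national survey; used as generating truth
FITTED = dict(psi=0.198, theta11=0.948, theta10=0.015, p11=0.808, p10=0.020)


@pytest.fixture(scope="session")
def fitted_values():
    return dict(FITTED)


@pytest.fixture(scope="session")
def small_survey():
    """A small covariate-driven survey shared across tests."""
    params = GenParams(
        S=400, M=1, K=12, theta11=FITTED["theta11"], theta10=FITTED["theta10"],
        p11=FITTED["p11"], p10=FITTED["p10"],
        occupancy_spec=(np.array([-1.2, 0.8, -0.5, 0.0, 0.4, -0.3]),
                        CovariateSpec(n_continuous=3,
                                      categorical={"landcover": [0.6, 0.3, 0.1]})),
        seed=42,
    )
    return simulate_survey(params)


@pytest.fixture(scope="session")
def small_fit(small_survey):
    """A short covariate fit reused by posterior-summary and GOF tests."""
    cfg = ModelConfig(n_burn=400, n_iter=600, n_thinned_draws=200, seed=3)
    return fit(small_survey.detection, design=small_survey.design, config=cfg)


@pytest.fixture()
def tiny_detection():
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(5)],
        "sample_id": "a",
        "k_replicates": 12,
        "y_positive": [0, 1, 2, 3, 12],
    })
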