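import numpy as np
import pandas as pd
import pytest

from vonet.synthetic_data import generate_observations, make_toy_system, toy_truth


@pytest.fixture(scope="session")
def chain_system():
    """Toy VO system (chain variant) shared across tests."""
    system, toy = make_toy_system("chain")
    return system, toy


@pytest.fixture(scope="session")
def truth():
    return toy_truth()


@pytest.fixture(scope="session")
def toy_observations(chain_system, truth):
    system, _ = chain_system
    rng = np.random.default_rng(11)
    return generate_observations(
        truth, system, timepoints=(0.25, 0.5, 1.0, 2.0, 4.0), n_studies=2, rng=rng
    )


@pytest.fixture(scope="session")
def toy_posterior():
    """Synthetic stand-in posterior ensemble around the toy truth.

    Emulates a calibrated parameter PDF for forward-simulation tests that
    do not themselves exercise the MCMC machinery.
    """
    rng = np.random.default_rng(2024)
    rows = [
        {
            "w_ago0": float(np.clip(rng.normal(0.12, 0.02), 0.01, 0.4)),
            "w_background": float(np.clip(rng.normal(0.08, 0.02), 0.01, 0.4)),
            "cmyo": float(np.clip(rng.normal(5.86, 1.38), 0.5, 20.0)),
        }
        for _ in range(50)
    ]
    return pd.DataFrame(rows)
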