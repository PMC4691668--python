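import logging

import numpy as np
import pytest

import mrpipe as mp


@pytest.fixture(autouse=True)
def _quiet_logs():
    # estimator-level warnings (weak instrument etc.) are exercised explicitly
    # where tested; keep bulk simulations quiet
    logger = logging.getLogger("mrpipe")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture(scope="session")
def default_cohort():
    return mp.simulate_cohort(mp.CohortConfig(seed=42))


def random_cohort(rng: np.random.Generator, n: int = 300):
    """Small ad-hoc instrument/exposure/outcome triple for oracle checks."""
    g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    x = rng.uniform(0.2, 0.8) * g + rng.standard_normal(n)
    y = rng.uniform(-1, 1) * x + rng.standard_normal(n)
    return g, x, y


def random_panel(rng: np.random.Generator, k: int = 12):
    import pandas as pd

    x = rng.uniform(0.03, 0.3, k)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(k)],
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "beta_exp": x,
            "se_exp": rng.uniform(0.005, 0.02, k),
            "beta_out": rng.normal(0.5 * x, 0.1),
            "se_out": rng.uniform(0.05, 0.2, k),
            "gene": [f"G{i}" for i in range(k)],
        }
    )
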