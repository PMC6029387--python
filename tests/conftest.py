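import numpy as np
import pandas as pd
import pytest

from nadirpath import GrowthSimParams, generate_newborns

PRINTED_BETA = np.array([3241.442, -9.378, 0.119, -0.0004])


def cubic(beta, t):
    t = np.asarray(t, dtype=float)
    return beta[0] + beta[1] * t + beta[2] * t**2 + beta[3] * t**3


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-newborn synthetic cohort with its truth table."""
    return generate_newborns(GrowthSimParams(n_newborns=400, seed=11))


@pytest.fixture(scope="session")
def noise_free_records():
    """Newborns lying exactly on the population cubic (no random effects,
    no measurement error)."""
    rng = np.random.default_rng(5)
    n = 150
    t = rng.uniform(6.3, 96.0, n)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "birthweight": np.full(n, cubic(PRINTED_BETA, 0.0)),
            "meas_time": t,
            "meas_weight": cubic(PRINTED_BETA, t),
        }
    )


@pytest.fixture(scope="session")
def complete_path_data():
    """Complete-case z-scale analysis table with known tracking 0.725."""
    from nadirpath import simulate_path_cohort

    return simulate_path_cohort("waist", 312, seed=42)
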