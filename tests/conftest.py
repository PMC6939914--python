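import numpy as np
import pandas as pd
import pytest

from recolonize.simulate import (
    IndividualSimParams,
    TrajectoryParams,
    default_layout,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """6 plots, 30 months, change at month 10 — cheap end-to-end runs."""
    return default_layout(
        n_control=2, n_kr_plus=2, n_rodent_plus=2, n_months=30, change_month=10
    )


@pytest.fixture(scope="session")
def kr_trajectory():
    return TrajectoryParams()


@pytest.fixture(scope="session")
def two_strata_params():
    """Simple two-stratum parameter set for multistate tests."""
    Psi = pd.DataFrame(
        [[0.8, 0.2], [0.3, 0.7]], index=["A", "B"], columns=["A", "B"]
    )
    return IndividualSimParams(
        S_by_stratum={"A": 0.9, "B": 0.5},
        p_by_stratum={"A": 0.5, "B": 0.5},
        Psi=Psi,
    )


def poisson_sine_frame(seed: int = 0, n: int = 200) -> pd.DataFrame:
    """Counts from log mu(t) = 1 + sin(2 pi t / 12) over one period."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 12.0, n)
    truth = 1.0 + np.sin(2.0 * np.pi * t / 12.0)
    y = rng.poisson(np.exp(truth))
    return pd.DataFrame({"response": y, "time": t, "truth": truth})
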