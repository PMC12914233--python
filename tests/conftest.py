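import numpy as np
import pandas as pd
import pytest

import trustdelay as td


@pytest.fixture(scope="session")
def default_population() -> pd.DataFrame:
    """The default calibrated survey sample (n=2460, seed 1)."""
    return td.generate_population(td.GeneratorConfig())


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A smaller sample for cheap structural tests."""
    return td.generate_population(
        td.GeneratorConfig(n_respondents=500, seed=3))


@pytest.fixture(scope="session")
def delay_model(default_population) -> td.LogisticFit:
    """The agents' three-predictor delay model on the 1-5 scale."""
    return td.published_delay_model(default_population)


def constant_risk_model(n_obs: int, risk: float) -> td.LogisticFit:
    """A delay model predicting the same probability for every agent."""
    from scipy.special import logit
    return td.LogisticFit(
        outcome="delay", predictors=["trust", "frequency", "chronic"],
        coefficients=np.array([logit(risk), 0.0, 0.0, 0.0]),
        standard_errors=np.full(4, np.nan), n_obs=n_obs, converged=True)


def records_from_arrays(trust, frequency, chronic, **extra) -> pd.DataFrame:
    """Minimal survey table with the agent-relevant columns."""
    n = len(trust)
    df = pd.DataFrame({
        "id": np.arange(n),
        "trust": trust,
        "frequency": frequency,
        "chronic": chronic,
    })
    for k, v in extra.items():
        df[k] = v
    return df
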