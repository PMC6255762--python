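import numpy as np
import pandas as pd
import pytest

from feverseek import (
    FeverTreatmentModel,
    McmcConfig,
    TrueParameters,
)

#: generative truth used across recovery-style tests
RECOVERY_TRUTH = TrueParameters(
    a=1.0, b=0.0, c=0.2, alpha=0.5, beta_time=-0.01, beta_urban=0.0,
    fever_prevalence=1.0, missing_rate=0.0,
)


def simulate_fever_frame(seed: int, n: int,
                         truth: TrueParameters = RECOVERY_TRUTH) -> pd.DataFrame:
    """Analysis table of n fever cases with travel times uniform on [0, 240]
    minutes, rural residence, responses drawn from the 3PL truth."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 240.0, n)
    p = truth.response_probability(t, 0)
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"y": y, "travel_time_min": t, "urban": 0})


@pytest.fixture(scope="session")
def recovered_fit():
    """One moderately sized fit against known truth, shared across tests that
    need a realistic posterior (curves, validation, distance decay)."""
    frame = simulate_fever_frame(seed=42, n=3000)
    model = FeverTreatmentModel(frame, fix={"beta_urban": 0.0})
    config = McmcConfig(n_iterations=14_000, burn_in=2_000, thinning=6,
                        n_chains=2, seed=3)
    return model.fit(config)
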