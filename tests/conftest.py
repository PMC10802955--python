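import numpy as np
import pandas as pd
import pytest

from mcibench.datagen import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear_cohort(n, beta, seed, censor=True):
    """Small two-covariate exponential cohort for model unit tests."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, size=n).astype(float)
    eta = beta[0] * x1 + beta[1] * x2
    t_event = -np.log(rng.uniform(size=n)) / np.exp(eta)
    if censor:
        t_cens = np.maximum(0.0, rng.normal(2.0, 3.611, size=n))
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    feats = pd.DataFrame({"AGE": 70.0 + 10.0 * x1, "MEMORY": x2})
    return SurvivalDataset(feats, time, event, true_event_time=t_event)
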