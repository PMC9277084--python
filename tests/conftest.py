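import numpy as np
import pandas as pd
import pytest

import psmcea as P


@pytest.fixture(scope="session")
def cfg():
    return P.default_config(seed=2022)


@pytest.fixture(scope="session")
def curves(cfg):
    return P.build_curves(cfg)


@pytest.fixture(scope="session")
def base_result(cfg, curves):
    res, breakdowns = P.evaluate(cfg, curves)
    return res, breakdowns


@pytest.fixture()
def toy_ipd():
    """Five subjects, alternating events/censorings at times 1..5 days."""
    return pd.DataFrame(
        {
            "time_days": [1.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 0, 1, 0, 1],
            "arm": "toy",
            "endpoint": "OS",
        }
    )


@pytest.fixture()
def mixed_ipd():
    """20 records with distinct times, mixed events, for estimator checks."""
    rng = np.random.default_rng(42)
    t = np.sort(rng.uniform(1, 300, 20))
    e = rng.integers(0, 2, 20)
    e[-1] = 1
    return pd.DataFrame({"time_days": t, "event": e, "arm": "mix", "endpoint": "OS"})
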