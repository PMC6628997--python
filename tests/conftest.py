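import numpy as np
import pandas as pd
import pytest

import placlock as pl


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset shared across read-only tests."""
    cfg = pl.SimConfig(n_samples=120, n_probes=300, n_clock_probes=20,
                       slope_range=(0.005, 0.02), ga_range=(6, 42),
                       noise_precision=50, seed=11)
    return pl.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def presets():
    return pl.standard_scenarios()


@pytest.fixture
def tiny_beta():
    return pl.BetaMatrix(np.array([[0.1, 0.9], [0.5, 0.5]]),
                         sample_ids=["s1", "s2"], probe_ids=["cg1", "cg2"])


def make_sheet(sample_ids, ga=None, sex=None, condition=None):
    n = len(sample_ids)
    return pl.SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "ga_weeks": ga if ga is not None else np.linspace(10, 40, n),
        "sex": sex if sex is not None else ["female"] * n,
        "condition": condition if condition is not None else ["control"] * n,
    }))
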