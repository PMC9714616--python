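import numpy as np
import pandas as pd
import pytest

import riskscreen as rs


@pytest.fixture(scope="session")
def default_params():
    return rs.SimParams(seed=42)


@pytest.fixture(scope="session")
def planted_world(default_params):
    """One full synthetic world at the default study conditions, seed 42."""
    cohorts, truth = rs.simulate_cohorts(default_params)
    survival = rs.simulate_survival(truth, default_params)
    ct = rs.simulate_ct(truth, default_params)
    return dict(params=default_params, cohorts=cohorts, truth=truth,
                survival=survival, ct=ct)


@pytest.fixture
def toy_expression():
    """3 genes x 4 samples, 2 tumor + 2 normal."""
    values = pd.DataFrame(
        [[5.0, 6.0, 1.0, 2.0],
         [2.0, 2.5, 2.1, 2.4],
         [1.0, 1.5, 7.0, 8.0]],
        index=["GA", "GB", "GC"],
        columns=["t1", "t2", "n1", "n2"],
    )
    group = {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"}
    return rs.ExpressionDataset("toy", values, group)


def make_records(times, events, expr=None):
    expr = expr or [{} for _ in times]
    return [
        rs.SurvivalRecord(f"p{i}", float(t), int(e), dict(x))
        for i, (t, e, x) in enumerate(zip(times, events, expr))
    ]
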