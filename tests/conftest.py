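import numpy as np
import pandas as pd
import pytest

from repwp.data import EventHistory


def make_history(rows, covariates=("x1",), time_scale="gap"):
    """Build a small EventHistory from (id, k, start, stop, status, A, x...) tuples."""
    cols = ["id", "k", "start", "stop", "status", "treatment", *covariates]
    df = pd.DataFrame(rows, columns=cols)
    return EventHistory(df, time_scale=time_scale)


def random_history(rng, n_subjects=10, max_events=3, p_cov=1):
    """Random valid gap-scale history for property tests."""
    rows = []
    for i in range(n_subjects):
        a = int(rng.integers(0, 2))
        x = rng.normal(size=p_cov)
        for k in range(1, max_events + 1):
            gap = float(rng.exponential(2.0) + 0.05)
            status = int(rng.integers(0, 2)) if k < max_events else 0
            rows.append((i, k, 0.0, gap, status, a, *x))
            if status == 0:
                break
    cols = ["id", "k", "start", "stop", "status", "treatment"] + [
        f"x{j+1}" for j in range(p_cov)
    ]
    return EventHistory(pd.DataFrame(rows, columns=cols), time_scale="gap")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bladder():
    from repwp.data import load_bladder_fixture

    return load_bladder_fixture()
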