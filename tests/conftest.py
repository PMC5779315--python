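import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stmbound import (
    ExperimentDesign,
    GenerativeModel,
    generate_dataset,
    performance_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Three subjects, fixed 4 blocks: fast but structurally complete."""
    return ExperimentDesign(n_subjects=3, blocks_min=4, blocks_max=4)


@pytest.fixture(scope="session")
def coded_trials(small_design):
    return generate_dataset(small_design, GenerativeModel(kind="coded"), seed=7)


@pytest.fixture(scope="session")
def coded_table(coded_trials):
    return performance_table(coded_trials)


def noiseless_table_from_curve(curve, set_sizes=(1, 2, 4, 6), delays=(0.1, 1.0, 2.0, 3.0)):
    """Build a PerformanceTable whose cell means follow `curve(K, T)` exactly.

    SEMs are small constants so WLS weighting is well defined; var_norm is a
    placeholder.  Used for self-consistency (noiseless recovery) checks.
    """
    from stmbound.empirical import PerformanceTable

    rows = []
    for k in set_sizes:
        for t in delays:
            rows.append(
                {
                    "set_size": k,
                    "delay_s": t,
                    "mse_norm": curve(k, t),
                    "sem_norm": 1e-4,
                    "var_norm": 1e-6,
                    "n_trials": 100,
                    "n_subjects": 10,
                }
            )
    pts = pd.DataFrame(rows)
    return PerformanceTable(points=pts, baseline_delay=float(min(delays)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
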