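import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from biocombo.core_data import BioassayTable

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_table(rows) -> BioassayTable:
    """Build a validated table from (label, ppm, conidia, rep, day, n, dead) tuples."""
    return BioassayTable(
        pd.DataFrame(
            rows,
            columns=[
                "treatment_label",
                "pyrethrum_ppm",
                "conidia_per_ml",
                "replicate",
                "day",
                "n_start",
                "n_dead_cum",
            ],
        )
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def paper_hyphae_counts():
    """Cadaver counts for the six fungus-treated arms of the published table."""
    from biocombo.ancillary import HyphaeCount

    data = [
        ("epf1e4", 19, 10),
        ("epf1e4+pyr25", 15, 6),
        ("epf1e4+pyr100", 23, 16),
        ("epf1e5", 21, 12),
        ("epf1e5+pyr25", 20, 14),
        ("epf1e5+pyr100", 27, 21),
    ]
    return [HyphaeCount(t, n, y) for t, n, y in data]


@pytest.fixture(scope="session")
def nine_arm_table():
    """One seeded realisation of the full 9-arm combination design."""
    from biocombo.synthetic import SimulationConfig, simulate_combination_experiment

    return simulate_combination_experiment(SimulationConfig(seed=123))


def brute_force_logrank_2group(times1, events1, times2, events2):
    """Independent O/E/V log-rank computation for two groups.

    Direct sum over distinct event times of hypergeometric expectations
    and variances; returns the chi-square statistic.
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    event_times = sorted(set(t1[e1 == 1]) | set(t2[e2 == 1]))
    O = E = V = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        n = n1 + n2
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        d = d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


@pytest.fixture
def logrank_oracle():
    return brute_force_logrank_2group
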