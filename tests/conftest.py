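import numpy as np
import pandas as pd
import pytest

from recensus import (
    PerturbConfig,
    SimConfig,
    build_hierarchy,
    publish_tables,
    simulate_truth,
)


def small_records(n=4, parents=("A", "A", "B", "B")):
    """Minimal fine-unit records: n units, explicit L2 parents, one state."""
    return pd.DataFrame(
        {
            "unit_id": [f"U{i}" for i in range(n)],
            "l2_id": list(parents),
            "l3_id": "L3A",
            "l4_id": "L4A",
            "state_id": "S",
            "ses_decile": [1, 1, 5, 5][:n] if n <= 4 else [1 + i % 10 for i in range(n)],
            "remoteness": "major_cities",
            "centroid_x_km": np.linspace(0, 30, n),
            "centroid_y_km": np.linspace(0, 10, n),
            "pop_age0_9": 50,
            "pop_age10_14": 40,
            "pop_age15_19": 45,
        }
    )


@pytest.fixture
def tiny_hierarchy():
    return build_hierarchy(small_records())


@pytest.fixture(scope="session")
def sim_small():
    """A 40-unit synthetic census reused by read-only tests."""
    cfg = SimConfig(n_fine=40, n_per_l2=4, n_per_l3=5, n_per_l4=2, seed=7)
    h, truth = simulate_truth(cfg)
    tables = publish_tables(h, truth, PerturbConfig(), seed=77)
    return cfg, h, truth, tables
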