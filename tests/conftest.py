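import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_growth_table(curves, day=6, replicates=1, vehicle=100.0):
    """Build a long-format growth table from {line: {conc: mean_viability}}.

    Vehicle rows (concentration 0) at ``vehicle`` are added per line.
    """
    rows = []
    for line, by_conc in curves.items():
        for rep in range(1, replicates + 1):
            rows.append((line, 0.0, day, rep, vehicle))
        for conc, viab in by_conc.items():
            for rep in range(1, replicates + 1):
                rows.append((line, conc, day, rep, viab))
    return pd.DataFrame(rows, columns=["cell_line", "concentration_uM", "day",
                                       "replicate", "viability"])


@pytest.fixture
def simple_growth():
    """Two lines, three doses, responses at 100%/50%/25% and 100%/80%/60%."""
    return make_growth_table({
        "A": {0.01: 100.0, 0.1: 50.0, 1.0: 25.0},
        "B": {0.01: 100.0, 0.1: 80.0, 1.0: 60.0},
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
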