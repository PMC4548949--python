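import numpy as np
import pandas as pd
import pytest

from saltrend import de_screen
from saltrend.synthetic_data import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def study():
    """The default synthetic study used across modules: 1000 genes,
    step 2 log2 units, NB dispersion 0.05, 3 replicates, seed 1."""
    cfg = SimulationConfig(seed=1)
    counts, truth = simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def de_results(study):
    _, counts, _ = study
    conds = counts.condition_order
    pairs = [(conds[0], conds[1]), (conds[0], conds[2]), (conds[1], conds[2])]
    return {f"{a}_vs_{b}": de_screen.pairwise_de(counts, a, b) for a, b in pairs}


@pytest.fixture(scope="session")
def condition_log_means(study):
    """Mean log2 CPM per condition (the trend-clustering input)."""
    _, counts, _ = study
    cpm = de_screen.normalize_cpm(counts)
    return pd.DataFrame(
        {c: np.log2(cpm[counts.samples_of(c)]).mean(axis=1) for c in counts.condition_order}
    )
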