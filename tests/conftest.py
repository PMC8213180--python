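import numpy as np
import pandas as pd
import pytest

import forestmort as fm


@pytest.fixture(scope="session")
def tiny_inventory():
    """Small synthetic inventory with a mild baseline hazard."""
    config = fm.SyntheticConfig(n_plots=8, trees_per_plot_mean=18,
                                n_measurements=3, seed=42)
    hazard = fm.HazardSpec(baseline=0.10)
    trees, plots, climate = fm.generate_inventory(config, hazard)
    return trees, plots, climate


@pytest.fixture(scope="session")
def tiny_model_table(tiny_inventory):
    trees, plots, climate = tiny_inventory
    cov = fm.build_covariate_table(trees, plots, climate)
    kept, _ = fm.qc_filter(cov)
    records, _ = fm.build_survival_records(trees)
    table, _ = fm.build_model_table(kept, records)
    return table


def make_planted_table(n: int, seed: int, threshold: float = 1500.0,
                       low: float = 0.05, high: float = 0.15) -> pd.DataFrame:
    """Direct record-level table with a single planted GDD threshold.

    Much faster than the full inventory generator; used by tree-learner
    tests that do not need the inventory plumbing.
    """
    rng = np.random.default_rng(seed)
    gdd = rng.normal(1500.0, 150.0, n)
    p = np.where(gdd > threshold, high, low)
    return pd.DataFrame({
        "gdd": gdd,
        "pcp": rng.normal(1100.0, 130.0, n),
        "slp": np.abs(rng.normal(10.0, 8.0, n)),
        "species": rng.choice(["FB", "SB", "MR", "BW"], size=n),
        "outcome": (rng.random(n) >= p).astype(int),
    })
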