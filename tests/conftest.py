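import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import salarfit as sf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_fish() -> pd.DataFrame:
    """Hand-built fish table: 4 parents (2 per provenance) and 3 offspring."""
    return pd.DataFrame(
        {
            "fish_id": ["w1", "w2", "c1", "c2", "o1", "o2", "o3"],
            "provenance": ["wild", "wild", "captive", "captive", "wild", "wild", "wild"],
            "sex": ["F", "M", "F", "M", "F", "M", "unknown"],
            "return_year": [1977, 1977, 1977, 1977, 1981, 1981, 1982],
            "sea_age": ["grilse", "MSW", "grilse", "grilse", "grilse", "grilse", "MSW"],
            "fork_length": [61.0, 77.5, 63.0, 60.0, 59.0, 62.0, 80.0],
        }
    )


@pytest.fixture
def small_links() -> pd.DataFrame:
    """Links: o1 has parents w1+w2; o2 has w1+c2; o3 has c1 only."""
    return pd.DataFrame(
        {
            "offspring_id": ["o1", "o1", "o2", "o2", "o3"],
            "parent_id": ["w1", "w2", "w1", "c2", "c1"],
        }
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic pedigree, shared across tests."""
    cfg = sf.SimulationConfig(seed=20260924)
    bundle = sf.simulate_pedigree(cfg)
    fish = sf.assign_spawning_cohorts(bundle.fish)
    lrs = sf.compute_lrs(bundle.parentage, fish)
    return cfg, bundle, fish, lrs


def exhaustive_perm_p(captive, wild, tie_rule="weak"):
    """Independent enumeration oracle: one-tailed p over all label splits."""
    from itertools import combinations

    pooled = list(wild) + list(captive)
    n_w = len(wild)
    obs = np.mean(wild) - np.mean(captive)
    diffs = []
    for idx in combinations(range(len(pooled)), n_w):
        w = [pooled[i] for i in idx]
        c = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diffs.append(np.mean(w) - np.mean(c))
    diffs = np.asarray(diffs)
    tol = 1e-12 + 1e-9 * max(1.0, float(np.abs(diffs).max()))
    if tie_rule == "strict":
        return float(np.mean(diffs > obs + tol))
    return float(np.mean(diffs >= obs - tol))
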